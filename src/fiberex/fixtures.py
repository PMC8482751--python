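"""Synthetic inputs with known ground truth, shared across the pipeline.

Two renderers bridge the exactly-known surrogate states into the inputs
the two classification pipelines consume:

* :func:`render_cv_rows` writes the canonical CV-space signature of each
  state (bulk (2, c), tip (1, c), defect (0.6, 1.3c), exchanged (0, 3c),
  plus Gaussian noise) — the supervised pipeline's oracle input;
* :func:`render_centers` places monomer centers in 3D accordingly
  (defects pushed out of stacking registry, exchanged monomers far from
  the fiber) — the descriptor pipeline's oracle input.

``fixture_suite`` bundles the standard small inputs used throughout the
tests: a 10-monomer perfect stack, a fiber-1/2/3-like surrogate triplet
whose ground-truth equilibrium defect numbers are ~0, ~0.8 and ~12.7,
synthetic CV tables with known labels, and Gaussian-mixture datasets for
the clustering oracles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fiberex import engine, surrogate
from fiberex.monomer import variant_monomer
from fiberex.supervised import CVTable, CV_COLUMNS
from fiberex.surrogate import BULK, DEFECT, SOLVENT, TIP, SurrogateRates

__all__ = [
    "STATE_CV_SIGNATURES",
    "FIBER_TRIPLET_RATES",
    "render_cv_rows",
    "render_centers",
    "fixture_suite",
]

# canonical CV-space signature per state:
# (coordination, min_core_distance [c], core_contacts, dipole_contacts)
STATE_CV_SIGNATURES = {
    BULK: (2.0, 1.0, 2.0, 2.0),
    TIP: (1.0, 1.0, 1.0, 1.0),
    DEFECT: (0.6, 1.3, 0.8, 0.3),
    SOLVENT: (0.0, 3.0, 0.0, 0.0),
}

# surrogate rates emulating the three fiber variants (per microsecond-
# equivalent time unit).  Equilibrium defect numbers for a 40-monomer
# stack: 0, 38*0.3/14.3 ~ 0.80, 38*1/3 ~ 12.7 — the fiber 1 < 2 < 3
# defectiveness ordering.
FIBER_TRIPLET_RATES = {
    1: SurrogateRates(k_bulk_def=0.0, k_def_bulk=14.0),
    2: SurrogateRates(k_bulk_def=0.3, k_def_bulk=14.0),
    3: SurrogateRates(k_bulk_def=1.0, k_def_bulk=2.0),
}


def render_cv_rows(
    states: np.ndarray,
    seed: int = 0,
    noise: float = 0.1,
    c: float = 1.0,
) -> CVTable:
    """Synthetic CV table whose rows carry the canonical state signatures.

    ``states`` is (n_frames, n_monomers) of surrogate state codes; tips
    are the fixed end pair, so the end flags are exact.
    """
    rng = np.random.default_rng(seed)
    n_frames, n_mono = states.shape
    sig = np.array([STATE_CV_SIGNATURES[s] for s in (BULK, DEFECT, TIP, SOLVENT)])
    rows = sig[states.ravel().astype(int)] + rng.normal(0.0, noise, (states.size, 4))
    rows[:, 0] = np.clip(rows[:, 0], 0.0, None)  # coordination >= 0
    rows[:, 1] = np.clip(rows[:, 1], 0.05, None)  # distances > 0
    index = pd.MultiIndex.from_product(
        [range(n_frames), range(n_mono)], names=["frame", "monomer"]
    )
    data = pd.DataFrame(rows * np.array([1.0, c, 1.0, 1.0]), columns=CV_COLUMNS, index=index)
    end_flags = pd.Series((states == TIP).ravel(), index=index)
    return CVTable(data=data, c=c, end_flags=end_flags)


def render_centers(
    states: np.ndarray,
    seed: int = 0,
    c: float = 1.0,
    jitter: float = 0.05,
    defect_offset: float = 1.0,
) -> np.ndarray:
    """3D monomer-center configurations realizing the surrogate states.

    Assembled monomers lie along z at spacing ``c``; defects keep their
    slot but are displaced laterally out of stacking registry (by one
    stacking distance by default); exchanged monomers are scattered at
    least 3c from the fiber axis.  Returns (n_frames, n_monomers, 3).
    """
    rng = np.random.default_rng(seed)
    n_frames, n_mono = states.shape
    out = np.zeros((n_frames, n_mono, 3))
    for f in range(n_frames):
        for m in range(n_mono):
            s = states[f, m]
            base = np.array([0.0, 0.0, m * c])
            if s == DEFECT:
                ang = rng.uniform(0, 2 * np.pi)
                base += defect_offset * c * np.array([np.cos(ang), np.sin(ang), 0.0])
            elif s == SOLVENT:
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(4.0, 8.0) * c
                base = np.array(
                    [rad * np.cos(ang), rad * np.sin(ang), rng.uniform(-2, n_mono + 2) * c]
                )
            out[f, m] = base + rng.normal(0.0, jitter * c, 3)
    return out


def fixture_suite(seed: int = 0) -> dict:
    """The standard bundle of small synthetic inputs used across the tests."""
    rng = np.random.default_rng(seed)
    bundle: dict = {}

    bundle["stack10"] = engine.build_stack(10, spec=variant_monomer(1))

    triplet = {}
    for fiber, rates in FIBER_TRIPLET_RATES.items():
        triplet[fiber] = surrogate.gillespie_stack(
            40, rates, t_end=200.0, seed=seed * 10 + fiber, t_stride=0.01
        )
    bundle["surrogate_triplet"] = triplet

    states = triplet[3].states[::10]
    bundle["cv_table"] = render_cv_rows(states, seed=seed + 1)
    bundle["cv_states"] = states

    blobs = []
    for center in ([0, 0, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]):
        blobs.append(rng.normal(center, 0.05, size=(300, 4)))
    bundle["three_blobs"] = (
        np.concatenate(blobs),
        np.repeat([0, 1, 2], 300),
    )
    bundle["two_gaussians"] = (
        np.concatenate(
            [rng.normal([0, 0], 0.1, (2000, 2)), rng.normal([1, 0], 0.1, (2000, 2))]
        ),
        np.repeat([0, 1], 2000),
    )
    return bundle
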