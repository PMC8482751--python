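"""Minimalistic directional monomer: bead classes, geometry, interactions.

A monomer is a flat core (3-bead equilateral triangle by default, or a
4/9-bead square) carrying one central bead with an embedded point dipole
(two charges +/-q at fixed separation along the core normal), plus
radial side arms of four beads each.  The outer two arm beads are always
solvophilic; the inner two set the monomer's nondirectional
(solvophobic) cohesion and are the single knob distinguishing the three
fiber variants:

* variant 1 — inner beads solvophilic (solvent-identical): the stack is
  held together by the directional dipole alone;
* variant 2 — inner beads mildly solvophobic;
* variant 3 — inner beads strongly solvophobic (amphiphilic arms).

Solvent is implicit: each solvophobicity tier maps to an effective
arm-arm Lennard-Jones well depth, so "more solvophobic" means "more
strongly attracted to other solvophobic beads and less to solvophilic
ones".  All quantities are in reduced Lennard-Jones units (bead diameter
sigma = 1 mapping to ~0.47 nm, energies in units of the reference well
depth epsilon); the dipole charge is in elementary charges with the
screened Coulomb constant below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BeadClass",
    "MonomerSpec",
    "MonomerTopology",
    "BEAD_CLASSES",
    "eps_lookup",
    "make_monomer",
    "variant_monomer",
    "pair_energy",
    "dimerization_free_energy",
    "KE_COULOMB",
]

# Coulomb constant in reduced units: 138.935 kJ/mol nm e^-2 (vacuum) at the
# sigma = 0.47 nm mapping, i.e. 138.935 / 0.47 energy*sigma/e^2, before
# dividing by the relative dielectric.
KE_COULOMB = 138.935 / 0.47

TIER_SOLVOPHILIC, TIER_MILD, TIER_STRONG = 0, 1, 2


@dataclass(frozen=True)
class BeadClass:
    """A coarse-grained bead type.

    ``solvophobicity_tier`` orders the arm chemistries (solvophilic <
    mild < strong); the tier maps strictly to a decreasing effective
    cross-interaction with the solvophilic class (implicit solvent).
    """

    name: str
    sigma: float = 1.0
    charge: float = 0.0
    solvophobicity_tier: int = TIER_SOLVOPHILIC

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def eps_matrix_row(self) -> dict[str, float]:
        return {other: eps_lookup(self.name, other) for other in BEAD_CLASSES}


# Effective (implicit-solvent) LJ well depths, reduced epsilon units.  The
# arm-tier entries are calibrated so that a variant-1 stack is bound almost
# purely by the dipole, while variant-3 arms contribute a nondirectional
# cohesion comparable to the directional term.  Cross-interactions of each
# tier with the solvophilic class decrease strictly with tier.
_EPS: dict[frozenset, float] = {}


def _set_eps(a: str, b: str, value: float) -> None:
    _EPS[frozenset((a, b))] = value


for _pair, _val in [
    # solvophilic arm bead (solvent-identical)
    (("C1", "C1"), 0.08),
    (("C1", "C5"), 0.07),
    (("C1", "N0"), 0.06),
    (("C1", "CORE"), 0.08),
    (("C1", "CENTER"), 0.08),
    # mildly solvophobic
    (("C5", "C5"), 0.30),
    (("C5", "N0"), 0.40),
    (("C5", "CORE"), 0.15),
    (("C5", "CENTER"), 0.08),
    # strongly solvophobic
    (("N0", "N0"), 0.55),
    (("N0", "CORE"), 0.18),
    (("N0", "CENTER"), 0.08),
    # core & center
    (("CORE", "CORE"), 0.30),
    (("CORE", "CENTER"), 0.10),
    (("CENTER", "CENTER"), 0.10),
]:
    _set_eps(*_pair, _val)

# dipole charge sites: Coulomb carriers with a shielding repulsive core so
# opposite sites of different monomers cannot fuse into a Coulomb funnel
for _other in ("C1", "C5", "N0", "CORE", "CENTER"):
    _set_eps("DIP", _other, 0.01)
_set_eps("DIP", "DIP", 0.20)


BEAD_CLASSES: dict[str, BeadClass] = {
    "C1": BeadClass("C1", sigma=1.0, solvophobicity_tier=TIER_SOLVOPHILIC),
    "C5": BeadClass("C5", sigma=1.0, solvophobicity_tier=TIER_MILD),
    "N0": BeadClass("N0", sigma=1.0, solvophobicity_tier=TIER_STRONG),
    "CORE": BeadClass("CORE", sigma=1.0, solvophobicity_tier=TIER_MILD),
    "CENTER": BeadClass("CENTER", sigma=1.0, solvophobicity_tier=TIER_SOLVOPHILIC),
    "DIP": BeadClass("DIP", sigma=0.92, solvophobicity_tier=TIER_SOLVOPHILIC),
}


def eps_lookup(a: str, b: str) -> float:
    return _EPS[frozenset((a, b))]


@dataclass(frozen=True)
class MonomerSpec:
    """Parameters defining one monomer variant."""

    core_shape: str = "triangle3"  # triangle3 | square4 | square9
    core_area_scale: float = 1.0
    dipole_charge: float = 1.45  # elementary charges, calibrated on variant 3
    dipole_separation: float = 0.2  # sigma, fixed; charges at +/- half this
    arm_count: int = 3
    inner_arm_class: str = "N0"
    outer_arm_class: str = "C1"
    relative_dielectric: float = 15.0  # implicit-screening convention

    def __post_init__(self) -> None:
        if self.core_shape not in ("triangle3", "square4", "square9"):
            raise ValueError(
                f"unknown core_shape {self.core_shape!r}: "
                "expected one of 'triangle3', 'square4', 'square9'"
            )
        if self.arm_count not in (3, 4):
            raise ValueError(f"arm_count must be 3 or 4, got {self.arm_count}")
        if BEAD_CLASSES[self.outer_arm_class].solvophobicity_tier != TIER_SOLVOPHILIC:
            raise ValueError("outer_arm_class must be solvophilic")
        if self.dipole_charge <= 0:
            raise ValueError("dipole_charge must be > 0")
        if self.core_area_scale <= 0:
            raise ValueError("core_area_scale must be > 0")


def variant_monomer(variant: int) -> MonomerSpec:
    """The three fiber variants: identical except for the inner arm beads.

    The dipole charge (1.45 e) is the same in all three; only the
    solvophobicity tier of the two inner arm beads changes
    (solvophilic -> mild -> strong).
    """
    inner = {1: "C1", 2: "C5", 3: "N0"}.get(variant)
    if inner is None:
        raise ValueError(f"variant must be 1, 2 or 3, got {variant}")
    return MonomerSpec(inner_arm_class=inner)


# base geometry (reduced sigma units, unscaled core)
_TRIANGLE_SIDE = 1.33
_ARM_BOND = 0.90
_ARM_BEADS = 4  # inner two variable, outer two solvophilic


@dataclass
class MonomerTopology:
    """One monomer in its body frame: beads, bonds, charges, index sets."""

    positions: np.ndarray  # (n_beads, 3)
    classes: list  # bead-class names, len n_beads
    bonds: list  # (i, j, rest_length)
    charges: np.ndarray  # (n_beads,)
    core_indices: list
    arm_indices: list
    center_index: int
    dipole_indices: tuple  # (+q site, -q site)
    spec: MonomerSpec = field(default=None)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def to_json_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "classes": list(self.classes),
            "bonds": [[int(i), int(j), float(r)] for i, j, r in self.bonds],
            "charges": self.charges.tolist(),
            "core_indices": [int(i) for i in self.core_indices],
            "arm_indices": [int(i) for i in self.arm_indices],
            "center_index": int(self.center_index),
            "dipole_indices": [int(i) for i in self.dipole_indices],
        }


def _core_vertices(shape: str, scale: float) -> tuple[np.ndarray, list]:
    """Planar core bead positions (z = 0) and the rigidifying bond pairs."""
    lin = math.sqrt(scale)  # similarity scaling: area scale = linear scale^2
    if shape == "triangle3":
        r = _TRIANGLE_SIDE / math.sqrt(3.0) * lin
        ang = np.deg2rad([90.0, 210.0, 330.0])
        pts = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)], axis=1)
        pairs = [(0, 1), (1, 2), (2, 0)]
    elif shape == "square4":
        # same core area as the reference triangle
        area = math.sqrt(3.0) / 4.0 * _TRIANGLE_SIDE**2 * scale
        a = math.sqrt(area)
        h = a / 2.0
        pts = np.array(
            [[h, h, 0.0], [-h, h, 0.0], [-h, -h, 0.0], [h, -h, 0.0]]
        )
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2), (1, 3)]
    else:  # square9: 3x3 grid, a larger (porphyrin-like) core
        a = 2.0 * _TRIANGLE_SIDE * lin
        xs = np.array([-a / 2, 0.0, a / 2])
        pts = np.array([[x, y, 0.0] for y in xs for x in xs])
        pairs = []
        for i in range(9):
            for j in range(i + 1, 9):
                d = np.linalg.norm(pts[i] - pts[j])
                if d < a * 0.75:  # nearest and diagonal neighbours
                    pairs.append((i, j))
    return pts, pairs


def make_monomer(spec: MonomerSpec) -> MonomerTopology:
    """Build the body-frame topology of one monomer.

    Bead layout: core beads, then the dipole-bearing center bead, then
    the two dipole charge sites, then ``arm_count`` arms of four beads
    (inner two of ``inner_arm_class``, outer two solvophilic).
    """
    core, core_pairs = _core_vertices(spec.core_shape, spec.core_area_scale)
    n_core = core.shape[0]

    positions = [core]
    classes = ["CORE"] * n_core
    center_index = n_core
    positions.append(np.zeros((1, 3)))
    classes.append("CENTER")

    half = spec.dipole_separation / 2.0
    dip_plus, dip_minus = n_core + 1, n_core + 2
    positions.append(np.array([[0.0, 0.0, half], [0.0, 0.0, -half]]))
    classes += ["DIP", "DIP"]

    bonds: list = [(i, j, float(np.linalg.norm(core[i] - core[j]))) for i, j in core_pairs]
    for i in range(n_core):
        bonds.append((i, center_index, float(np.linalg.norm(core[i]))))
    for d, z in ((dip_plus, half), (dip_minus, -half)):
        bonds.append((center_index, d, half))
        for i in range(n_core):
            bonds.append((i, d, float(math.hypot(np.linalg.norm(core[i]), z))))

    # arms grafted radially at the outermost core beads
    radial = np.linalg.norm(core[:, :2], axis=1)
    graft = np.argsort(radial)[-spec.arm_count :][::-1]
    graft = sorted(int(g) for g in graft)
    arm_indices: list = []
    idx = n_core + 3
    arms_pos = []
    for g in graft:
        u = core[g] / np.linalg.norm(core[g])
        prev = g
        first_arm_bead = idx
        for k in range(1, _ARM_BEADS + 1):
            p = core[g] + u * (_ARM_BOND * k)
            arms_pos.append(p)
            cls = spec.inner_arm_class if k <= 2 else spec.outer_arm_class
            classes.append(cls)
            arm_indices.append(idx)
            bonds.append((prev, idx, _ARM_BOND))
            prev = idx
            idx += 1
        # next-nearest bonds keep the arm extended without angle terms
        for k in range(_ARM_BEADS - 2):
            bonds.append((first_arm_bead + k, first_arm_bead + k + 2, 2 * _ARM_BOND))
        bonds.append((center_index, first_arm_bead, float(np.linalg.norm(core[g])) + _ARM_BOND))
    if arms_pos:
        positions.append(np.stack(arms_pos))

    pos = np.concatenate(positions, axis=0)
    charges = np.zeros(pos.shape[0])
    charges[dip_plus] = +spec.dipole_charge
    charges[dip_minus] = -spec.dipole_charge

    # dedupe bonds (graft bead may get a duplicate 1-2/1-3 entry)
    seen = set()
    uniq = []
    for i, j, r in bonds:
        key = (min(i, j), max(i, j))
        if key in seen or i == j:
            continue
        seen.add(key)
        uniq.append((int(key[0]), int(key[1]), float(r)))

    return MonomerTopology(
        positions=pos,
        classes=classes,
        bonds=uniq,
        charges=charges,
        core_indices=list(range(n_core)),
        arm_indices=arm_indices,
        center_index=center_index,
        dipole_indices=(dip_plus, dip_minus),
        spec=spec,
    )


def pair_energy(
    class_i: str | BeadClass,
    class_j: str | BeadClass,
    r: float,
    eps_r: float = 15.0,
    q_i: float = 0.0,
    q_j: float = 0.0,
) -> float:
    """12-6 Lennard-Jones plus screened Coulomb between two beads.

    Plain (uncut) functional forms; the engine applies its own cutoff
    scheme.  Symmetric in its arguments by construction.
    """
    if r <= 0:
        raise ValueError("r must be > 0: the pair potential is singular at r = 0")
    bi = BEAD_CLASSES[class_i] if isinstance(class_i, str) else class_i
    bj = BEAD_CLASSES[class_j] if isinstance(class_j, str) else class_j
    sigma = 0.5 * (bi.sigma + bj.sigma)
    eps = eps_lookup(bi.name, bj.name)
    x6 = (sigma / r) ** 6
    e = 4.0 * eps * (x6 * x6 - x6)
    if q_i != 0.0 and q_j != 0.0:
        e += KE_COULOMB * q_i * q_j / (eps_r * r)
    return e


def dimerization_free_energy(
    spec: MonomerSpec,
    engine_params=None,
    seed: int = 0,
    r_bound: float = 1.1,
    r_max: float = 6.0,
    n_windows: int = 18,
    steps_per_window: int = 4000,
    equil_steps: int = 1000,
    k_restraint: float = 60.0,
    n_blocks: int = 5,
) -> tuple[float, float, dict]:
    """Dimerization free energy of two monomers by restrained mean-force integration.

    Runs Langevin windows with a harmonic restraint on the center-center
    separation from contact (``r_bound``) to ``r_max``, estimates the mean
    force per window from the restraint displacement, and integrates it
    (trapezoid) to obtain the depth of the bound state relative to the
    separated pair.  The statistical error comes from block analysis of
    the per-window mean force.  This is the calibration handle tying the
    dipole charge to a target binding strength.

    Returns ``(delta_g, delta_g_err, info)``; ``delta_g`` < 0 for a bound
    dimer.  Windows whose mean restraint displacement exceeds the window
    spacing are flagged in ``info["unreliable"]``.
    """
    from fiberex import engine as _engine

    if engine_params is None:
        engine_params = _engine.EngineParams(
            timestep=0.005, friction=2.0, temperature=0.3,
            box=(20.0, 20.0, 20.0), seed=seed, n_steps=steps_per_window,
            save_stride=steps_per_window + 1,
        )

    topo = make_monomer(spec)
    centers = np.linspace(r_bound, r_max, n_windows)
    spacing = centers[1] - centers[0]
    mean_forces = np.zeros(n_windows)
    block_err = np.zeros(n_windows)
    unreliable = []

    for w, r0 in enumerate(centers):
        sys_w = _engine.build_dimer(topo, separation=r0)
        p = replace(engine_params, seed=seed * 1000 + w, n_steps=steps_per_window)
        disp = _engine.run_restrained_distance(
            sys_w, p, k_restraint=k_restraint, r0=r0, equil_steps=equil_steps
        )
        # restraint force balances the mean force along r: f = k (<r> - r0)
        f_blocks = k_restraint * (
            np.array([b.mean() for b in np.array_split(disp, n_blocks)]) - r0
        )
        mean_forces[w] = f_blocks.mean()
        block_err[w] = f_blocks.std(ddof=1) / math.sqrt(n_blocks)
        if abs(disp.mean() - r0) > spacing:
            unreliable.append(w)

    # W(r) = integral_r^rmax F dr', so the bound-state depth relative to the
    # separated pair is integral_{r_bound}^{rmax} F dr (negative when bound)
    delta_g = np.trapezoid(mean_forces, centers)
    err = math.sqrt(np.sum((block_err * spacing) ** 2))
    info = {
        "windows": centers.tolist(),
        "mean_forces": mean_forces.tolist(),
        "unreliable": unreliable,
    }
    return float(delta_g), float(err), info
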