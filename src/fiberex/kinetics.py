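"""Rare-event kinetics: infrequent metadynamics and Poisson statistics.

Monomer exchange out of a fiber (and defect creation along it) are rare
events: far too slow to sample by brute force at realistic coupling.
Infrequent well-tempered metadynamics (WT-MetaD) accelerates them by
depositing tempered Gaussian bias on a slow collective variable (here
the core-core coordination number of the escaping monomer) and recovers
the *physical* transition time by exponential reweighting of the
accumulated bias,

    t_phys = sum_i dt * exp(V(s(t_i), t_i) / k_B T).

An ensemble of such rescaled transition times from independent replicas
is expected to be exponentially distributed (rare events are Poisson
processes); ``fit_poisson`` extracts the characteristic time tau by
maximum likelihood and checks the exponential law with a two-sided
Kolmogorov-Smirnov test — the standard reliability check for infrequent
metadynamics estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy import stats

from fiberex.supervised import SwitchingParams, switching

__all__ = [
    "MetaDParams",
    "PoissonFit",
    "MetaDResult",
    "coordination_cv",
    "fit_poisson",
    "pathway_gap",
    "rescaled_time",
    "DoubleWell1D",
    "wtmetad_transition",
    "brute_force_escape",
    "hills_log",
]


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered metadynamics bias parameters.

    Defaults follow the production setup used for fiber escape events
    (hill height in energy units, width in CV units, deposition pace in
    steps, dimensionless bias factor, and the coordination switching
    range r0/dmax).
    """

    hill_height: float = 0.3
    hill_width: float = 0.3
    pace: int = 5000
    bias_factor: float = 20.0
    cv_r0: float = 0.5
    cv_dmax: float = 1.0

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if self.hill_height < 0 or self.hill_width <= 0:
            raise ValueError("hill height must be >= 0 and width > 0")


@dataclass
class PoissonFit:
    """Exponential (cumulative-Poisson) fit of a transition-time ensemble."""

    tau: float
    k: float
    tau_sigma: float
    ks_pvalue: float
    n_samples: int
    n_censored: int = 0


@dataclass
class MetaDResult:
    """One infrequent-WT-MetaD replica."""

    rescaled_time: float
    wall_steps: int
    transitioned: bool  # False = censored (step budget exhausted)
    hills: np.ndarray = None  # (n_hills, 3): deposition time, center, height
    cv_final: float = 0.0


def coordination_cv(
    center_positions: np.ndarray,
    target: int,
    r0: float = 0.5,
    dmax: float = 1.0,
) -> float:
    """Smooth count of other monomer cores within range of the target core.

    ~2 for a perfectly stacked interior monomer, ~1 at a tip or defect,
    ~0 once the monomer has left for the solution.  ``r0``/``dmax`` are in
    the same length units as the positions (for fiber configurations pass
    multiples of the stacking distance).
    """
    params = SwitchingParams(r0=r0, dmax=dmax)
    d = np.linalg.norm(center_positions - center_positions[target], axis=1)
    d = np.delete(d, target)
    return float(np.sum(switching(d, params)))


def fit_poisson(times: Sequence[float], n_censored: int = 0) -> PoissonFit:
    """Maximum-likelihood exponential fit plus a KS reliability check.

    For the exponential law the MLE of tau is the sample mean; the
    KS statistic compares the empirical CDF against 1 - exp(-t/tau).
    Censored replicas (no transition within budget) do not enter the fit
    but inflate the reported uncertainty.
    """
    t = np.asarray(list(times), dtype=float)
    if t.size < 5:
        raise ValueError(
            f"need at least 5 uncensored transition times for a reliable fit, got {t.size}"
        )
    if np.any(t <= 0):
        raise ValueError("transition times must be > 0")
    tau = float(t.mean())
    ks = stats.kstest(t, lambda x: 1.0 - np.exp(-x / tau))
    # relative error of the exponential-mean estimator, inflated by censoring
    sigma = tau / math.sqrt(t.size) * math.sqrt(1.0 + n_censored / t.size)
    return PoissonFit(
        tau=tau,
        k=1.0 / tau,
        tau_sigma=sigma,
        ks_pvalue=float(ks.pvalue),
        n_samples=int(t.size),
        n_censored=int(n_censored),
    )


def rescaled_time(bias_values: np.ndarray, dt: float, kT: float) -> float:
    """Bias-reweighted physical time: dt * sum_i exp(V_i / kT).

    With zero bias this is the plain elapsed time; a static uniform bias
    V0 multiplies the elapsed time by exp(V0/kT).
    """
    return float(dt * np.sum(np.exp(np.asarray(bias_values) / kT)))


def pathway_gap(tau_tip: float, tau_defect_creation: float) -> float:
    """Orders of magnitude separating defect creation from tip exchange.

    Positive when creating a backbone defect is slower than exchanging a
    monomer from the tip.
    """
    if tau_tip <= 0 or tau_defect_creation <= 0:
        raise ValueError("characteristic times must be > 0")
    return math.log10(tau_defect_creation / tau_tip)


# ---------------------------------------------------------------------------
# toy system: 1D double well, the validation ground for the rescaled-time
# estimator (brute-force oracle is affordable here)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _dw_force(x, barrier):
    # V(x) = barrier * (x^2 - 1)^2 ; minima at +-1, barrier height at x=0
    return -4.0 * barrier * x * (x * x - 1.0)


@njit(cache=True)
def _dw_metad(seed, x0, dt, friction, kT, barrier, w0, width, pace, gamma,
              max_steps, x_commit, hill_cap):
    """Underdamped BAOAB on the double well with tempered hills on x.

    Returns (rescaled time, steps, transitioned, n_hills, hills array).
    """
    np.random.seed(seed)
    x = x0
    v = np.random.normal() * math.sqrt(kT)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    centers = np.empty(hill_cap)
    heights = np.empty(hill_cap)
    h_times = np.empty(hill_cap)
    n_h = 0
    t_resc = 0.0
    inv_2w2 = 1.0 / (2.0 * width * width)
    for step in range(1, max_steps + 1):
        # bias potential and force at x
        vb = 0.0
        fb = 0.0
        for h in range(n_h):
            d = x - centers[h]
            g = heights[h] * math.exp(-d * d * inv_2w2)
            vb += g
            fb += g * d * 2.0 * inv_2w2
        f = _dw_force(x, barrier) + fb
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * math.sqrt(kT) * np.random.normal()
        x += 0.5 * dt * v
        # recompute force at new position
        vb = 0.0
        fb = 0.0
        for h in range(n_h):
            d = x - centers[h]
            g = heights[h] * math.exp(-d * d * inv_2w2)
            vb += g
            fb += g * d * 2.0 * inv_2w2
        f = _dw_force(x, barrier) + fb
        v += 0.5 * dt * f
        t_resc += dt * math.exp(vb / kT)
        if x >= x_commit:
            return t_resc, step, True, n_h, h_times[:n_h], centers[:n_h], heights[:n_h]
        if step % pace == 0 and n_h < hill_cap:
            h = w0 * math.exp(-vb / ((gamma - 1.0) * kT))
            centers[n_h] = x
            heights[n_h] = h
            h_times[n_h] = step * dt
            n_h += 1
    return t_resc, max_steps, False, n_h, h_times[:n_h], centers[:n_h], heights[:n_h]


@njit(cache=True)
def _dw_brute(seed, x0, dt, friction, kT, barrier, max_steps, x_commit):
    np.random.seed(seed)
    x = x0
    v = np.random.normal() * math.sqrt(kT)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    for step in range(1, max_steps + 1):
        f = _dw_force(x, barrier)
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * math.sqrt(kT) * np.random.normal()
        x += 0.5 * dt * v
        f = _dw_force(x, barrier)
        v += 0.5 * dt * f
        if x >= x_commit:
            return step * dt, True
    return max_steps * dt, False


@dataclass
class DoubleWell1D:
    """Langevin particle in V(x) = barrier (x^2 - 1)^2 (reduced units)."""

    barrier: float = 6.0
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.005
    x_start: float = -1.0
    x_commit: float = 0.8


def wtmetad_transition(
    system: DoubleWell1D,
    params: MetaDParams,
    seed: int,
    max_steps: int = 5_000_000,
) -> MetaDResult:
    """One infrequent-WT-MetaD escape replica on the toy double well.

    Gaussians of tempered height ``w0 exp(-V/((gamma-1) kT))`` are
    deposited on x every ``pace`` steps; the physical transition time is
    the bias-reweighted elapsed time at the moment the commit threshold
    is crossed.  A replica that exhausts the step budget is returned as
    censored and must be excluded from the Poisson fit.
    """
    t, steps, ok, n_h, h_t, h_c, h_h = _dw_metad(
        seed, system.x_start, system.dt, system.friction, system.kT,
        system.barrier, params.hill_height, params.hill_width, params.pace,
        params.bias_factor, max_steps, system.x_commit,
        max(max_steps // params.pace + 1, 8),
    )
    hills = np.column_stack([h_t, h_c, h_h]) if n_h else np.empty((0, 3))
    return MetaDResult(
        rescaled_time=float(t), wall_steps=int(steps), transitioned=bool(ok),
        hills=hills,
    )


def brute_force_escape(
    system: DoubleWell1D,
    seed: int,
    max_steps: int = 50_000_000,
) -> tuple[float, bool]:
    """Unbiased escape time over the same barrier (the oracle)."""
    t, ok = _dw_brute(
        seed, system.x_start, system.dt, system.friction, system.kT,
        system.barrier, max_steps, system.x_commit,
    )
    return float(t), bool(ok)


def hills_log(hills: np.ndarray, params: MetaDParams) -> str:
    """HILLS-style text block: time, center, width, height, bias factor."""
    lines = ["#! FIELDS time center sigma height biasf"]
    for t, c, h in hills:
        lines.append(f"{t:.6f} {c:.6f} {params.hill_width:.6f} {h:.6f} {params.bias_factor:.1f}")
    return "\n".join(lines) + "\n"


def fiber_escape_wtmetad(
    sys_,
    params,
    target: int,
    metad: MetaDParams,
    seed: int,
    max_steps: int = 2_000_000,
    cv_stop: float = 0.2,
    dwell_segments: int = 3,
    escape_distance_factor: float = 2.0,
) -> MetaDResult:
    """Infrequent WT-MetaD escape of one monomer from a particle-engine fiber.

    The bias acts on the target monomer's core-core coordination number
    (switching range ``metad.cv_r0``/``metad.cv_dmax`` in absolute length
    units, i.e. multiples of the stacking distance when positions are in
    those units).  Hills are deposited every ``metad.pace`` steps with
    tempered heights; the run commits to "escaped" once the CV stays
    below ``cv_stop`` for ``dwell_segments`` consecutive deposition
    intervals and the target's nearest core lies beyond
    ``escape_distance_factor`` stacking distances.  Returns the
    bias-rescaled physical escape time (censored if the step budget runs
    out first).
    """
    from fiberex import engine as _engine

    pos = sys_.positions.copy()
    rng = np.random.default_rng(seed)
    vel = rng.normal(size=pos.shape) * math.sqrt(params.temperature)
    vel -= vel.mean(axis=0)

    cap = max_steps // metad.pace + 2
    h_centers = np.zeros(cap)
    h_heights = np.zeros(cap)
    h_times = np.zeros(cap)
    n_h = 0
    t_resc = 0.0
    steps = 0
    dwell = 0
    kT = params.temperature
    c_est = _engine.DEFAULT_STACKING_DISTANCE

    while steps < max_steps:
        dt_r, s_cv = _engine._metad_segment(
            pos, vel, sys_.masses, sys_.class_idx, sys_.charges,
            sys_.monomer_id, sys_.bond_i, sys_.bond_j, sys_.bond_r0,
            sys_.bond_k, np.array(params.box), params.timestep,
            params.friction, kT, metad.pace,
            int(rng.integers(2**31)),
            _engine._EPS_TAB, _engine._SIG_TAB, _engine._SHIFT_TAB,
            _engine.KE_COULOMB / sys_.eps_r,
            sys_.center_indices, target, metad.cv_r0, metad.cv_dmax,
            h_centers, h_heights, metad.hill_width, n_h,
        )
        t_resc += dt_r
        steps += metad.pace

        centers = pos[sys_.center_indices]
        d = np.linalg.norm(centers - centers[target], axis=1)
        d[target] = np.inf
        far = d.min() > escape_distance_factor * c_est
        dwell = dwell + 1 if (s_cv < cv_stop and far) else 0
        if dwell >= dwell_segments:
            hills = np.column_stack([h_times[:n_h], h_centers[:n_h], h_heights[:n_h]])
            return MetaDResult(
                rescaled_time=float(t_resc), wall_steps=steps, transitioned=True,
                hills=hills, cv_final=float(s_cv),
            )
        # deposit a tempered hill at the current CV
        vbias = float(
            np.sum(
                h_heights[:n_h]
                * np.exp(-((s_cv - h_centers[:n_h]) ** 2) / (2 * metad.hill_width**2))
            )
        )
        if n_h < cap:
            h_centers[n_h] = s_cv
            h_heights[n_h] = metad.hill_height * math.exp(
                -vbias / ((metad.bias_factor - 1.0) * kT)
            )
            h_times[n_h] = steps * params.timestep
            n_h += 1

    hills = np.column_stack([h_times[:n_h], h_centers[:n_h], h_heights[:n_h]])
    return MetaDResult(
        rescaled_time=float(t_resc), wall_steps=steps, transitioned=False,
        hills=hills, cv_final=0.0,
    )
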