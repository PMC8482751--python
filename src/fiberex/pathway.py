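"""Kinetic decision layer: tips-vs-backbone exchange pathway.

A dynamic 1D fiber of ``N_tot`` monomers exchanges monomers with the
solution either from its two tips (single-step tip->solvent events) or
from transient stacking defects along the backbone (bulk->defect
followed by defect->solvent).  Which pathway dominates statistically is
decided by the dimensionless ratio of the two exchange fluxes,

    alpha = (N_def * k_def_sol) / (N_tip * k_tip_sol),     N_tip = 2,

where ``N_def`` is the equilibrium mean number of backbone defects.  At
equilibrium, per-monomer creation/annihilation balance
``N_bulk * k_bulk_def = N_def * k_def_bulk`` with
``N_bulk = N_tot - 2 - N_def`` fixes

    N_def = (N_tot - 2) * k_bulk_def / (k_bulk_def + k_def_bulk),

so alpha can be written purely in terms of rate constants and the fiber
length.  ``alpha > 1`` means backbone exchange is statistically
favoured; the fiber length at which that first happens is the crossover
length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "RateSet",
    "PathwayReport",
    "alpha",
    "ndef_equilibrium",
    "alpha_combined",
    "crossover_length",
    "pathway_report",
]

N_TIP = 2  # a linear, unbroken fiber has exactly two tips


@dataclass(frozen=True)
class RateSet:
    """The four rate constants of the exchange scheme, with 1-sigma errors.

    Rates are in inverse time units (any consistent choice); ``N_tot`` is
    the number of monomers in the fiber.
    """

    k_tip_sol: float
    k_def_sol: float
    k_bulk_def: float
    k_def_bulk: float
    n_tot: int = 40
    sigma_tip_sol: float = 0.0
    sigma_def_sol: float = 0.0
    sigma_bulk_def: float = 0.0
    sigma_def_bulk: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_tip_sol", "k_def_sol", "k_bulk_def", "k_def_bulk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_tot < 3:
            raise ValueError(f"n_tot must be >= 3, got {self.n_tot}")


@dataclass
class PathwayReport:
    """Verdict of the pathway analysis plus everything that went into it."""

    alpha: float
    alpha_sigma: float
    n_def: float
    n_bulk: float
    n_tot: int
    verdict: str  # TIPS | BACKBONE | COMPETING
    crossover_n: float
    consistency_ratio: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_sigma": self.alpha_sigma,
            "n_def": self.n_def,
            "n_bulk": self.n_bulk,
            "n_tot": self.n_tot,
            "verdict": self.verdict,
            "crossover_n": self.crossover_n,
            "consistency_ratio": self.consistency_ratio,
            "provenance": self.provenance,
        }


def alpha(n_def: float, k_def_sol: float, k_tip_sol: float) -> float:
    """Ratio of defect-pathway to tip-pathway exchange flux.

    ``alpha > 1`` means the fiber statistically swaps monomers from
    backbone defects rather than from its two tips.
    """
    if k_tip_sol <= 0:
        raise ValueError("k_tip_sol must be > 0: alpha is undefined without a tip pathway")
    if n_def < 0 or k_def_sol < 0:
        raise ValueError("n_def and k_def_sol must be >= 0")
    return (n_def * k_def_sol) / (N_TIP * k_tip_sol)


def ndef_equilibrium(n_tot: int, k_bulk_def: float, k_def_bulk: float) -> float:
    """Stationary mean number of backbone defects from creation/annihilation balance."""
    if n_tot < 3:
        raise ValueError(f"n_tot must be >= 3, got {n_tot}")
    if k_bulk_def < 0 or k_def_bulk < 0:
        raise ValueError("rates must be >= 0")
    if k_bulk_def + k_def_bulk <= 0:
        raise ValueError("k_bulk_def + k_def_bulk must be > 0")
    return (n_tot - N_TIP) * k_bulk_def / (k_bulk_def + k_def_bulk)


def alpha_combined(rates: RateSet) -> tuple[float, float]:
    """alpha written purely in rate constants (and fiber length).

    Substitutes the equilibrium defect number into the flux ratio:

        alpha = (N_tot - 2) * k_bd / (k_bd + k_db) * k_def_sol / (2 k_tip_sol)

    Returns ``(alpha, sigma_alpha)`` with the uncertainty propagated to
    first order (delta method, rate estimates assumed independent).
    """
    n_def = ndef_equilibrium(rates.n_tot, rates.k_bulk_def, rates.k_def_bulk)
    a = alpha(n_def, rates.k_def_sol, rates.k_tip_sol)
    # d ln(alpha) building blocks; alpha = C * kbd/(kbd+kdb) * kds / kts
    kbd, kdb = rates.k_bulk_def, rates.k_def_bulk
    rel_var = 0.0
    if a > 0:
        if rates.sigma_def_sol and rates.k_def_sol > 0:
            rel_var += (rates.sigma_def_sol / rates.k_def_sol) ** 2
        if rates.sigma_tip_sol:
            rel_var += (rates.sigma_tip_sol / rates.k_tip_sol) ** 2
        if kbd > 0:
            # d ln a / d kbd = 1/kbd - 1/(kbd+kdb) = kdb / (kbd (kbd+kdb))
            rel_var += (rates.sigma_bulk_def * kdb / (kbd * (kbd + kdb))) ** 2
            rel_var += (rates.sigma_def_bulk / (kbd + kdb)) ** 2
    return a, a * math.sqrt(rel_var)


def crossover_length(
    k_bulk_def: float,
    k_def_bulk: float,
    k_def_sol: float,
    k_tip_sol: float,
) -> float:
    """Smallest fiber length (in monomers) at which backbone exchange wins.

    Solves ``alpha(N_tot) = 1`` for the combined form and returns the
    smallest integer ``N_tot`` with ``alpha >= 1``; ``math.inf`` when the
    per-monomer defect probability vanishes.
    """
    for name, k in (
        ("k_def_bulk", k_def_bulk),
        ("k_def_sol", k_def_sol),
        ("k_tip_sol", k_tip_sol),
    ):
        if k < 0:
            raise ValueError(f"{name} must be >= 0")
    if k_tip_sol <= 0:
        raise ValueError("k_tip_sol must be > 0")
    p_def = k_bulk_def / (k_bulk_def + k_def_bulk)  # per-monomer defect probability
    if p_def <= 0 or k_def_sol <= 0:
        return math.inf
    # (N - 2) * p_def * k_ds / (2 k_ts) >= 1
    n_real = 2.0 + 2.0 * k_tip_sol / (p_def * k_def_sol)
    return float(math.ceil(n_real))


def _verdict(a: float, sigma: float) -> str:
    if a - sigma <= 1.0 <= a + sigma:
        return "COMPETING"
    return "BACKBONE" if a > 1.0 else "TIPS"


def pathway_report(
    rates: RateSet,
    measured_n_def: Optional[float] = None,
    measured_n_def_sigma: float = 0.0,
) -> PathwayReport:
    """Full pathway analysis from a rate set and (optionally) a measured defect count.

    When a measured equilibrium defect number is supplied, alpha uses it
    directly and the equilibrium-balance prediction is reported as a
    consistency ratio (prediction / measurement; ~1 at equilibrium).
    Otherwise alpha comes from the rates-only combined form.
    """
    have_creation = rates.k_bulk_def + rates.k_def_bulk > 0
    if measured_n_def is None and not have_creation:
        raise ValueError(
            "insufficient inputs: need measured_n_def or nonzero "
            "(k_bulk_def, k_def_bulk) creation/annihilation rates"
        )

    n_def_pred = (
        ndef_equilibrium(rates.n_tot, rates.k_bulk_def, rates.k_def_bulk)
        if have_creation
        else None
    )

    consistency = None
    if measured_n_def is not None:
        n_def = measured_n_def
        a = alpha(n_def, rates.k_def_sol, rates.k_tip_sol)
        rel_var = 0.0
        if a > 0:
            if measured_n_def_sigma and n_def > 0:
                rel_var += (measured_n_def_sigma / n_def) ** 2
            if rates.sigma_def_sol and rates.k_def_sol > 0:
                rel_var += (rates.sigma_def_sol / rates.k_def_sol) ** 2
            if rates.sigma_tip_sol:
                rel_var += (rates.sigma_tip_sol / rates.k_tip_sol) ** 2
        sigma = a * math.sqrt(rel_var)
        if n_def_pred is not None and measured_n_def > 0:
            consistency = n_def_pred / measured_n_def
        source = "measured_n_def"
    else:
        n_def = n_def_pred
        a, sigma = alpha_combined(rates)
        source = "equilibrium_balance"

    crossover = crossover_length(
        rates.k_bulk_def, rates.k_def_bulk, rates.k_def_sol, rates.k_tip_sol
    )
    return PathwayReport(
        alpha=a,
        alpha_sigma=sigma,
        n_def=n_def,
        n_bulk=rates.n_tot - N_TIP - n_def,
        n_tot=rates.n_tot,
        verdict=_verdict(a, sigma),
        crossover_n=crossover,
        consistency_ratio=consistency,
        provenance={"n_def_source": source},
    )
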