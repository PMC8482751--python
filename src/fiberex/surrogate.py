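"""Continuous-time Markov surrogate of a defect-forming fiber.

The surrogate stands in for long coarse-grained MD runs: a stack of
``n_tot`` monomers whose two end monomers are tips and whose interior
monomers interconvert independently between an ordered BULK state and a
DEFECT state at rates ``k_bulk_def`` (creation) and ``k_def_bulk``
(annihilation).  With exchange enabled, tips escape to the solution at
``k_tip_sol`` and defects at ``k_def_sol``; when a tip escapes its inner
neighbour becomes the new tip, so an unbroken stack always carries
exactly two tips.  Every transition is realised exactly (Gillespie /
stochastic simulation algorithm), so all downstream estimators —
rate-matrix counting, Poisson fits, the equilibrium defect number — can
be checked against known ground truth.

The per-monomer independence mirrors the well-mixed kinetic scheme the
pathway model itself assumes; the surrogate deliberately contains no
spatial coupling between neighbouring defects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "BULK",
    "DEFECT",
    "TIP",
    "SOLVENT",
    "STATE_NAMES",
    "SurrogateRates",
    "StateTrajectory",
    "gillespie_stack",
    "first_escape_times",
]

BULK, DEFECT, TIP, SOLVENT = 0, 1, 2, 3
STATE_NAMES = {BULK: "BULK", DEFECT: "DEFECT", TIP: "TIP", SOLVENT: "SOLVENT"}
_NAME_CODES = {v: k for k, v in STATE_NAMES.items()}


@dataclass(frozen=True)
class SurrogateRates:
    """Ground-truth rates of the kinetic scheme (inverse time units).

    ``k_readsorb`` is non-physical plumbing: an optional solvent->tip
    re-adsorption channel that keeps the assembled count roughly constant
    in long exchange-on runs.
    """

    k_bulk_def: float = 0.3
    k_def_bulk: float = 14.0
    k_tip_sol: float = 0.0
    k_def_sol: float = 0.0
    exchange_enabled: bool = False
    k_readsorb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_bulk_def", "k_def_bulk", "k_tip_sol", "k_def_sol", "k_readsorb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class StateTrajectory:
    """Per-monomer categorical states sampled on a fixed time grid.

    ``states`` is an ``(n_frames, n_monomers)`` int array of state codes;
    ``event_log`` records every exact transition as
    ``(time, monomer_id, from_code, to_code)``.
    """

    states: np.ndarray
    t_stride: float
    event_log: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.states.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.t_stride

    def counts(self, code: int) -> np.ndarray:
        """Per-frame number of monomers in a given state."""
        return (self.states == code).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, monomer_id, state) table in deterministic row order."""
        n_f, n_m = self.states.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n_m),
                "monomer_id": np.tile(np.arange(n_m), n_f),
                "state": [STATE_NAMES[c] for c in self.states.ravel()],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def events_to_csv(self, path) -> None:
        pd.DataFrame(
            self.event_log, columns=["time", "monomer_id", "from", "to"]
        ).assign(
            **{
                "from": lambda d: d["from"].map(STATE_NAMES),
                "to": lambda d: d["to"].map(STATE_NAMES),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, t_stride: Optional[float] = None) -> "StateTrajectory":
        df = pd.read_csv(path)
        times = np.unique(df["time"].to_numpy())
        monomers = np.unique(df["monomer_id"].to_numpy())
        states = np.empty((times.size, monomers.size), dtype=np.int8)
        codes = df["state"].map(_NAME_CODES).to_numpy()
        t_idx = np.searchsorted(times, df["time"].to_numpy())
        m_idx = np.searchsorted(monomers, df["monomer_id"].to_numpy())
        states[t_idx, m_idx] = codes
        if t_stride is None:
            t_stride = float(times[1] - times[0]) if times.size > 1 else 1.0
        return cls(states=states, t_stride=t_stride)


def gillespie_stack(
    n_tot: int,
    rates: SurrogateRates,
    t_end: float,
    seed: int,
    t_stride: float = 0.01,
) -> StateTrajectory:
    """Exact stochastic realization of the stack's kinetic scheme.

    Starts from a defect-free stack (two tips, ``n_tot - 2`` bulk) and
    simulates independent per-monomer transitions until ``t_end``,
    sampling frames every ``t_stride``.
    """
    if n_tot < 3:
        raise ValueError(f"n_tot must be >= 3, got {n_tot}")
    if t_end <= 0 or t_stride <= 0:
        raise ValueError("t_end and t_stride must be > 0")

    rng = np.random.default_rng(seed)
    # stack order: list of monomer ids, ends are tips
    order = list(range(n_tot))
    state = np.full(n_tot, BULK, dtype=np.int8)
    state[order[0]] = TIP
    state[order[-1]] = TIP

    n_frames = int(np.floor(t_end / t_stride)) + 1
    frames = np.empty((n_frames, n_tot), dtype=np.int8)
    events: list = []

    t = 0.0
    next_frame = 0
    while True:
        # channel rates in the current configuration
        bulk_ids = np.flatnonzero(state == BULK)
        def_ids = np.flatnonzero(state == DEFECT)
        sol_ids = np.flatnonzero(state == SOLVENT)
        r_create = rates.k_bulk_def * bulk_ids.size
        r_annih = rates.k_def_bulk * def_ids.size
        r_tip = r_def_esc = r_ads = 0.0
        if rates.exchange_enabled and len(order) >= 2:
            r_tip = rates.k_tip_sol * 2
            r_def_esc = rates.k_def_sol * def_ids.size
            r_ads = rates.k_readsorb * sol_ids.size
        r_tot = r_create + r_annih + r_tip + r_def_esc + r_ads

        if r_tot <= 0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / r_tot)

        # emit frames up to the next event (or the end of the run)
        while next_frame < n_frames and next_frame * t_stride <= min(t_next, t_end):
            frames[next_frame] = state
            next_frame += 1
        if t_next > t_end or next_frame >= n_frames and t_next == np.inf:
            break
        if t_next > t_end:
            break
        t = t_next

        u = rng.uniform(0.0, r_tot)
        if u < r_create:
            m = bulk_ids[rng.integers(bulk_ids.size)]
            events.append((t, int(m), BULK, DEFECT))
            state[m] = DEFECT
        elif u < r_create + r_annih:
            m = def_ids[rng.integers(def_ids.size)]
            events.append((t, int(m), DEFECT, BULK))
            state[m] = BULK
        elif u < r_create + r_annih + r_tip:
            end = 0 if rng.uniform() < 0.5 else -1
            m = order[end]
            events.append((t, int(m), TIP, SOLVENT))
            state[m] = SOLVENT
            order.pop(end)
            if len(order) >= 2:
                new_tip = order[0 if end == 0 else -1]
                if state[new_tip] != TIP:
                    events.append((t, int(new_tip), int(state[new_tip]), TIP))
                    state[new_tip] = TIP
        elif u < r_create + r_annih + r_tip + r_def_esc:
            m = def_ids[rng.integers(def_ids.size)]
            events.append((t, int(m), DEFECT, SOLVENT))
            state[m] = SOLVENT
            order.remove(int(m))
        else:
            m = sol_ids[rng.integers(sol_ids.size)]
            end = 0 if rng.uniform() < 0.5 else -1
            old_tip = order[end]
            events.append((t, int(old_tip), TIP, BULK))
            state[old_tip] = BULK
            events.append((t, int(m), SOLVENT, TIP))
            state[m] = TIP
            order.insert(0 if end == 0 else len(order), int(m))

    # pad any remaining frames with the final (absorbing) configuration
    while next_frame < n_frames:
        frames[next_frame] = state
        next_frame += 1

    return StateTrajectory(states=frames, t_stride=t_stride, event_log=events)


def first_escape_times(
    rates: SurrogateRates,
    origin: str,
    n_replicas: int,
    seed: int,
) -> np.ndarray:
    """I.i.d. first-escape times from a tip or a defect: exponential ground truth.

    These are the oracle inputs for the Poisson-fit stage; ``origin`` is
    ``"TIP"`` or ``"DEFECT"``.
    """
    k = {"TIP": rates.k_tip_sol, "DEFECT": rates.k_def_sol}.get(origin)
    if k is None:
        raise ValueError(f"origin must be 'TIP' or 'DEFECT', got {origin!r}")
    if k <= 0:
        raise ValueError(f"escape rate for origin {origin} must be > 0")
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / k, size=n_replicas)
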