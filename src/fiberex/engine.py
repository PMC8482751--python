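"""Langevin dynamics of semi-rigid directional monomers in implicit solvent.

The integrator is BAOAB-splitting Langevin (reducing to velocity Verlet
at zero friction), with truncated-shifted Lennard-Jones, shifted-force
Coulomb for the dipole charge sites, stiff harmonic bonds providing the
semi-rigid monomer scaffold, periodic boundaries with minimum-image
convention, and a Verlet neighbour list.  Intra-monomer nonbonded pairs
are excluded: the bonded scaffold alone fixes the monomer shape, and the
exclusion keeps arms from collapsing onto their own core.

All quantities are in reduced units (sigma, epsilon, bead mass m = 1,
time tau = sigma sqrt(m/epsilon)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from fiberex.monomer import (
    BEAD_CLASSES,
    KE_COULOMB,
    MonomerSpec,
    MonomerTopology,
    eps_lookup,
    make_monomer,
)

__all__ = [
    "EngineParams",
    "System",
    "Trajectory",
    "build_stack",
    "build_dimer",
    "run_ld",
    "run_restrained_distance",
    "potential_energy",
    "kinetic_temperature",
    "DEFAULT_STACKING_DISTANCE",
]

CLASS_ORDER = ["C1", "C5", "N0", "CORE", "CENTER", "DIP"]
_CLASS_IDX = {name: i for i, name in enumerate(CLASS_ORDER)}

RC_LJ = 2.5  # LJ cutoff, units of the pair sigma
RC_COUL = 2.34  # Coulomb shifted-force cutoff (1.1 nm at sigma = 0.47 nm)
K_BOND = 400.0  # scaffold bond stiffness, epsilon/sigma^2
K_BOND_DIPOLE = 2000.0  # dipole-cage bonds: must out-pull the Coulomb gradient
NLIST_SKIN = 0.6
NLIST_EVERY = 20

# equilibrium center-center stacking distance of the default parametrization
DEFAULT_STACKING_DISTANCE = 1.12


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(CLASS_ORDER)
    eps = np.zeros((n, n))
    sig = np.zeros((n, n))
    for i, a in enumerate(CLASS_ORDER):
        for j, b in enumerate(CLASS_ORDER):
            eps[i, j] = eps_lookup(a, b)
            sig[i, j] = 0.5 * (BEAD_CLASSES[a].sigma + BEAD_CLASSES[b].sigma)
    rc = RC_LJ * sig
    x6 = (sig / rc) ** 6
    shift = 4.0 * eps * (x6 * x6 - x6)
    return eps, sig, shift


_EPS_TAB, _SIG_TAB, _SHIFT_TAB = _pair_tables()


@dataclass(frozen=True)
class EngineParams:
    """Integration parameters (reduced units)."""

    timestep: float = 0.004
    friction: float = 1.0
    temperature: float = 0.35  # k_B T in epsilon
    box: tuple = (30.0, 30.0, 60.0)
    seed: int = 0
    n_steps: int = 10_000
    save_stride: int = 200

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if min(self.box) < 2 * RC_LJ:
            raise ValueError("box edges must exceed twice the interaction cutoff")


@dataclass
class System:
    """A collection of monomers flattened into per-bead arrays."""

    positions: np.ndarray  # (n, 3)
    class_idx: np.ndarray  # (n,) int
    charges: np.ndarray
    masses: np.ndarray
    monomer_id: np.ndarray  # (n,) int
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    center_indices: np.ndarray  # per-monomer center bead, (n_monomers,)
    core_indices_by_monomer: list
    dipole_indices_by_monomer: list
    topology: MonomerTopology = None
    eps_r: float = 15.0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.center_indices.shape[0]


@dataclass
class Trajectory:
    """Saved frames of a Langevin run."""

    frames: np.ndarray  # (n_frames, n_beads, 3)
    times: np.ndarray  # (n_frames,)
    system: System = None
    velocities: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def t_stride(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    def center_positions(self) -> np.ndarray:
        """(n_frames, n_monomers, 3) positions of the monomer center beads."""
        return self.frames[:, self.system.center_indices, :]


def _assemble(placed: list, topo: MonomerTopology, eps_r: float) -> System:
    """Flatten copies of one topology at given rigid placements."""
    n_per = topo.n_beads
    n_mono = len(placed)
    pos = np.concatenate(placed, axis=0)
    class_idx = np.tile(np.array([_CLASS_IDX[c] for c in topo.classes]), n_mono)
    charges = np.tile(topo.charges, n_mono)
    masses = np.ones(n_per * n_mono)
    mono_id = np.repeat(np.arange(n_mono), n_per)
    dip_set = set(topo.dipole_indices)
    bi, bj, br, bk = [], [], [], []
    for m in range(n_mono):
        off = m * n_per
        for i, j, r in topo.bonds:
            bi.append(i + off)
            bj.append(j + off)
            br.append(r)
            bk.append(K_BOND_DIPOLE if (i in dip_set or j in dip_set) else K_BOND)
    centers = np.array([topo.center_index + m * n_per for m in range(n_mono)])
    return System(
        positions=pos,
        class_idx=class_idx.astype(np.int64),
        charges=charges,
        masses=masses,
        monomer_id=mono_id.astype(np.int64),
        bond_i=np.array(bi, dtype=np.int64),
        bond_j=np.array(bj, dtype=np.int64),
        bond_r0=np.array(br, dtype=np.float64),
        bond_k=np.array(bk, dtype=np.float64),
        center_indices=centers,
        core_indices_by_monomer=[
            [i + m * n_per for i in topo.core_indices] for m in range(n_mono)
        ],
        dipole_indices_by_monomer=[
            [i + m * n_per for i in topo.dipole_indices] for m in range(n_mono)
        ],
        topology=topo,
        eps_r=eps_r,
    )


def build_stack(
    n_monomers: int,
    stacking_distance: float = DEFAULT_STACKING_DISTANCE,
    spec: Optional[MonomerSpec] = None,
    box: tuple = (30.0, 30.0, 60.0),
) -> System:
    """A perfect coaxial stack along z, cores parallel, arms extended radially.

    Neighbouring monomer centers sit exactly ``stacking_distance`` apart.
    """
    if n_monomers < 2:
        raise ValueError("n_monomers must be >= 2")
    if stacking_distance < 0.5:
        raise ValueError(
            f"stacking distance {stacking_distance} is below the core thickness"
        )
    spec = spec or MonomerSpec()
    topo = make_monomer(spec)
    z0 = -0.5 * (n_monomers - 1) * stacking_distance
    placed = []
    for m in range(n_monomers):
        p = topo.positions.copy()
        p[:, 2] += z0 + m * stacking_distance
        placed.append(p)
    sys_ = _assemble(placed, topo, spec.relative_dielectric)
    sys_.positions -= sys_.positions.mean(axis=0)  # center in the box frame
    _check_overlaps(sys_)
    return sys_


def build_dimer(topo: MonomerTopology, separation: float) -> System:
    """Two coaxial monomers at a given center-center separation (PMF windows)."""
    p1 = topo.positions.copy()
    p2 = topo.positions.copy()
    p1[:, 2] -= separation / 2.0
    p2[:, 2] += separation / 2.0
    return _assemble([p1, p2], topo, topo.spec.relative_dielectric)


def _check_overlaps(sys_: System, dmin: float = 0.8) -> None:
    # different-monomer bead pairs must not overlap in the initial build
    pos = sys_.positions
    for m in range(sys_.n_monomers - 1):
        a = pos[sys_.monomer_id == m]
        b = pos[sys_.monomer_id == m + 1]
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        if d.min() <= dmin * 0.75:  # sigma scaled: beads are soft below 0.8 sigma
            raise ValueError(f"bead overlap between monomers {m} and {m+1}: {d.min():.3f}")


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _build_pairs(pos, mono_id, box, rc_list):
    n = pos.shape[0]
    cap = n * 80
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    cnt = 0
    rc2 = rc_list * rc_list
    for i in range(n):
        for j in range(i + 1, n):
            if mono_id[i] == mono_id[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            if dx * dx + dy * dy + dz * dz < rc2:
                if cnt >= cap:
                    # grow
                    new_cap = cap * 2
                    npi = np.empty(new_cap, dtype=np.int64)
                    npj = np.empty(new_cap, dtype=np.int64)
                    npi[:cnt] = pi[:cnt]
                    npj[:cnt] = pj[:cnt]
                    pi, pj, cap = npi, npj, new_cap
                pi[cnt] = i
                pj[cnt] = j
                cnt += 1
    return pi[:cnt], pj[:cnt]


@njit(cache=True)
def _forces_nonbonded(pos, class_idx, charges, box, eps_tab, sig_tab, shift_tab,
                      ke_over_epsr, pair_i, pair_j, forces):
    e = 0.0
    rc_c = RC_COUL
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            continue
        ci = class_idx[i]
        cj = class_idx[j]
        sig = sig_tab[ci, cj]
        rc = RC_LJ * sig
        fr = 0.0  # force magnitude / r
        if r2 < rc * rc:
            inv_r2 = 1.0 / r2
            s2 = sig * sig * inv_r2
            s6 = s2 * s2 * s2
            eps = eps_tab[ci, cj]
            e += 4.0 * eps * (s6 * s6 - s6) - shift_tab[ci, cj]
            fr += 24.0 * eps * (2.0 * s6 * s6 - s6) * inv_r2
        qq = charges[i] * charges[j]
        if qq != 0.0 and r2 < rc_c * rc_c:
            r = math.sqrt(r2)
            pref = ke_over_epsr * qq
            # shifted-force: V = pref (1/r - 1/rc + (r - rc)/rc^2)
            e += pref * (1.0 / r - 1.0 / rc_c + (r - rc_c) / (rc_c * rc_c))
            fr += pref * (1.0 / r2 - 1.0 / (rc_c * rc_c)) / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return e


@njit(cache=True)
def _forces_bonded(pos, bond_i, bond_j, bond_r0, bond_k, forces):
    e = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        k_b = bond_k[b]
        dr = r - bond_r0[b]
        e += 0.5 * k_b * dr * dr
        fr = -k_b * dr / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return e


@njit(cache=True)
def _run_kernel(pos, vel, masses, class_idx, charges, mono_id,
                bond_i, bond_j, bond_r0, bond_k,
                box, dt, friction, kT, n_steps, save_stride, seed,
                eps_tab, sig_tab, shift_tab, ke_over_epsr,
                restr_on, restr_a, restr_b, restr_k, restr_r0, sample_stride):
    """BAOAB Langevin loop; returns (frames, vel frames, times, restraint samples, status).

    status: 0 ok, frame index of failure otherwise (force blow-up / NaN).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_frames = n_steps // save_stride + 1
    frames = np.empty((n_frames, n, 3))
    vframes = np.empty((n_frames, n, 3))
    times = np.empty(n_frames)
    n_samp = n_steps // sample_stride if restr_on else 0
    samples = np.empty(max(n_samp, 1))

    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))

    forces = np.zeros((n, 3))
    _forces_bonded(pos, bond_i, bond_j, bond_r0, bond_k, forces)
    pi, pj = _build_pairs(pos, mono_id, box, RC_LJ + NLIST_SKIN)
    _forces_nonbonded(pos, class_idx, charges, box, eps_tab, sig_tab, shift_tab,
                      ke_over_epsr, pi, pj, forces)
    if restr_on:
        dxr = pos[restr_a] - pos[restr_b]
        rr = math.sqrt(dxr[0] ** 2 + dxr[1] ** 2 + dxr[2] ** 2)
        fr = -restr_k * (rr - restr_r0) / rr
        forces[restr_a] += fr * dxr
        forces[restr_b] -= fr * dxr

    frames[0] = pos
    vframes[0] = vel
    times[0] = 0.0
    fidx = 1
    sidx = 0
    status = 0

    for step in range(1, n_steps + 1):
        # B
        for i in range(n):
            inv_m = 1.0 / masses[i]
            vel[i, 0] += 0.5 * dt * forces[i, 0] * inv_m
            vel[i, 1] += 0.5 * dt * forces[i, 1] * inv_m
            vel[i, 2] += 0.5 * dt * forces[i, 2] * inv_m
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O
        if friction > 0.0:
            for i in range(n):
                s = math.sqrt(kT / masses[i])
                vel[i, 0] = c1 * vel[i, 0] + c2 * s * np.random.normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * s * np.random.normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * s * np.random.normal()
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # forces
        if step % NLIST_EVERY == 0:
            pi, pj = _build_pairs(pos, mono_id, box, RC_LJ + NLIST_SKIN)
        forces[:] = 0.0
        _forces_bonded(pos, bond_i, bond_j, bond_r0, bond_k, forces)
        _forces_nonbonded(pos, class_idx, charges, box, eps_tab, sig_tab,
                          shift_tab, ke_over_epsr, pi, pj, forces)
        if restr_on:
            dxr = pos[restr_a] - pos[restr_b]
            rr = math.sqrt(dxr[0] ** 2 + dxr[1] ** 2 + dxr[2] ** 2)
            fr = -restr_k * (rr - restr_r0) / rr
            forces[restr_a] += fr * dxr
            forces[restr_b] -= fr * dxr
        # B
        for i in range(n):
            inv_m = 1.0 / masses[i]
            vel[i, 0] += 0.5 * dt * forces[i, 0] * inv_m
            vel[i, 1] += 0.5 * dt * forces[i, 1] * inv_m
            vel[i, 2] += 0.5 * dt * forces[i, 2] * inv_m

        if restr_on and step % sample_stride == 0 and sidx < n_samp:
            dxr = pos[restr_a] - pos[restr_b]
            samples[sidx] = math.sqrt(dxr[0] ** 2 + dxr[1] ** 2 + dxr[2] ** 2)
            sidx += 1

        if step % save_stride == 0:
            bad = False
            for i in range(n):
                for d in range(3):
                    f = forces[i, d]
                    if not np.isfinite(f) or abs(f) > 1e6 or not np.isfinite(pos[i, d]):
                        bad = True
            frames[fidx] = pos
            vframes[fidx] = vel
            times[fidx] = step * dt
            if bad:
                status = fidx
                return frames[: fidx + 1], vframes[: fidx + 1], times[: fidx + 1], samples[:sidx], status
            fidx += 1

    return frames[:fidx], vframes[:fidx], times[:fidx], samples[:sidx], status


def _initial_velocities(sys_: System, kT: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(sys_.n_beads, 3)) * np.sqrt(kT / sys_.masses)[:, None]
    v -= np.average(v, axis=0, weights=sys_.masses)  # zero total momentum
    return v


def run_ld(sys_: System, params: EngineParams, velocities: Optional[np.ndarray] = None) -> Trajectory:
    """Integrate the system; returns the saved trajectory.

    Deterministic per (seed, params): identical inputs give bit-identical
    frames.  Raises ``RuntimeError`` on force blow-up or NaN coordinates,
    naming the frame.
    """
    pos = sys_.positions.copy()
    vel = (
        velocities.copy()
        if velocities is not None
        else _initial_velocities(sys_, params.temperature, params.seed)
    )
    f0 = forces(sys_, pos)
    if not np.all(np.isfinite(f0)):
        raise RuntimeError("forces not finite at the initial configuration")
    frames, vframes, times, _, status = _run_kernel(
        pos, vel, sys_.masses, sys_.class_idx, sys_.charges, sys_.monomer_id,
        sys_.bond_i, sys_.bond_j, sys_.bond_r0, sys_.bond_k,
        np.array(params.box), params.timestep, params.friction,
        params.temperature, params.n_steps, params.save_stride, params.seed,
        _EPS_TAB, _SIG_TAB, _SHIFT_TAB, KE_COULOMB / sys_.eps_r,
        False, 0, 0, 0.0, 0.0, 1_000_000_000,
    )
    if status != 0:
        raise RuntimeError(f"force blow-up or NaN coordinates at frame {status}")
    traj = Trajectory(
        frames=frames, times=times, system=sys_, velocities=vframes,
        meta={"params": params, "units": "reduced (sigma=0.47 nm mapping)"},
    )
    return traj


def run_restrained_distance(
    sys_: System,
    params: EngineParams,
    k_restraint: float,
    r0: float,
    equil_steps: int = 0,
    sample_stride: int = 10,
) -> np.ndarray:
    """Langevin run with a harmonic restraint on the two monomer centers.

    Returns the sampled center-center distances after the equilibration
    cut (umbrella-window workhorse for the dimerization PMF).
    """
    a, b = int(sys_.center_indices[0]), int(sys_.center_indices[1])
    pos = sys_.positions.copy()
    vel = _initial_velocities(sys_, params.temperature, params.seed)
    _, _, _, samples, status = _run_kernel(
        pos, vel, sys_.masses, sys_.class_idx, sys_.charges, sys_.monomer_id,
        sys_.bond_i, sys_.bond_j, sys_.bond_r0, sys_.bond_k,
        np.array(params.box), params.timestep, params.friction,
        params.temperature, params.n_steps, max(params.n_steps, 1), params.seed,
        _EPS_TAB, _SIG_TAB, _SHIFT_TAB, KE_COULOMB / sys_.eps_r,
        True, a, b, k_restraint, r0, sample_stride,
    )
    if status != 0:
        raise RuntimeError(f"restrained run failed at frame {status}")
    n_skip = equil_steps // sample_stride
    return samples[n_skip:]


def forces(sys_: System, pos: Optional[np.ndarray] = None) -> np.ndarray:
    """Total forces at a configuration (bonded + nonbonded)."""
    if pos is None:
        pos = sys_.positions
    f = np.zeros_like(pos)
    _forces_bonded(pos, sys_.bond_i, sys_.bond_j, sys_.bond_r0, sys_.bond_k, f)
    pi, pj = _build_pairs(pos, sys_.monomer_id, np.array((1e6, 1e6, 1e6)), RC_LJ + NLIST_SKIN)
    _forces_nonbonded(pos, sys_.class_idx, sys_.charges, np.array((1e6, 1e6, 1e6)),
                      _EPS_TAB, _SIG_TAB, _SHIFT_TAB, KE_COULOMB / sys_.eps_r, pi, pj, f)
    return f


def potential_energy(sys_: System, pos: Optional[np.ndarray] = None,
                     box: Optional[tuple] = None) -> float:
    """Total potential energy of a configuration."""
    if pos is None:
        pos = sys_.positions
    b = np.array(box) if box is not None else np.array((1e6, 1e6, 1e6))
    f = np.zeros_like(pos)
    e = _forces_bonded(pos, sys_.bond_i, sys_.bond_j, sys_.bond_r0, sys_.bond_k, f)
    pi, pj = _build_pairs(pos, sys_.monomer_id, b, RC_LJ + NLIST_SKIN)
    e += _forces_nonbonded(pos, sys_.class_idx, sys_.charges, b,
                           _EPS_TAB, _SIG_TAB, _SHIFT_TAB,
                           KE_COULOMB / sys_.eps_r, pi, pj, f)
    return float(e)


def kinetic_temperature(vel: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature k_B T = 2 KE / (3 N)."""
    ke = 0.5 * np.sum(masses[:, None] * vel**2)
    return float(2.0 * ke / (3.0 * vel.shape[0]))


# ---------------------------------------------------------------------------
# biased (well-tempered metadynamics) integration segments: a Gaussian bias
# on the coordination CV of one target monomer, hills frozen within a segment
# ---------------------------------------------------------------------------


@njit(cache=True)
def _switch_and_deriv(d, r0, dmax, u_max):
    """Stretched rational switching (n=6, m=12) and its derivative in d."""
    if d >= dmax:
        return 0.0, 0.0
    x = d / r0
    x5 = x ** 5
    u = 1.0 / (1.0 + x5 * x)
    du = -6.0 * x5 * u * u / r0
    s = (u - u_max) / (1.0 - u_max)
    ds = du / (1.0 - u_max)
    if s < 0.0:
        return 0.0, 0.0
    return s, ds


@njit(cache=True)
def _metad_segment(pos, vel, masses, class_idx, charges, mono_id,
                   bond_i, bond_j, bond_r0, bond_k,
                   box, dt, friction, kT, n_steps, seed,
                   eps_tab, sig_tab, shift_tab, ke_over_epsr,
                   center_idx, target, cv_r0, cv_dmax,
                   hill_centers, hill_heights, hill_width, n_hills):
    """Integrate n_steps with a frozen hill set biased on the target's
    coordination CV; returns (rescaled time increment, final CV)."""
    np.random.seed(seed)
    n = pos.shape[0]
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    u_max = 1.0 / (1.0 + (cv_dmax / cv_r0) ** 6)
    inv_2w2 = 1.0 / (2.0 * hill_width * hill_width)
    t_resc = 0.0
    s_cv = 0.0
    forces = np.zeros((n, 3))
    pi, pj = _build_pairs(pos, mono_id, box, RC_LJ + NLIST_SKIN)

    for step in range(n_steps):
        if step % NLIST_EVERY == 0:
            pi, pj = _build_pairs(pos, mono_id, box, RC_LJ + NLIST_SKIN)
        forces[:] = 0.0
        _forces_bonded(pos, bond_i, bond_j, bond_r0, bond_k, forces)
        _forces_nonbonded(pos, class_idx, charges, box, eps_tab, sig_tab,
                          shift_tab, ke_over_epsr, pi, pj, forces)
        # CV and bias
        t_c = center_idx[target]
        s_cv = 0.0
        for m in range(center_idx.shape[0]):
            if m == target:
                continue
            j = center_idx[m]
            dx = pos[t_c, 0] - pos[j, 0]
            dy = pos[t_c, 1] - pos[j, 1]
            dz = pos[t_c, 2] - pos[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            s, _ = _switch_and_deriv(d, cv_r0, cv_dmax, u_max)
            s_cv += s
        vbias = 0.0
        dvds = 0.0
        for h in range(n_hills):
            dd = s_cv - hill_centers[h]
            g = hill_heights[h] * math.exp(-dd * dd * inv_2w2)
            vbias += g
            dvds += -g * dd * 2.0 * inv_2w2
        # chain rule: F = -dV/ds * ds/dx on the target and its neighbours
        for m in range(center_idx.shape[0]):
            if m == target:
                continue
            j = center_idx[m]
            dx = pos[t_c, 0] - pos[j, 0]
            dy = pos[t_c, 1] - pos[j, 1]
            dz = pos[t_c, 2] - pos[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-12:
                continue
            s, ds = _switch_and_deriv(d, cv_r0, cv_dmax, u_max)
            f = -dvds * ds / d
            forces[t_c, 0] += f * dx
            forces[t_c, 1] += f * dy
            forces[t_c, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
        # BAOAB step (forces recomputed next iteration)
        for i in range(n):
            inv_m = 1.0 / masses[i]
            vel[i, 0] += 0.5 * dt * forces[i, 0] * inv_m
            vel[i, 1] += 0.5 * dt * forces[i, 1] * inv_m
            vel[i, 2] += 0.5 * dt * forces[i, 2] * inv_m
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        if friction > 0.0:
            for i in range(n):
                sd = math.sqrt(kT / masses[i])
                vel[i, 0] = c1 * vel[i, 0] + c2 * sd * np.random.normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * sd * np.random.normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * sd * np.random.normal()
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        for i in range(n):
            inv_m = 1.0 / masses[i]
            vel[i, 0] += 0.5 * dt * forces[i, 0] * inv_m
            vel[i, 1] += 0.5 * dt * forces[i, 1] * inv_m
            vel[i, 2] += 0.5 * dt * forces[i, 2] * inv_m
        t_resc += dt * math.exp(vbias / kT)
    return t_resc, s_cv
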