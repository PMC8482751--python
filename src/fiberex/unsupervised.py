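"""Unsupervised defect detection: descriptors, PCA, density clustering, rates.

The agnostic route to structural motifs: a rotation/permutation-invariant
SOAP-style power-spectrum descriptor is built on each monomer center from
the other centers in its neighbourhood, reduced by PCA to a few
components, and clustered by a PAMM-style density-based scheme (kernel
density estimation on a farthest-point grid, quick-shift uphill linking
into micro-clusters, bootstrap stability analysis and population-based
merging into macro-clusters).  Macro-cluster populations give the
free-energy surface (F_i = -kT ln p_i / p_max), and frame-to-frame
macro-cluster changes give the transition-rate matrix

    R_tr[a -> b] = N_events[a -> b] / t_tot,     t_tot = N_frames * t_stride,

from which per-monomer interconversion rates (defect creation and
annihilation in particular) are obtained by normalizing with the source
state's occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.special import sph_harm_y
from sklearn.decomposition import PCA

__all__ = [
    "DescriptorParams",
    "PAMMParams",
    "ClusterModel",
    "RateMatrix",
    "center_descriptors",
    "pca_reduce",
    "pamm_cluster",
    "fes_from_populations",
    "rate_matrix",
    "stride_corrected_rates",
]


@dataclass(frozen=True)
class DescriptorParams:
    """SOAP-style power-spectrum settings (single species: monomer centers).

    The descriptor dimension is nmax (nmax + 1) / 2 * (lmax + 1); the
    defaults give 324 features.
    """

    rcut: float = 8.0
    nmax: int = 8
    lmax: int = 8

    def __post_init__(self) -> None:
        if self.rcut <= 0:
            raise ValueError("rcut must be > 0")

    @property
    def dimension(self) -> int:
        return self.nmax * (self.nmax + 1) // 2 * (self.lmax + 1)


@dataclass(frozen=True)
class PAMMParams:
    """PAMM-style density clustering settings."""

    grid_size: int = 1000
    fspread: float = 0.30
    quickshift_lambda: float = 1.0
    bootstrap_runs: int = 73
    merger_threshold: float = 0.005

    def __post_init__(self) -> None:
        if self.fspread <= 0:
            raise ValueError("fspread must be > 0")
        if not (0 < self.merger_threshold < 1):
            raise ValueError("merger_threshold must be in (0, 1)")


@dataclass
class ClusterModel:
    """Micro/macro clustering of a score space with grid densities."""

    grid: np.ndarray  # (g, d) farthest-point grid
    grid_density: np.ndarray  # (g,)
    grid_micro: np.ndarray  # micro-cluster id per grid point
    grid_macro: np.ndarray  # macro-cluster id per grid point
    assignments: np.ndarray  # macro id per sample
    populations: np.ndarray  # macro population fractions, sums to 1
    bandwidth: float = 0.0

    @property
    def n_macro(self) -> int:
        return int(self.populations.size)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Macro-cluster of new points via the nearest grid point."""
        d = cdist(np.atleast_2d(X), self.grid)
        return self.grid_macro[d.argmin(axis=1)]


def _radial_basis(r: np.ndarray, params: DescriptorParams) -> np.ndarray:
    """(len(r), nmax) Gaussian radial shells with a smooth cosine cutoff."""
    centers = np.linspace(0.0, params.rcut, params.nmax)
    width = centers[1] - centers[0] if params.nmax > 1 else params.rcut
    g = np.exp(-0.5 * ((r[:, None] - centers[None, :]) / width) ** 2)
    fc = 0.5 * (np.cos(np.pi * np.clip(r / params.rcut, 0.0, 1.0)) + 1.0)
    return g * fc[:, None]


def center_descriptors(
    centers: np.ndarray,
    params: DescriptorParams = DescriptorParams(),
) -> np.ndarray:
    """Power-spectrum fingerprint of each monomer-center environment.

    For center i the neighbour density within ``rcut`` is expanded in
    Gaussian radial shells times spherical harmonics,
    ``c_nlm = sum_j g_n(r_ij) Y_lm(r_ij_hat)``, and contracted into the
    rotationally invariant power spectrum
    ``p(n, n', l) = sum_m c_nlm conj(c_n'lm)`` (n <= n').  Environments
    with no neighbour inside ``rcut`` map to the all-zero vector (the
    empty-environment fingerprint, identical for all isolated monomers).

    Returns an (n_monomers, dimension) real array.
    """
    centers = np.asarray(centers, dtype=float)
    n = centers.shape[0]
    if n < 2:
        raise ValueError("need at least 2 monomer centers")
    nmax, lmax = params.nmax, params.lmax
    out = np.zeros((n, params.dimension))
    iu = np.triu_indices(nmax)
    for i in range(n):
        rel = np.delete(centers, i, axis=0) - centers[i]
        r = np.linalg.norm(rel, axis=1)
        keep = (r > 1e-12) & (r < params.rcut)
        rel, r = rel[keep], r[keep]
        if r.size == 0:
            continue  # empty environment: zero vector
        gn = _radial_basis(r, params)  # (nb, nmax)
        theta = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        feats = []
        for l in range(lmax + 1):
            # c[n, m] = sum_j g_n(r_j) Y_lm(j)
            ylm = np.empty((r.size, 2 * l + 1), dtype=complex)
            for k, m in enumerate(range(-l, l + 1)):
                ylm[:, k] = sph_harm_y(l, m, theta, phi)
            c = gn.T @ ylm  # (nmax, 2l+1)
            p = (c @ c.conj().T).real  # (nmax, nmax)
            feats.append(p[iu])
        out[i] = np.concatenate(feats)
    return out


def pca_reduce(X: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Centered linear projection onto the top-k principal components.

    Returns (scores, explained-variance fractions, fitted model).  The
    component signs are fixed by making each component's largest-loading
    entry positive, so results are deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {X.shape[0]}")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant matrix: zero variance, nothing to reduce")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    # deterministic sign convention
    for j in range(k):
        load = model.components_[j]
        sign = np.sign(load[np.argmax(np.abs(load))])
        if sign < 0:
            model.components_[j] *= -1
            scores[:, j] *= -1
    return scores, model.explained_variance_ratio_.copy(), model


def _farthest_point_grid(X: np.ndarray, g: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a farthest-point-sampling subset of size g."""
    n = X.shape[0]
    idx = np.empty(g, dtype=int)
    idx[0] = rng.integers(n)
    dmin = np.linalg.norm(X - X[idx[0]], axis=1)
    for i in range(1, g):
        idx[i] = int(dmin.argmax())
        dmin = np.minimum(dmin, np.linalg.norm(X - X[idx[i]], axis=1))
    return idx


def _kde_at(grid: np.ndarray, X: np.ndarray, h: float, weights=None) -> np.ndarray:
    d2 = cdist(grid, X, "sqeuclidean")
    w = np.exp(-0.5 * d2 / (h * h))
    if weights is not None:
        w = w * weights[None, :]
    return w.sum(axis=1) / (X.shape[0] * (h * math.sqrt(2 * math.pi)) ** X.shape[1])


def _quickshift(grid: np.ndarray, density: np.ndarray, link_max) -> np.ndarray:
    """Uphill nearest-higher-density linking; roots become micro-cluster modes.

    ``link_max`` may be a scalar or a per-point array (adaptive range:
    sparse outskirts of the grid link farther than dense basin cores).
    """
    g = grid.shape[0]
    d = cdist(grid, grid)
    link = np.broadcast_to(np.asarray(link_max, dtype=float), (g,))
    parent = np.arange(g)
    order = np.argsort(density)
    for i in order:
        higher = density > density[i]
        if not higher.any():
            continue
        cand = np.where(higher, d[i], np.inf)
        j = int(cand.argmin())
        if cand[j] <= link[i]:
            parent[i] = j
    # path-compress to roots
    labels = np.arange(g)
    for i in range(g):
        p = i
        while parent[p] != p:
            p = parent[p]
        labels[i] = p
    roots, inv = np.unique(labels, return_inverse=True)
    return inv


def pamm_cluster(
    scores: np.ndarray,
    params: PAMMParams = PAMMParams(),
    seed: int = 0,
) -> ClusterModel:
    """PAMM-style density clustering of a low-dimensional score space.

    Pipeline: farthest-point grid subsample -> Gaussian KDE with
    bandwidth ``fspread * mean(std per dimension)`` -> quick-shift uphill
    linking (link range ``quickshift_lambda`` in units of the grid's
    typical spacing) -> micro-clusters -> bootstrap stability merge
    (modes that coalesce in most density resamples are one basin) ->
    population merge (macro-clusters lighter than ``merger_threshold``
    are absorbed into the nearest-mode neighbour; a threshold approaching
    1 therefore collapses everything into a single macro-cluster).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, dim = X.shape
    if params.grid_size > n:
        raise ValueError(f"grid_size {params.grid_size} exceeds n_samples {n}")
    rng = np.random.default_rng(seed)

    gidx = _farthest_point_grid(X, params.grid_size, rng)
    grid = X[gidx]
    h = params.fspread * float(X.std(axis=0).mean())
    if h <= 0:
        raise ValueError("degenerate scores: zero spread")
    density = _kde_at(grid, X, h)

    # adaptive quick-shift link range: a point may link as far as its local
    # grid spacing (10th-neighbour distance) or the KDE bandwidth, whichever
    # is larger, scaled by quickshift_lambda
    dg = np.sort(cdist(grid, grid), axis=1)
    local = dg[:, min(10, params.grid_size - 1)]
    link_max = params.quickshift_lambda * np.maximum(1.5 * local, h)

    micro = _quickshift(grid, density, link_max)
    n_micro = micro.max() + 1

    # bootstrap stability: do two modes coalesce when the density wiggles?
    if n_micro > 1 and params.bootstrap_runs > 0:
        modes = np.array(
            [np.flatnonzero(micro == m)[np.argmax(density[micro == m])] for m in range(n_micro)]
        )
        together = np.zeros((n_micro, n_micro))
        for b in range(params.bootstrap_runs):
            take = rng.integers(n, size=n)
            dens_b = _kde_at(grid, X[take], h)
            lab_b = _quickshift(grid, dens_b, link_max)
            for a in range(n_micro):
                for c in range(a + 1, n_micro):
                    if lab_b[modes[a]] == lab_b[modes[c]]:
                        together[a, c] += 1
                        together[c, a] += 1
        together /= params.bootstrap_runs
        # union-find merge of modes that co-basin in the majority of resamples
        macro_of = np.arange(n_micro)

        def find(a):
            while macro_of[a] != a:
                a = macro_of[a]
            return a

        for a in range(n_micro):
            for c in range(a + 1, n_micro):
                if together[a, c] > 0.5:
                    ra, rc = find(a), find(c)
                    if ra != rc:
                        macro_of[max(ra, rc)] = min(ra, rc)
        macro = np.array([find(m) for m in micro])
    else:
        macro = micro.copy()

    # population-based merging
    assignments = macro[cdist(X, grid).argmin(axis=1)]
    while True:
        labs, counts = np.unique(assignments, return_counts=True)
        if labs.size <= 1:
            break
        frac = counts / n
        light = labs[frac < params.merger_threshold]
        if light.size == 0:
            break
        # absorb the lightest cluster into its nearest-mode neighbour
        victim = labs[frac.argmin()]
        vmask = macro == victim
        vmode = np.flatnonzero(vmask)[np.argmax(density[vmask])]
        best, bestd = None, np.inf
        for other in labs:
            if other == victim:
                continue
            om = macro == other
            omode = np.flatnonzero(om)[np.argmax(density[om])]
            dd = np.linalg.norm(grid[vmode] - grid[omode])
            if dd < bestd:
                best, bestd = other, dd
        macro[vmask] = best
        assignments = macro[cdist(X, grid).argmin(axis=1)]

    # relabel contiguously, ordered by decreasing population
    labs, counts = np.unique(assignments, return_counts=True)
    order = np.argsort(-counts)
    remap = {int(labs[o]): i for i, o in enumerate(order)}
    macro = np.array([remap[int(m)] for m in macro])
    assignments = np.array([remap[int(a)] for a in assignments])
    pops = np.bincount(assignments) / n

    return ClusterModel(
        grid=grid, grid_density=density, grid_micro=micro, grid_macro=macro,
        assignments=assignments, populations=pops, bandwidth=h,
    )


def fes_from_populations(p: np.ndarray, kT: float = 1.0) -> np.ndarray:
    """Free energy per cluster from populations: F_i = -kT ln(p_i / p_max).

    The most populated cluster sits at exactly zero.  Zero-population
    clusters are returned as +inf (excluded states).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("populations must be >= 0")
    if p.max() <= 0:
        raise ValueError("at least one population must be > 0")
    with np.errstate(divide="ignore"):
        return -kT * np.log(p / p.max())


@dataclass
class RateMatrix:
    """Transition counts and rates between labelled states."""

    states: list
    n_events: np.ndarray  # (s, s) integer counts, diagonal zero
    t_tot: float
    t_stride: float
    n_frames: int
    occupancy: np.ndarray  # mean fraction of monomers per state
    n_monomers: int = 1

    @property
    def r_tr(self) -> np.ndarray:
        """Aggregate fiber-level rates: events per unit total time."""
        return self.n_events / self.t_tot

    def per_monomer_rates(self, corrected: bool = True) -> np.ndarray:
        """Per-monomer rate constants: events / (time spent in source state).

        With ``corrected`` the two-state finite-stride bias (flips missed
        within one stride) is removed pairwise via the embedded
        discrete-chain relation k_naive = k g(lambda tau), g(u) = (1-e^-u)/u.
        """
        time_in_state = self.occupancy * self.n_monomers * self.t_tot
        with np.errstate(divide="ignore", invalid="ignore"):
            naive = np.where(
                time_in_state[:, None] > 0,
                self.n_events / time_in_state[:, None],
                0.0,
            )
        if not corrected:
            return naive
        out = naive.copy()
        tau = self.t_stride
        s = len(self.states)
        for a in range(s):
            for b in range(a + 1, s):
                kab, kba = naive[a, b], naive[b, a]
                lam_naive = kab + kba
                if lam_naive <= 0:
                    continue
                gfun = lambda u: (1.0 - math.exp(-u)) / u if u > 1e-12 else 1.0
                f = lambda lam: lam * gfun(lam * tau) - lam_naive
                hi = max(lam_naive * 10, 1.0 / tau * 20)
                try:
                    lam = brentq(f, lam_naive * 0.999, hi)
                except ValueError:
                    lam = lam_naive
                corr = lam / lam_naive
                out[a, b] = kab * corr
                out[b, a] = kba * corr
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_tr, index=self.states, columns=self.states)


def rate_matrix(labels: np.ndarray, t_stride: float, states: Optional[list] = None) -> RateMatrix:
    """Count frame-to-frame label changes and convert to rates.

    ``labels`` is (n_frames, n_monomers) (or (n_frames,) for a single
    walker) of hashable state labels; self-transitions are excluded.
    """
    lab = np.asarray(labels)
    if lab.ndim == 1:
        lab = lab[:, None]
    n_frames, n_mono = lab.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames to count transitions")
    if states is None:
        states = sorted(np.unique(lab).tolist())
    s_index = {s: i for i, s in enumerate(states)}
    s = len(states)
    code = np.vectorize(s_index.get)(lab)
    n_events = np.zeros((s, s), dtype=np.int64)
    a, b = code[:-1].ravel(), code[1:].ravel()
    changed = a != b
    np.add.at(n_events, (a[changed], b[changed]), 1)
    t_tot = n_frames * t_stride
    occupancy = np.bincount(code.ravel(), minlength=s) / code.size
    return RateMatrix(
        states=list(states), n_events=n_events, t_tot=t_tot, t_stride=t_stride,
        n_frames=n_frames, occupancy=occupancy, n_monomers=n_mono,
    )


def stride_corrected_rates(rm: RateMatrix, a, b) -> tuple[float, float, float, float]:
    """Pairwise corrected (k_ab, k_ba) with Poisson standard errors."""
    ia, ib = rm.states.index(a), rm.states.index(b)
    k = rm.per_monomer_rates(corrected=True)
    t_a = rm.occupancy[ia] * rm.n_monomers * rm.t_tot
    t_b = rm.occupancy[ib] * rm.n_monomers * rm.t_tot
    se_ab = math.sqrt(max(rm.n_events[ia, ib], 1)) / t_a if t_a > 0 else math.inf
    se_ba = math.sqrt(max(rm.n_events[ib, ia], 1)) / t_b if t_b > 0 else math.inf
    return k[ia, ib], se_ab, k[ib, ia], se_ba
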