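"""Statistics on ensemble results.

Covers the whole downstream pipeline: log/z-score normalization of
terminal expression, automatic state counting (Gaussian mixtures scored
by BIC), noise- or parameter-binned "global bifurcation" summaries,
histogram comparison by the Bhattacharyya distance

    BD(p, q) = -ln sum_i sqrt(p_i q_i),

response-time curves (BD of intermediate-time vs end-of-run
distributions), and the noise-robustness index of a circuit (BD between
the zero-noise and noise-D terminal distributions, reported at D = 1 and
as the fitted low-D slope).  Expression distributions are compared via
per-gene histograms on a shared 100-bin grid spanning the pooled range,
averaged over genes, which keeps BD comparable across circuits of
different size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .circuit import Circuit
from .parameters import ParameterRanges
from .schemes import CircuitEnsemble, EnsembleResult
from .simulate import ensemble_simulate, initial_conditions

#: documented ceiling for the Bhattacharyya distance of (near-)disjoint
#: histograms, where -ln of the overlap diverges
BD_CAP = 100.0

#: pseudocount added before the log transform; one expression unit, so
#: zero-clamped records map continuously onto genuinely low expression
#: instead of forming a detached outlier mass on the log scale
PSEUDOCOUNT = 1.0


@dataclass
class ExpressionNormalizer:
    """Stored log2/z-score transform so different noise slices of one
    experiment share a common scale.

    Fit on a reference ensemble (typically the zero-noise or pooled
    records): per-gene mean and standard deviation of log2(1 + x).
    Genes with zero variance in the reference fall back to unit variance
    (with a warning) so a constant column maps to all zeros.
    """

    genes: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, expression: np.ndarray, genes: Sequence[str]) -> "ExpressionNormalizer":
        logx = np.log2(PSEUDOCOUNT + np.maximum(np.asarray(expression, float), 0.0))
        mean = logx.mean(axis=0)
        sd = logx.std(axis=0)
        degenerate = sd <= 0
        if np.any(degenerate):
            warnings.warn(
                f"zero-variance gene(s) {[genes[i] for i in np.flatnonzero(degenerate)]}: "
                "falling back to unit variance",
                stacklevel=2,
            )
            sd = np.where(degenerate, 1.0, sd)
        return cls(tuple(genes), mean, sd)

    def transform(self, expression: np.ndarray) -> np.ndarray:
        logx = np.log2(PSEUDOCOUNT + np.maximum(np.asarray(expression, float), 0.0))
        return (logx - self.mean) / self.sd


def normalize_expression(
    result: EnsembleResult | np.ndarray,
    genes: Sequence[str] | None = None,
    normalizer: ExpressionNormalizer | None = None,
) -> tuple[np.ndarray, ExpressionNormalizer]:
    """Normalize an ensemble's expression matrix; returns the matrix and
    the (possibly freshly fitted) transform for reuse on other slices."""
    if isinstance(result, EnsembleResult):
        expr, genes = result.expression, result.genes
    else:
        expr = np.asarray(result, float)
        if genes is None:
            genes = tuple(f"x{i}" for i in range(expr.shape[1]))
    if normalizer is None:
        normalizer = ExpressionNormalizer.fit(expr, genes)
    return normalizer.transform(expr), normalizer


@dataclass
class OccupancyProfile:
    """Per-state model counts/fractions from a clustering of records."""

    states: tuple[str, ...]
    counts: np.ndarray
    labels: np.ndarray  # per-record state index
    scheme: str | None = None
    noise: float | None = None

    def __post_init__(self) -> None:
        if self.counts.sum() != len(self.labels):
            raise ValueError("state counts must sum to the number of records")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def count_states(
    normalized: np.ndarray,
    *,
    k_max: int = 6,
    seed: int = 0,
    n_init: int = 3,
    min_records: int = 50,
    min_fraction: float = 0.1,
    scheme: str | None = None,
    noise: float | None = None,
) -> OccupancyProfile:
    """Count expression states by Gaussian-mixture fits for k = 1..k_max,
    choosing the k minimizing BIC; deterministic given ``seed``.

    Two post-processing rules turn mixture components into *states*:
    components that do not form separate modes are merged (BIC spends
    extra Gaussians on skewed cluster shapes), and clusters holding less
    than ``min_fraction`` of the records are folded into their nearest
    neighbor (a state is a cluster that a non-negligible share of the
    ensemble occupies).

    Duplicate-only data (fewer distinct rows than components) is treated
    as a single state per distinct row cluster.
    """
    x = np.asarray(normalized, float)
    if len(x) < min_records:
        raise ValueError(f"need at least {min_records} records to count states, got {len(x)}")
    n_distinct = len(np.unique(x, axis=0))
    best = None
    for k in range(1, min(k_max, n_distinct) + 1):
        gmm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed,
            n_init=n_init, reg_covar=1e-6,
        )
        try:
            gmm.fit(x)
        except ValueError:
            continue
        bic = gmm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, gmm)
    if best is None:  # all rows identical: a single state
        labels = np.zeros(len(x), dtype=int)
        return OccupancyProfile(("state_0",), np.array([len(x)]), labels, scheme, noise)
    gmm = best[1]
    labels = _merge_overlapping(gmm, gmm.predict(x))
    labels = _absorb_minor_clusters(x, labels, min_fraction)
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    labels = np.array([remap[v] for v in labels])
    counts = np.bincount(labels, minlength=len(used))
    names = tuple(f"state_{i}" for i in range(len(used)))
    return OccupancyProfile(names, counts, labels, scheme, noise)


def _absorb_minor_clusters(x: np.ndarray, labels: np.ndarray, min_fraction: float) -> np.ndarray:
    """Fold clusters holding less than ``min_fraction`` of the records into
    the cluster with the nearest mean: an ensemble state is a cluster a
    non-negligible share of models occupies, not a stray tail."""
    labels = labels.copy()
    while True:
        used, counts = np.unique(labels, return_counts=True)
        if len(used) <= 1:
            return labels
        frac = counts / counts.sum()
        if frac.min() >= min_fraction:
            return labels
        means = np.stack([x[labels == u].mean(axis=0) for u in used])
        i = int(np.argmin(frac))
        dist = np.linalg.norm(means - means[i], axis=1)
        dist[i] = np.inf
        labels[labels == used[i]] = used[int(np.argmin(dist))]


def _pair_is_unimodal(w1, w2, s1, s2, dist, n_grid: int = 400) -> bool:
    """Whether the two-component 1-D Gaussian mixture (weights w1/w2,
    standard deviations s1/s2, means 0 and dist) has a single mode —
    checked numerically along the segment between (and slightly beyond)
    the two means."""
    w = w1 + w2
    w1, w2 = w1 / w, w2 / w
    s1 = max(s1, 1e-12)
    s2 = max(s2, 1e-12)
    t = np.linspace(-2.0 * s1, dist + 2.0 * s2, n_grid)
    f = (w1 / s1) * np.exp(-0.5 * (t / s1) ** 2) + (w2 / s2) * np.exp(
        -0.5 * ((t - dist) / s2) ** 2
    )
    interior_max = (f[1:-1] > f[:-2]) & (f[1:-1] >= f[2:])
    return int(interior_max.sum()) <= 1


def _merge_overlapping(gmm: GaussianMixture, labels: np.ndarray) -> np.ndarray:
    """Collapse mixture components that do not form distinct modes.

    BIC may spend several Gaussians on the shape of one skewed cluster;
    what the analysis calls a *state* is a mode of the distribution.  Two
    components are merged when their pairwise mixture, projected on the
    line joining the means, is unimodal; merging is transitive."""
    k = gmm.n_components
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            diff = gmm.means_[i] - gmm.means_[j]
            dist = np.linalg.norm(diff)
            if dist == 0:
                parent[find(j)] = find(i)
                continue
            u = diff / dist
            s_i = np.sqrt(u @ gmm.covariances_[i] @ u)
            s_j = np.sqrt(u @ gmm.covariances_[j] @ u)
            if _pair_is_unimodal(gmm.weights_[i], gmm.weights_[j], s_i, s_j, dist):
                parent[find(j)] = find(i)
    return np.array([find(v) for v in labels])


def occupancy_from_labels(labels: Sequence[str], scheme=None, noise=None) -> OccupancyProfile:
    """Occupancy profile from pre-assigned categorical labels (e.g. the
    low/high labels of the induction experiment)."""
    labels = np.asarray(labels)
    states, idx = np.unique(labels, return_inverse=True)
    counts = np.bincount(idx)
    return OccupancyProfile(tuple(states), counts, idx, scheme, noise)


# -- Bhattacharyya machinery ---------------------------------------------

def bhattacharyya_distance(p: np.ndarray, q: np.ndarray, cap: float = BD_CAP) -> float:
    """BD = -ln sum sqrt(p q) between two histograms on identical binning.

    Nonnegative, symmetric, zero iff the histograms coincide; capped at
    ``cap`` when the supports are disjoint (the overlap is zero and the
    logarithm diverges)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError(f"histograms use mismatched binning: {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histogram masses must be nonnegative")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        raise ValueError("histograms must have positive total mass")
    bc = np.sqrt((p / ps) * (q / qs)).sum()
    if bc <= np.exp(-cap):
        return cap
    return float(min(-np.log(min(bc, 1.0)), cap))


def expression_bd(a: np.ndarray, b: np.ndarray, n_bins: int = 100) -> float:
    """Distance between two expression samples: per-gene histograms on a
    shared ``n_bins``-bin grid spanning the pooled range, BD per gene,
    averaged over genes."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples have different numbers of genes")
    vals = []
    for j in range(a.shape[1]):
        lo = min(a[:, j].min(), b[:, j].min())
        hi = max(a[:, j].max(), b[:, j].max())
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, n_bins + 1)
        pa, _ = np.histogram(a[:, j], bins=edges)
        pb, _ = np.histogram(b[:, j], bins=edges)
        vals.append(bhattacharyya_distance(pa.astype(float), pb.astype(float)))
    return float(np.mean(vals))


# -- global bifurcation ---------------------------------------------------

def global_bifurcation(
    result: EnsembleResult,
    n_bins: int,
    *,
    values: np.ndarray | None = None,
    value_range: tuple[float, float] | None = None,
    normalizer: ExpressionNormalizer | None = None,
    k_max: int = 6,
    seed: int = 0,
    min_records: int = 50,
) -> pd.DataFrame:
    """Bin records along a randomized control axis (the noise level by
    default, or any per-record parameter passed via ``values``) and count
    expression states per bin.

    Returns one row per bin with the bin edges, record count, state count
    (NaN when the bin holds fewer than ``min_records`` records) and an
    ``empty`` flag — empty bins are reported, never silently dropped."""
    axis = result.noise if values is None else np.asarray(values, float)
    if len(axis) != len(result.data):
        raise ValueError("control-axis values must align with the records")
    lo, hi = value_range if value_range is not None else (axis.min(), axis.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    normed, normalizer = normalize_expression(result, normalizer=normalizer)
    rows = []
    for b in range(n_bins):
        in_bin = (axis >= edges[b]) & (axis < edges[b + 1] if b < n_bins - 1 else axis <= edges[b + 1])
        n = int(in_bin.sum())
        n_states = np.nan
        if n >= min_records:
            prof = count_states(normed[in_bin], k_max=k_max, seed=seed, min_records=min_records)
            n_states = prof.n_states
        rows.append(
            {"bin_lo": edges[b], "bin_hi": edges[b + 1], "n_records": n,
             "n_states": n_states, "empty": n == 0}
        )
    return pd.DataFrame(rows)


def cluster_spread(normalized: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-cluster covariance trace — the 'spread of the clusters'
    that parametric variation widens."""
    vals = []
    for lab in np.unique(labels):
        pts = normalized[labels == lab]
        if len(pts) > 1:
            vals.append(float(np.trace(np.cov(pts.T).reshape(pts.shape[1], pts.shape[1]))))
    return float(np.mean(vals)) if vals else 0.0


# -- response time and noise robustness -----------------------------------

def response_curve(
    circuit: Circuit,
    ranges: ParameterRanges,
    n_models: int,
    noise: float,
    record_times: Sequence[float],
    seed: int,
    *,
    dt: float = 0.05,
    t_max: float = 50.0,
    n_bins: int = 100,
) -> pd.DataFrame:
    """BD between the expression distribution at each recorded time and
    the end-of-run (t_max) zero-noise distribution of the same ensemble.

    Saturation of the curve signals that the ensemble has relaxed; larger
    noise saturates earlier but at a larger plateau."""
    ensemble = CircuitEnsemble.sample(circuit, ranges, n_models, seed)
    rng = np.random.default_rng(seed + 1)
    x0 = initial_conditions(circuit, ensemble.params, rng)
    times, snaps = ensemble_simulate(
        circuit, ensemble.params, dt=dt, t_max=t_max, noise=noise,
        rng=rng, x0=x0, record_times=record_times,
    )
    if noise == 0:
        reference = snaps[-1] if abs(times[-1] - t_max) < 1e-9 else ensemble_simulate(
            circuit, ensemble.params, dt=dt, t_max=t_max, noise=0.0, rng=rng, x0=x0
        )
    else:
        reference = ensemble_simulate(
            circuit, ensemble.params, dt=dt, t_max=t_max, noise=0.0,
            rng=np.random.default_rng(seed + 2), x0=x0,
        )
    normalizer = ExpressionNormalizer.fit(reference, circuit.genes)
    ref_n = normalizer.transform(reference)
    bd = [expression_bd(normalizer.transform(s), ref_n, n_bins=n_bins) for s in snaps]
    return pd.DataFrame({"time": times, "bd": bd})


DEFAULT_NOISE_GRID = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass
class RobustnessReport:
    """Noise-robustness summary of one circuit: the BD(D) curve, the
    headline index (BD at D = 1), and the fitted low-noise slope
    lim_{D->0} d(BD)/dD (least squares through the origin on D <= 1)."""

    circuit: str
    noise_grid: np.ndarray
    bd: np.ndarray
    r_d: float
    low_noise_slope: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"D": self.noise_grid, "bd": self.bd})


def noise_robustness(
    circuit: Circuit,
    ranges: ParameterRanges,
    n_models: int,
    seed: int,
    *,
    noise_grid: Sequence[float] = DEFAULT_NOISE_GRID,
    dt: float = 0.05,
    t_max: float = 50.0,
    n_bins: int = 100,
) -> RobustnessReport:
    """BD between the zero-noise terminal distribution and the terminal
    distribution at each noise level on the grid (same models, same
    initial conditions).  A flat curve means a noise-robust circuit."""
    grid = np.asarray(sorted(set(float(d) for d in noise_grid) | {0.0, 1.0}))
    ensemble = CircuitEnsemble.sample(circuit, ranges, n_models, seed)
    rng_ic = np.random.default_rng(seed + 1)
    x0 = initial_conditions(circuit, ensemble.params, rng_ic)
    terminal: dict[float, np.ndarray] = {}
    for i, d in enumerate(grid):
        rng = np.random.default_rng(seed + 2 + i)
        terminal[d] = ensemble_simulate(
            circuit, ensemble.params, dt=dt, t_max=t_max, noise=d, rng=rng, x0=x0
        )
    normalizer = ExpressionNormalizer.fit(terminal[0.0], circuit.genes)
    ref = normalizer.transform(terminal[0.0])
    bd = np.array([
        expression_bd(normalizer.transform(terminal[d]), ref, n_bins=n_bins) for d in grid
    ])
    r_d = float(bd[np.argmin(np.abs(grid - 1.0))])
    low = grid <= 1.0 + 1e-9
    denom = float(np.sum(grid[low] ** 2))
    slope = float(np.sum(grid[low] * bd[low]) / denom) if denom > 0 else 0.0
    return RobustnessReport(circuit.name, grid, bd, r_d, slope)


# -- dimensionality reduction / clustering --------------------------------

def pca_embed(normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First two principal components of the normalized expression.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making embeddings reproducible bit-for-bit.
    Returns (coordinates, components, explained variance ratio)."""
    x = np.asarray(normalized, float)
    if x.shape[1] < 2:
        raise ValueError("PCA embedding needs at least 2 genes")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            coords[:, i] = -coords[:, i]
    return coords, comps, pca.explained_variance_ratio_


def hierarchical_cluster(
    normalized: np.ndarray, n_clusters: int | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Average-linkage hierarchical clustering on Euclidean distances.

    Returns the scipy linkage matrix and, when ``n_clusters`` is given,
    flat cluster labels (0-based)."""
    x = np.asarray(normalized, float)
    z = linkage(x, method="average", metric="euclidean")
    labels = None
    if n_clusters is not None:
        labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    return z, labels
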