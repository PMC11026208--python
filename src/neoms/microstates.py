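"""Microstate map identification.

Dominant scalp topographies are extracted from the EEG samples at global
field power (GFP) peaks by a polarity-invariant modified k-means: each
sample is assigned to the map maximizing the squared spatial correlation
(sign ignored), and each map is re-estimated as the first principal
eigenvector of its assigned samples' outer-product sum.  The number of
maps is chosen with the Krzanowski-Lai (KL) elbow criterion on the
within-cluster dispersion curve.  Fit quality is summarized by the
global explained variance (GEV).

All comparisons between topographies in this package are
polarity-invariant: a microstate map and its sign-flip describe the same
state, so maps are defined only up to sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from neoms.epoch import EEGEpoch

# Modified k-means policy: restarts/tolerance/iteration cap used
# everywhere clustering is run (individual maps, group maps, KL scan).
N_RESTARTS = 20
MAX_ITER = 500
TOL = 1e-6


@dataclass
class MapSet:
    """An ordered set of k unit-norm, average-referenced microstate maps.

    Each row of ``maps`` is one scalp topography (one value per channel),
    zero-mean across channels and unit L2 norm.  The sign of each map is
    fixed for display so that the channel with the largest absolute
    loading is positive; all mathematical consumers ignore polarity.
    """

    maps: np.ndarray
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.maps = _canonicalize(self.maps)

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def reordered(self, perm: np.ndarray) -> "MapSet":
        return MapSet(self.maps[np.asarray(perm)], self.channel_names)


@dataclass
class ClusteringResult:
    """Output of one modified k-means run (best restart)."""

    mapset: MapSet
    peak_labels: np.ndarray  # 0-based map index per input sample
    gev: float  # explained variance on the clustered samples
    dispersion: float  # within-cluster dispersion W(k)
    n_iter: int
    converged: bool
    meta: dict = field(default_factory=dict)


def _canonicalize(maps: np.ndarray) -> np.ndarray:
    """Demean, L2-normalize, and sign-fix each topography row."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero topography cannot be normalized")
    maps = maps / norms
    lead = np.argmax(np.abs(maps), axis=1)
    signs = np.sign(maps[np.arange(maps.shape[0]), lead])
    return maps * signs[:, None]


def global_field_power(epoch: EEGEpoch) -> np.ndarray:
    """Per-sample GFP: the standard deviation of voltages across channels.

    Requires an average-referenced epoch, for which the GFP equals the
    L2 norm of the sample vector divided by sqrt(n_channels).
    """
    if not epoch.is_average_referenced(rtol=1e-6):
        raise ValueError("GFP requires a common-average-referenced epoch")
    return epoch.data.std(axis=0)  # population SD; mean is ~0 per sample


def gfp_peaks(gfp: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of the GFP series.

    A peak satisfies gfp[i-1] < gfp[i] >= gfp[i+1], so a flat plateau is
    credited once, at its onset.  Endpoints are never peaks.
    """
    gfp = np.asarray(gfp, dtype=float)
    if gfp.ndim != 1 or gfp.size < 3:
        raise ValueError("GFP series must be 1-D with >= 3 samples")
    interior = np.arange(1, gfp.size - 1)
    mask = (gfp[interior] > gfp[interior - 1]) & (gfp[interior] >= gfp[interior + 1])
    return interior[mask]


def spatial_correlation(
    a: np.ndarray, b: np.ndarray, polarity_invariant: bool = True
) -> float:
    """Pearson correlation across channels of two scalp topographies.

    Both vectors are average-referenced (demeaned) first.  With
    ``polarity_invariant`` the absolute value is returned, because
    microstate maps are defined only up to sign.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("topographies must have equal channel counts >= 2")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance topography")
    r = float(np.dot(a, b) / (na * nb))
    r = float(np.clip(r, -1.0, 1.0))
    return abs(r) if polarity_invariant else r


def _prep_samples(samples: np.ndarray) -> np.ndarray:
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    return samples - samples.mean(axis=1, keepdims=True)


def _explained_variance(samples: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of total sample power captured by the assigned maps."""
    proj = np.einsum("ij,ij->i", samples, maps[labels])
    total = np.einsum("ij,ij->", samples, samples)
    if total == 0:
        raise ValueError("all-zero sample set")
    return float(np.sum(proj**2) / total)


def _single_kmeans(
    samples: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n = samples.shape[0]
    init = rng.choice(n, size=k, replace=False)
    maps = samples[init].copy()
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    prev_ev = -np.inf
    labels = np.zeros(n, dtype=int)
    converged = False
    for it in range(1, max_iter + 1):
        proj = samples @ maps.T  # (n, k)
        labels = np.argmax(proj**2, axis=1)
        # re-estimate each map as the principal eigenvector of its
        # cluster's scatter; an emptied cluster is reseeded from the
        # currently worst-fit sample
        fit = proj[np.arange(n), labels] ** 2 / np.maximum(
            np.einsum("ij,ij->i", samples, samples), np.finfo(float).tiny
        )
        for j in range(k):
            members = samples[labels == j]
            if len(members) == 0:
                worst = int(np.argmin(fit))
                v = samples[worst]
                maps[j] = v / np.linalg.norm(v)
                labels[worst] = j
                continue
            scatter = members.T @ members
            w, vecs = np.linalg.eigh(scatter)
            maps[j] = vecs[:, -1]
        ev = _explained_variance(samples, maps, labels)
        if abs(ev - prev_ev) < tol * max(abs(prev_ev), 1e-12):
            converged = True
            break
        prev_ev = ev
    proj = samples @ maps.T
    labels = np.argmax(proj**2, axis=1)
    ev = _explained_variance(samples, maps, labels)
    return maps, labels, ev, it, converged


def modified_kmeans(
    samples: np.ndarray,
    k: int,
    n_restarts: int = N_RESTARTS,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    seed: int | None = None,
) -> ClusteringResult:
    """Polarity-invariant modified k-means over scalp topographies.

    Parameters
    ----------
    samples
        (n, channels) matrix of average-referenced topographies, usually
        the EEG samples at GFP peaks.
    k
        Number of microstate maps to extract.
    n_restarts, max_iter, tol
        Restart count, iteration cap per restart, and relative
        explained-variance convergence tolerance.
    seed
        Seed for the restart initializations.

    Returns
    -------
    ClusteringResult
        Best restart by explained variance; its ``gev`` is the explained
        variance on the clustered samples themselves.
    """
    samples = _prep_samples(samples)
    n = samples.shape[0]
    if n < k:
        raise ValueError(f"need >= {k} samples for k={k}, got {n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        maps, labels, ev, n_iter, converged = _single_kmeans(samples, k, rng, max_iter, tol)
        if best is None or ev > best[2]:
            best = (maps, labels, ev, n_iter, converged)
    maps, labels, ev, n_iter, converged = best
    mapset = MapSet(maps)
    # re-derive labels for the canonicalized maps (sign fixing does not
    # change polarity-invariant assignment)
    proj = samples @ mapset.maps.T
    labels = np.argmax(proj**2, axis=1)
    disp = _dispersion(samples, mapset.maps, labels)
    return ClusteringResult(
        mapset=mapset,
        peak_labels=labels,
        gev=ev,
        dispersion=disp,
        n_iter=n_iter,
        converged=converged,
    )


def _dispersion(samples: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster dispersion W for the KL criterion.

    The trace of the within-cluster scatter once each cluster's principal
    axis (its microstate map) is removed:
    W = sum_i (|x_i|^2 - (x_i . m_{l(i)})^2).
    This is the polarity-invariant analogue of the within-cluster sum of
    squares: clusters here are axes, not centroids, so the residual is
    taken orthogonal to the map rather than around a mean.  It is also
    exactly the quantity the modified k-means minimizes, which keeps the
    W(k) curve smooth enough for elbow detection.
    """
    proj = np.einsum("ij,ij->i", samples, maps[labels])
    total = np.einsum("ij,ij->", samples, samples)
    return float(total - np.sum(proj**2))


def compute_gev(epoch: EEGEpoch, mapset: MapSet, labels: np.ndarray) -> float:
    """Global explained variance of a labelled epoch.

    GEV = sum_t (GFP_t * corr(v_t, map_{label_t}))^2 / sum_t GFP_t^2,
    with polarity-invariant correlations.  Samples with zero GFP carry
    zero weight.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != epoch.n_samples:
        raise ValueError("labels must cover every sample")
    v = epoch.data - epoch.data.mean(axis=0, keepdims=True)  # (C, T)
    gfp2 = np.einsum("ct,ct->t", v, v) / epoch.n_channels
    total = gfp2.sum()
    if total == 0:
        raise ValueError("all-zero epoch")
    proj = np.einsum("ct,tc->t", v, mapset.maps[labels])  # v_t . m_{l(t)}
    # (GFP * corr)^2 = (v.m)^2 / C for unit-norm zero-mean maps
    return float(np.sum(proj**2) / epoch.n_channels / total)


def select_k_kl(
    samples: np.ndarray,
    k_min: int = 3,
    k_max: int = 15,
    seed: int | None = None,
    n_restarts: int = N_RESTARTS,
) -> tuple[int, dict[int, float], dict[int, float]]:
    """Choose the number of maps with the Krzanowski-Lai criterion.

    Clustering is run for every k in [k_min - 1, k_max + 1] so that the
    KL statistic KL(k) = |DIFF(k)| / |DIFF(k+1)|, with
    DIFF(k) = (k-1)^(2/m) W(k-1) - k^(2/m) W(k), is defined for every k
    in [k_min, k_max].  The effective dimension m is n_channels - 1: the
    common-average reference removes one dimension.

    Returns
    -------
    (k_opt, kl_curve, dispersion_curve)
        ``k_opt`` maximizes KL(k) over [k_min, k_max]; non-finite KL
        values are recorded in the curve but excluded from the argmax.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max <= k_min + 1:
        raise ValueError("k_max must exceed k_min + 1")
    samples = _prep_samples(samples)
    if samples.shape[0] < k_max + 1:
        raise ValueError("need more samples than k_max + 1")
    m = samples.shape[1] - 1
    rng = np.random.default_rng(seed)
    disp: dict[int, float] = {}
    for k in range(k_min - 1, k_max + 2):
        res = modified_kmeans(
            samples, k, n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
        disp[k] = res.dispersion

    def diff(k: int) -> float:
        return (k - 1) ** (2 / m) * disp[k - 1] - k ** (2 / m) * disp[k]

    kl: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        d0, d1 = diff(k), diff(k + 1)
        kl[k] = abs(d0) / abs(d1) if d1 != 0 else np.inf
    # a genuine elbow requires an actual dispersion improvement at k:
    # candidates are restricted to DIFF(k) > 0, which screens out the
    # spurious ratio blow-ups that near-zero DIFF values produce on the
    # flat tail of the curve
    finite = {
        k: v for k, v in kl.items() if np.isfinite(v) and diff(k) > 0
    }
    if not finite:
        finite = {k: v for k, v in kl.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("KL criterion non-finite at every k")
    k_opt = max(finite, key=finite.get)
    return k_opt, kl, {k: disp[k] for k in range(k_min, k_max + 1)}


def group_maps(
    individual_mapsets: list[MapSet],
    k: int,
    seed: int | None = None,
    n_restarts: int = N_RESTARTS,
) -> MapSet:
    """Group-level maps: cluster the pooled individual maps.

    The individual maps of every epoch in the group are stacked into one
    topography matrix and the same modified k-means is run on the pool.
    """
    channels = {ms.n_channels for ms in individual_mapsets}
    if len(channels) != 1:
        raise ValueError("all MapSets must share the channel count")
    pooled = np.vstack([ms.maps for ms in individual_mapsets])
    if pooled.shape[0] < k:
        raise ValueError(f"pooled {pooled.shape[0]} maps < k={k}")
    res = modified_kmeans(pooled, k, n_restarts=n_restarts, seed=seed)
    return MapSet(res.mapset.maps, individual_mapsets[0].channel_names)


def match_map_order(
    reference: MapSet, others: list[MapSet]
) -> tuple[list[MapSet], list[np.ndarray]]:
    """Align map ordering across groups to a reference MapSet.

    For each MapSet the permutation maximizing the mean polarity-invariant
    spatial correlation with the corresponding reference maps is found by
    optimal linear assignment (exact for this sum objective).

    Returns the reordered MapSets and, per set, the permutation ``p``
    such that ``reordered.maps[i] == original.maps[p[i]]``.
    """
    reordered, perms = [], []
    for ms in others:
        if ms.k != reference.k or ms.n_channels != reference.n_channels:
            raise ValueError("MapSet shape mismatch with reference")
        corr = np.abs(reference.maps @ ms.maps.T)  # unit-norm zero-mean rows
        row, col = linear_sum_assignment(-corr)
        perm = col[np.argsort(row)]
        reordered.append(ms.reordered(perm))
        perms.append(perm)
    return reordered, perms
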