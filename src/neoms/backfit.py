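"""Backfitting microstate maps to continuous EEG.

Each sample is assigned to the map with maximal polarity-invariant
spatial correlation; an iterative smoothing pass then penalizes isolated
label flips.  Run-length encoding of the resulting label sequence yields
the standard microstate metrics: per-map duration (s), occurrence (Hz)
and coverage (fraction), plus the overall mean duration and occurrence
across all maps.

Map indices are 0-based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neoms.epoch import EEGEpoch
from neoms.microstates import MapSet

#: Smoothing defaults: 30 ms one-sided window, non-smoothness penalty 1.
SMOOTH_WINDOW_MS = 30.0
SMOOTH_PENALTY = 1.0


@dataclass
class LabelSeq:
    """Per-sample microstate assignment for one epoch."""

    labels: np.ndarray  # 0-based map indices, one per sample
    fs: float
    k: int
    corr: np.ndarray | None = None  # per-sample assignment |correlation|
    flagged: np.ndarray | None = None  # samples with degenerate assignment

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D sequence")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError(f"labels must lie in [0, {self.k})")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class RunSeq:
    """Maximal constant-label runs of a LabelSeq (run-length encoding)."""

    labels: np.ndarray  # run labels; adjacent entries differ
    starts: np.ndarray  # start sample of each run
    lengths: np.ndarray  # run lengths in samples
    fs: float
    k: int

    @property
    def n_runs(self) -> int:
        return self.labels.size

    @property
    def n_samples(self) -> int:
        return int(self.lengths.sum())

    def expand(self) -> np.ndarray:
        """Invert the encoding back to a per-sample label array."""
        return np.repeat(self.labels, self.lengths)


@dataclass
class MSMetrics:
    """Duration/occurrence/coverage summary of one backfitted epoch.

    ``duration[i]`` is the mean lifetime (s) of map i's runs,
    ``occurrence[i]`` its rate of appearance (runs per second), and
    ``coverage[i]`` the fraction of samples it occupies, so that
    coverage = occurrence * duration holds per map, and
    1 = overall occurrence * overall duration.  Maps with no runs get
    zeros and are listed in ``absent_maps``.
    """

    duration: np.ndarray
    occurrence: np.ndarray
    coverage: np.ndarray
    mean_duration: float
    mean_occurrence: float
    absent_maps: tuple[int, ...] = ()
    gev: float | None = None
    hurst: float | None = None
    meta: dict = field(default_factory=dict)


def assign_labels(epoch: EEGEpoch, mapset: MapSet) -> LabelSeq:
    """Label every sample with the best-correlated microstate map.

    Polarity is ignored (squared correlation is maximized) and ties
    break to the lowest map index.  Zero-variance samples cannot be
    correlated with anything; they inherit the previous sample's label
    (map 0 for a leading zero sample) and are flagged.
    """
    if epoch.n_channels != mapset.n_channels:
        raise ValueError("epoch and MapSet channel counts differ")
    if not epoch.is_average_referenced(rtol=1e-6):
        raise ValueError("backfitting requires an average-referenced epoch")
    v = epoch.data - epoch.data.mean(axis=0, keepdims=True)  # (C, T)
    proj = mapset.maps @ v  # (k, T)
    labels = np.argmax(proj**2, axis=0)
    norms = np.linalg.norm(v, axis=0)
    degenerate = norms == 0
    corr = np.abs(proj[labels, np.arange(v.shape[1])]) / np.where(degenerate, 1.0, norms)
    if degenerate.any():
        corr[degenerate] = 0.0
        idx = np.where(degenerate, 0, np.arange(v.shape[1]) + 1)
        carry = np.maximum.accumulate(idx)  # last non-degenerate position + 1
        labels = np.where(carry == 0, 0, labels[np.maximum(carry - 1, 0)])
    return LabelSeq(labels=labels, fs=epoch.fs, k=mapset.k, corr=corr, flagged=degenerate)


def smooth_labels(
    epoch: EEGEpoch,
    mapset: MapSet,
    labels: LabelSeq,
    window_ms: float = SMOOTH_WINDOW_MS,
    penalty: float = SMOOTH_PENALTY,
    max_iter: int = 100,
) -> LabelSeq:
    """Temporal smoothing of a microstate label sequence.

    Iterative relabelling in which each sample's misfit term (the signal
    variance its map leaves unexplained, normalized by the mean residual
    variance of the unsmoothed fit) is reduced by ``penalty`` times the
    number of same-label neighbours within +-``window`` samples, with
    window = round(window_ms * fs / 1000).  Iterates to a fixed point of
    the labelling or ``max_iter`` sweeps.

    ``penalty = 0`` is the identity on the labels.
    """
    if window_ms < 0 or penalty < 0:
        raise ValueError("window_ms and penalty must be nonnegative")
    if penalty == 0:
        return LabelSeq(labels.labels.copy(), labels.fs, labels.k, labels.corr, labels.flagged)
    v = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    n_ch, n_t = v.shape
    proj2 = (mapset.maps @ v) ** 2  # (k, T)
    power = np.einsum("ct,ct->t", v, v)
    resid = power[None, :] - proj2  # misfit of each map at each sample
    lab = labels.labels.copy()
    # residual-variance scale from the unsmoothed labelling, kept fixed
    e = np.mean(power - proj2[lab, np.arange(n_t)]) / (n_ch - 1)
    e = max(e, np.finfo(float).tiny)
    fit = resid / (2.0 * e * (n_ch - 1))
    w = round(window_ms * labels.fs / 1000.0)
    k = mapset.k
    for _ in range(max_iter):
        onehot = np.zeros((k, n_t))
        onehot[lab, np.arange(n_t)] = 1.0
        csum = np.cumsum(onehot, axis=1)
        pad = np.zeros((k, 1))
        csum = np.hstack([pad, csum])
        hi = np.minimum(np.arange(n_t) + w + 1, n_t)
        lo = np.maximum(np.arange(n_t) - w, 0)
        neigh = csum[:, hi] - csum[:, lo] - onehot  # same-label counts, self excluded
        new = np.argmin(fit - penalty * neigh, axis=0)
        if np.array_equal(new, lab):
            break
        lab = new
    return LabelSeq(labels=lab, fs=labels.fs, k=labels.k, corr=labels.corr, flagged=labels.flagged)


def segment_runs(labels: LabelSeq) -> RunSeq:
    """Run-length encode a label sequence into maximal constant runs."""
    lab = labels.labels
    changes = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [lab.size]])
    return RunSeq(
        labels=lab[starts],
        starts=starts,
        lengths=ends - starts,
        fs=labels.fs,
        k=labels.k,
    )


def ms_metrics(runs: RunSeq, fs: float | None = None, k: int | None = None) -> MSMetrics:
    """Duration, occurrence and coverage from a run sequence.

    Boundary runs truncated by the epoch edges are included; at 5-minute
    epochs with ~0.2 s microstates the edge bias is below 0.2%.  The
    occurrence denominator is the full epoch length in seconds (epochs
    carry no missing data).
    """
    fs = runs.fs if fs is None else fs
    k = runs.k if k is None else k
    if runs.n_runs == 0:
        raise ValueError("empty run sequence")
    total_samples = runs.n_samples
    total_s = total_samples / fs
    duration = np.zeros(k)
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    absent = []
    for j in range(k):
        sel = runs.labels == j
        n_j = int(sel.sum())
        if n_j == 0:
            absent.append(j)
            continue
        duration[j] = runs.lengths[sel].mean() / fs
        occurrence[j] = n_j / total_s
        coverage[j] = runs.lengths[sel].sum() / total_samples
    return MSMetrics(
        duration=duration,
        occurrence=occurrence,
        coverage=coverage,
        mean_duration=float(runs.lengths.mean() / fs),
        mean_occurrence=float(runs.n_runs / total_s),
        absent_maps=tuple(absent),
    )


def backfit(
    epoch: EEGEpoch,
    mapset: MapSet,
    window_ms: float = SMOOTH_WINDOW_MS,
    penalty: float = SMOOTH_PENALTY,
) -> LabelSeq:
    """Assign labels and smooth them in one call."""
    raw = assign_labels(epoch, mapset)
    return smooth_labels(epoch, mapset, raw, window_ms=window_ms, penalty=penalty)
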