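"""Microstate syntax: transition-probability structure of the run sequence.

The run-level label sequence has no self-transitions by construction, so
chance expectations must respect that constraint: the expected
probability of A -> B is q(B) / (1 - q(A)), with q the run-label shares.
Two tests are provided: a randomized chi-square test of the hypothesis
that the whole syntax is random (null built by shuffling the run labels
while forbidding adjacent equals), and per-transition paired t-tests of
observed minus expected probabilities across the epochs of a group, with
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from neoms.backfit import RunSeq


@dataclass
class TransitionStats:
    """Observed vs expected transition probabilities for one epoch."""

    observed: np.ndarray  # k x k row-stochastic, zero diagonal
    expected: np.ndarray
    counts: np.ndarray  # raw transition counts
    k: int


def _run_labels(runs: RunSeq | np.ndarray) -> np.ndarray:
    if isinstance(runs, RunSeq):
        return np.asarray(runs.labels, dtype=int)
    return np.asarray(runs, dtype=int)


def _transition_counts(labels: np.ndarray, k: int) -> np.ndarray:
    idx = labels[:-1] * k + labels[1:]
    return np.bincount(idx, minlength=k * k).reshape(k, k).astype(float)


def observed_transitions(runs: RunSeq | np.ndarray, k: int) -> np.ndarray:
    """Row-normalized counts of consecutive run-label pairs.

    The diagonal is structurally zero (adjacent runs differ).  Rows for
    labels with no outgoing transitions are NaN.
    """
    labels = _run_labels(runs)
    if labels.size < 2:
        raise ValueError("need >= 2 runs to count transitions")
    counts = _transition_counts(labels, k)
    out_deg = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(out_deg > 0, counts / out_deg, np.nan)


def expected_transitions(runs: RunSeq | np.ndarray, k: int) -> np.ndarray:
    """Chance transition probabilities from run-label shares.

    expected(A -> B) = q(B) / (1 - q(A)) for A != B, where q(X) is the
    fraction of runs labelled X; this is the distribution of the next
    run label under random ordering with no self-transitions.
    """
    labels = _run_labels(runs)
    if labels.size < 2:
        raise ValueError("need >= 2 runs")
    q = np.bincount(labels, minlength=k) / labels.size
    if np.any(q >= 1.0):
        raise ValueError("single-label sequence: expected matrix undefined")
    e = np.tile(q, (k, 1)) / (1.0 - q)[:, None]
    np.fill_diagonal(e, 0.0)
    absent = q == 0
    e[absent, :] = np.nan
    return e


def transition_stats(runs: RunSeq | np.ndarray, k: int) -> TransitionStats:
    labels = _run_labels(runs)
    return TransitionStats(
        observed=observed_transitions(labels, k),
        expected=expected_transitions(labels, k),
        counts=_transition_counts(labels, k),
        k=k,
    )


def _chisq_stat(counts: np.ndarray, q: np.ndarray) -> float:
    """Chi-square of transition counts against the run-share expectation."""
    k = q.size
    out_deg = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = out_deg[:, None] * q[None, :] / (1.0 - q)[:, None]
    np.fill_diagonal(e, 0.0)
    mask = e > 0
    return float(np.sum((counts[mask] - e[mask]) ** 2 / e[mask]))


def _batch_shuffle_no_adjacent(
    labels: np.ndarray, n_perm: int, rng: np.random.Generator, max_passes: int = 500
) -> np.ndarray:
    """Random rearrangements of ``labels`` with no adjacent equal pair.

    Each row starts as an independent uniform permutation of the label
    multiset; remaining adjacent duplicates are then removed by local
    redraws: a random duplicate position is swapped with a random
    partner, accepted only when the swap leaves no violation around
    either position (so the violation count strictly decreases).
    """
    r = labels.size
    s = labels[np.argsort(rng.random((n_perm, r)), axis=1)]
    active = np.arange(n_perm)
    for _ in range(max_passes):
        viol = s[active, 1:] == s[active, :-1]
        still_bad = viol.any(axis=1)
        active = active[still_bad]
        if active.size == 0:
            break
        viol = viol[still_bad]
        # one random violation per bad row, one random swap partner
        pick = np.where(viol, rng.random(viol.shape), -1.0)
        i = pick.argmax(axis=1) + 1  # position of the duplicate
        j = rng.integers(0, r, size=active.size)
        si = s[active, i]
        sj = s[active, j]

        def val_after(pos: np.ndarray) -> np.ndarray:
            # post-swap value at position array ``pos`` (clipped gather)
            v = s[active, np.clip(pos, 0, r - 1)]
            v = np.where(pos == i, sj, v)
            v = np.where(pos == j, si, v)
            return v

        ok = si != sj
        for pos, new in ((i, sj), (j, si)):
            for off in (-1, 1):
                nbpos = pos + off
                inside = (nbpos >= 0) & (nbpos < r)
                ok &= ~inside | (val_after(nbpos) != new)
        acc = active[ok]
        s[acc, i[ok]] = sj[ok]
        s[acc, j[ok]] = si[ok]
    return s


def syntax_chisq_test(
    runs: RunSeq | np.ndarray,
    k: int,
    n_perm: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Randomized chi-square test that the microstate syntax is random.

    The statistic compares transition counts with the run-share
    expectation (self-transitions structurally excluded); the null is
    built by shuffling the run-label sequence, preserving the label
    multiset and forbidding adjacent equal labels.  The p-value uses the
    add-one estimator p = (1 + #{null >= observed}) / (1 + n_perm), so
    p >= 1/(n_perm + 1) always.
    """
    labels = _run_labels(runs)
    if labels.size < 10:
        raise ValueError("need >= 10 runs")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if np.unique(labels).size < 2:
        raise ValueError("degenerate single-label sequence")
    rng = np.random.default_rng(seed)
    q = np.bincount(labels, minlength=k) / labels.size
    obs = _chisq_stat(_transition_counts(labels, k), q)
    perms = _batch_shuffle_no_adjacent(labels, n_perm, rng)
    # batched transition counts
    idx = perms[:, :-1] * k + perms[:, 1:]
    offs = (np.arange(n_perm) * k * k)[:, None]
    flat = np.bincount((idx + offs).ravel(), minlength=n_perm * k * k)
    counts = flat.reshape(n_perm, k, k).astype(float)
    out_deg = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = out_deg[:, :, None] * (q[None, None, :] / (1.0 - q)[None, :, None])
    eye = np.eye(k, dtype=bool)
    e[:, eye] = 0.0
    mask = e > 0
    null = np.divide((counts - e) ** 2, e, out=np.zeros_like(e), where=mask).sum(axis=(1, 2))
    p = (1 + int(np.sum(null >= obs))) / (1 + n_perm)
    return obs, p


def syntax_chisq_test_pooled(
    runs_list: list[RunSeq | np.ndarray],
    k: int,
    n_perm: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Group variant: pool transition counts across epochs.

    The statistic sums each epoch's counts against its own run-share
    expectation; the null shuffles every epoch's run sequence
    independently.
    """
    if not runs_list:
        raise ValueError("empty group")
    rng = np.random.default_rng(seed)
    obs = 0.0
    null = np.zeros(n_perm)
    for runs in runs_list:
        labels = _run_labels(runs)
        q = np.bincount(labels, minlength=k) / labels.size
        obs += _chisq_stat(_transition_counts(labels, k), q)
        perms = _batch_shuffle_no_adjacent(labels, n_perm, rng)
        idx = perms[:, :-1] * k + perms[:, 1:]
        offs = (np.arange(n_perm) * k * k)[:, None]
        counts = np.bincount((idx + offs).ravel(), minlength=n_perm * k * k).reshape(
            n_perm, k, k
        ).astype(float)
        out_deg = counts.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = out_deg[:, :, None] * (q[None, None, :] / (1.0 - q)[None, :, None])
        e[:, np.eye(k, dtype=bool)] = 0.0
        mask = e > 0
        null += np.divide((counts - e) ** 2, e, out=np.zeros_like(e), where=mask).sum(axis=(1, 2))
    p = (1 + int(np.sum(null >= obs))) / (1 + n_perm)
    return obs, p


def transition_group_test(
    per_epoch_stats: list[TransitionStats | tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-transition paired t-tests of observed vs expected probabilities.

    For each of the k(k-1) ordered transitions, the per-epoch differences
    (observed - expected) are tested against zero with a two-sided paired
    t-test; Benjamini-Hochberg FDR correction is applied across the
    k(k-1) tests of the group.  Zero-variance transitions get NaN p and
    are flagged.  Significance is reported at ``alpha`` and at 0.1 (the
    two arrow classes of the usual syntax graphs).
    """
    if len(per_epoch_stats) < 3:
        raise ValueError("need >= 3 epochs per group")
    pairs = []
    for st in per_epoch_stats:
        if isinstance(st, TransitionStats):
            pairs.append((st.observed, st.expected))
        else:
            pairs.append(st)
    k = pairs[0][0].shape[0]
    diffs = np.stack([o - e for o, e in pairs])  # (n_epochs, k, k)
    rows = []
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            d = diffs[:, a, b]
            d = d[np.isfinite(d)]
            if d.size < 3 or np.allclose(d, d[0]):
                t_stat, p = np.nan, np.nan
            else:
                t_stat, p = stats.ttest_1samp(d, 0.0)
            rows.append(
                {
                    "from": a,
                    "to": b,
                    "mean_diff": float(np.mean(d)) if d.size else np.nan,
                    "t": float(t_stat),
                    "p_raw": float(p),
                    "direction": "more" if d.size and np.mean(d) > 0 else "less",
                    "flagged": bool(np.isnan(p)),
                }
            )
    df = pd.DataFrame(rows)
    valid = df["p_raw"].notna().to_numpy()
    p_fdr = np.full(len(df), np.nan)
    if valid.any():
        p_fdr[valid] = multipletests(df.loc[valid, "p_raw"], method="fdr_bh")[1]
    df["p_fdr"] = p_fdr
    df["sig_alpha"] = df["p_fdr"] < alpha
    df["sig_trend"] = df["p_fdr"] < 0.1
    return df
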