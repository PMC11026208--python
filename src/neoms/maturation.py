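"""Maturation statistics: topography similarity, Hurst exponents, age trends.

TANOVA compares two scalp topographies with the polarity-invariant
spatial correlation as effect size; the null distribution is built by
randomly permuting the channel order of one map.  Significance means
*similarity*: a small p says the observed correlation is larger than
chance channel alignment would produce.

The Hurst exponent of a microstate label sequence is estimated with
detrended fluctuation analysis (DFA).  A categorical sequence has no
canonical embedding into a random walk, so every nontrivial bipartition
of the k labels is mapped to a +-1 series, each series is analysed with
order-1 DFA, and the estimate is the mean scaling slope across the
2^(k-1) - 1 bipartitions.  H = 0.5 is the memoryless reference; values
above indicate long-range persistence of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from neoms.backfit import LabelSeq


@dataclass
class TanovaResult:
    effect_size: float  # |spatial correlation| of the two maps
    p: float
    n_perm: int
    null_mean: float
    null_sd: float


@dataclass
class AgeAssociation:
    metric: str
    sleep_state: str
    r: float  # Pearson correlation with PMA
    p: float
    n: int
    slope: float  # least-squares slope of metric on PMA (per week)


def tanova_similarity(
    map_a: np.ndarray,
    map_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
) -> TanovaResult:
    """Channel-permutation test of topographic similarity (TANOVA).

    Effect size is the polarity-invariant spatial correlation between
    the maps.  The null permutes the channel order of ``map_b`` and
    recomputes the correlation; p uses the add-one estimator, so
    p >= 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("channel counts differ")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("constant map has no topography to compare")
    a /= na
    b /= nb
    obs = abs(float(a @ b))
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, b.size)), axis=1)
    null = np.abs(b[perms] @ a)  # demeaning is permutation-invariant
    p = (1 + int(np.sum(null >= obs))) / (1 + n_perm)
    return TanovaResult(
        effect_size=obs,
        p=p,
        n_perm=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )


def _dfa_fluctuation(walk: np.ndarray, box: int) -> float:
    """RMS residual of per-box linear detrending (order-1 DFA)."""
    n = walk.size
    n_boxes = n // box
    segs = walk[: n_boxes * box].reshape(n_boxes, box)
    t = np.arange(box, dtype=float)
    t_mean = t.mean()
    t_var = np.sum((t - t_mean) ** 2)
    y_mean = segs.mean(axis=1, keepdims=True)
    slope = (segs - y_mean) @ (t - t_mean) / t_var
    resid = segs - y_mean - slope[:, None] * (t - t_mean)
    return float(np.sqrt(np.mean(resid**2)))


def hurst_dfa(
    labels: LabelSeq | np.ndarray,
    n_scales: int = 15,
    min_box: int = 10,
) -> float:
    """Hurst exponent of a microstate sequence via bipartition DFA.

    For each nontrivial bipartition of the label alphabet, the sequence
    is mapped to +-1, integrated into a walk, and the fluctuation
    function F(n) computed over ``n_scales`` log-spaced box sizes in
    [min_box, length/4] with linear detrending; H is the mean slope of
    log F against log n across bipartitions.  Bipartitions yielding a
    constant series (e.g. a label never occurs) carry no information and
    are skipped; an entirely constant sequence is an error.
    """
    if isinstance(labels, LabelSeq):
        lab = labels.labels
        k = labels.k
    else:
        lab = np.asarray(labels, dtype=int)
        k = int(lab.max()) + 1
    n = lab.size
    if n < 1000:
        raise ValueError("need >= 1000 samples for a stable DFA estimate")
    boxes = np.unique(
        np.round(np.geomspace(min_box, n // 4, n_scales)).astype(int)
    )
    alphabet = list(range(k))
    slopes = []
    # enumerate bipartitions as subsets containing label 0 (complement-unique)
    for size in range(1, k):
        for subset in combinations(alphabet[1:], size - 1):
            side = np.isin(lab, [0, *subset])
            x = np.where(side, 1.0, -1.0)
            if np.all(x == x[0]):
                continue
            walk = np.cumsum(x - x.mean())
            f = np.array([_dfa_fluctuation(walk, b) for b in boxes])
            good = f > 0
            if good.sum() < 3:
                continue
            slope, _ = np.polyfit(np.log(boxes[good]), np.log(f[good]), 1)
            slopes.append(slope)
    if not slopes:
        raise ValueError("constant label sequence: Hurst exponent undefined")
    return float(np.mean(slopes))


METRIC_COLUMNS = ("mean_duration", "mean_occurrence", "hurst")


def metric_age_association(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson association of per-epoch metrics with post-menstrual age.

    ``table`` must hold one row per epoch with at least ``subject_id``,
    ``pma_weeks``, ``sleep_state`` and the metric columns.  For each
    sleep state and metric the Pearson r against PMA, its two-sided p,
    and the least-squares slope are computed.  Also returns the tidy
    long-format table (one row per epoch x metric) that an external
    mixed-effects model would consume.

    Row order of the input is irrelevant.
    """
    required = {"subject_id", "pma_weeks", "sleep_state"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    rows = []
    for state, sub in table.groupby("sleep_state"):
        if len(sub) < 3:
            raise ValueError(f"need >= 3 epochs per sleep state, {state} has {len(sub)}")
        pma = sub["pma_weeks"].to_numpy(dtype=float)
        if np.allclose(pma, pma[0]):
            raise ValueError("constant PMA: association undefined")
        for metric in metrics:
            y = sub[metric].to_numpy(dtype=float)
            if np.allclose(y, y[0]):
                raise ValueError(f"constant metric {metric!r} in state {state}")
            r, p = stats.pearsonr(pma, y)
            fit = stats.linregress(pma, y)
            rows.append(
                AgeAssociation(
                    metric=metric,
                    sleep_state=str(state),
                    r=float(r),
                    p=float(p),
                    n=len(sub),
                    slope=float(fit.slope),
                )
            )
    assoc = pd.DataFrame([vars(a) for a in rows])
    id_cols = [
        c
        for c in ("subject_id", "pma_weeks", "ga_weeks", "sex", "sleep_state")
        if c in table.columns
    ]
    tidy = table.melt(
        id_vars=id_cols,
        value_vars=list(metrics),
        var_name="metric",
        value_name="value",
    )
    return assoc, tidy
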