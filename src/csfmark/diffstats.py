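"""Discovery-phase statistics: t-tests, permutation FDR, power analysis.

The per-protein test is the equal-variance two-sample Student t-test; fold
changes are reported as log2 mean differences on the pre-z-score log2
matrix. Multiple testing is handled with a SAM-style permutation FDR: the
same statistic is recomputed under group-label permutations, and each
protein's q-value estimates the FDR at its observed statistic as the median
permuted exceedance count over the observed exceedance count. The
sample-size calculator inverts the two-sample noncentral-t power equation.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of a two-sample, two-sided t-test power analysis.

    ``delta`` is the detectable log2 difference, ``sigma`` the within-group
    SD on the same scale; power is evaluated with the noncentral t
    distribution (df = 2n-2, noncentrality delta/sigma * sqrt(n/2)).
    """

    delta: float
    sigma: float
    alpha: float = 1e-4
    power: float = 0.8

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta == 0:
            raise ValueError("delta must be non-zero")


def two_sample_t_power(n: float, effect_size: float, alpha: float) -> float:
    """Power of the two-sided two-sample t-test at per-group size ``n``.

    ``effect_size`` is delta/sigma. The negligible lower-tail term can
    underflow to NaN in scipy's noncentral t at large noncentrality; it is
    treated as zero.
    """
    df = 2.0 * n - 2.0
    ncp = abs(effect_size) * math.sqrt(n / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    return float(np.nan_to_num(upper) + np.nan_to_num(lower))


def power_sample_size(spec: PowerSpec, n_max: float = 1e6) -> tuple[float, int]:
    """Per-group sample size achieving the requested power.

    Solves the noncentral-t power equation for real-valued n by
    root-finding; returns (n, ceil(n)).
    """
    d = abs(spec.delta) / spec.sigma

    def gap(n):
        return two_sample_t_power(n, d, spec.alpha) - spec.power

    lo = 2.0 + 1e-9
    if gap(lo) >= 0:
        return lo, 2
    if gap(n_max) < 0:
        raise ValueError(f"no solution below n_max={n_max:g}")
    n = optimize.brentq(gap, lo, n_max, xtol=1e-10)
    return float(n), int(math.ceil(n))


def _as_frame(matrix) -> pd.DataFrame:
    """Accept an AbundanceMatrix or a plain proteins x samples DataFrame."""
    if isinstance(matrix, pd.DataFrame):
        return matrix
    values = getattr(matrix, "values", None)
    if isinstance(values, pd.DataFrame):
        return values
    raise TypeError("matrix must be an AbundanceMatrix or DataFrame")


def _group_arrays(
    matrix, labels: pd.Series, group_order=("ALS", "HC")
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    """Split a matrix (AbundanceMatrix or DataFrame) into two group blocks."""
    values = _as_frame(matrix)
    labels = pd.Series(labels)
    missing = [g for g in group_order if (labels == g).sum() < 2]
    if missing:
        raise ValueError(f"group(s) with <2 samples: {missing}")
    cols1 = labels.index[labels == group_order[0]]
    cols2 = labels.index[labels == group_order[1]]
    a = values[cols1].to_numpy(dtype=float)
    b = values[cols2].to_numpy(dtype=float)
    return a, b, values.to_numpy(dtype=float), values.index


def _t_statistics(a: np.ndarray, b: np.ndarray, s0: float = 0.0) -> np.ndarray:
    """Row-wise equal-variance t statistics, NaN-aware, with SAM offset s0.

    Rows with zero pooled variance get a 0 statistic (flagged upstream).
    """
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    m1 = np.nanmean(a, axis=1)
    m2 = np.nanmean(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / (se + s0)
    t[~np.isfinite(t)] = 0.0
    return t


def differential_table(
    matrix,
    labels: pd.Series,
    group_order=("ALS", "HC"),
) -> pd.DataFrame:
    """Per-protein differential table, sorted by p.

    p comes from the equal-variance two-sample t-test on the transformed
    matrix; log2fc is the group mean difference on the pre-z-score log2
    matrix (``matrix.log2_values`` when present, the matrix itself
    otherwise). Zero-variance proteins get p = 1 and a flag, never NaN.
    """
    a, b, _, index = _group_arrays(matrix, labels, group_order)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    t = _t_statistics(a, b)
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)

    with np.errstate(invalid="ignore"):
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
    zero_var = (v1 + v2) == 0
    p = np.where(zero_var, 1.0, p)

    log2_source = getattr(matrix, "log2_values", None)
    if log2_source is None:
        log2_source = _as_frame(matrix)
    labels = pd.Series(labels)
    la = log2_source[labels.index[labels == group_order[0]]].to_numpy(dtype=float)
    lb = log2_source[labels.index[labels == group_order[1]]].to_numpy(dtype=float)
    log2fc = np.nanmean(la, axis=1) - np.nanmean(lb, axis=1)
    log2fc = np.where(zero_var & (log2fc == 0), 0.0, log2fc)

    table = pd.DataFrame(
        {
            "protein_id": index,
            "log2fc": log2fc,
            "t_statistic": t,
            "p_value": p,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "zero_variance": zero_var,
        }
    ).set_index("protein_id")
    return table.sort_values("p_value")


def _max_arrangements(n1: int, n2: int) -> int:
    return math.comb(n1 + n2, n1)


def sam_qvalues(
    matrix,
    labels: pd.Series,
    n_permutations: int = 1000,
    seed: int | None = None,
    s0: float = 0.0,
    group_order=("ALS", "HC"),
    exhaustive_cap: int = 20000,
    aggregate: str = "mean",
) -> pd.Series:
    """SAM-style permutation q-values per protein.

    For each protein, the FDR at its observed |statistic| is estimated as
    the number of permuted statistics at least as extreme — aggregated over
    permutations — divided by the number of observed statistics at least as
    extreme, clipped to [0, 1] and made monotone (non-increasing in
    |statistic| rank). ``aggregate="mean"`` (default) is the expected
    false-call count of the original formulation and is well calibrated at
    the top of the list: under a complete null the expected exceedance
    count of the observed maximum is ~1, so the top q stays near 1.
    ``aggregate="median"`` gives the median-FDR variant, which can report
    q = 0 for the top-ranked protein whenever more than half of the
    permutations produce no exceedance, and is therefore anticonservative
    for the extreme ranks. When the requested permutation count reaches the
    number of distinct label arrangements (and that number is below
    ``exhaustive_cap``), all arrangements are enumerated instead.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a, b, values, index = _group_arrays(matrix, labels, group_order)
    n1, n2 = a.shape[1], b.shape[1]
    combined = np.concatenate([a, b], axis=1)
    d_obs = np.abs(_t_statistics(a, b, s0=s0))

    with np.errstate(invalid="ignore"):
        var_total = np.nanvar(combined, axis=1, ddof=1)
    testable = var_total > 0
    if not testable.any():
        logger.warning("all rows constant; q-values undefined")
        return pd.Series(np.nan, index=index, name="q_value")

    total = n1 + n2
    n_distinct = _max_arrangements(n1, n2)
    if n_permutations >= n_distinct and n_distinct <= exhaustive_cap:
        logger.info(
            "requested %d permutations >= %d distinct arrangements; "
            "enumerating exhaustively",
            n_permutations, n_distinct,
        )
        perms = [
            np.array(c)
            for c in itertools.combinations(range(total), n1)
        ]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(total)[:n1] for _ in range(n_permutations)]

    obs_sorted = np.sort(d_obs[testable])
    m = len(obs_sorted)
    # observed exceedance count per protein (>= its own statistic)
    obs_count = m - np.searchsorted(obs_sorted, d_obs, side="left")
    obs_count = np.maximum(obs_count, 1)

    all_idx = np.arange(total)
    perm_counts = np.empty((len(perms), len(d_obs)), dtype=np.int64)
    for k, pa in enumerate(perms):
        mask = np.zeros(total, dtype=bool)
        mask[pa] = True
        pa_cols = all_idx[mask]
        pb_cols = all_idx[~mask]
        d_perm = np.abs(
            _t_statistics(combined[:, pa_cols], combined[:, pb_cols], s0=s0)
        )
        perm_sorted = np.sort(d_perm[testable])
        perm_counts[k] = m - np.searchsorted(perm_sorted, d_obs, side="left")

    if aggregate == "mean":
        agg_count = perm_counts.mean(axis=0)
    else:
        agg_count = np.median(perm_counts, axis=0)
    q_raw = np.clip(agg_count / obs_count, 0.0, 1.0)

    # Monotone: a protein's q is the smallest estimated FDR over all
    # cutoffs at or below its |statistic| (the rejection regions that
    # contain it), so a running minimum along ascending |statistic| makes q
    # non-increasing with significance.
    order = np.argsort(d_obs)  # ascending |d|
    q_sorted = q_raw[order]
    q_mono = np.minimum.accumulate(q_sorted)
    q = np.empty_like(q_raw)
    q[order] = q_mono
    q[~testable] = np.nan
    return pd.Series(q, index=index, name="q_value")


def normality_screen(
    matrix,
    labels: pd.Series | None = None,
    mode: str = "pooled",
    alpha: float = 0.05,
    group_order=("ALS", "HC"),
) -> tuple[pd.DataFrame, float]:
    """Shapiro-Wilk normality screen per protein.

    ``mode="pooled"`` (default) tests the within-group-centered residuals of
    each protein; ``mode="per_group"`` tests each group separately and a
    protein passes only when both groups do. Rows with fewer than 3 values
    or zero variance are flagged untestable. Returns the per-protein table
    and the fraction of testable proteins with p > alpha.
    """
    values = _as_frame(matrix)
    rows = []
    for protein, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        if labels is not None:
            lab = pd.Series(labels)
            groups = [
                row[lab.index[lab == g]].dropna().to_numpy(dtype=float)
                for g in group_order
            ]
        else:
            groups = [row.dropna().to_numpy(dtype=float)]
        if mode == "pooled":
            resid = np.concatenate([g - g.mean() for g in groups if len(g)])
            testable = len(resid) >= 3 and np.ptp(resid) > 0
            p = float(stats.shapiro(resid).pvalue) if testable else np.nan
        elif mode == "per_group":
            ps = []
            testable = True
            for g in groups:
                if len(g) < 3 or np.ptp(g) == 0:
                    testable = False
                    break
                ps.append(float(stats.shapiro(g).pvalue))
            p = min(ps) if testable else np.nan
        else:
            raise ValueError("mode must be 'pooled' or 'per_group'")
        rows.append((protein, p, not testable))
    out = pd.DataFrame(rows, columns=["protein_id", "shapiro_p", "untestable"])
    out = out.set_index("protein_id")
    tested = out.loc[~out["untestable"], "shapiro_p"]
    fraction = float((tested > alpha).mean()) if len(tested) else float("nan")
    return out, fraction
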