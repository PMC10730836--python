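"""Group comparisons, PSI-expression correlation, permutation test, IHC scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    effect: float  # delta PSI or correlation coefficient
    statistic: float
    p_value: float
    df: float | None
    n_used: dict
    method: str
    pairwise: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    observed_mean_abs_r: float
    n_targets: int
    n_perm: int
    null_mean: float
    null_sd: float
    empirical_p: float
    seed: int | None


@dataclass
class IhcScore:
    counts: tuple[int, int, int, int]  # Negative, Low, Moderate, High
    percent_positive: float
    h_score: float


def trim_outliers(values, k_sd: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass +/- k SD trim around the population mean.

    Mean and sample (n-1) SD are computed once on all values; entries with
    |v - mean| > k_sd * SD are removed.  If SD is zero nothing is removed.
    Returns (retained values, removed indices).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    mean = values.mean()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0 or np.isnan(sd):
        return values.copy(), np.array([], dtype=int)
    removed = np.flatnonzero(np.abs(values - mean) > k_sd * sd)
    kept = np.delete(values, removed)
    return kept, removed


def compare_psi_groups(
    psi: pd.Series,
    design: pd.Series,
    trim: bool = False,
    k_sd: float = 2.0,
    equal_var: bool = False,
    trim_per_group: bool = False,
    compute_pairwise: bool = True,
) -> StatResult:
    """Compare PSI between groups: two-sided t-test for two groups, one-way
    ANOVA with Tukey HSD pairwise comparisons for more.

    ``psi`` is indexed by sample, ``design`` maps sample -> group label.
    Missing PSI values are dropped.  Trimming (off by default) is a single
    pooled-population +/- k_sd SD pass; per-group mode is available.
    """
    common = psi.index.intersection(design.index)
    psi = psi.loc[common].dropna()
    design = design.loc[psi.index]
    groups = sorted(design.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    flags: list[str] = []
    if trim:
        n_before = len(psi)
        if trim_per_group:
            keep_idx = []
            for g in groups:
                vals = psi[design == g]
                _, removed = trim_outliers(vals.values, k_sd)
                keep_idx.extend(vals.index[np.setdiff1d(np.arange(len(vals)), removed)])
            psi = psi.loc[keep_idx]
        else:
            _, removed = trim_outliers(psi.values, k_sd)
            psi = psi.drop(psi.index[removed])
        design = design.loc[psi.index]
        n_removed = n_before - len(psi)
        if n_removed:
            flags.append(f"trimmed {n_removed} samples")

    arrays = {g: psi[design == g].values for g in groups}
    n_used = {g: len(a) for g, a in arrays.items()}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values after trimming")

    if len(groups) == 2:
        g1, g2 = groups
        res = sps.ttest_ind(arrays[g2], arrays[g1], equal_var=equal_var)
        effect = float(arrays[g2].mean() - arrays[g1].mean())
        if np.isnan(res.statistic) and effect == 0.0:
            # both groups constant and equal: no difference, not undefined
            return StatResult(
                effect=0.0,
                statistic=0.0,
                p_value=1.0,
                df=float(res.df) if not np.isnan(res.df) else None,
                n_used=n_used,
                method="welch_t" if not equal_var else "pooled_t",
                flags=flags + ["zero_variance"],
            )
        return StatResult(
            effect=effect,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            df=float(res.df),
            n_used=n_used,
            method="welch_t" if not equal_var else "pooled_t",
            flags=flags,
        )

    f_stat, p = sps.f_oneway(*(arrays[g] for g in groups))
    pairwise = None
    if compute_pairwise:
        tukey = pairwise_tukeyhsd(
            endog=psi.values, groups=design.values.astype(str), alpha=0.05
        )
        pairwise = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
    k = len(groups)
    return StatResult(
        effect=float("nan"),
        statistic=float(f_stat),
        p_value=float(p),
        df=float(k - 1),
        n_used=n_used,
        method="anova_tukey",
        pairwise=pairwise,
        flags=flags,
    )


def correlate_psi_expression(
    psi_vector,
    expr_vector,
    method: str = "pearson",
) -> StatResult:
    """Correlation (Pearson or Spearman) between PSI and log2 TPM expression."""
    psi = np.asarray(psi_vector, dtype=float)
    expr = np.asarray(expr_vector, dtype=float)
    if psi.shape != expr.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(psi) | np.isnan(expr))
    psi, expr = psi[ok], expr[ok]
    if psi.size < 3:
        raise ValueError("need at least 3 complete pairs")
    flags = []
    if psi.std() == 0 or expr.std() == 0:
        return StatResult(
            effect=float("nan"),
            statistic=float("nan"),
            p_value=float("nan"),
            df=None,
            n_used={"pairs": int(psi.size)},
            method=method,
            flags=["zero_variance"],
        )
    if method == "pearson":
        r, p = sps.pearsonr(psi, expr)
    elif method == "spearman":
        r, p = sps.spearmanr(psi, expr)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(
        effect=float(r),
        statistic=float(r),
        p_value=float(p),
        df=float(psi.size - 2),
        n_used={"pairs": int(psi.size)},
        method=method,
        flags=flags,
    )


def _abs_correlations(psi_matrix: pd.DataFrame, expr: np.ndarray, method: str) -> pd.Series:
    """|r| of each PSI row against the expression vector; constant rows -> 0."""
    mat = psi_matrix.values.astype(float)
    if method == "spearman":
        mat = np.apply_along_axis(sps.rankdata, 1, np.where(np.isnan(mat), np.nan, mat))
        expr = sps.rankdata(expr)
    out = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        row = mat[i]
        ok = ~np.isnan(row)
        x, y = row[ok], np.asarray(expr, dtype=float)[ok]
        if x.size < 3 or x.std() == 0 or y.std() == 0:
            if x.size >= 3 and x.std() == 0:
                logger.warning("constant PSI row %s; |r| set to 0", psi_matrix.index[i])
            out[i] = 0.0
        else:
            out[i] = abs(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, index=psi_matrix.index)


def permutation_correlation_test(
    psi_matrix: pd.DataFrame,
    expr_vector,
    target_ids,
    background_ids,
    n_perm: int = 10000,
    seed: int | None = None,
    method: str = "pearson",
    strict_greater: bool = True,
    plus_one_correction: bool = False,
) -> PermutationResult:
    """Permutation test of the mean |r| of a target exon set.

    Observed statistic: mean over targets of |corr(PSI row, expression)|.
    Each permutation draws |targets| exon ids from the background pool without
    replacement and recomputes the mean |r|; the empirical p-value is the
    proportion of permutations whose null mean exceeds the observed one
    (strictly greater by default; >= available via ``strict_greater=False``;
    a (+1)/(+1) small-sample correction is opt-in).
    """
    target_ids = list(target_ids)
    background_ids = list(background_ids)
    if len(target_ids) == 0:
        raise ValueError("empty target set")
    if len(background_ids) < len(target_ids):
        raise ValueError("background pool smaller than target set")
    missing = set(target_ids) - set(psi_matrix.index)
    if missing:
        raise ValueError(f"target ids absent from PSI matrix: {sorted(missing)[:5]}")

    expr = np.asarray(expr_vector, dtype=float)
    all_ids = list(dict.fromkeys(target_ids + background_ids))
    abs_r = _abs_correlations(psi_matrix.loc[all_ids], expr, method)

    observed = float(abs_r.loc[target_ids].mean())
    rng = np.random.default_rng(seed)
    bg = abs_r.loc[background_ids].values
    k = len(target_ids)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = bg[rng.choice(len(bg), size=k, replace=False)].mean()

    # tolerance so summation-order noise cannot turn an exact tie either way
    tol = 1e-12 * max(1.0, abs(observed))
    if strict_greater:
        exceed = int((null > observed + tol).sum())
    else:
        exceed = int((null >= observed - tol).sum())
    if plus_one_correction:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    return PermutationResult(
        observed_mean_abs_r=observed,
        n_targets=k,
        n_perm=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        empirical_p=float(p),
        seed=seed,
    )


def ihc_scores(bin_counts) -> IhcScore:
    """Percent-positive and H-score from Negative/Low/Moderate/High cell counts.

    percent_positive = 100 * (L + M + H) / total;
    h_score = 100 * (1*pL + 2*pM + 3*pH) in [0, 300].
    """
    neg, low, mod, high = (int(c) for c in bin_counts)
    if min(neg, low, mod, high) < 0:
        raise ValueError("counts must be >= 0")
    total = neg + low + mod + high
    if total == 0:
        raise ValueError("total count must be > 0")
    percent_positive = 100.0 * (low + mod + high) / total
    h = 100.0 * (1 * low / total + 2 * mod / total + 3 * high / total)
    return IhcScore(counts=(neg, low, mod, high), percent_positive=percent_positive, h_score=h)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
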