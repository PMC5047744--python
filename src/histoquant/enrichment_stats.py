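"""Pulldown-vs-input enrichment statistics.

The comparison scheme: establish a technical-variability threshold from the
H2A T16/S16 variant-pair recovery control, test each group for normality
with Shapiro-Wilk, and where the gate passes compare pulldown vs input
relative abundances with an unpaired two-sample Welch's t-test (no equal-
variance assumption).  Pattern-level similarity between whole samples is
summarized with Pearson correlation (Fisher-z confidence intervals), and
paired timepoint tables with per-form -log2 ratios.

Sign convention: group A is always the input, so enrichment in the pulldown
yields a *negative* t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantification import AbundanceTable

__all__ = [
    "WelchResult",
    "ShapiroResult",
    "ThresholdResult",
    "CorrelationMatrix",
    "welch_test",
    "shapiro_gate",
    "variability_threshold",
    "fold_change_table",
    "pearson_matrix",
    "global_log2_compare",
    "DEFAULT_TECHNICAL_THRESHOLD",
]

#: fixed fallback fold-change threshold (twice a 20% technical spread)
DEFAULT_TECHNICAL_THRESHOLD = 0.4

H2A_VARIANT_PAIR = ("H2A_12-17_T", "H2A_12-17_S")


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance but different means: t undefined."""


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    degenerate: bool = False


@dataclass(frozen=True)
class ShapiroResult:
    W: float
    p: float
    normal: bool
    applicable: bool
    reason: str = ""


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    spread: float
    per_sample_ratio: dict
    mode: str
    fallback: bool = False


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r between samples with 95% CIs and H0: r=0 p-values."""

    samples: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    ci_lower: pd.DataFrame
    ci_upper: pd.DataFrame
    n: pd.DataFrame


def welch_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Unpaired two-sample Welch's t-test (unequal variances).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with the
    Welch-Satterthwaite degrees of freedom and a two-sided p from the t
    distribution.  Pass the input group first so pulldown enrichment gives a
    negative t.  Identical zero-variance groups return t=0, p=1 flagged
    degenerate; zero variance with different means raises.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, ma, mb, degenerate=True)
        raise DegenerateVarianceError("zero variance in both groups with unequal means")
    sa, sb = va / len(a), vb / len(b)
    se2 = sa + sb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), float(ma), float(mb))


def shapiro_gate(group: Sequence[float], alpha: float = 0.05) -> ShapiroResult:
    """Shapiro-Wilk normality gate: normal when p > alpha.

    n < 3 makes the test inapplicable (small pulldowns are reported with
    ranges instead); an all-equal group is degenerate and flagged.
    """
    x = np.asarray(group, dtype=float)
    if len(x) < 3:
        return ShapiroResult(np.nan, np.nan, False, False, reason=f"n={len(x)} < 3")
    if len(x) > 5000:
        return ShapiroResult(np.nan, np.nan, False, False, reason="n > 5000")
    if np.ptp(x) == 0.0:
        return ShapiroResult(np.nan, np.nan, False, False, reason="all values identical")
    W, p = sps.shapiro(x)
    return ShapiroResult(float(W), float(p), bool(p > alpha), True)


def variability_threshold(
    table: AbundanceTable,
    variant_pair: tuple[str, str] = H2A_VARIANT_PAIR,
    mode: str = "max_dev",
) -> ThresholdResult:
    """Fold-change threshold from the variant-pair recovery control.

    Per sample, the ratio of the two variant-peptide levels (T16/S16) is
    computed; the spread is the maximum absolute deviation from the sample
    mean divided by the mean (``mode="sd"``: coefficient of variation
    instead).  Fold changes beyond *twice* this spread exceed expected
    technical variability.  When the variant peptides are missing the fixed
    default of 0.4 (double a 20% spread) is returned with a warning.
    """
    if mode not in ("max_dev", "sd"):
        raise ValueError(f"unknown mode {mode!r}")
    t_id, s_id = variant_pair
    d = table.data
    ratios = {}
    for sample, grp in d.groupby("sample", sort=False):
        ft = grp.loc[grp["form"] == t_id, "fraction"]
        fs = grp.loc[grp["form"] == s_id, "fraction"]
        if len(ft) == 1 and len(fs) == 1 and float(fs.iloc[0]) > 0:
            ratios[sample] = float(ft.iloc[0]) / float(fs.iloc[0])
    if len(ratios) < 2:
        warnings.warn(
            f"variant pair {variant_pair} not quantified in >= 2 samples; "
            f"falling back to the fixed threshold {DEFAULT_TECHNICAL_THRESHOLD}",
            stacklevel=2,
        )
        return ThresholdResult(DEFAULT_TECHNICAL_THRESHOLD, np.nan, ratios, mode, fallback=True)
    vals = np.array(list(ratios.values()))
    mean = vals.mean()
    if mode == "max_dev":
        spread = float(np.abs(vals - mean).max() / mean)
    else:
        spread = float(vals.std(ddof=1) / mean)
    return ThresholdResult(2.0 * spread, spread, ratios, mode)


def _bh_qvalues(pvals: pd.Series) -> pd.Series:
    out = pd.Series(np.nan, index=pvals.index)
    ok = pvals.notna()
    if ok.sum():
        out[ok] = multipletests(pvals[ok].to_numpy(), method="fdr_bh")[1]
    return out


def fold_change_table(
    table: AbundanceTable,
    comparisons: Sequence[tuple[str, str]],
    threshold: float | None = None,
    alpha: float = 0.05,
    qvalues: bool = False,
) -> pd.DataFrame:
    """Per-form enrichment results for (input, pulldown) condition pairs.

    Fold change = pulldown mean / input mean of relative abundances.  Welch's
    t is attached when both groups have n >= 3 (smaller pulldowns get
    range-based descriptive output only); the Shapiro-Wilk gate per group
    determines ``gate_passed`` but does not suppress the statistic.
    ``exceeds_technical`` marks |log2 fold| > log2(1 + threshold); a zero
    input mean with pulldown signal is reported as an infinite fold change.
    Optional ``qvalues``: Benjamini-Hochberg adjusted p-values per comparison
    (an extra, clearly non-primary column).
    """
    if threshold is None:
        threshold = variability_threshold(table).threshold
    known = set(table.data["condition"])
    rows = []
    for cond_in, cond_pull in comparisons:
        for cond in (cond_in, cond_pull):
            if cond not in known:
                raise KeyError(f"unknown condition {cond!r}; table has {sorted(known)}")
        forms = table.data[table.data["condition"].isin([cond_in, cond_pull])]["form"].unique()
        for form in forms:
            a = table.group_values(cond_in, form)
            b = table.group_values(cond_pull, form)
            mean_a = a.mean() if len(a) else np.nan
            mean_b = b.mean() if len(b) else np.nan
            if mean_a > 0:
                fold = mean_b / mean_a
            else:
                fold = np.inf if mean_b > 0 else np.nan
            log2_threshold = np.log2(1.0 + threshold)
            if np.isfinite(fold) and fold > 0:
                exceeds = bool(abs(np.log2(fold)) > log2_threshold)
            else:
                exceeds = bool(np.isinf(fold))
            sh_a = shapiro_gate(a, alpha)
            sh_b = shapiro_gate(b, alpha)
            gate = bool(sh_a.applicable and sh_b.applicable and sh_a.normal and sh_b.normal)
            row = dict(
                form=form,
                comparison=f"{cond_in}_vs_{cond_pull}",
                n_input=len(a),
                n_pulldown=len(b),
                mean_input=float(mean_a),
                mean_pulldown=float(mean_b),
                fold_change=float(fold),
                exceeds_technical=exceeds,
                shapiro_p_input=sh_a.p,
                shapiro_p_pulldown=sh_b.p,
                gate_passed=gate,
                t=np.nan,
                df=np.nan,
                p=np.nan,
                range_input=float(np.ptp(a)) if len(a) else np.nan,
                range_pulldown=float(np.ptp(b)) if len(b) else np.nan,
            )
            if len(a) >= 3 and len(b) >= 3:
                try:
                    w = welch_test(a, b)
                    row.update(t=w.t, df=w.df, p=w.p)
                except DegenerateVarianceError:
                    row["gate_passed"] = False
            rows.append(row)
    out = pd.DataFrame(rows)
    if qvalues and len(out):
        out["q_bh"] = out.groupby("comparison")["p"].transform(_bh_qvalues)
    return out


def pearson_matrix(table: AbundanceTable, min_common: int = 3) -> CorrelationMatrix:
    """Pairwise Pearson correlation of PTM patterns between samples.

    Each pair is correlated over the forms quantified (not below-limit) in
    *both* samples; p-values come from the t transform of r, and 95% CIs
    from the Fisher z transform (NaN when n <= 3).  Pairs with fewer than
    ``min_common`` shared forms are flagged not-computable (all-NaN).
    """
    wide = table.wide()
    samples = list(wide.index)
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two samples")
    mats = {name: np.full((k, k), np.nan) for name in ("r", "p", "lo", "hi", "n")}
    for i in range(k):
        mats["r"][i, i] = 1.0
        mats["p"][i, i] = 0.0
        mats["n"][i, i] = wide.iloc[i].notna().sum()
    for i in range(k):
        for j in range(i + 1, k):
            x, y = wide.iloc[i], wide.iloc[j]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            mats["n"][i, j] = mats["n"][j, i] = n
            if n < min_common:
                continue
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                continue
            r, p = sps.pearsonr(xv, yv)
            mats["r"][i, j] = mats["r"][j, i] = r
            mats["p"][i, j] = mats["p"][j, i] = p
            if n > 3 and abs(r) < 1.0:
                z = np.arctanh(r)
                half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
                lo, hi = np.tanh(z - half), np.tanh(z + half)
            elif abs(r) == 1.0:
                lo = hi = r
            else:
                lo = hi = np.nan
            mats["lo"][i, j] = mats["lo"][j, i] = lo
            mats["hi"][i, j] = mats["hi"][j, i] = hi
    frames = {
        name: pd.DataFrame(mat, index=samples, columns=samples) for name, mat in mats.items()
    }
    return CorrelationMatrix(
        samples=samples,
        r=frames["r"],
        p=frames["p"],
        ci_lower=frames["lo"],
        ci_upper=frames["hi"],
        n=frames["n"],
    )


def global_log2_compare(
    table_t0: AbundanceTable,
    table_t1: AbundanceTable,
) -> pd.Series:
    """Per-form -log2(level_t1 / level_t0) between two timepoint tables.

    Levels are per-form means over each table's samples; forms below limit or
    zero in either table are excluded (NaN).  Under this sign convention a
    2-fold *decrease* at t1 maps to +1.
    """
    m0 = table_t0.wide().mean(axis=0)
    m1 = table_t1.wide().mean(axis=0)
    forms = m0.index.union(m1.index)
    out = pd.Series(np.nan, index=forms, name="neg_log2_ratio")
    for f in forms:
        v0 = m0.get(f, np.nan)
        v1 = m1.get(f, np.nan)
        if np.isfinite(v0) and np.isfinite(v1) and v0 > 0 and v1 > 0:
            out[f] = -np.log2(v1 / v0)
    return out
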