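"""Paired and Welch t comparisons with Benjamini-Hochberg FDR control.

Glycoform-resolved PK parameters are compared within an experiment by
paired t tests across animals (each animal contributes every glycoform, so
pairing removes the large inter-animal kinetic variability). Serum profile
abundances between groups use unpaired Welch tests. P values are adjusted
per experimental group with the Benjamini-Hochberg step-up procedure at a
5% false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import SchemaError

#: Significance-star tiers on the unadjusted p value; stars are shown only
#: for tests that survive FDR adjustment.
STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"))


class TestResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool = False


class SummaryStats(NamedTuple):
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float


@dataclass
class BHResult:
    """Benjamini-Hochberg step-up outcome for one family of tests.

    ``alpha_adjusted`` is each test's rank-specific threshold (i/m)·fdr in
    the original input order; ``reject`` the step-up decision.
    """

    reject: np.ndarray
    alpha_adjusted: np.ndarray
    p_adjusted: np.ndarray


def paired_test(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided paired t test; df = n - 1.

    Zero-variance differences make the statistic degenerate: the result is
    flagged and p is NaN rather than 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise SchemaError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise SchemaError("paired test needs at least 2 pairs")
    diffs = a - b
    if np.std(diffs, ddof=1) == 0:
        return TestResult(t=0.0 if np.all(diffs == 0) else np.inf, df=n - 1, p=np.nan, degenerate=True)
    res = sps.ttest_rel(a, b)
    return TestResult(t=float(res.statistic), df=float(n - 1), p=float(res.pvalue))


def welch_test(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided unpaired t test with Welch-Satterthwaite correction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SchemaError("Welch test needs at least 2 observations per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return TestResult(
            t=0.0 if np.mean(a) == np.mean(b) else np.inf,
            df=len(a) + len(b) - 2,
            p=np.nan,
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return TestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def bh_adjust(p_values: Sequence[float], fdr: float = 0.05) -> BHResult:
    """Benjamini-Hochberg step-up over one family of p values.

    Sort ascending, find the largest i with p_(i) <= (i/m)·fdr, and reject
    every test at or below it. NaN p values (degenerate tests) are never
    rejected and do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return BHResult(
            reject=np.zeros(0, dtype=bool), alpha_adjusted=np.zeros(0), p_adjusted=np.zeros(0)
        )
    if np.any((p < 0) | (p > 1)):
        raise SchemaError("p values must lie in [0, 1]")
    valid = ~np.isnan(p)
    m = int(valid.sum())
    reject = np.zeros(p.size, dtype=bool)
    alpha_adjusted = np.full(p.size, np.nan)
    p_adjusted = np.full(p.size, np.nan)
    if m:
        rej, padj, _, _ = multipletests(p[valid], alpha=fdr, method="fdr_bh")
        reject[valid] = rej
        p_adjusted[valid] = padj
        ranks = sps.rankdata(p[valid], method="max")
        alpha_adjusted[valid] = ranks / m * fdr
    return BHResult(reject=reject, alpha_adjusted=alpha_adjusted, p_adjusted=p_adjusted)


def summarize(values: Sequence[float]) -> SummaryStats:
    """Sample mean, SD (n-1 denominator) and t-based 95% confidence interval."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise SchemaError("summary statistics need at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return SummaryStats(mean=mean, sd=sd, ci95_low=mean - half, ci95_high=mean + half)


def stars(p: float, significant: bool) -> str:
    """Star annotation: shown only for FDR-significant tests, tiered by p."""
    if not significant or np.isnan(p):
        return ""
    for threshold, symbol in STAR_TIERS:
        if p < threshold:
            return symbol
    return "*"


def compare_glycoforms(
    results: pd.DataFrame,
    reference: str,
    fdr: float = 0.05,
    value_column: str = "clearance_ml_day_kg",
    extra_contrasts: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Paired comparison of each glycoform's clearance against a reference.

    ``results`` holds one row per (animal_id, glycoform) with the parameter in
    ``value_column`` — the shape produced by :func:`glycopk.nca.nca_study` for
    one experimental group. Each non-reference glycoform is compared to the
    reference by a paired t test across animals; ``extra_contrasts`` adds
    ad-hoc glycoform-vs-glycoform pairs to the same family. The whole family
    is then Benjamini-Hochberg adjusted at ``fdr``.

    Returns a table with columns glycoform, reference, n, mean_diff,
    mean_ratio, t, df, p, alpha_adjusted, significant, stars.
    """
    wide = results.pivot_table(index="animal_id", columns="glycoform", values=value_column)
    if reference not in wide.columns:
        raise SchemaError(f"reference glycoform {reference!r} missing from results")
    if wide[reference].notna().sum() < 2:
        raise SchemaError(f"reference {reference!r} estimable in fewer than 2 animals")

    contrasts = [(g, reference) for g in wide.columns if g not in (reference, "Total")]
    contrasts += [tuple(c) for c in extra_contrasts]
    rows = []
    for g, ref in contrasts:
        if g not in wide.columns or ref not in wide.columns:
            raise SchemaError(f"contrast ({g}, {ref}): glycoform missing from results")
        paired = wide[[g, ref]].dropna()
        if len(paired) < 2:
            raise SchemaError(f"contrast ({g}, {ref}): fewer than 2 complete pairs")
        res = paired_test(paired[g], paired[ref])
        rows.append(
            {
                "glycoform": g,
                "reference": ref,
                "n": len(paired),
                "mean_diff": float((paired[g] - paired[ref]).mean()),
                "mean_ratio": float((paired[g] / paired[ref]).mean()),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["glycoform", "reference", "n", "mean_diff", "mean_ratio", "t", "df", "p"]
    )
    if len(table):
        bh = bh_adjust(table["p"].to_numpy(), fdr=fdr)
        table["alpha_adjusted"] = bh.alpha_adjusted
        table["significant"] = bh.reject
    else:
        table["alpha_adjusted"] = []
        table["significant"] = []
    table["stars"] = [stars(p, s) for p, s in zip(table["p"], table["significant"])]
    return table
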