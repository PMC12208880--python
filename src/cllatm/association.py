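"""2x2 association statistics and pairwise co-occurrence analysis.

Odds ratios are computed on the raw counts with a Haldane–Anscombe 0.5
correction when any cell is zero; 95% confidence intervals use the Woolf
logit method.  Fisher exact p-values (two-sided, probability-mass
convention) and Pearson chi-squared tests come from scipy; the
Benjamini–Hochberg step-up adjustment comes from statsmodels.  The
co-occurrence matrix applies the Fisher test to every unordered pair of
binary cohort features with one BH family per matrix, the convention used
for mutual-exclusivity/co-occurrence plots (OR below 1: trend toward mutual
exclusivity; above 1: toward co-occurrence).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyResult",
    "CoOccurrenceMatrix",
    "odds_ratio_2x2",
    "fisher_exact_two_sided",
    "chi_squared_2x2",
    "benjamini_hochberg",
    "contingency_test",
    "cooccurrence_matrix",
    "association_table",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 table (a=exposed&event, b=exposed&no-event, c, d) with its
    odds ratio, Woolf 95% CI and test p-values."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool
    p_fisher: Optional[float] = None
    p_chisq: Optional[float] = None

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _validate_counts(a: int, b: int, c: int, d: int) -> None:
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be nonnegative integers")
    if a + b + c + d < 1:
        raise ValueError("empty 2x2 table")


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Sample odds ratio (a*d)/(b*c) with a Woolf logit 95% CI.

    The point estimate uses the raw counts.  If any cell is zero, 0.5 is
    added to every cell (Haldane–Anscombe) for both the OR and the CI and
    ``continuity_corrected`` is set.  An all-zero row or column leaves the OR
    undefined and raises.
    """
    _validate_counts(a, b, c, d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("odds ratio undefined: a zero row or column margin")
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se_log = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_)
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=or_,
        ci_low=math.exp(log_or - _Z975 * se_log),
        ci_high=math.exp(log_or + _Z975 * se_log),
        continuity_corrected=corrected,
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: the hypergeometric mass of all tables with
    the same margins that are at most as probable as the observed one."""
    _validate_counts(a, b, c, d)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def chi_squared_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> float:
    """Pearson chi-squared p-value (1 df, upper tail), no Yates correction
    by default.  Raises when any expected cell count is zero."""
    _validate_counts(a, b, c, d)
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected == 0).any():
        raise ValueError(
            "zero expected cell count; use the Fisher exact test instead"
        )
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def contingency_test(a: int, b: int, c: int, d: int,
                     yates: bool = False) -> ContingencyResult:
    """OR + CI plus Fisher and chi-squared p-values in one result.

    The chi-squared p is omitted (None) when an expected count is zero.
    """
    res = odds_ratio_2x2(a, b, c, d)
    p_fisher = fisher_exact_two_sided(a, b, c, d)
    try:
        p_chisq = chi_squared_2x2(a, b, c, d, yates=yates)
    except ValueError:
        p_chisq = None
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=res.odds_ratio, ci_low=res.ci_low, ci_high=res.ci_high,
        continuity_corrected=res.continuity_corrected,
        p_fisher=p_fisher, p_chisq=p_chisq,
    )


@dataclass
class CoOccurrenceMatrix:
    """Pairwise Fisher-exact co-occurrence analysis over binary features."""

    features: List[str]
    or_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    q_matrix: pd.DataFrame
    tests: pd.DataFrame  # tidy: feature_a, feature_b, a, b, c, d, or, p, q

    def pair(self, f1: str, f2: str) -> pd.Series:
        mask = (
            ((self.tests.feature_a == f1) & (self.tests.feature_b == f2))
            | ((self.tests.feature_a == f2) & (self.tests.feature_b == f1))
        )
        hits = self.tests[mask]
        if hits.empty:
            raise KeyError(f"no test for pair ({f1}, {f2})")
        return hits.iloc[0]


def cooccurrence_matrix(
    profiles: pd.DataFrame, features: Sequence[str]
) -> CoOccurrenceMatrix:
    """Fisher-exact co-occurrence over all unordered feature pairs.

    ``profiles`` holds one row per patient; feature columns are 0/1 with NA
    for missing.  Patients missing either feature of a pair are dropped for
    that pair only (pairwise-complete deletion).  Features constant across
    the cohort are skipped with a warning.  All pairwise p-values form one
    Benjamini–Hochberg family.
    """
    features = list(features)
    usable = []
    for f in features:
        col = profiles[f].dropna()
        if col.nunique() < 2:
            warnings.warn(f"feature {f!r} is constant; skipped", stacklevel=2)
        else:
            usable.append(f)

    rows = []
    for i, f1 in enumerate(usable):
        for f2 in usable[i + 1:]:
            sub = profiles[[f1, f2]].dropna()
            x = sub[f1].astype(bool)
            y = sub[f2].astype(bool)
            a = int((x & y).sum())
            b = int((x & ~y).sum())
            c = int((~x & y).sum())
            d = int((~x & ~y).sum())
            try:
                res = contingency_test(a, b, c, d)
            except ValueError:
                warnings.warn(
                    f"pair ({f1}, {f2}) degenerate after pairwise deletion; skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "feature_a": f1, "feature_b": f2,
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p": res.p_fisher,
                }
            )

    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["q"] = benjamini_hochberg(tests["p"].tolist())
    else:
        tests["q"] = pd.Series(dtype=float)

    or_m = pd.DataFrame(np.nan, index=usable, columns=usable)
    p_m = pd.DataFrame(np.nan, index=usable, columns=usable)
    q_m = pd.DataFrame(np.nan, index=usable, columns=usable)
    for _, r in tests.iterrows():
        for m, key in ((or_m, "odds_ratio"), (p_m, "p"), (q_m, "q")):
            m.loc[r.feature_a, r.feature_b] = r[key]
            m.loc[r.feature_b, r.feature_a] = r[key]
    return CoOccurrenceMatrix(
        features=usable, or_matrix=or_m, p_matrix=p_m, q_matrix=q_m, tests=tests
    )


def association_table(
    profiles: pd.DataFrame,
    outcome: str,
    exposures: Sequence[str],
    yates: bool = False,
) -> pd.DataFrame:
    """Clinicobiological association table: one 2x2 test per exposure.

    For each exposure the table is (exposed & outcome, exposed & not, ...),
    with pairwise-complete deletion.  Emits raw chi-squared and Fisher
    p-values plus one BH family across the exposures.
    """
    rows = []
    for exp in exposures:
        sub = profiles[[exp, outcome]].dropna()
        x = sub[exp].astype(bool)
        y = sub[outcome].astype(bool)
        a, b = int((x & y).sum()), int((x & ~y).sum())
        c, d = int((~x & y).sum()), int((~x & ~y).sum())
        res = contingency_test(a, b, c, d, yates=yates)
        rows.append(
            {
                "exposure": exp, "outcome": outcome,
                "a": a, "b": b, "c": c, "d": d,
                "n_exposed_with_outcome": a,
                "n_exposed": a + b,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_chisq": res.p_chisq, "p_fisher": res.p_fisher,
            }
        )
    out = pd.DataFrame(rows)
    out["q_chisq"] = benjamini_hochberg(
        [p if p is not None else 1.0 for p in out["p_chisq"]]
    )
    return out
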