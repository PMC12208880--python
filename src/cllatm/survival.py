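"""Time-to-first-treatment and overall-survival modeling.

Endpoints follow the usual CLL conventions: TTFT runs from diagnosis to
first treatment, with untreated patients censored at administrative
follow-up or death; OS runs from diagnosis to death or last follow-up.
Kaplan–Meier estimation (with Greenwood standard errors), the Cox–Mantel
log-rank test (with Benjamini–Hochberg-adjusted pairwise comparisons) and
multivariable Cox proportional-hazards models (Efron tie handling, Wald
inference) are provided on top of lifelines.

Covariate coding mirrors common CLL prognostic modeling: TP53 mutation and
del(17p) are merged into a single "TP53 aberrant" term, and NFKBIE counts as
mutated only for the p.Y254fs/p.254* hotspot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test
from lifelines.utils import median_survival_times

from .association import benjamini_hochberg

__all__ = [
    "SurvivalRecord",
    "KMFit",
    "CoxFit",
    "CovariateSpec",
    "DEFAULT_COVARIATE_SPEC",
    "build_endpoint",
    "km_fit",
    "median_followup_reverse_km",
    "logrank_test",
    "pairwise_logrank",
    "build_covariates",
    "cox_fit",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: bool
    endpoint: str  # "TTFT" | "OS"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time >= 0):
            raise ValueError(
                f"patient {self.patient_id}: negative or non-finite time {self.time!r}"
            )


def _records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no survival records")
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time": [r.time for r in records],
            "event": [bool(r.event) for r in records],
        }
    )


def build_endpoint(clinical: pd.DataFrame, endpoint: str) -> List[SurvivalRecord]:
    """Construct TTFT or OS records from a clinical table.

    Expected columns: ``patient_id``; for TTFT ``ttft_years`` (time from
    diagnosis to first treatment, or to censoring for untreated patients)
    and ``treated`` (0/1); for OS ``os_years`` and ``dead`` (0/1).  For the
    TTFT endpoint untreated patients are censored — death without treatment
    is censoring, not an event.  Rows with negative times are rejected.
    """
    endpoint = endpoint.upper()
    if endpoint == "TTFT":
        time_col, event_col = "ttft_years", "treated"
    elif endpoint == "OS":
        time_col, event_col = "os_years", "dead"
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    for col in ("patient_id", time_col, event_col):
        if col not in clinical.columns:
            raise ValueError(f"clinical table missing column {col!r}")

    records = []
    for _, row in clinical[["patient_id", time_col, event_col]].dropna().iterrows():
        t = float(row[time_col])
        if t < 0:
            raise ValueError(
                f"patient {row['patient_id']}: negative {endpoint} time {t}"
            )
        records.append(
            SurvivalRecord(
                patient_id=str(row["patient_id"]),
                time=t,
                event=bool(row[event_col]),
                endpoint=endpoint,
            )
        )
    return records


@dataclass
class KMFit:
    """Product-limit estimate with Greenwood standard errors."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    median: Optional[float]
    median_ci: Tuple[Optional[float], Optional[float]] = (None, None)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "se": self.greenwood_se,
            }
        )


def km_fit(records: Sequence[SurvivalRecord]) -> KMFit:
    """Kaplan–Meier estimate (deaths before censorings at tied times).

    The median is the earliest time at which the survival curve drops to
    0.5 or below, absent when never reached.
    """
    df = _records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0 else kmf.event_table
    times = np.asarray(table.index, dtype=float)
    n_risk = table["at_risk"].to_numpy(dtype=int)
    n_event = table["observed"].to_numpy(dtype=int)
    surv = np.asarray(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in times]
    )
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(
            n_risk > n_event, n_event / (n_risk * (n_risk - n_event)), np.nan
        )
    cum = np.nancumsum(inc)
    se = surv * np.sqrt(cum)

    median = kmf.median_survival_time_
    median = None if not np.isfinite(median) else float(median)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    median_ci = (
        lo if np.isfinite(lo) else None,
        hi if np.isfinite(hi) else None,
    )
    return KMFit(
        event_times=times,
        survival=surv,
        greenwood_se=se,
        n_risk=n_risk,
        n_event=n_event,
        median=median,
        median_ci=median_ci,
    )


def median_followup_reverse_km(
    records: Sequence[SurvivalRecord],
) -> Tuple[Optional[float], Tuple[Optional[float], Optional[float]]]:
    """Median follow-up by reverse Kaplan–Meier.

    Event and censoring indicators are flipped so the KM estimate targets the
    censoring (follow-up) distribution; returns the median and its 95% CI,
    with ``None`` when the median is never reached.
    """
    flipped = [
        SurvivalRecord(r.patient_id, r.time, not r.event, r.endpoint)
        for r in records
    ]
    fit = km_fit(flipped)
    return fit.median, fit.median_ci


def logrank_test(
    groups: Sequence[Sequence[SurvivalRecord]],
) -> Tuple[float, int, float]:
    """Cox–Mantel log-rank test over k groups: (chi2 statistic, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    frames = []
    for i, g in enumerate(groups):
        if not g:
            raise ValueError(f"group {i} has zero subjects")
        f = _records_frame(g)
        f["group"] = i
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    if df["event"].sum() < 1:
        raise ValueError("log-rank test needs at least one event overall")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def pairwise_logrank(
    groups: Dict[str, Sequence[SurvivalRecord]],
) -> pd.DataFrame:
    """All pairwise log-rank comparisons with BH-adjusted q-values.

    The Benjamini–Hochberg family is the full set of pairwise comparisons
    (one family per figure-panel-style analysis).
    """
    frames = []
    for name, g in groups.items():
        if not g:
            raise ValueError(f"group {name!r} has zero subjects")
        f = _records_frame(g)
        f["group"] = name
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    res = pairwise_logrank_test(df["time"], df["group"], df["event"])
    summary = res.summary.reset_index()
    out = pd.DataFrame(
        {
            "group_a": summary.iloc[:, 0],
            "group_b": summary.iloc[:, 1],
            "statistic": summary["test_statistic"].astype(float),
            "p": summary["p"].astype(float),
        }
    )
    out["q"] = benjamini_hochberg(out["p"].tolist())
    return out


@dataclass(frozen=True)
class CovariateSpec:
    """Model terms and coding rules for the multivariable Cox models.

    ``male``: 1 for male patients.  ``age``: continuous age at diagnosis in
    years.  ``ucll``: 1 for unmutated IGHV (U-CLL) vs. M-CLL.
    ``tp53_aberrant``: TP53 mutation OR del(17p).  ``nfkbie``: hotspot
    mutation (p.Y254fs/p.254*) only.  ``genes``: further 0/1 mutation flags.
    """

    include_gender: bool = True
    include_age: bool = True
    include_ighv: bool = True
    include_del11q: bool = True
    include_trisomy12: bool = True
    include_tp53_aberrant: bool = True
    include_atm: bool = True
    genes: Tuple[str, ...] = (
        "BIRC3", "EGR2", "MYD88", "NFKBIE", "NOTCH1", "POT1", "SF3B1", "XPO1",
    )


DEFAULT_COVARIATE_SPEC = CovariateSpec()


def build_covariates(
    clinical: pd.DataFrame, spec: CovariateSpec = DEFAULT_COVARIATE_SPEC
) -> pd.DataFrame:
    """Build the Cox design matrix from the clinical table.

    Expected columns (0/1 unless noted): ``male``, ``age`` (years), ``ucll``
    (NA allowed for unknown IGHV), ``del11q``, ``trisomy12``, ``del17p``,
    ``TP53``, ``NFKBIE_hotspot``, per-gene mutation flags, and ``atm_mutated``.
    Returns one column per model term, indexed like ``clinical``; rows with
    missing values are preserved (complete-case filtering happens at fit
    time).
    """
    design = pd.DataFrame(index=clinical.index)
    design["patient_id"] = clinical["patient_id"].astype(str)
    if spec.include_gender:
        design["male"] = clinical["male"]
    if spec.include_age:
        design["age"] = clinical["age"]
    if spec.include_ighv:
        design["ucll"] = clinical["ucll"]
    if spec.include_del11q:
        design["del11q"] = clinical["del11q"]
    if spec.include_trisomy12:
        design["trisomy12"] = clinical["trisomy12"]
    if spec.include_tp53_aberrant:
        tp53 = clinical["TP53"].astype("float")
        del17p = clinical["del17p"].astype("float")
        design["tp53_aberrant"] = ((tp53 > 0) | (del17p > 0)).astype(float)
        design.loc[tp53.isna() & del17p.isna(), "tp53_aberrant"] = np.nan
    if spec.include_atm:
        design["atm_mutated"] = clinical["atm_mutated"]
    for gene in spec.genes:
        col = "NFKBIE_hotspot" if gene == "NFKBIE" else gene
        design[gene] = clinical[col]
    return design


@dataclass
class CoxFit:
    """Multivariable Cox proportional-hazards fit (Efron ties)."""

    terms: List[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n_used: int
    converged: bool
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def term(self, name: str) -> pd.Series:
        return self.summary.loc[name]


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: pd.DataFrame,
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron tie handling).

    ``covariates`` must carry ``patient_id`` plus numeric model terms.
    Complete-case analysis: rows with any missing term are dropped and
    ``n_used`` reports the rows actually fit.  Constant covariates are
    rejected.  Non-convergence (including monotone likelihood from perfect
    separation) is reported via ``converged=False`` rather than raising.
    """
    recs = _records_frame(records)
    merged = recs.merge(covariates, on="patient_id", how="inner")
    terms = [c for c in covariates.columns if c != "patient_id"]
    data = merged[["time", "event"] + terms].apply(pd.to_numeric, errors="coerce")
    data = data.dropna()
    n_used = len(data)
    if n_used < 10 * len(terms):
        warnings.warn(
            f"only {n_used} complete cases for {len(terms)} terms "
            "(fewer than 10 per term)",
            stacklevel=2,
        )
    for t in terms:
        if data[t].nunique() < 2:
            raise ValueError(f"covariate {t!r} is constant in the complete cases")

    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event")
    except Exception:
        return CoxFit(
            terms=terms,
            coefficients=np.full(len(terms), np.nan),
            hazard_ratios=np.full(len(terms), np.nan),
            ci_low=np.full(len(terms), np.nan),
            ci_high=np.full(len(terms), np.nan),
            p_values=np.full(len(terms), np.nan),
            n_used=n_used,
            converged=False,
        )

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    summary["n_used"] = n_used
    return CoxFit(
        terms=list(summary.index),
        coefficients=summary["coef"].to_numpy(),
        hazard_ratios=summary["hr"].to_numpy(),
        ci_low=summary["ci_low"].to_numpy(),
        ci_high=summary["ci_high"].to_numpy(),
        p_values=summary["p"].to_numpy(),
        n_used=n_used,
        converged=converged,
        summary=summary,
    )
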