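"""Synthetic CLL cohort generator.

Emits clinical tables, annotated ATM variant tables and censored survival
outcomes with the statistical structure the downstream analyses assume:

* correlated binary markers (IGHV status, FISH lesions, gene mutations)
  built sequentially, with configurable pairwise odds multipliers applied on
  the log-odds scale (centered so marginal frequencies are approximately
  preserved);
* per-variant annotation evidence generated to be consistent with the
  variant's true somatic or germline origin (optionally corrupted at a
  configurable noise rate), so the classification flowchart can be checked
  against known truth;
* VAFs drawn from a near-50% truncated normal for germline variants and a
  sub-50% Beta model for somatic variants, with inflation above 50% only in
  the presence of del(11q) or simulated copy-neutral LOH;
* exponential proportional-hazards event times for time-to-first-treatment
  (baseline rate calibrated so the treated fraction matches its target under
  uniform administrative censoring) and an independent death process for
  overall survival.

Every draw flows from a single numpy Generator seeded by ``CohortSimConfig.
seed``, so a config fully determines the cohort.  Ground truth (true marker
flags, true variant origins, true log-hazards) is emitted alongside every
table for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["CohortSimConfig", "simulate_patients", "simulate_variants",
           "simulate_outcomes", "simulate_cohort"]

# ATM coding region landmarks (GRCh37); used to map protein positions to
# plausible genomic coordinates.
_ATM_CHROM = "11"
_ATM_CDS_START = 108_098_321
_PROTEIN_LENGTH = 3056
_FAT_START = 1960

_BASES = ("A", "C", "G", "T")

# Recurrent hotspot changes, emitted with fixed genomic coordinates so the
# same change recurs across patients (exercises cohort harmonization).
_HOTSPOTS = (
    {"protein_change": "p.K468fs", "protein_pos": 468,
     "consequence": "frameshift", "ref": "CT", "alt": "C"},
    {"protein_change": "p.R3008C", "protein_pos": 3008,
     "consequence": "missense", "ref": "C", "alt": "T"},
)


def _default_marginals() -> Dict[str, float]:
    # Marker prevalences for a large untreated European CLL cohort.
    return {
        "male": 0.63,
        "binet_a": 0.72,
        "ucll": 0.44,
        "del13q": 0.41,
        "trisomy12": 0.13,
        "del11q": 0.12,
        "del17p": 0.06,
        "NOTCH1": 0.12,
        "SF3B1": 0.10,
        "TP53": 0.08,
        "atm_mutated": 0.068,
        "XPO1": 0.045,
        "BIRC3": 0.035,
        "POT1": 0.035,
        "NFKBIE_hotspot": 0.030,
        "EGR2": 0.025,
        "MYD88": 0.025,
    }


def _default_odds_multipliers() -> Dict[Tuple[str, str], float]:
    # Pairwise association structure: ATM mutations co-occur with del(11q)
    # and U-CLL and with SF3B1 mutations, and trend toward mutual exclusivity
    # with trisomy 12 and TP53 mutations.
    return {
        ("atm_mutated", "del11q"): 8.07,
        ("atm_mutated", "ucll"): 4.93,
        ("atm_mutated", "trisomy12"): 0.50,
        ("atm_mutated", "TP53"): 0.50,
        ("atm_mutated", "SF3B1"): 2.0,
    }


def _default_ttft_hrs() -> Dict[str, float]:
    # Multiplicative hazards on time-to-first-treatment.  The ATM-mutation
    # hazard defaults to 1.0: its apparent univariable effect should arise
    # entirely through linkage with del(11q) and U-CLL.
    return {
        "ucll": 2.5,
        "del11q": 1.8,
        "trisomy12": 1.4,
        "SF3B1": 1.6,
        "EGR2": 1.5,
        "TP53": 1.5,
        "del17p": 1.5,
        "XPO1": 1.3,
        "NOTCH1": 1.3,
        "atm_mutated": 1.0,
    }


def _default_os_hrs() -> Dict[str, float]:
    return {"ucll": 1.6, "del11q": 1.5, "TP53": 1.8, "del17p": 1.8}


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters for a synthetic CLL cohort.

    Marker ordering for the sequential construction is IGHV status, then
    FISH lesions, then gene mutations.  ``treated_fraction`` is the target
    marginal probability of requiring treatment during follow-up; the
    baseline TTFT hazard is calibrated against it at simulation time.
    """

    n_patients: int = 3631
    seed: int = 0
    marginals: Dict[str, float] = field(default_factory=_default_marginals)
    odds_multipliers: Dict[Tuple[str, str], float] = field(
        default_factory=_default_odds_multipliers
    )
    # clinical structure
    binet_b_given_not_a: float = 0.70  # remaining stage mass split B vs C
    ighv_missing: float = 0.063
    fish_missing: float = 0.029
    age_mean: float = 64.7
    age_sd: float = 10.8
    # ATM variant structure
    multi_mutation_prob: float = 0.232
    decoy_fraction: float = 0.037  # patients carrying a germline/neutral variant
    paired_fraction: float = 0.118  # patients with paired tumor/germline data
    hotspot_prob: float = 0.10
    cnloh_prob: float = 0.055  # mutated patients without del(11q)
    high_vaf_prob_del11q: float = 0.33
    annotation_noise: float = 0.0
    germline_vaf_mean: float = 0.5
    germline_vaf_sd: float = 0.04
    germline_vaf_bounds: Tuple[float, float] = (0.02, 0.98)
    somatic_vaf_beta: Tuple[float, float] = (2.0, 3.0)
    somatic_vaf_range: Tuple[float, float] = (0.05, 0.50)
    high_vaf_range: Tuple[float, float] = (0.55, 0.95)
    # survival structure
    treated_fraction: float = 0.58
    ttft_hrs: Dict[str, float] = field(default_factory=_default_ttft_hrs)
    binet_bc_ttft_hr: float = 2.2
    censor_window: Tuple[float, float] = (0.25, 15.0)
    os_baseline_rate: float = 0.035
    os_hrs: Dict[str, float] = field(default_factory=_default_os_hrs)
    os_age_log_hr_per_year: float = 0.04
    followup_window: Tuple[float, float] = (3.0, 20.0)

    def __post_init__(self) -> None:
        for name, p in self.marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal {name!r}={p} outside [0, 1]")
        for pair, m in self.odds_multipliers.items():
            if m <= 0:
                raise ValueError(f"odds multiplier {pair}={m} must be > 0")
        for p in (self.multi_mutation_prob, self.decoy_fraction,
                  self.paired_fraction, self.cnloh_prob, self.annotation_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# Order of the sequential logistic construction.
_MARKER_ORDER = (
    "ucll", "del13q", "trisomy12", "del11q", "del17p",
    "NOTCH1", "SF3B1", "TP53", "atm_mutated", "XPO1", "BIRC3", "POT1",
    "NFKBIE_hotspot", "EGR2", "MYD88",
)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_patients(
    cfg: CohortSimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the clinical table and its ground truth.

    Binary markers are drawn sequentially; each marker's log-odds is shifted
    by ``ln(OR) * (x_j - p_j)`` for every already-drawn marker ``j`` with a
    configured odds multiplier, which produces the requested pairwise odds
    ratios while approximately preserving marginal frequencies.  Returns
    ``(clinical, truth)``: the clinical frame carries NA for masked IGHV and
    FISH values, the truth frame is complete.
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_patients
    truth = pd.DataFrame({"patient_id": [f"P{i:05d}" for i in range(n)]})

    truth["male"] = (rng.random(n) < cfg.marginals["male"]).astype(int)
    truth["age"] = np.clip(
        rng.normal(cfg.age_mean, cfg.age_sd, size=n), 25.0, 95.0
    ).round(1)
    truth["binet_a"] = (rng.random(n) < cfg.marginals["binet_a"]).astype(int)
    b_or_c = rng.random(n) < cfg.binet_b_given_not_a
    truth["binet"] = np.where(
        truth["binet_a"] == 1, "A", np.where(b_or_c, "B", "C")
    )

    lookup = {}
    for name in _MARKER_ORDER:
        target = cfg.marginals[name]
        shift = np.zeros(n)
        for (m1, m2), mult in cfg.odds_multipliers.items():
            other = None
            if m1 == name and m2 in lookup:
                other = m2
            elif m2 == name and m1 in lookup:
                other = m1
            if other is not None:
                shift += math.log(mult) * (
                    lookup[other] - cfg.marginals[other]
                )
        # Solve for the intercept so the cohort-mean probability hits the
        # marginal exactly (the raw logit would overshoot: sigmoid is convex
        # on the relevant range, so log-odds noise inflates the mean).
        base = _logit(target)
        if shift.any():
            base = optimize.brentq(
                lambda b: float(np.mean(_sigmoid(b + shift))) - target,
                base - 12.0, base + 12.0,
            )
        probs = np.clip(_sigmoid(base + shift), 1e-9, 1 - 1e-9)
        lookup[name] = (rng.random(n) < probs).astype(int)
        truth[name] = lookup[name]

    clinical = truth.drop(columns=["atm_mutated"]).copy()
    ighv_mask = rng.random(n) < cfg.ighv_missing
    clinical["ucll"] = clinical["ucll"].astype("float")
    clinical.loc[ighv_mask, "ucll"] = np.nan
    fish_mask = rng.random(n) < cfg.fish_missing
    for col in ("del13q", "trisomy12", "del11q", "del17p"):
        clinical[col] = clinical[col].astype("float")
        clinical.loc[fish_mask, col] = np.nan

    # Patient-level variant plumbing recorded in truth.
    truth["paired"] = (rng.random(n) < cfg.paired_fraction).astype(int)
    no_del11q = truth["del11q"] == 0
    cnloh = (rng.random(n) < cfg.cnloh_prob) & (truth["atm_mutated"] == 1) & no_del11q
    truth["cnloh"] = cnloh.astype(int)
    truth["has_decoy"] = (rng.random(n) < cfg.decoy_fraction).astype(int)
    return clinical, truth


def _truncnorm_vaf(cfg: CohortSimConfig, rng: np.random.Generator) -> float:
    lo, hi = cfg.germline_vaf_bounds
    a = (lo - cfg.germline_vaf_mean) / cfg.germline_vaf_sd
    b = (hi - cfg.germline_vaf_mean) / cfg.germline_vaf_sd
    return float(stats.truncnorm.rvs(
        a, b, loc=cfg.germline_vaf_mean, scale=cfg.germline_vaf_sd,
        random_state=rng,
    ))


def _somatic_vaf(cfg: CohortSimConfig, high: bool,
                 rng: np.random.Generator) -> float:
    if high:
        lo, hi = cfg.high_vaf_range
        return float(rng.uniform(lo, hi))
    a, b = cfg.somatic_vaf_beta
    lo, hi = cfg.somatic_vaf_range
    return float(lo + (hi - lo) * rng.beta(a, b))


def _random_coords(protein_pos: int, consequence: str,
                   rng: np.random.Generator) -> Tuple[int, str, str]:
    pos = _ATM_CDS_START + 3 * (protein_pos - 1) + int(rng.integers(0, 3))
    ref = _BASES[rng.integers(0, 4)]
    if consequence == "frameshift":
        return pos, ref + _BASES[rng.integers(0, 4)], ref
    if consequence == "inframe_indel":
        ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        return pos, ref, ref + ins
    alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
    return pos, ref, alt


def _somatic_protein_position(consequence: str, rng: np.random.Generator) -> int:
    # Missense mass sits in the C-terminal (FAT/kinase) region; truncating
    # mass in the N-terminal region.
    c_term = rng.random() < (0.80 if consequence in ("missense", "inframe_indel")
                             else 0.20)
    if c_term:
        return int(rng.integers(_FAT_START, _PROTEIN_LENGTH + 1))
    return int(rng.integers(1, _FAT_START))


_SOMATIC_CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice",
                         "inframe_indel")
_SOMATIC_CONSEQ_P = (0.48, 0.17, 0.25, 0.06, 0.04)


def _somatic_annotations(consequence: str, paired: bool, noise: bool,
                         rng: np.random.Generator) -> dict:
    """Annotation evidence consistent with a somatic origin.

    Exactly the fields needed for the flowchart to land on a somatic verdict
    (via paired call, ClinVar, OncoKB, variant type or in-silico predictors),
    with no earlier germline rule firing.  ``noise=True`` instead emits
    germline-style evidence.
    """
    if noise:
        ann = _germline_annotations("gnomad", paired=False, noise=False, rng=rng)
        ann["paired_germline_call"] = "unknown"
        return ann
    ann = {
        "gnomad_max_pop_af": (
            None if rng.random() < 0.9 else float(rng.uniform(0, 0.001))
        ),
        "clinvar": "absent",
        "oncokb": "absent",
        "alphamissense": "absent",
        "alphamissense_score": None,
        "cadd_phred": None,
        "in_germline_dataset": False,
        "paired_germline_call": "confirmed_somatic" if paired else "unknown",
    }
    truncating = consequence in ("nonsense", "frameshift", "splice")
    evid = rng.choice(["clinvar", "oncokb", "insilico"], p=[0.35, 0.25, 0.40])
    if evid == "clinvar":
        ann["clinvar"] = str(rng.choice(["pathogenic", "likely_pathogenic"]))
    elif evid == "oncokb":
        ann["oncokb"] = str(rng.choice(["oncogenic", "likely_oncogenic"]))
    if consequence in ("missense", "inframe_indel"):
        if evid == "insilico":
            if rng.random() < 0.7:
                ann["alphamissense"] = "likely_pathogenic"
                ann["alphamissense_score"] = float(rng.uniform(0.7, 1.0))
                ann["cadd_phred"] = float(rng.uniform(15, 40))
            else:
                ann["alphamissense"] = "ambiguous"
                ann["alphamissense_score"] = float(rng.uniform(0.35, 0.55))
                ann["cadd_phred"] = float(rng.uniform(20, 40))
        else:
            # decided upstream; predictors stay non-benign-concordant
            ann["alphamissense"] = str(
                rng.choice(["likely_pathogenic", "ambiguous"], p=[0.5, 0.5])
            )
            ann["cadd_phred"] = float(rng.uniform(20, 40))
    elif truncating:
        ann["cadd_phred"] = float(rng.uniform(25, 50))
    return ann


def _germline_annotations(mechanism: str, paired: bool, noise: bool,
                          rng: np.random.Generator) -> dict:
    """Annotation evidence consistent with a germline/neutral origin."""
    if noise:
        return _somatic_annotations("missense", paired=False, noise=False, rng=rng)
    ann = {
        "gnomad_max_pop_af": None,
        "clinvar": "absent",
        "oncokb": "absent",
        "alphamissense": "likely_benign",
        "alphamissense_score": float(rng.uniform(0.0, 0.3)),
        "cadd_phred": float(rng.uniform(0, 18)),
        "in_germline_dataset": False,
        "paired_germline_call": "confirmed_germline" if paired else "unknown",
    }
    if mechanism == "gnomad":
        ann["gnomad_max_pop_af"] = float(rng.uniform(0.0015, 0.009))
    elif mechanism == "clinvar_benign":
        ann["clinvar"] = str(rng.choice(["benign", "likely_benign"]))
    elif mechanism == "germline_dataset":
        ann["in_germline_dataset"] = True
    elif mechanism == "fallback":
        # discordant/absent predictors: the conservative fallback decides
        ann["alphamissense"] = "ambiguous"
        ann["alphamissense_score"] = float(rng.uniform(0.35, 0.55))
        ann["cadd_phred"] = float(rng.uniform(0, 18))
    # mechanism "insilico": defaults above already encode benign predictors
    return ann


_GERMLINE_MECHANISMS = ("gnomad", "clinvar_benign", "germline_dataset",
                        "insilico", "fallback")
_GERMLINE_MECH_P = (0.45, 0.15, 0.10, 0.20, 0.10)


def simulate_variants(
    truth: pd.DataFrame,
    cfg: CohortSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the annotated ATM variant table plus per-variant ground truth.

    Every ATM-mutated patient receives one somatic variant (or two to three
    with probability ``multi_mutation_prob``); a ``decoy_fraction`` of all
    patients additionally carries a germline/neutral variant.  Annotation
    fields are generated to be rule-consistent with the true origin except
    at rate ``annotation_noise``.  Somatic VAFs exceed 50% only with
    del(11q) or simulated cnLOH.
    """
    rng = cfg.rng() if rng is None else rng
    rows, truth_rows = [], []
    # A genomic change must have one true origin cohort-wide (recurrences of
    # one change across patients are fine; the same change being somatic in
    # one patient and germline in another would be contradictory evidence),
    # so cross-origin coordinate collisions are resampled.
    origin_of_key: Dict[str, str] = {
        f"{_ATM_CHROM}:{_ATM_CDS_START + 3 * (h['protein_pos'] - 1)}:"
        f"{h['ref']}:{h['alt']}": "somatic"
        for h in _HOTSPOTS
    }

    def _fresh_coords(protein_pos: int, consequence: str, origin: str):
        for _ in range(20):
            pos, ref, alt = _random_coords(protein_pos, consequence, rng)
            key = f"{_ATM_CHROM}:{pos}:{ref}:{alt}"
            if origin_of_key.get(key, origin) == origin:
                origin_of_key[key] = origin
                return pos, ref, alt
        raise RuntimeError("could not draw a collision-free genomic change")

    for rec in truth.itertuples(index=False):
        uid = 0
        variants_here = []
        if getattr(rec, "atm_mutated", 0) == 1:
            if rng.random() < cfg.multi_mutation_prob:
                k = 2 if rng.random() < 0.8 else 3
            else:
                k = 1
            variants_here += ["somatic"] * k
        if getattr(rec, "has_decoy", 0) == 1:
            variants_here.append("germline")

        for origin in variants_here:
            uid += 1
            noise = rng.random() < cfg.annotation_noise
            if origin == "somatic":
                if cfg.hotspot_prob > 0 and rng.random() < cfg.hotspot_prob:
                    hs = _HOTSPOTS[int(rng.integers(0, len(_HOTSPOTS)))]
                    consequence = hs["consequence"]
                    protein_pos = hs["protein_pos"]
                    pos = _ATM_CDS_START + 3 * (protein_pos - 1)
                    ref, alt = hs["ref"], hs["alt"]
                    protein_change = hs["protein_change"]
                else:
                    consequence = str(rng.choice(_SOMATIC_CONSEQUENCES,
                                                 p=_SOMATIC_CONSEQ_P))
                    protein_pos = _somatic_protein_position(consequence, rng)
                    pos, ref, alt = _fresh_coords(protein_pos, consequence,
                                                  "somatic")
                    protein_change = f"p.X{protein_pos}"
                high = bool(
                    (rec.del11q == 1 and rng.random() < cfg.high_vaf_prob_del11q)
                    or rec.cnloh == 1
                )
                vaf = _somatic_vaf(cfg, high, rng)
                ann = _somatic_annotations(
                    consequence, paired=bool(rec.paired), noise=noise, rng=rng
                )
                mechanism = "somatic"
            else:
                mechanism = str(rng.choice(_GERMLINE_MECHANISMS,
                                           p=_GERMLINE_MECH_P))
                consequence = "missense" if rng.random() < 0.95 else "inframe_indel"
                protein_pos = int(rng.integers(1, _PROTEIN_LENGTH + 1))
                pos, ref, alt = _fresh_coords(protein_pos, consequence,
                                              "germline")
                protein_change = f"p.X{protein_pos}"
                vaf = _truncnorm_vaf(cfg, rng)
                ann = _germline_annotations(
                    mechanism, paired=bool(rec.paired), noise=noise, rng=rng
                )

            row = {
                "patient_id": rec.patient_id,
                "variant_uid": f"{rec.patient_id}_v{uid}",
                "chrom": _ATM_CHROM,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "protein_change": protein_change,
                "vaf": round(vaf, 4),
                "consequence": consequence,
                **ann,
            }
            rows.append(row)
            truth_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "variant_uid": row["variant_uid"],
                    "true_origin": origin,
                    "mechanism": mechanism,
                    "noised": bool(noise),
                    "protein_pos": protein_pos,
                }
            )

    columns = [
        "patient_id", "variant_uid", "chrom", "pos", "ref", "alt",
        "protein_change", "vaf", "consequence", "gnomad_max_pop_af",
        "clinvar", "oncokb", "alphamissense", "alphamissense_score",
        "cadd_phred", "in_germline_dataset", "paired_germline_call",
    ]
    variants = pd.DataFrame(rows, columns=columns)
    variant_truth = pd.DataFrame(truth_rows)
    return variants, variant_truth


def _ttft_log_hr(cfg: CohortSimConfig, truth: pd.DataFrame) -> np.ndarray:
    log_hr = np.zeros(len(truth))
    for marker, hr in cfg.ttft_hrs.items():
        log_hr += math.log(hr) * truth[marker].to_numpy(dtype=float)
    log_hr += math.log(cfg.binet_bc_ttft_hr) * (
        1.0 - truth["binet_a"].to_numpy(dtype=float)
    )
    return log_hr


def _death_rate(cfg: CohortSimConfig, truth: pd.DataFrame) -> np.ndarray:
    mu = cfg.os_baseline_rate * np.ones(len(truth))
    for marker, hr in cfg.os_hrs.items():
        mu *= np.power(hr, truth[marker].to_numpy(dtype=float))
    mu *= np.exp(
        cfg.os_age_log_hr_per_year * (truth["age"].to_numpy() - cfg.age_mean)
    )
    return mu


def _p_treated(lam: np.ndarray, mu: np.ndarray, a: float, b: float) -> np.ndarray:
    """P(T < min(C, D)) for T ~ Exp(lam), D ~ Exp(mu) independent, and
    administrative censoring C ~ Uniform(a, b), closed form."""
    lam = np.asarray(lam, dtype=float)
    s = lam + mu
    frac = 1.0 - (np.exp(-s * a) - np.exp(-s * b)) / (s * (b - a))
    return (lam / s) * frac


def calibrate_baseline_rate(cfg: CohortSimConfig, truth: pd.DataFrame) -> float:
    """Baseline TTFT hazard such that the cohort-average probability of
    treatment before censoring (administrative or death) equals
    ``treated_fraction``."""
    a, b = cfg.censor_window
    mult = np.exp(_ttft_log_hr(cfg, truth))
    mu = _death_rate(cfg, truth)

    def mean_event_prob(lam0: float) -> float:
        return float(np.mean(_p_treated(lam0 * mult, mu, a, b)))

    return float(
        optimize.brentq(
            lambda l0: mean_event_prob(l0) - cfg.treated_fraction, 1e-6, 50.0
        )
    )


def simulate_outcomes(
    truth: pd.DataFrame,
    cfg: CohortSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw TTFT and OS columns from exponential proportional hazards.

    TTFT: event time ~ Exp(baseline x product of marker HRs), administrative
    censoring ~ Uniform(censor window); untreated patients are additionally
    censored at death.  OS: an independent exponential death process with its
    own hazard multipliers and an age trend, censored at a uniform follow-up
    horizon.  Returns patient_id, ttft_years, treated, os_years, dead, plus
    the true log-hazard used per patient.
    """
    rng = cfg.rng() if rng is None else rng
    n = len(truth)
    lam0 = calibrate_baseline_rate(cfg, truth)

    log_hr = _ttft_log_hr(cfg, truth)
    lam = lam0 * np.exp(log_hr)
    t_treat = rng.exponential(1.0 / lam)
    censor = rng.uniform(*cfg.censor_window, size=n)

    mu = _death_rate(cfg, truth)
    t_death = rng.exponential(1.0 / mu)
    followup = rng.uniform(*cfg.followup_window, size=n)

    os_years = np.minimum(t_death, followup)
    dead = (t_death <= followup).astype(int)
    ttft_cut = np.minimum(censor, t_death)
    treated = (t_treat <= ttft_cut).astype(int)
    ttft_years = np.where(treated == 1, t_treat, ttft_cut)

    return pd.DataFrame(
        {
            "patient_id": truth["patient_id"],
            "ttft_years": np.round(ttft_years, 4),
            "treated": treated,
            "os_years": np.round(os_years, 4),
            "dead": dead,
            "true_ttft_log_hr": log_hr,
        }
    )


def simulate_cohort(
    cfg: Optional[CohortSimConfig] = None,
) -> Dict[str, pd.DataFrame]:
    """Run the full generator off one random stream.

    Returns a dict with ``clinical`` (covariates + survival columns, masked
    missingness), ``variants`` (annotated ATM variant table), ``truth``
    (complete per-patient flags) and ``variant_truth``.
    """
    cfg = cfg or CohortSimConfig()
    rng = cfg.rng()
    clinical, truth = simulate_patients(cfg, rng)
    variants, variant_truth = simulate_variants(truth, cfg, rng)
    outcomes = simulate_outcomes(truth, cfg, rng)
    clinical = clinical.merge(
        outcomes.drop(columns=["true_ttft_log_hr"]), on="patient_id"
    )
    truth = truth.merge(outcomes, on="patient_id")
    return {
        "clinical": clinical,
        "variants": variants,
        "truth": truth,
        "variant_truth": variant_truth,
    }
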