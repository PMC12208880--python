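"""End-to-end pipeline orchestration.

Stage order mirrors the analysis workflow: classify variants, derive
per-patient ATM status, run clinicobiological association tests and
co-occurrence matrices (entire cohort plus U-CLL / M-CLL strata), then
Kaplan–Meier / log-rank and multivariable Cox models on the configured
survival strata.  Every run writes a manifest with a hash of the effective
configuration so identical inputs produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .association import association_table, cooccurrence_matrix
from .classify import assign_patient_status, classify_cohort, vaf_distribution_summary
from .io import (
    read_blocklist,
    read_clinical_table,
    read_variant_table,
    status_to_frame,
    write_classified_table,
    write_status_table,
    write_table,
)
from .survival import (
    DEFAULT_COVARIATE_SPEC,
    build_covariates,
    build_endpoint,
    cox_fit,
    km_fit,
    pairwise_logrank,
)
from .types import ClassifierConfig

log = logging.getLogger("cllatm")

COOCCURRENCE_FEATURES = [
    "atm_mutated", "del11q", "del13q", "trisomy12", "del17p", "ucll",
    "BIRC3", "EGR2", "MYD88", "NFKBIE_hotspot", "NOTCH1", "POT1", "SF3B1",
    "TP53", "XPO1",
]

ASSOCIATION_EXPOSURES = [
    "male", "ucll", "binet_bc", "treated", "del11q", "del17p", "trisomy12",
    "del13q",
]


@dataclass
class PipelineConfig:
    variants_path: str
    clinical_path: str
    output_dir: str
    blocklist_path: Optional[str] = None
    variant_format: str = "auto"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    strata: List[str] = field(default_factory=lambda: ["all", "binet_a", "binet_a_ighv"])
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        classifier = ClassifierConfig(**raw.pop("classifier", {}))
        return cls(classifier=classifier, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"]["tier_order"] = list(d["classifier"]["tier_order"])
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _group_records(clinical: pd.DataFrame, mask: pd.Series, endpoint: str):
    return build_endpoint(clinical[mask], endpoint)


def _atm_groups(clinical: pd.DataFrame) -> Dict[str, pd.Series]:
    """The four ATM-status groups: wildtype, mutation only, del(11q) only,
    biallelic (mutation + del(11q))."""
    mut = clinical["atm_mutated"] == 1
    d11 = clinical["del11q"] == 1
    return {
        "wildtype": ~mut & ~d11,
        "atm_mut_only": mut & ~d11,
        "del11q_only": ~mut & d11,
        "biallelic": mut & d11,
    }


def run_pipeline(cfg: PipelineConfig) -> Dict[str, str]:
    """Run every stage; returns a map of artifact name -> path.

    Raises on missing inputs before any computation; partial failures are
    recorded in the manifest and re-raised.
    """
    logging.basicConfig(level=cfg.log_level)
    for path in (cfg.variants_path, cfg.clinical_path):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    if cfg.blocklist_path and not os.path.exists(cfg.blocklist_path):
        raise FileNotFoundError(cfg.blocklist_path)
    os.makedirs(cfg.output_dir, exist_ok=True)

    artifacts: Dict[str, str] = {}
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    def _out(name: str) -> str:
        path = os.path.join(cfg.output_dir, name)
        artifacts[os.path.splitext(name)[0]] = path
        return path

    t0 = time.time()
    blocklist = read_blocklist(cfg.blocklist_path) if cfg.blocklist_path else set()
    variants = read_variant_table(cfg.variants_path, cfg.variant_format)
    clinical = read_clinical_table(cfg.clinical_path)
    log.info("read %d variants, %d patients (%.2fs)",
             len(variants), len(clinical), time.time() - t0)

    # --- classification -------------------------------------------------
    t0 = time.time()
    classified = classify_cohort(variants, cfg.classifier, blocklist)
    del11q_flags = {
        str(r.patient_id): bool(r.del11q)
        for r in clinical.dropna(subset=["del11q"]).itertuples()
    }
    statuses = assign_patient_status(classified, del11q_flags, cfg.classifier)
    write_classified_table(classified, _out("classified_variants.tsv"))
    write_status_table(statuses, _out("patient_status.tsv"))
    write_table(
        vaf_distribution_summary(classified, del11q_flags),
        _out("vaf_summary.tsv"),
    )
    manifest["stages"]["classify"] = {
        "n_variants": len(classified),
        "n_mutated_patients": sum(s.status == "mutated" for s in statuses),
        "seconds": round(time.time() - t0, 2),
    }

    # --- join ATM status into the clinical table ------------------------
    status_frame = status_to_frame(statuses)
    clinical = clinical.merge(
        status_frame[["patient_id", "atm_status"]], on="patient_id", how="left"
    )
    clinical["atm_mutated"] = (clinical["atm_status"] == "mutated").astype(int)
    if "binet" in clinical.columns:
        clinical["binet_bc"] = clinical["binet"].map(
            {"A": 0, "B": 1, "C": 1}
        )
    write_table(clinical, _out("clinical_with_status.tsv"))

    # --- associations ----------------------------------------------------
    t0 = time.time()
    exposures = [e for e in ASSOCIATION_EXPOSURES if e in clinical.columns]
    assoc = association_table(clinical, "atm_mutated", exposures)
    write_table(assoc, _out("associations.tsv"))

    strata_masks = {
        "all": pd.Series(True, index=clinical.index),
        "ucll": clinical["ucll"] == 1,
        "mcll": clinical["ucll"] == 0,
    }
    for name, mask in strata_masks.items():
        feats = [f for f in COOCCURRENCE_FEATURES
                 if f in clinical.columns and f != ("ucll" if name != "all" else "")]
        com = cooccurrence_matrix(clinical[mask], feats)
        write_table(com.tests, _out(f"cooccurrence_{name}.tsv"))
    manifest["stages"]["associate"] = {"seconds": round(time.time() - t0, 2)}

    # --- survival --------------------------------------------------------
    t0 = time.time()
    surv_strata: Dict[str, pd.Series] = {}
    if "all" in cfg.strata:
        surv_strata["all"] = pd.Series(True, index=clinical.index)
    if "binet_a" in cfg.strata:
        surv_strata["binet_a"] = clinical["binet"] == "A"
    if "binet_a_ighv" in cfg.strata:
        surv_strata["binet_a_ucll"] = (clinical["binet"] == "A") & (clinical["ucll"] == 1)
        surv_strata["binet_a_mcll"] = (clinical["binet"] == "A") & (clinical["ucll"] == 0)

    for stratum, mask in surv_strata.items():
        sub = clinical[mask]
        groups = {}
        for gname, gmask in _atm_groups(sub).items():
            recs = build_endpoint(sub[gmask], "TTFT")
            if recs:
                groups[gname] = recs
                km = km_fit(recs)
                write_table(km.to_frame(), _out(f"km_ttft_{stratum}_{gname}.tsv"))
        if len(groups) >= 2:
            write_table(pairwise_logrank(groups),
                        _out(f"logrank_ttft_{stratum}.tsv"))
        try:
            covs = build_covariates(sub, DEFAULT_COVARIATE_SPEC)
            fit = cox_fit(build_endpoint(sub, "TTFT"), covs)
            write_table(fit.summary.reset_index(names="term"),
                        _out(f"cox_ttft_{stratum}.tsv"))
        except ValueError as exc:
            log.warning("Cox model skipped for stratum %s: %s", stratum, exc)
    manifest["stages"]["survive"] = {"seconds": round(time.time() - t0, 2)}

    manifest_path = os.path.join(cfg.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = manifest_path
    return artifacts
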