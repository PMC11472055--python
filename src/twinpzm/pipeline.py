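"""End-to-end PZM analysis pipeline.

Stages: input (simulate a cohort or read per-pair VCFs) -> genotype and
variant QC -> per-pair genotype concordance -> discordant-site (PZM)
extraction with germline-database and exonic-region annotation ->
96-motif spectra -> artefact profile from low-concordance pairs ->
likelihood-based signature attribution -> cohort report.

Every stage writes its intermediate table when an output directory is
given, and the run is deterministic given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    DISCORDANT_CLASSES,
    build_contingency,
    classify_pairs,
    cohort_concordance_summary,
    concordance_table,
    evaluate_pair,
)
from .discovery import (
    classify_functional_region,
    compare_exonic_burden,
    extract_discordant,
    filter_known_germline,
    load_germline_db,
    read_exon_bed,
    regress_counts_on_covariates,
    regress_vaf,
    summarize_pzm_counts,
)
from .motifs import MOTIFS, spectrum_from_records
from .qc import QCThresholds, RegionMask, apply_qc
from .signatures import (
    SignatureAttribution,
    build_artefact_profile,
    load_packaged_signatures,
    read_cosmic_v2,
    uniform_profile,
)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    mode: str = "simulate"  # "simulate" | "vcf-dir"
    sim: SimulationConfig | None = None
    vcf_dir: str | None = None
    metadata_path: str | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    mask_beds: list | None = None
    exon_bed: str | None = None
    exon_intervals: list | None = None
    germline_db_path: str | None = None
    signatures_path: str | None = None
    concordance_cutoff: float = 0.99
    discordant_classes: tuple = DISCORDANT_CLASSES
    vaf_filter: bool = True
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("simulate", "vcf-dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.sim is None:
            self.sim = SimulationConfig()
        if self.mode == "vcf-dir" and not self.vcf_dir:
            raise ValueError("vcf-dir mode requires vcf_dir")
        if self.seed is not None and self.sim is not None:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        if d.get("sim") is not None:
            sim = d["sim"]
            ap = sim.get("artefact_profile")
            if isinstance(ap, dict):
                sim["artefact_profile"] = {
                    "id": ap["id"], "p": list(np.round(np.asarray(ap["p"]), 12)),
                }
            if sim.get("context_weights") is not None:
                sim["context_weights"] = list(np.asarray(sim["context_weights"], float))
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs; every number is recomputable from the stored intermediates."""

    per_pair: pd.DataFrame
    pzm_records: pd.DataFrame
    spectra: pd.DataFrame
    concordance_summary: dict
    pzm_summary_all: dict | None
    pzm_summary_high: dict | None
    count_regression: pd.DataFrame | None
    vaf_regression: pd.DataFrame | None
    exonic_test: dict | None
    similarity: pd.DataFrame | None
    best_signature: pd.Series | None
    artefact_counts: np.ndarray
    qc_logs: pd.DataFrame
    provenance: dict

    def to_json_dict(self) -> dict:
        def df_dict(df):
            return None if df is None else json.loads(df.to_json(orient="split"))

        return {
            "provenance": self.provenance,
            "concordance_summary": self.concordance_summary,
            "pzm_summary_all": self.pzm_summary_all,
            "pzm_summary_high": self.pzm_summary_high,
            "count_regression": df_dict(self.count_regression),
            "vaf_regression": df_dict(self.vaf_regression),
            "exonic_test": self.exonic_test,
            "best_signature": None
            if self.best_signature is None
            else {str(k): v for k, v in self.best_signature.items()},
            "per_pair": df_dict(self.per_pair),
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_pair.to_csv(out / "per_pair.tsv", sep="\t", index=False)
        self.pzm_records.to_csv(out / "pzm_records.tsv", sep="\t", index=False)
        self.spectra.to_csv(out / "spectra.tsv", sep="\t")
        self.qc_logs.to_csv(out / "qc_log.tsv", sep="\t", index=False)
        if self.similarity is not None:
            self.similarity.to_csv(out / "similarity.tsv", sep="\t")
        if self.best_signature is not None:
            self.best_signature.rename_axis("pair_id").to_csv(
                out / "best_signature.tsv", sep="\t"
            )
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_inputs(config: PipelineConfig):
    if config.mode == "simulate":
        cohort = simulate_cohort(config.sim, signatures=_signatures(config))
        return cohort.pairs, cohort.metadata
    from .vcfio import read_pair_vcf

    vcf_paths = sorted(Path(config.vcf_dir).glob("*.vcf"))
    if not vcf_paths:
        raise FileNotFoundError(f"no .vcf files in {config.vcf_dir}")
    pairs = {p.stem: read_pair_vcf(p) for p in vcf_paths}
    if config.metadata_path:
        metadata = pd.read_csv(config.metadata_path, sep="\t")
        metadata["pair_id"] = metadata["pair_id"].astype(type(next(iter(pairs))))
    else:
        metadata = pd.DataFrame({"pair_id": list(pairs), "age": np.nan, "sex": None})
    return pairs, metadata


def _signatures(config: PipelineConfig):
    if config.signatures_path:
        return read_cosmic_v2(config.signatures_path)
    return load_packaged_signatures()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and return (and optionally write) the report."""
    pairs, metadata = _load_inputs(config)
    signatures = _signatures(config)
    masks = None
    if config.mask_beds:
        masks = [RegionMask.from_bed(p) for p in config.mask_beds]
    exons = config.exon_intervals
    if exons is None and config.exon_bed:
        exons = read_exon_bed(config.exon_bed)
    germline_db = (
        load_germline_db(config.germline_db_path) if config.germline_db_path else set()
    )

    meta = metadata.set_index("pair_id")
    results, qc_logs, pzm_frames, spectra = [], [], [], {}
    for pair_id, table in pairs.items():
        clean, log = apply_qc(
            table, config.thresholds, masks=masks, vaf_filter=config.vaf_filter
        )
        log["pair_id"] = pair_id
        qc_logs.append(log)
        contingency = build_contingency(clean["gt1"], clean["gt2"])
        results.append(
            evaluate_pair(
                pair_id,
                contingency,
                cutoff=config.concordance_cutoff,
                discordant_classes=config.discordant_classes,
            )
        )
        records = extract_discordant(clean, pair_id, classes=config.discordant_classes)
        records, n_germline_hits = filter_known_germline(records, germline_db)
        log["removed_known_germline"] = n_germline_hits
        if exons is not None:
            records = classify_functional_region(records, exons)
        pzm_frames.append(records)
        spectra[pair_id] = spectrum_from_records(records) if len(records) else np.zeros(96, dtype=np.int64)
        logger.info(
            "pair %s: %d sites post-QC, rate %.4f, %d PZM records",
            pair_id, len(clean), results[-1].rate, len(records),
        )

    pzm_records = pd.concat(pzm_frames, ignore_index=True)
    spectra_df = pd.DataFrame(spectra, index=list(MOTIFS)).T.rename_axis("pair_id")
    high, low = classify_pairs(results, cutoff=config.concordance_cutoff)

    # artefact background from the low-concordance stratum
    low_spectra = [spectra[r.pair_id] for r in low if spectra[r.pair_id].sum() > 0]
    if low_spectra:
        artefact = build_artefact_profile(low_spectra)
    else:
        artefact = uniform_profile("artefact")
        logger.info("no low-concordance pairs with mutations: uniform background used")

    scored = {
        r.pair_id: spectra[r.pair_id] for r in high if spectra[r.pair_id].sum() > 0
    }
    if scored:
        fit = SignatureAttribution(scored, signatures, artefact=artefact).fit()
        similarity, best = fit.scores, fit.best_signature
    else:
        similarity, best = None, None

    per_pair = concordance_table(results)
    pzm_counts = pzm_records.groupby("pair_id").size()
    per_pair["n_pzm"] = per_pair["pair_id"].map(pzm_counts).fillna(0).astype(int)
    if exons is not None:
        exonic = pzm_records[pzm_records["region_label"] == "exonic"].groupby("pair_id").size()
        per_pair["n_exonic"] = per_pair["pair_id"].map(exonic).fillna(0).astype(int)
    per_pair["age"] = per_pair["pair_id"].map(meta["age"]) if "age" in meta else np.nan
    per_pair["sex"] = per_pair["pair_id"].map(meta["sex"]) if "sex" in meta else None

    concordance_summary = cohort_concordance_summary([r.rate for r in results])
    concordance_summary["n_high"] = len(high)
    concordance_summary["n_low"] = len(low)
    pzm_summary_all = summarize_pzm_counts(per_pair["n_pzm"])
    high_ids = {r.pair_id for r in high}
    pzm_summary_high = (
        summarize_pzm_counts(per_pair.loc[per_pair["pair_id"].isin(high_ids), "n_pzm"])
        if high
        else None
    )

    count_regression = vaf_regression = None
    if per_pair["age"].notna().all() and per_pair["sex"].notna().all():
        try:
            count_regression = regress_counts_on_covariates(
                per_pair["n_pzm"], per_pair["age"], per_pair["sex"]
            )
        except (ValueError, np.linalg.LinAlgError) as e:
            logger.warning("count regression skipped: %s", e)
        rate_of = {r.pair_id: r.rate for r in results}
        rows = pzm_records[pzm_records["vaf"].notna()]
        if len(rows) >= 5:
            try:
                vaf_regression = regress_vaf(
                    rows["vaf"],
                    rows["pair_id"].map(rate_of),
                    rows["pair_id"].map(meta["age"]),
                    rows["pair_id"].map(meta["sex"]),
                )
            except (ValueError, np.linalg.LinAlgError) as e:
                logger.warning("VAF regression skipped: %s", e)

    exonic_test = None
    if exons is not None and len(per_pair):
        u, p = compare_exonic_burden(
            per_pair["n_exonic"], per_pair["n_pzm"] - per_pair["n_exonic"]
        )
        exonic_test = {"U": u, "p": p}

    provenance = {
        "package": "twinpzm",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.sim.seed if config.sim is not None else config.seed,
        "mode": config.mode,
    }
    report = RunReport(
        per_pair=per_pair,
        pzm_records=pzm_records,
        spectra=spectra_df,
        concordance_summary=concordance_summary,
        pzm_summary_all=pzm_summary_all,
        pzm_summary_high=pzm_summary_high,
        count_regression=count_regression,
        vaf_regression=vaf_regression,
        exonic_test=exonic_test,
        similarity=similarity,
        best_signature=best,
        artefact_counts=np.sum(low_spectra, axis=0) if low_spectra else np.zeros(96),
        qc_logs=pd.DataFrame(qc_logs),
        provenance=provenance,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
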