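"""Genotype and variant quality control.

Filters mirror a conservative germline-calling workflow used to extract
high-confidence variants from ~24x WGS of twin pairs:

* genotype-level: mask a genotype to Missing when DP < 5, GQ < 20, or
  (DP > 60 and GQ < 95) — the last rule removes suspiciously deep sites
  that are nonetheless ambiguous;
* variant-level: call rate >= 0.90 across cohort samples; biallelic
  autosomal SNVs only; sites inside low-complexity / cytoband-excluded /
  low-accessibility region masks removed;
* allele-support: for non-reference genotypes, VAF >= 0.10 and at least
  2 alt-supporting reads (VAF = AD_alt / (AD_ref + AD_alt)).

Boundary semantics are strict as stated: values exactly at a threshold
are retained. VCF positions are 1-based; BED masks are 0-based
half-open, converted at the reader boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

# genotype class codes used throughout the package
GT_MISSING = -1
GT_RR = 0
GT_RA = 1
GT_AA = 2

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}

PAIR_COLUMNS = [
    "chrom", "pos", "ref", "alt", "context",
    "gt1", "dp1", "gq1", "ad_ref1", "ad_alt1",
    "gt2", "dp2", "gq2", "ad_ref2", "ad_alt2",
]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults are the analysis-grade settings."""

    min_dp: float = 5
    min_gq: float = 20
    high_dp: float = 60
    high_dp_min_gq: float = 95
    min_call_rate: float = 0.90
    min_vaf: float = 0.10
    min_alt_count: int = 2

    def __post_init__(self):
        for name in ("min_dp", "min_gq", "high_dp_min_gq", "min_alt_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be in [0, 1]")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")

    @classmethod
    def disabled(cls) -> "QCThresholds":
        """Thresholds that retain everything (for truth-recovery runs)."""
        return cls(
            min_dp=0, min_gq=0, high_dp=math.inf, high_dp_min_gq=0,
            min_call_rate=0.0, min_vaf=0.0, min_alt_count=0,
        )


@dataclass(frozen=True)
class SiteGenotype:
    """One sample's call at one site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt_class: int
    dp: int
    gq: int
    ad_ref: int
    ad_alt: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt or self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"bad alleles {self.ref}>{self.alt}")
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("negative allele depth")

    @property
    def vaf(self) -> float:
        denom = self.ad_ref + self.ad_alt
        return self.ad_alt / denom if denom > 0 else float("nan")


def filter_genotype(dp, gq, thresholds: QCThresholds = QCThresholds()):
    """Retained flag(s) for the genotype-level DP/GQ rules.

    Vectorized over array inputs. NaN depth or quality fails.
    """
    dp = np.asarray(dp, dtype=float)
    gq = np.asarray(gq, dtype=float)
    bad = (
        np.isnan(dp) | np.isnan(gq)
        | (dp < thresholds.min_dp)
        | (gq < thresholds.min_gq)
        | ((dp > thresholds.high_dp) & (gq < thresholds.high_dp_min_gq))
    )
    retained = ~bad
    return bool(retained) if retained.ndim == 0 else retained


def filter_call_rate(called, thresholds: QCThresholds = QCThresholds()) -> bool:
    """Retain a variant iff the called fraction over samples >= threshold."""
    called = np.asarray(called, dtype=bool)
    if called.size == 0:
        raise ValueError("empty presence vector")
    return bool(called.mean() >= thresholds.min_call_rate)


def filter_vaf(ad_ref, ad_alt, thresholds: QCThresholds = QCThresholds()):
    """Retained flag(s) for the allele-support rules on non-ref genotypes.

    VAF = ad_alt / (ad_ref + ad_alt); retained iff VAF >= min_vaf and
    ad_alt >= min_alt_count. Zero total allele depth fails.
    """
    ad_ref = np.asarray(ad_ref, dtype=float)
    ad_alt = np.asarray(ad_alt, dtype=float)
    denom = ad_ref + ad_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(denom > 0, ad_alt / np.where(denom > 0, denom, 1), np.nan)
    retained = (
        (denom > 0)
        & (vaf >= thresholds.min_vaf)
        & (ad_alt >= thresholds.min_alt_count)
    )
    return bool(retained) if retained.ndim == 0 else retained


class RegionMask:
    """Set of half-open genomic intervals (0-based) to exclude."""

    def __init__(self, intervals, label: str = "mask"):
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"malformed interval {chrom}:{start}-{end}")
            self._trees.setdefault(str(chrom), IntervalTree()).addi(start, end)
            n += 1
        self.n_intervals = n

    @classmethod
    def from_bed(cls, path, label: str | None = None) -> "RegionMask":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.append((chrom, int(start), int(end)))
        return cls(intervals, label=label or str(path))

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` falls inside any interval."""
        tree = self._trees.get(str(chrom))
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def flags(self, chroms, positions) -> np.ndarray:
        return np.fromiter(
            (self.contains(c, p) for c, p in zip(chroms, positions)),
            dtype=bool,
            count=len(positions),
        )


def apply_region_mask(sites: pd.DataFrame, masks) -> pd.DataFrame:
    """Drop sites whose position intersects any mask interval."""
    if masks is None:
        return sites
    if isinstance(masks, RegionMask):
        masks = [masks]
    keep = np.ones(len(sites), dtype=bool)
    for m in masks:
        keep &= ~m.flags(sites["chrom"].to_numpy(), sites["pos"].to_numpy())
    return sites.loc[keep]


def restrict_snv_autosomes(sites: pd.DataFrame) -> pd.DataFrame:
    """Keep biallelic single-base substitutions on autosomes 1-22."""
    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    keep = (
        sites["chrom"].astype(str).isin(AUTOSOMES)
        & ref.isin(list("ACGT"))
        & alt.isin(list("ACGT"))
        & (ref != alt)
    )
    return sites.loc[keep]


def apply_qc(
    pair: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    masks=None,
    vaf_filter: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full QC cascade on a two-sample pair table.

    Order: SNV/autosome restriction -> region masks -> genotype DP/GQ
    masking -> allele-support (VAF) masking of non-reference genotypes.
    Genotypes failing a genotype-level rule are set to Missing; sites
    are never re-added. Returns the filtered table and a counter log.
    """
    log: dict[str, int] = {"input_sites": len(pair)}
    out = restrict_snv_autosomes(pair)
    log["removed_non_snv_autosome"] = log["input_sites"] - len(out)
    n = len(out)
    out = apply_region_mask(out, masks)
    log["removed_region_mask"] = n - len(out)
    out = out.copy()
    for s in ("1", "2"):
        gt = out[f"gt{s}"].to_numpy().copy()
        ok = filter_genotype(out[f"dp{s}"], out[f"gq{s}"], thresholds)
        fired = (gt != GT_MISSING) & ~np.asarray(ok, dtype=bool)
        log[f"genotypes_masked_dp_gq_twin{s}"] = int(fired.sum())
        gt[fired] = GT_MISSING
        if vaf_filter:
            nonref = (gt == GT_RA) | (gt == GT_AA)
            ok_vaf = filter_vaf(out[f"ad_ref{s}"], out[f"ad_alt{s}"], thresholds)
            fired = nonref & ~np.asarray(ok_vaf, dtype=bool)
            log[f"genotypes_masked_vaf_twin{s}"] = int(fired.sum())
            gt[fired] = GT_MISSING
        out[f"gt{s}"] = gt
    log["output_sites"] = len(out)
    return out, log


def tighten(thresholds: QCThresholds, **kwargs) -> QCThresholds:
    """Convenience for building stricter thresholds in property tests."""
    return replace(thresholds, **kwargs)
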