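"""VCF serialization of twin-pair call tables (pysam-backed).

One VCF v4.2 per pair, two sample columns, FORMAT GT:AD:DP:GQ. The
trinucleotide reference context is carried in the INFO field ``TNC`` so
that round-trips need no reference FASTA; when reading third-party VCFs
without ``TNC``, contexts can be filled from a FASTA by the caller.

Coordinates are 1-based in the pair tables and in the VCF; conversion
to pysam's 0-based starts happens only here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .qc import GT_AA, GT_MISSING, GT_RA, GT_RR, PAIR_COLUMNS
from .simulate import CHROM_LENGTH, CHROMS

logger = logging.getLogger(__name__)

_GT_TO_ALLELES = {
    GT_RR: (0, 0),
    GT_RA: (0, 1),
    GT_AA: (1, 1),
    GT_MISSING: (None, None),
}

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMS)}


def _make_header(sample_names) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for chrom in CHROMS:
        header.contigs.add(chrom, length=CHROM_LENGTH)
    header.add_line(
        '##INFO=<ID=TNC,Number=1,Type=String,'
        'Description="Trinucleotide reference context centred on POS">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    )
    for name in sample_names:
        header.add_sample(name)
    return header


def _check_sorted(table: pd.DataFrame) -> None:
    order = table["chrom"].map(_CHROM_ORDER).to_numpy()
    if np.isnan(order.astype(float)).any():
        bad = sorted(set(table["chrom"]) - set(CHROMS))
        raise ValueError(f"unknown contigs {bad}; expected {CHROMS[0]}..{CHROMS[-1]}")
    pos = table["pos"].to_numpy()
    key = order.astype(np.int64) * (CHROM_LENGTH + 1) + pos
    if (np.diff(key) < 0).any():
        raise ValueError("input table is not sorted by chromosome then position")


def write_pair_vcf(
    table: pd.DataFrame, path, sample_names=("twin1", "twin2")
) -> None:
    """Write a two-sample pair table as an uncompressed VCF v4.2.

    The table must be sorted by chromosome (chr1..chr22) then position.
    An empty table yields a header-only VCF.
    """
    if len(table):
        _check_sorted(table)
    header = _make_header(sample_names)
    path = str(path)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for row in table.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.info["TNC"] = row.context
            for s, name in enumerate(sample_names, start=1):
                sample = rec.samples[name]
                sample["GT"] = _GT_TO_ALLELES[int(getattr(row, f"gt{s}"))]
                sample["AD"] = (
                    int(getattr(row, f"ad_ref{s}")),
                    int(getattr(row, f"ad_alt{s}")),
                )
                sample["DP"] = int(getattr(row, f"dp{s}"))
                sample["GQ"] = int(getattr(row, f"gq{s}"))
            vcf.write(rec)


def _gt_class(alleles) -> int:
    if alleles is None or any(a is None for a in alleles):
        return GT_MISSING
    s = sum(alleles)
    return {0: GT_RR, 1: GT_RA, 2: GT_AA}.get(s, GT_MISSING)


def read_pair_vcf(path) -> pd.DataFrame:
    """Read a two-sample pair VCF back into a pair table.

    Multiallelic records are dropped (biallelic SNV analysis only) and
    counted in the log. Missing TNC yields an ``NNN`` context
    placeholder; signature analysis then requires contexts from a
    reference FASTA upstream.
    """
    rows = []
    n_multiallelic = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(f"{path}: expected 2 samples, found {len(samples)}")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multiallelic += 1
                continue
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alts[0],
                "context": rec.info.get("TNC", "NNN"),
            }
            for s, name in enumerate(samples, start=1):
                call = rec.samples[name]
                ad = call.get("AD") or (0, 0)
                row[f"gt{s}"] = _gt_class(call.get("GT"))
                row[f"dp{s}"] = call.get("DP") or 0
                row[f"gq{s}"] = call.get("GQ") or 0
                row[f"ad_ref{s}"] = ad[0] or 0
                row[f"ad_alt{s}"] = ad[1] if len(ad) > 1 and ad[1] is not None else 0
            rows.append(row)
    if n_multiallelic:
        logger.info("%s: dropped %d multiallelic records", path, n_multiallelic)
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    for col in df.columns:
        if col.startswith(("gt", "dp", "gq", "ad_")):
            df[col] = df[col].astype(np.int64)
    df["pos"] = df["pos"].astype(np.int64)
    return df
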