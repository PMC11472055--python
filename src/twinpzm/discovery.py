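"""Postzygotic somatic mutation (PZM) discovery and cohort statistics.

A PZM candidate is a QC-passed site at which co-twins carry different
genotypes. Candidates matching known germline variants (exact
chrom/pos/ref/alt key) are removed to limit germline contamination.
Remaining records are labelled exonic / non-exonic by BED-interval
overlap, and the cohort is summarized with descriptive statistics, OLS
regressions of mutation burden and VAF on covariates, and a Wilcoxon
rank-sum comparison of exonic vs non-exonic burden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats

from .concordance import DISCORDANT_CLASSES, genotype_pair_class
from .qc import GT_MISSING

PZM_COLUMNS = [
    "pair_id", "chrom", "pos", "ref", "alt", "genotype_pair",
    "carrier", "vaf", "context", "region_label",
]


def extract_discordant(
    pair: pd.DataFrame, pair_id, classes=DISCORDANT_CLASSES
) -> pd.DataFrame:
    """One PZM record per discordant QC-passed site.

    The carrier is the twin with more alt alleles; its VAF is
    AD_alt / (AD_ref + AD_alt). Sites Missing in either twin are
    skipped.
    """
    rows = []
    gt1 = pair["gt1"].to_numpy()
    gt2 = pair["gt2"].to_numpy()
    for i in range(len(pair)):
        if gt1[i] == GT_MISSING or gt2[i] == GT_MISSING:
            continue
        cls = genotype_pair_class(gt1[i], gt2[i])
        if cls not in classes:
            continue
        carrier = 1 if gt1[i] > gt2[i] else 2
        r = pair.iloc[i]
        ad_ref = r[f"ad_ref{carrier}"]
        ad_alt = r[f"ad_alt{carrier}"]
        denom = ad_ref + ad_alt
        rows.append(
            {
                "pair_id": pair_id,
                "chrom": r["chrom"],
                "pos": int(r["pos"]),
                "ref": r["ref"],
                "alt": r["alt"],
                "genotype_pair": cls,
                "carrier": carrier,
                "vaf": float(ad_alt / denom) if denom > 0 else np.nan,
                "context": r["context"],
                "region_label": "non-exonic",
            }
        )
    return pd.DataFrame(rows, columns=PZM_COLUMNS)


def load_germline_db(path) -> set[tuple]:
    """Known germline sites from a TSV with chrom, pos, ref, alt columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    return {
        (str(c), int(p), str(r), str(a))
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    }


def filter_known_germline(records: pd.DataFrame, db: set[tuple]) -> tuple[pd.DataFrame, int]:
    """Drop records whose (chrom, pos, ref, alt) key is in the database.

    Matching is on the full allele key: a database C>T entry does not
    remove a C>A record at the same position. Returns the filtered
    table and the number removed.
    """
    if not db or records.empty:
        return records, 0
    keys = [
        (str(c), int(p), str(r), str(a))
        for c, p, r, a in zip(records["chrom"], records["pos"], records["ref"], records["alt"])
    ]
    keep = np.array([k not in db for k in keys], dtype=bool)
    return records.loc[keep], int((~keep).sum())


def classify_functional_region(records: pd.DataFrame, exon_intervals) -> pd.DataFrame:
    """Label each record exonic / non-exonic by interval overlap.

    ``exon_intervals`` is an iterable of (chrom, start, end), 0-based
    half-open (BED convention); records carry 1-based positions.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in exon_intervals:
        if start >= end:
            raise ValueError(f"malformed exon interval {chrom}:{start}-{end}")
        trees.setdefault(str(chrom), IntervalTree()).addi(start, end)
    records = records.copy()
    labels = []
    for c, p in zip(records["chrom"], records["pos"]):
        tree = trees.get(str(c))
        hit = tree is not None and tree.overlaps_point(int(p) - 1)
        labels.append("exonic" if hit else "non-exonic")
    records["region_label"] = labels
    return records


def read_exon_bed(path):
    """Exon intervals from a BED file (first three columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def summarize_pzm_counts(counts) -> dict:
    """Mean, sample (n-1) SD, min, max of per-pair PZM counts."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty pair subset")
    return {
        "n_pairs": int(counts.size),
        "mean": float(counts.mean()),
        "sd": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        "min": float(counts.min()),
        "max": float(counts.max()),
    }


def _ols_table(y, X: pd.DataFrame) -> pd.DataFrame:
    X = sm.add_constant(X, has_constant="add")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient (singular)")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )


def encode_sex(sexes) -> np.ndarray:
    """Encode sex labels as 0 (M) / 1 (F); numeric codes pass through."""
    mapping = {"M": 0.0, "F": 1.0, "male": 0.0, "female": 1.0}
    out = []
    for s in sexes:
        if isinstance(s, str):
            if s not in mapping:
                raise ValueError(f"unknown sex label {s!r}")
            out.append(mapping[s])
        else:
            out.append(float(s))
    return np.array(out, dtype=float)


def regress_counts_on_covariates(counts, ages, sexes) -> pd.DataFrame:
    """OLS of per-pair PZM counts on age and sex.

    Returns a table with beta, standard error, t and two-sided p per
    factor (t distribution, n - p - 1 degrees of freedom).
    """
    X = pd.DataFrame({"age": np.asarray(ages, dtype=float), "sex": encode_sex(sexes)})
    if len(X) < X.shape[1] + 2:
        raise ValueError("too few pairs for the regression")
    return _ols_table(counts, X)


def regress_vaf(vafs, concordance, ages, sexes) -> pd.DataFrame:
    """OLS of per-mutation VAF on pair concordance rate, age and sex."""
    X = pd.DataFrame(
        {
            "concordance": np.asarray(concordance, dtype=float),
            "age": np.asarray(ages, dtype=float),
            "sex": encode_sex(sexes),
        }
    )
    if len(X) < X.shape[1] + 2:
        raise ValueError("too few mutations for the regression")
    return _ols_table(vafs, X)


def compare_exonic_burden(exonic_counts, non_exonic_counts):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Exact null distribution for small samples without ties, normal
    approximation otherwise. Returns (U statistic, p-value).
    """
    x = np.asarray(list(exonic_counts), dtype=float)
    y = np.asarray(list(non_exonic_counts), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
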