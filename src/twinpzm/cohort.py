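"""Reference cohort table: loading and summary statistics.

The packaged fixture ``data/reference_cohort.tsv`` transcribes the
characteristics of a 30-pair adult monozygotic twin WGS cohort (~24x
coverage): per-pair age, sex, mean depth per twin, genotype concordance
rate (percent), discordant-variant count and exonic discordant count.
It anchors the presentation-layer summaries and provides the default
ages/sexes for study-like simulations.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd


def load_reference_cohort(path=None) -> pd.DataFrame:
    """Load the packaged reference cohort table (or a compatible TSV)."""
    if path is not None:
        df = pd.read_csv(path, sep="\t")
    else:
        ref = importlib.resources.files("twinpzm.data") / "reference_cohort.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    required = {
        "pair_id", "age", "sex", "depth_twin1", "depth_twin2",
        "concordance_rate_pct", "n_discordant",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def summarize_cohort_table(df: pd.DataFrame, cutoff: float = 0.99) -> dict:
    """Cohort summary block from a reference-style cohort table.

    Counts of discordant variants double as PZM counts here: the table
    records post-filter discordant sites. The high-concordance subset is
    pairs with rate >= cutoff (on the table's percent scale).
    """
    high = df[df["concordance_rate_pct"] >= 100 * cutoff]
    counts_all = df["n_discordant"].to_numpy(dtype=float)
    counts_high = high["n_discordant"].to_numpy(dtype=float)
    depths = np.concatenate(
        [df["depth_twin1"].to_numpy(dtype=float), df["depth_twin2"].to_numpy(dtype=float)]
    )
    sexes = df["sex"].astype(str).to_numpy()
    return {
        "n_pairs": int(len(df)),
        "n_high_concordance_pairs": int(len(high)),
        "mean_age_years": float(df["age"].mean()),
        "female_ratio": float((sexes == "F").mean()),
        "mean_depth": float(depths.mean()),
        "concordance_mean_pct": float(df["concordance_rate_pct"].mean()),
        "concordance_median_pct": float(df["concordance_rate_pct"].median()),
        "concordance_min_pct": float(df["concordance_rate_pct"].min()),
        "concordance_max_pct": float(df["concordance_rate_pct"].max()),
        "pzm_mean_all_pairs": float(counts_all.mean()),
        "pzm_mean_high": float(counts_high.mean()),
        "pzm_sd_high": float(counts_high.std(ddof=1)),
        "pzm_min_high": float(counts_high.min()),
        "pzm_max_high": float(counts_high.max()),
    }


def format_cohort_summary(summary: dict) -> str:
    """Human-readable rendering of :func:`summarize_cohort_table`."""
    lines = [
        f"pairs: {summary['n_pairs']} "
        f"(high-concordance: {summary['n_high_concordance_pairs']})",
        f"mean age: {summary['mean_age_years']:.1f} y; "
        f"female ratio: {100 * summary['female_ratio']:.0f}%",
        f"mean depth: {summary['mean_depth']:.1f}x",
        f"concordance: mean {summary['concordance_mean_pct']:.1f}%, "
        f"median {summary['concordance_median_pct']:.1f}%, "
        f"range {summary['concordance_min_pct']:.1f}-"
        f"{summary['concordance_max_pct']:.1f}%",
        f"PZM count, all pairs: mean {summary['pzm_mean_all_pairs']:.0f}",
        f"PZM count, high subset: {summary['pzm_mean_high']:.1f} "
        f"+/- {summary['pzm_sd_high']:.1f} "
        f"(range {summary['pzm_min_high']:.0f}-{summary['pzm_max_high']:.0f})",
    ]
    return "\n".join(lines)
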