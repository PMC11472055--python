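"""Twin genotype concordance.

For each pair, genotype calls at QC-passed sites are tallied into a
3x3 contingency matrix over {Ref/Ref, Ref/Alt, Alt/Alt}, collapsed to
unordered pair classes (twin labels are arbitrary). Sites where both
twins are Ref/Ref are unobservable in a variants-only callset and are
not counted. The concordance rate is

    (n_RA~RA + n_AA~AA) /
    (n_RR~RA + n_RR~AA + n_RA~RA + n_RA~AA + n_AA~AA)

Pairs at or above the 99% cutoff are classed as high-concordance; the
remainder are treated as artefact-prone and supply the background
profile for signature scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import GT_AA, GT_MISSING, GT_RA, GT_RR

#: unordered discordant genotype-pair classes
DISCORDANT_CLASSES = ("rr_ra", "rr_aa", "ra_aa")

_CLASS_OF = {
    (GT_RR, GT_RA): "rr_ra",
    (GT_RR, GT_AA): "rr_aa",
    (GT_RA, GT_RA): "ra_ra",
    (GT_RA, GT_AA): "ra_aa",
    (GT_AA, GT_AA): "aa_aa",
}


def genotype_pair_class(gt1: int, gt2: int) -> str | None:
    """Unordered pair class, or None for (RR,RR)/anything Missing."""
    if gt1 == GT_MISSING or gt2 == GT_MISSING:
        return None
    lo, hi = sorted((gt1, gt2))
    return _CLASS_OF.get((lo, hi))


@dataclass
class PairContingency:
    """Collapsed genotype contingency counts for one twin pair."""

    n_rr_ra: int = 0
    n_rr_aa: int = 0
    n_ra_ra: int = 0
    n_ra_aa: int = 0
    n_aa_aa: int = 0

    def __post_init__(self):
        if min(self.n_rr_ra, self.n_rr_aa, self.n_ra_ra, self.n_ra_aa, self.n_aa_aa) < 0:
            raise ValueError("negative contingency count")

    @property
    def denominator(self) -> int:
        return self.n_rr_ra + self.n_rr_aa + self.n_ra_ra + self.n_ra_aa + self.n_aa_aa

    def n_discordant(self, classes=DISCORDANT_CLASSES) -> int:
        return sum(getattr(self, f"n_{c}") for c in classes)


def build_contingency(gt1, gt2) -> PairContingency:
    """Tally genotype-class combinations over a pair's sites.

    Sites Missing in either twin are excluded; (RR,RR) sites are not
    counted. The tally is invariant under swapping the twin columns.
    """
    gt1 = np.asarray(gt1)
    gt2 = np.asarray(gt2)
    if gt1.shape != gt2.shape:
        raise ValueError("genotype vectors differ in length")
    lo = np.minimum(gt1, gt2)
    hi = np.maximum(gt1, gt2)
    ok = (lo != GT_MISSING) & (hi != GT_MISSING)
    c = PairContingency()
    key = lo * 3 + hi  # unique per (lo, hi) with codes 0..2
    for (a, b), name in _CLASS_OF.items():
        setattr(c, f"n_{name}", int(((key == a * 3 + b) & ok).sum()))
    return c


def concordance_rate(c: PairContingency) -> float:
    """Concordant non-reference fraction; undefined for empty matrices."""
    denom = c.denominator
    if denom == 0:
        raise ZeroDivisionError("concordance rate undefined: no non-(RR,RR) sites")
    return (c.n_ra_ra + c.n_aa_aa) / denom


@dataclass
class ConcordanceResult:
    pair_id: object
    rate: float
    n_discordant: int
    high_concordance: bool


def evaluate_pair(
    pair_id,
    contingency: PairContingency,
    cutoff: float = 0.99,
    discordant_classes=DISCORDANT_CLASSES,
) -> ConcordanceResult:
    rate = concordance_rate(contingency)
    return ConcordanceResult(
        pair_id=pair_id,
        rate=rate,
        n_discordant=contingency.n_discordant(discordant_classes),
        high_concordance=rate >= cutoff,
    )


def classify_pairs(results, cutoff: float = 0.99):
    """Split pairs into (high, low) sets at the cutoff (>= is high).

    Classification uses the full-precision rate; rounding to one
    decimal happens only at presentation time.
    """
    high = [r for r in results if r.rate >= cutoff]
    low = [r for r in results if r.rate < cutoff]
    return high, low


def cohort_concordance_summary(rates) -> dict:
    """Mean / median / min / max of per-pair concordance rates."""
    rates = np.asarray(list(rates), dtype=float)
    if rates.size == 0:
        raise ValueError("empty cohort")
    return {
        "mean": float(rates.mean()),
        "median": float(np.median(rates)),
        "min": float(rates.min()),
        "max": float(rates.max()),
    }


def concordance_table(results) -> pd.DataFrame:
    """Per-pair presentation table (rates as % to one decimal)."""
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in results],
            "concordance_rate_pct": [round(100 * r.rate, 1) for r in results],
            "n_discordant": [r.n_discordant for r in results],
            "high_concordance": [r.high_concordance for r in results],
        }
    )
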