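"""Mutational-signature catalogues and likelihood-based attribution.

A signature is a 96-component probability profile over trinucleotide
substitution motifs. A pair's mutation spectrum ``x`` (96 counts,
``n = sum(x)``) is scored against each catalogued signature with the
multinomial log-likelihood

    logL(x; p) = log n! - sum_k log x_k! + sum_k x_k log p_k

after replacing zero entries of each profile by half its minimum
positive entry (and renormalizing). Scores are corrected for a
sequencing-artefact background profile, pooled from low-concordance
twin pairs, as

    score_s = (logL(x; p_s) - logL(x; p_artefact)) / n

and the best-scoring signature is assigned. The per-mutation scaling
keeps scores comparable across pairs with different mutation counts,
and the artefact subtraction removes terms common to all signatures.

The packaged catalogue (``data/signatures_30_synthetic.tsv``) is a
synthetic 30-signature stand-in in the COSMIC v2 file schema; a real
COSMIC v2 probability TSV can be read with :func:`read_cosmic_v2`
unchanged.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .motifs import MOTIFS, N_MOTIFS

__all__ = [
    "SignatureProfile",
    "SignatureMatrix",
    "read_cosmic_v2",
    "load_packaged_signatures",
    "uniform_profile",
    "complement_zeros",
    "multinomial_loglik",
    "build_artefact_profile",
    "corrected_similarity",
    "SimilarityRow",
    "SignatureAttribution",
    "SignatureAttributionResults",
]


@dataclass(frozen=True)
class SignatureProfile:
    """One 96-motif probability profile."""

    id: str
    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_MOTIFS,):
            raise ValueError(f"profile {self.id}: expected 96 entries, got {p.shape}")
        if (p < 0).any():
            raise ValueError(f"profile {self.id}: negative probabilities")
        s = p.sum()
        if s <= 0:
            raise ValueError(f"profile {self.id}: all-zero profile")
        object.__setattr__(self, "p", p / s)


class SignatureMatrix:
    """Ordered collection of signature profiles in canonical motif order."""

    def __init__(self, profiles: list[SignatureProfile]):
        ids = [pr.id for pr in profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate signature ids")
        self.profiles = list(profiles)
        self.ids = ids
        self._by_id = {pr.id: pr for pr in profiles}

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, sig_id: str) -> SignatureProfile:
        try:
            return self._by_id[sig_id]
        except KeyError:
            raise KeyError(f"unknown signature id {sig_id!r}") from None

    def __contains__(self, sig_id: str) -> bool:
        return sig_id in self._by_id

    def to_frame(self) -> pd.DataFrame:
        """96 x S probability table indexed by motif label."""
        return pd.DataFrame(
            {pr.id: pr.p for pr in self.profiles}, index=list(MOTIFS)
        )


def read_cosmic_v2(path) -> SignatureMatrix:
    """Read a COSMIC v2-format signature probability TSV.

    The file must have ``Substitution Type``, ``Trinucleotide`` and
    ``Somatic Mutation Type`` columns followed by one column per
    signature. Rows may appear in any order; all 96 motifs must be
    present exactly once. Each signature column is renormalized and
    must sum to 1 within 1e-3 beforehand.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"Substitution Type", "Trinucleotide", "Somatic Mutation Type"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    keys = df["Somatic Mutation Type"].astype(str)
    if keys.duplicated().any():
        dupes = sorted(keys[keys.duplicated()].unique())
        raise ValueError(f"duplicate motif rows: {dupes}")
    absent = [m for m in MOTIFS if m not in set(keys)]
    if absent:
        raise ValueError(f"missing motif rows: {absent}")
    df = df.set_index(keys).loc[list(MOTIFS)]
    sig_cols = [c for c in df.columns if c not in required]
    profiles = []
    for c in sig_cols:
        vals = pd.to_numeric(df[c], errors="raise").to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError(f"signature column {c!r} has invalid entries")
        if abs(vals.sum() - 1.0) > 1e-3:
            raise ValueError(
                f"signature column {c!r} sums to {vals.sum():.6f}, not 1"
            )
        profiles.append(SignatureProfile(str(c), vals))
    if not profiles:
        raise ValueError("no signature columns found")
    return SignatureMatrix(profiles)


def load_packaged_signatures() -> SignatureMatrix:
    """Load the packaged synthetic 30-signature catalogue."""
    ref = importlib.resources.files("twinpzm.data") / "signatures_30_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_cosmic_v2(path)


def uniform_profile(sig_id: str = "uniform") -> SignatureProfile:
    return SignatureProfile(sig_id, np.full(N_MOTIFS, 1.0 / N_MOTIFS))


def complement_zeros_values(p) -> np.ndarray:
    """Zero-complement a raw probability vector of any length.

    Zeros are replaced by half the minimum positive entry and the
    vector renormalized to sum 1.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probabilities")
    if (p <= 0).all():
        raise ValueError("all-zero profile")
    if (p > 0).all():
        return p / p.sum()
    fill = p[p > 0].min() / 2.0
    q = np.where(p > 0, p, fill)
    return q / q.sum()


def complement_zeros(profile: SignatureProfile) -> SignatureProfile:
    """Replace zero entries by half the minimum positive entry.

    The result is renormalized to sum 1 so it stays a probability
    profile. Profiles without zeros are returned unchanged.
    """
    if (profile.p > 0).all():
        return profile
    return SignatureProfile(profile.id, complement_zeros_values(profile.p))


def multinomial_loglik(x, p) -> float:
    """Multinomial log-likelihood log n! - sum log x_k! + sum x_k log p_k.

    Log-factorials are computed with the log-gamma function. ``p`` must
    be strictly positive wherever ``x`` is positive (zero-complement
    profiles first).
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape:
        raise ValueError("x and p must have the same length")
    if (x < 0).any():
        raise ValueError("negative counts")
    n = x.sum()
    if n < 1:
        raise ValueError("spectrum is empty (n = 0)")
    if (p[x > 0] <= 0).any():
        raise ValueError("p has zero mass on an observed motif; complement zeros first")
    ll = gammaln(n + 1.0) - gammaln(x + 1.0).sum()
    pos = x > 0
    return float(ll + (x[pos] * np.log(p[pos])).sum())


def build_artefact_profile(spectra) -> SignatureProfile:
    """Pool spectra of low-concordance pairs into an artefact profile.

    Counts are summed elementwise across pairs and normalized to sum 1.
    """
    spectra = [np.asarray(s, dtype=float) for s in spectra]
    if not spectra:
        raise ValueError(
            "no low-concordance pairs: skip the artefact correction "
            "(e.g. score against a uniform background instead)"
        )
    pooled = np.sum(spectra, axis=0)
    if pooled.sum() <= 0:
        raise ValueError("pooled artefact spectrum is empty")
    return SignatureProfile("artefact", pooled / pooled.sum())


@dataclass
class SimilarityRow:
    """Corrected per-signature scores for one pair's spectrum."""

    pair_id: object
    scores: pd.Series
    best_signature: str = field(init=False)

    def __post_init__(self):
        best = self.scores.idxmax()  # first index at the max: lowest-index tie-break
        self.best_signature = str(best)


def corrected_similarity(
    x,
    signatures: SignatureMatrix,
    artefact: SignatureProfile,
    pair_id=None,
    complement: bool = True,
) -> SimilarityRow:
    """Score one spectrum against every catalogued signature.

    score_s = (logL(x; p_s) - logL(x; p_artefact)) / n. The argmax is the
    assigned signature; ties break to the lowest signature index.
    """
    x = np.asarray(x, dtype=float)
    n = x.sum()
    if n < 1:
        raise ValueError("cannot score an empty spectrum (n = 0)")
    if complement:
        artefact = complement_zeros(artefact)
    ll_art = multinomial_loglik(x, artefact.p)
    scores = {}
    for pr in signatures.profiles:
        if complement:
            pr = complement_zeros(pr)
        scores[pr.id] = (multinomial_loglik(x, pr.p) - ll_art) / n
    return SimilarityRow(pair_id, pd.Series(scores))


class SignatureAttribution:
    """Model attributing pair spectra to a signature catalogue.

    Parameters
    ----------
    spectra : mapping or DataFrame
        Pair id -> 96-count motif spectrum (DataFrame rows are pairs,
        columns the canonical 96 motifs).
    signatures : SignatureMatrix
        Candidate signatures.
    artefact : SignatureProfile, optional
        Background profile subtracted from every score. Typically built
        with :func:`build_artefact_profile` from low-concordance pairs;
        defaults to a uniform background when no such pairs exist.
    """

    def __init__(self, spectra, signatures: SignatureMatrix, artefact=None):
        if isinstance(spectra, pd.DataFrame):
            spectra = {pid: row.to_numpy() for pid, row in spectra.iterrows()}
        self.spectra = {pid: np.asarray(v, dtype=float) for pid, v in spectra.items()}
        for pid, x in self.spectra.items():
            if x.shape != (N_MOTIFS,):
                raise ValueError(f"pair {pid}: spectrum must have 96 entries")
        self.signatures = signatures
        self.artefact = artefact if artefact is not None else uniform_profile("artefact")

    def fit(self) -> "SignatureAttributionResults":
        rows = [
            corrected_similarity(x, self.signatures, self.artefact, pair_id=pid)
            for pid, x in self.spectra.items()
        ]
        return SignatureAttributionResults(self, rows)


class SignatureAttributionResults:
    """Fitted attribution: per-pair corrected scores and assignments."""

    def __init__(self, model: SignatureAttribution, rows: list[SimilarityRow]):
        self.model = model
        self.rows = rows
        self.scores = pd.DataFrame(
            {r.pair_id: r.scores for r in rows}
        ).T.rename_axis("pair_id")
        self.best_signature = pd.Series(
            {r.pair_id: r.best_signature for r in rows}, name="best_signature"
        )

    def summary(self) -> str:
        lines = ["Signature attribution (artefact-corrected per-mutation log-likelihood)"]
        lines.append(f"  pairs scored: {len(self.rows)}")
        lines.append(f"  candidate signatures: {len(self.model.signatures)}")
        counts = self.best_signature.value_counts()
        lines.append("  assignments:")
        for sig, k in counts.items():
            lines.append(f"    {sig}: {k}")
        return "\n".join(lines)
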