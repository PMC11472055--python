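"""Trinucleotide substitution motifs.

Single-base substitutions are collapsed onto the pyrimidine reference
strand (C or T), giving six substitution classes; adding the 5' and 3'
flanking reference bases yields the standard 96 motifs used in
mutational-signature analysis.

The canonical motif order is substitution-major (C>A, C>G, C>T, T>A,
T>C, T>G), then 5' base A,C,G,T, then 3' base A,C,G,T, i.e.

    index = 16 * substitution + 4 * five_prime + three_prime

This order is shared by spectra, signature catalogues and all outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
N_MOTIFS = 96


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (upper-case ACGT only)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as e:
        raise ValueError(f"non-ACGT base in {seq!r}") from e


def _make_motif_labels() -> list[str]:
    labels = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


MOTIFS: list[str] = _make_motif_labels()
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}


def motif_of(context: str, ref: str, alt: str) -> int:
    """Motif index of a substitution given its 3-base reference context.

    ``context`` is the reference trinucleotide centred on the mutated
    base, on either strand. Purine references (A/G) are mapped to the
    pyrimidine strand by reverse-complementing the context and
    complementing both alleles.

    Parameters
    ----------
    context : str
        Three reference bases; the middle base must equal ``ref``.
    ref, alt : str
        Reference and alternative alleles, single bases, distinct.

    Returns
    -------
    int
        Index into the canonical 96-motif order.
    """
    context = context.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(context) != 3:
        raise ValueError(f"context must be 3 bases, got {context!r}")
    if any(b not in COMPLEMENT for b in context + ref + alt):
        raise ValueError(f"non-ACGT base in context={context!r} {ref}>{alt}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # strand collapse onto the pyrimidine reference
        context = revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    sub = f"{ref}>{alt}"
    return (
        16 * SUBSTITUTIONS.index(sub)
        + 4 * BASES.index(context[0])
        + BASES.index(context[2])
    )


def motif_label(index: int) -> str:
    """Human-readable label, e.g. ``'A[C>T]G'``."""
    return MOTIFS[index]


def split_motif(label: str) -> tuple[str, str, str]:
    """Decompose ``'A[C>T]G'`` into (substitution, 5' base, 3' base)."""
    return label[2:5], label[0], label[6]


def motif_context_alleles(index: int) -> tuple[str, str, str]:
    """Pyrimidine-strand (context, ref, alt) for a motif index."""
    sub, five, three = split_motif(MOTIFS[index])
    ref, alt = sub.split(">")
    return five + ref + three, ref, alt


def build_spectrum(contexts, refs, alts) -> np.ndarray:
    """Aggregate mutations into a 96-component motif count vector."""
    x = np.zeros(N_MOTIFS, dtype=np.int64)
    for c, r, a in zip(contexts, refs, alts, strict=True):
        x[motif_of(c, r, a)] += 1
    return x


def spectrum_from_records(records: pd.DataFrame) -> np.ndarray:
    """Spectrum from a mutation table with context/ref/alt columns."""
    return build_spectrum(records["context"], records["ref"], records["alt"])


def substitution_marginals(spectrum: np.ndarray) -> pd.Series:
    """Collapse a 96-motif vector to the six substitution classes."""
    spectrum = np.asarray(spectrum)
    vals = spectrum.reshape(6, 16).sum(axis=1)
    return pd.Series(vals, index=list(SUBSTITUTIONS))
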