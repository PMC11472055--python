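"""Synthetic twin-pair cohort simulator with known truth.

Each monozygotic pair shares germline variants (identical genotypes in
both twins) onto which the simulator injects:

* postzygotic somatic mutations (PZMs): heterozygous in exactly one
  twin, trinucleotide motifs drawn i.i.d. from a chosen signature
  profile, true VAFs from a two-component Beta mixture centred at 0.5
  and 0.25 (mutations arising around the 2-cell and 4-cell stages);
* low-VAF sequencing artefacts: heterozygous calls in one twin with
  VAF below 0.25 (most mass below 0.10), motifs drawn from a
  configurable artefact profile; their per-pair rate is higher in a
  subset of pairs, producing the low-concordance stratum.

Per site and sample, depth is Poisson(depth_mean) and the alt read
count Binomial(depth, true VAF). The emitted genotype is a naive call
from the allele depths (alt fraction >= 0.9 -> Alt/Alt, otherwise
>= het_floor with at least one alt read -> Ref/Alt), standing in for a
production caller: only the output schema matters downstream. Allele
depths at simulated variant sites are redrawn until the naive call
matches the intended truth genotype, so that with zero noise the
discordant-site set equals the truth PZM set exactly for every seed.

All sites are biallelic SNVs on autosomes 1-22 at non-colliding
positions. A single integer seed drives one random stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import BASES, COMPLEMENT, motif_context_alleles, revcomp
from .qc import GT_AA, GT_RA, GT_RR, PAIR_COLUMNS
from .signatures import SignatureMatrix, SignatureProfile, load_packaged_signatures

CHROMS = [f"chr{i}" for i in range(1, 23)]
CHROM_LENGTH = 100_000_000  # uniform stand-in lengths; positions are arbitrary


def default_artefact_profile() -> SignatureProfile:
    """Artefact motif profile dominated by T>C (70% of mass).

    Low-concordance pairs empirically show an excess of low-VAF T>C
    calls, so the default noise generator concentrates there and
    spreads the remaining 30% uniformly over the other 80 motifs.
    """
    p = np.full(96, 0.3 / 80)
    p[64:80] = 0.7 / 16  # the T>C block of the canonical order
    return SignatureProfile("artefact_truth", p)


@dataclass(frozen=True)
class VAFMixture:
    """Two-component Beta mixture for true PZM allele fractions.

    Components are centred at 0.5 and 0.25; each is
    Beta(mean * concentration, (1 - mean) * concentration). The default
    equal weights with concentration 60 put roughly 44% of PZM VAFs in
    [0.4, 0.6], matching the observed share of early-division-like
    mutations in ~24x twin WGS.
    """

    weights: tuple[float, ...] = (0.5, 0.5)
    means: tuple[float, ...] = (0.5, 0.25)
    concentration: float = 60.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if len(self.weights) != len(self.means):
            raise ValueError("weights and means differ in length")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        means = np.asarray(self.means)[comp]
        k = self.concentration
        return rng.beta(means * k, (1 - means) * k, size=n)


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters (defaults: study-like scale)."""

    n_pairs: int = 30
    n_germline_sites: int = 20_000
    n_pzm: int = 86
    pzm_signature_id: str = "Signature 5"
    pzm_vaf_model: VAFMixture = field(default_factory=VAFMixture)
    noise_rate: float | list | None = None  # None -> tiered study-like default
    artefact_profile: SignatureProfile | None = None
    depth_mean: float = 24.0
    gq_per_read: float = 3.0
    het_floor: float = 0.05
    hom_threshold: float = 0.9
    context_weights: np.ndarray | None = None  # 32 pyrimidine-centred contexts
    ages: list[int] | None = None
    sexes: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1 or self.n_germline_sites < 1:
            raise ValueError("n_pairs and n_germline_sites must be positive")
        if self.n_pzm < 0:
            raise ValueError("n_pzm must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.ages is not None and len(self.ages) != self.n_pairs:
            raise ValueError("ages must have one entry per pair")
        if self.sexes is not None and len(self.sexes) != self.n_pairs:
            raise ValueError("sexes must have one entry per pair")
        if self.context_weights is not None:
            w = np.asarray(self.context_weights, dtype=float)
            if w.shape != (32,) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("context_weights must be 32 non-negative weights")

    def per_pair_noise_rates(self) -> np.ndarray:
        """Expected artefact sites per pair.

        Scalar rates broadcast; the default (None) assigns a low rate to
        ~23/30 of pairs and a high rate to the rest, emulating a cohort
        in which roughly a quarter of pairs are artefact-prone.
        """
        if self.noise_rate is None:
            n_low_conc = max(1, round(self.n_pairs * 7 / 30)) if self.n_pairs >= 5 else 0
            rates = np.full(self.n_pairs, 25.0)
            if n_low_conc:
                rates[self.n_pairs - n_low_conc:] = 1500.0
            return rates
        rates = np.asarray(self.noise_rate, dtype=float)
        if rates.ndim == 0:
            rates = np.full(self.n_pairs, float(rates))
        if rates.shape != (self.n_pairs,) or (rates < 0).any():
            raise ValueError("noise_rate must be a non-negative scalar or per-pair list")
        return rates


def study_default_config(seed: int = 0) -> SimulationConfig:
    """Study-like conditions: 30 pairs with the reference cohort's ages/sexes."""
    from .cohort import load_reference_cohort

    ref = load_reference_cohort()
    return SimulationConfig(
        ages=ref["age"].tolist(), sexes=ref["sex"].tolist(), seed=seed
    )


@dataclass
class TruthTable:
    """Injected-site ground truth (PZMs and artefact sites) per pair."""

    pzm: pd.DataFrame
    noise: pd.DataFrame


@dataclass
class SimulatedCohort:
    pairs: dict  # pair_id -> pair table (PAIR_COLUMNS)
    truth: TruthTable
    metadata: pd.DataFrame  # pair_id, age, sex
    config: SimulationConfig


def naive_call(dp, ad_alt, het_floor: float = 0.05, hom_threshold: float = 0.9):
    """Naive genotype call from allele depths (vectorized)."""
    dp = np.asarray(dp)
    ad_alt = np.asarray(ad_alt)
    frac = ad_alt / np.maximum(dp, 1)
    call = np.full(dp.shape, GT_RR, dtype=np.int8)
    hom = (dp > 0) & (frac >= hom_threshold) & (ad_alt >= 1)
    het = (dp > 0) & ~hom & (ad_alt >= 1) & (frac >= het_floor)
    call[het] = GT_RA
    call[hom] = GT_AA
    call[dp == 0] = -1
    return call


def _sample_positions(rng: np.random.Generator, n: int):
    """Unique (chrom index, position) pairs, rejection-resampling collisions."""
    chrom = np.empty(0, dtype=np.int64)
    pos = np.empty(0, dtype=np.int64)
    while len(chrom) < n:
        need = n - len(chrom)
        c = rng.integers(0, 22, size=need + 16)
        p = rng.integers(1, CHROM_LENGTH + 1, size=need + 16)
        chrom = np.concatenate([chrom, c])
        pos = np.concatenate([pos, p])
        _, idx = np.unique(chrom * (CHROM_LENGTH + 1) + pos, return_index=True)
        idx.sort()
        chrom, pos = chrom[idx], pos[idx]
    return chrom[:n], pos[:n]


def _sample_context_for_ref(rng, ref: str, weights: np.ndarray | None) -> str:
    """Reference trinucleotide with the given middle base.

    Contexts are drawn from a 32-entry table over pyrimidine-centred
    trinucleotides (16 C-centred then 16 T-centred, flanks 5'-major in
    A,C,G,T order; default uniform); purine references use the reverse
    complement of a draw for the complementary pyrimidine.
    """
    pyr = ref if ref in "CT" else COMPLEMENT[ref]
    block = 0 if pyr == "C" else 16
    if weights is None:
        w = np.ones(16)
    else:
        w = np.asarray(weights, dtype=float)[block:block + 16]
    w = w / w.sum()
    k = int(rng.choice(16, p=w))
    ctx = BASES[k // 4] + pyr + BASES[k % 4]
    return ctx if ref in "CT" else revcomp(ctx)


def _enforced_reads(rng, true_vaf, expected_call, cfg: SimulationConfig):
    """Draw DP/AD/GQ, redrawing until the naive call matches the truth."""
    n = len(true_vaf)
    dp = rng.poisson(cfg.depth_mean, n)
    alt = rng.binomial(dp, true_vaf)
    for _ in range(500):
        call = naive_call(dp, alt, cfg.het_floor, cfg.hom_threshold)
        bad = call != expected_call
        if not bad.any():
            break
        k = int(bad.sum())
        dp[bad] = rng.poisson(cfg.depth_mean, k)
        alt[bad] = rng.binomial(dp[bad], true_vaf[bad])
    else:
        raise RuntimeError("could not realize the intended genotype calls")
    gq = np.minimum(rng.poisson(cfg.gq_per_read * dp), 99).astype(np.int64)
    return dp.astype(np.int64), alt.astype(np.int64), gq


def _sample_noise_vafs(rng, n: int) -> np.ndarray:
    """Artefact VAFs: Beta(1.5, 15) truncated to [0.04, 0.25).

    Most mass sits below 0.10 (so the allele-support QC removes the
    bulk); the lower bound reflects that an allele fraction under ~4%
    would not be emitted as a het call at ~24x depth at all.
    """
    out = np.empty(0)
    while len(out) < n:
        draw = rng.beta(1.5, 15.0, size=2 * (n - len(out)) + 8)
        out = np.concatenate([out, draw[(draw >= 0.04) & (draw < 0.25)]])
    return out[:n]


def simulate_cohort(
    config: SimulationConfig, signatures: SignatureMatrix | None = None
) -> SimulatedCohort:
    """Generate a twin cohort with ground truth; deterministic given seed."""
    if signatures is None:
        signatures = load_packaged_signatures()
    if config.pzm_signature_id not in signatures:
        raise KeyError(f"unknown signature id {config.pzm_signature_id!r}")
    sig_p = signatures[config.pzm_signature_id].p
    artefact = config.artefact_profile or default_artefact_profile()
    rng = np.random.default_rng(config.seed)
    noise_rates = config.per_pair_noise_rates()

    ages = list(config.ages) if config.ages is not None else [
        int(a) for a in rng.integers(21, 83, size=config.n_pairs)
    ]
    sexes = list(config.sexes) if config.sexes is not None else [
        ("M", "F")[i % 2] for i in range(config.n_pairs)
    ]

    pair_tables = {}
    pzm_truth_rows = []
    noise_truth_rows = []
    for i in range(config.n_pairs):
        pair_id = i + 1
        n_noise = int(rng.poisson(noise_rates[i]))
        n_total = config.n_germline_sites + config.n_pzm + n_noise
        chrom_idx, pos = _sample_positions(rng, n_total)

        kind = np.array(
            ["germline"] * config.n_germline_sites
            + ["pzm"] * config.n_pzm
            + ["noise"] * n_noise
        )
        ref = np.empty(n_total, dtype="<U1")
        alt = np.empty(n_total, dtype="<U1")
        context = np.empty(n_total, dtype="<U3")
        true_vaf1 = np.zeros(n_total)
        true_vaf2 = np.zeros(n_total)
        exp1 = np.full(n_total, GT_RR, dtype=np.int8)
        exp2 = np.full(n_total, GT_RR, dtype=np.int8)
        carrier = np.zeros(n_total, dtype=np.int8)
        motif_idx = np.full(n_total, -1, dtype=np.int64)
        site_vaf = np.zeros(n_total)

        # shared germline variants: identical genotype in both twins
        g = config.n_germline_sites
        g_ref = rng.integers(0, 4, size=g)
        g_shift = rng.integers(1, 4, size=g)
        base_arr = np.array(list(BASES))
        ref[:g] = base_arr[g_ref]
        alt[:g] = base_arr[(g_ref + g_shift) % 4]
        for b_idx, r in enumerate(BASES):
            sel = np.where(g_ref == b_idx)[0]
            if sel.size == 0:
                continue
            pyr = r if r in "CT" else COMPLEMENT[r]
            block = 0 if pyr == "C" else 16
            if config.context_weights is None:
                w = np.ones(16)
            else:
                w = np.asarray(config.context_weights, dtype=float)[block:block + 16]
            w = w / w.sum()
            ks = rng.choice(16, size=sel.size, p=w)
            ctx_table = [BASES[k // 4] + pyr + BASES[k % 4] for k in range(16)]
            if r not in "CT":
                ctx_table = [revcomp(c) for c in ctx_table]
            context[sel] = np.array(ctx_table)[ks]
        g_gt = np.where(rng.random(g) < 2 / 3, GT_RA, GT_AA).astype(np.int8)
        exp1[:g] = exp2[:g] = g_gt
        gv = np.where(g_gt == GT_RA, 0.5, 1.0)
        true_vaf1[:g] = true_vaf2[:g] = gv

        # injected sites: PZMs then artefacts, each carried by one twin
        inj = [
            ("pzm", g, config.n_pzm, sig_p,
             config.pzm_vaf_model.sample(rng, config.n_pzm)),
            ("noise", g + config.n_pzm, n_noise, artefact.p,
             _sample_noise_vafs(rng, n_noise)),
        ]
        for _kind, off, count, profile, vafs in inj:
            if count == 0:
                continue
            motifs = rng.choice(96, size=count, p=profile)
            flip = rng.random(count) < 0.5  # report on the purine strand half the time
            carriers = rng.integers(1, 3, size=count).astype(np.int8)
            for j in range(count):
                ctx, r, a = motif_context_alleles(int(motifs[j]))
                if flip[j]:
                    ctx, r, a = revcomp(ctx), COMPLEMENT[r], COMPLEMENT[a]
                k = off + j
                ref[k], alt[k], context[k] = r, a, ctx
                motif_idx[k] = motifs[j]
                carrier[k] = carriers[j]
                site_vaf[k] = vafs[j]
                if carriers[j] == 1:
                    true_vaf1[k], exp1[k] = vafs[j], GT_RA
                else:
                    true_vaf2[k], exp2[k] = vafs[j], GT_RA

        dp1, ad_alt1, gq1 = _enforced_reads(rng, true_vaf1, exp1, config)
        dp2, ad_alt2, gq2 = _enforced_reads(rng, true_vaf2, exp2, config)

        table = pd.DataFrame(
            {
                "chrom": np.array(CHROMS)[chrom_idx],
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "context": context,
                "gt1": exp1,
                "dp1": dp1,
                "gq1": gq1,
                "ad_ref1": dp1 - ad_alt1,
                "ad_alt1": ad_alt1,
                "gt2": exp2,
                "dp2": dp2,
                "gq2": gq2,
                "ad_ref2": dp2 - ad_alt2,
                "ad_alt2": ad_alt2,
            }
        )
        order = np.lexsort((pos, chrom_idx))
        table = table.iloc[order].reset_index(drop=True)[PAIR_COLUMNS]
        pair_tables[pair_id] = table

        for name, rows in (("pzm", pzm_truth_rows), ("noise", noise_truth_rows)):
            sel = kind == name
            rows.append(
                pd.DataFrame(
                    {
                        "pair_id": pair_id,
                        "chrom": np.array(CHROMS)[chrom_idx[sel]],
                        "pos": pos[sel],
                        "ref": ref[sel],
                        "alt": alt[sel],
                        "context": context[sel],
                        "carrier": carrier[sel],
                        "vaf": site_vaf[sel],
                        "motif": motif_idx[sel],
                    }
                )
            )

    truth = TruthTable(
        pzm=pd.concat(pzm_truth_rows, ignore_index=True),
        noise=pd.concat(noise_truth_rows, ignore_index=True),
    )
    metadata = pd.DataFrame(
        {"pair_id": range(1, config.n_pairs + 1), "age": ages, "sex": sexes}
    )
    return SimulatedCohort(pairs=pair_tables, truth=truth, metadata=metadata, config=config)


def write_cohort(cohort: SimulatedCohort, out_dir) -> None:
    """Serialize a cohort: per-pair VCFs, truth TSVs, metadata TSV."""
    from pathlib import Path

    from .vcfio import write_pair_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair_id, table in cohort.pairs.items():
        write_pair_vcf(table, out / f"pair_{pair_id:02d}.vcf")
    cohort.truth.pzm.to_csv(out / "truth_pzm.tsv", sep="\t", index=False)
    cohort.truth.noise.to_csv(out / "truth_noise.tsv", sep="\t", index=False)
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
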