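"""Signature catalogue IO, multinomial likelihood and attribution."""

import math

import numpy as np
import pandas as pd
import pytest

from twinpzm.motifs import MOTIFS
from twinpzm.signatures import (
    SignatureAttribution,
    SignatureProfile,
    build_artefact_profile,
    complement_zeros,
    complement_zeros_values,
    corrected_similarity,
    multinomial_loglik,
    read_cosmic_v2,
    uniform_profile,
)


def brute_force_logpmf(x, p):
    """Direct factorial multinomial pmf, valid for small n."""
    n = int(sum(x))
    pmf = math.factorial(n)
    for xk, pk in zip(x, p):
        pmf = pmf / math.factorial(int(xk)) * pk**xk
    return math.log(pmf)


class TestMultinomialLoglik:
    def test_closed_forms(self):
        assert multinomial_loglik([1, 1], [0.5, 0.5]) == pytest.approx(-math.log(2))
        assert multinomial_loglik([2, 0], [0.5, 0.5]) == pytest.approx(-2 * math.log(2))

    def test_matches_brute_force_factorials(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(1, 21))
            p = rng.dirichlet(np.ones(k) * rng.uniform(0.5, 3))
            x = rng.multinomial(n, p)
            assert multinomial_loglik(x, p) == pytest.approx(
                brute_force_logpmf(x, p), abs=1e-10
            )

    def test_mle_is_empirical_frequency(self, rng):
        """logL is maximized over profiles at p = x / n."""
        for _ in range(50):
            x = rng.multinomial(30, rng.dirichlet(np.ones(8)))
            best = multinomial_loglik(x, x / x.sum())
            for _ in range(40):
                q = rng.dirichlet(np.ones(8) * rng.uniform(0.3, 5))
                assert multinomial_loglik(x, q) <= best + 1e-9

    def test_rejects_zero_mass_on_observed_motif(self):
        with pytest.raises(ValueError):
            multinomial_loglik([1, 1], [1.0, 0.0])
        with pytest.raises(ValueError):
            multinomial_loglik([0, 0], [0.5, 0.5])


class TestComplementZeros:
    def test_small_example(self):
        out = complement_zeros_values([0.5, 0.5, 0.0])
        assert out == pytest.approx([0.4, 0.4, 0.2])

    def test_no_zero_profile_unchanged(self):
        prof = uniform_profile()
        assert complement_zeros(prof) is prof

    def test_output_strictly_positive_sums_one(self, rng):
        p = rng.dirichlet(np.ones(96) * 0.2)
        p[rng.integers(0, 96, size=10)] = 0.0
        out = complement_zeros(SignatureProfile("s", p))
        assert (out.p > 0).all()
        assert out.p.sum() == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            complement_zeros_values(np.zeros(4))


class TestArtefactProfile:
    def test_single_pair_is_normalized_counts(self):
        x = np.zeros(96)
        x[0], x[1] = 2, 2
        prof = build_artefact_profile([x])
        assert prof.p[0] == pytest.approx(0.5)
        assert prof.p.sum() == pytest.approx(1.0)

    def test_pooling_identical_pairs_invariant(self, rng):
        x = rng.multinomial(100, np.full(96, 1 / 96))
        one = build_artefact_profile([x])
        two = build_artefact_profile([x, x])
        np.testing.assert_allclose(one.p, two.p)

    def test_equals_sum_then_normalize_oracle(self, rng):
        spectra = [rng.multinomial(50, rng.dirichlet(np.ones(96))) for _ in range(4)]
        pooled = np.sum(spectra, axis=0)
        np.testing.assert_allclose(
            build_artefact_profile(spectra).p, pooled / pooled.sum()
        )

    def test_empty_low_set_instructs_skip(self):
        with pytest.raises(ValueError, match="skip"):
            build_artefact_profile([])


class TestCorrectedSimilarity:
    def test_zero_when_artefact_equals_signature(self, signatures, rng):
        x = rng.multinomial(200, signatures["Signature 5"].p)
        art = SignatureProfile("artefact", signatures["Signature 5"].p)
        row = corrected_similarity(x, signatures, art)
        assert row.scores["Signature 5"] == pytest.approx(0.0, abs=1e-12)

    def test_per_mutation_score_is_cross_entropy_gap(self, signatures):
        """The factorial terms cancel in the artefact subtraction, so the
        per-mutation score equals sum f_k log(p_s / p_a) exactly and is
        invariant to doubling every count."""
        rng = np.random.default_rng(3)
        x = rng.multinomial(400, signatures["Signature 5"].p).astype(float)
        art = uniform_profile("artefact")
        ps = complement_zeros(signatures["Signature 1"]).p
        f = x / x.sum()
        gap = float((f[x > 0] * np.log(ps[x > 0] / art.p[x > 0])).sum())
        s1 = corrected_similarity(x, signatures, art).scores["Signature 1"]
        s2 = corrected_similarity(2 * x, signatures, art).scores["Signature 1"]
        assert s1 == pytest.approx(gap, abs=1e-9)
        assert s2 == pytest.approx(s1, abs=1e-9)

    def test_ties_break_to_lowest_signature_index(self, rng):
        p = rng.dirichlet(np.ones(96))
        from twinpzm.signatures import SignatureMatrix

        sigs = SignatureMatrix(
            [SignatureProfile("Signature 1", p), SignatureProfile("Signature 2", p)]
        )
        x = rng.multinomial(50, p)
        row = corrected_similarity(x, sigs, uniform_profile())
        assert row.best_signature == "Signature 1"

    def test_empty_spectrum_errors(self, signatures):
        with pytest.raises(ValueError):
            corrected_similarity(np.zeros(96), signatures, uniform_profile())


class TestCatalogueReader:
    def test_packaged_catalogue_loads(self, signatures):
        assert len(signatures) == 30
        for prof in signatures.profiles:
            assert prof.p.sum() == pytest.approx(1.0)
            assert prof.p.shape == (96,)

    def test_row_order_independence(self, signatures, tmp_path, rng):
        frame = signatures.to_frame().reset_index(names="Somatic Mutation Type")
        frame["Substitution Type"] = frame["Somatic Mutation Type"].str[2:5]
        frame["Trinucleotide"] = (
            frame["Somatic Mutation Type"].str[0]
            + frame["Somatic Mutation Type"].str[2]
            + frame["Somatic Mutation Type"].str[6]
        )
        shuffled = frame.sample(frac=1.0, random_state=17)
        path = tmp_path / "shuffled.tsv"
        shuffled.to_csv(path, sep="\t", index=False)
        again = read_cosmic_v2(path)
        pd.testing.assert_frame_equal(again.to_frame(), signatures.to_frame())

    def test_missing_motif_row_names_it(self, signatures, tmp_path):
        frame = signatures.to_frame().reset_index(names="Somatic Mutation Type")
        frame["Substitution Type"] = frame["Somatic Mutation Type"].str[2:5]
        frame["Trinucleotide"] = "AAA"
        frame = frame[frame["Somatic Mutation Type"] != "A[C>T]G"]
        path = tmp_path / "missing.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match=r"A\[C>T\]G"):
            read_cosmic_v2(path)

    def test_duplicate_motif_row_rejected(self, signatures, tmp_path):
        frame = signatures.to_frame().reset_index(names="Somatic Mutation Type")
        frame["Substitution Type"] = frame["Somatic Mutation Type"].str[2:5]
        frame["Trinucleotide"] = "AAA"
        dup = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        path = tmp_path / "dup.tsv"
        dup.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_cosmic_v2(path)


class TestAttributionModel:
    def test_fit_assigns_generating_signature(self, signatures, rng):
        spectra = {
            i: rng.multinomial(500, signatures["Signature 5"].p) for i in range(3)
        }
        res = SignatureAttribution(spectra, signatures).fit()
        assert list(res.best_signature) == ["Signature 5"] * 3
        assert res.scores.shape == (3, 30)
        assert "Signature 5" in res.summary()

    def test_best_attains_row_maximum(self, signatures, rng):
        spectra = {0: rng.multinomial(300, signatures["Signature 2"].p)}
        res = SignatureAttribution(spectra, signatures).fit()
        row = res.scores.loc[0]
        assert row[res.best_signature[0]] == row.max()
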