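"""PZM extraction, annotation and cohort statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from twinpzm.cohort import load_reference_cohort
from twinpzm.discovery import (
    classify_functional_region,
    compare_exonic_burden,
    extract_discordant,
    filter_known_germline,
    regress_counts_on_covariates,
    regress_vaf,
    summarize_pzm_counts,
)
from twinpzm.qc import GT_AA, GT_RA, GT_RR


def _pair(rows):
    cols = [
        "chrom", "pos", "ref", "alt", "context",
        "gt1", "dp1", "gq1", "ad_ref1", "ad_alt1",
        "gt2", "dp2", "gq2", "ad_ref2", "ad_alt2",
    ]
    return pd.DataFrame(rows, columns=cols)


class TestExtractDiscordant:
    def test_carrier_is_twin_with_more_alt_alleles(self):
        pair = _pair(
            [
                ("chr1", 10, "C", "T", "ACG", GT_RR, 24, 70, 24, 0, GT_RA, 22, 70, 11, 11),
                ("chr2", 20, "C", "A", "CCG", GT_RA, 24, 70, 12, 12, GT_RA, 25, 70, 13, 12),
            ]
        )
        rec = extract_discordant(pair, pair_id=7)
        assert len(rec) == 1
        r = rec.iloc[0]
        assert r["carrier"] == 2 and r["vaf"] == pytest.approx(0.5)
        assert r["genotype_pair"] == "rr_ra" and r["pair_id"] == 7

    def test_noise_free_simulation_recovers_truth_exactly(self, noisefree_cohort):
        truth = noisefree_cohort.truth.pzm
        for pair_id, table in noisefree_cohort.pairs.items():
            rec = extract_discordant(table, pair_id)
            got = set(map(tuple, rec[["chrom", "pos", "ref", "alt", "carrier"]].itertuples(index=False)))
            t = truth[truth["pair_id"] == pair_id]
            want = set(map(tuple, t[["chrom", "pos", "ref", "alt", "carrier"]].itertuples(index=False)))
            assert got == want


class TestGermlineFilter:
    def test_empty_db_is_identity(self):
        rec = extract_discordant(
            _pair([("chr1", 10, "C", "T", "ACG", GT_RR, 24, 70, 24, 0, GT_RA, 22, 70, 11, 11)]),
            pair_id=1,
        )
        out, n = filter_known_germline(rec, set())
        assert n == 0 and len(out) == 1

    def test_exact_key_match_removed_allele_mismatch_kept(self):
        rec = extract_discordant(
            _pair(
                [
                    ("chr1", 10, "C", "T", "ACG", GT_RR, 24, 70, 24, 0, GT_RA, 22, 70, 11, 11),
                    ("chr1", 20, "C", "A", "ACG", GT_RR, 24, 70, 24, 0, GT_RA, 22, 70, 11, 11),
                ]
            ),
            pair_id=1,
        )
        db = {("chr1", 10, "C", "T"), ("chr1", 20, "C", "T")}  # second is C>T, record is C>A
        out, n = filter_known_germline(rec, db)
        assert n == 1 and list(out["pos"]) == [20]


class TestFunctionalRegion:
    def test_inside_exon_is_exonic(self):
        rec = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "region_label": ["non-exonic"]})
        out = classify_functional_region(rec, [("chr1", 50, 150)])
        assert out["region_label"].iloc[0] == "exonic"

    def test_empty_exon_set_all_non_exonic(self):
        rec = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "region_label": ["x"]})
        out = classify_functional_region(rec, [])
        assert (out["region_label"] == "non-exonic").all()

    def test_matches_brute_force_overlap(self, rng):
        exons = [
            ("chr1", int(s), int(s) + int(rng.integers(1, 30)))
            for s in rng.integers(0, 500, size=20)
        ]
        rec = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(1, 551, size=100), "region_label": "?"}
        )
        out = classify_functional_region(rec, exons)
        for p, label in zip(out["pos"], out["region_label"]):
            hit = any(s <= p - 1 < e for _, s, e in exons)
            assert label == ("exonic" if hit else "non-exonic")


class TestSummaries:
    def test_reference_cohort_reproduces_printed_statistics(self):
        ref = load_reference_cohort()
        all30 = summarize_pzm_counts(ref["n_discordant"])
        assert round(all30["mean"]) == 227
        high = ref[ref["concordance_rate_pct"] >= 99]
        s = summarize_pzm_counts(high["n_discordant"])
        assert round(s["mean"], 1) == 86.3
        assert round(s["sd"], 1) == 34.1
        assert (s["min"], s["max"]) == (49, 164)

    def test_constant_counts_have_zero_sd(self):
        s = summarize_pzm_counts([5, 5, 5])
        assert s["sd"] == 0.0 and s["mean"] == 5

    def test_permutation_invariance(self, rng):
        counts = rng.integers(0, 300, size=12)
        a = summarize_pzm_counts(counts)
        b = summarize_pzm_counts(rng.permutation(counts))
        assert a == b

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            summarize_pzm_counts([])


class TestRegression:
    def test_perfect_linear_fit_recovers_slope(self):
        ages = np.arange(20, 50)
        sexes = ["M", "F"] * 15
        counts = 10 + 2.5 * ages + 4.0 * (np.arange(30) % 2)
        tab = regress_counts_on_covariates(counts, ages, sexes)
        assert tab.loc["age", "beta"] == pytest.approx(2.5)
        assert tab.loc["sex", "beta"] == pytest.approx(4.0)
        assert tab.loc["age", "se"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        n = 60
        age = rng.uniform(20, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), age, sex])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        tab = regress_counts_on_covariates(y, age, sex)
        np.testing.assert_allclose(tab["beta"].to_numpy(), beta_hat, rtol=1e-10)
        resid = y - X @ beta_hat
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(tab["se"].to_numpy(), se, rtol=1e-8)

    def test_duplicated_covariate_raises_singularity(self, rng):
        n = 20
        age = rng.uniform(20, 80, n)
        with pytest.raises(np.linalg.LinAlgError):
            regress_vaf(rng.random(n), age, age, rng.integers(0, 2, n))

    def test_standardized_covariates_same_t_statistics(self, rng):
        n = 80
        age = rng.uniform(20, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        conc = rng.uniform(0.96, 1.0, n)
        y = rng.normal(size=n)
        raw = regress_vaf(y, conc, age, sex)
        z = lambda v: (v - v.mean()) / v.std()
        std = regress_vaf(y, z(conc), z(age), z(sex))
        np.testing.assert_allclose(
            raw.loc[["concordance", "age", "sex"], "t"],
            std.loc[["concordance", "age", "sex"], "t"],
            rtol=1e-8,
        )


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        _, p = compare_exonic_burden([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_separated_samples_match_full_enumeration(self):
        x, y = [1, 2, 3], [10, 11, 12]
        u, p = compare_exonic_burden(x, y)
        assert u == 0.0
        # exact null: enumerate all rank assignments of 3 + 3 values
        pooled = x + y
        n1 = len(x)
        us = []
        for combo in itertools.combinations(range(6), n1):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(1 for a in xs for b in ys if a > b))
        us = np.array(us)
        expected = np.mean(np.minimum(us, n1 * n1 - us) <= 0) # two-sided at U=0
        assert p == pytest.approx(expected)

    def test_power_increases_with_shift(self, rng):
        rejections = []
        for shift in (0.0, 1.0, 3.0):
            rej = 0
            for _ in range(200):
                a = rng.normal(0, 1, 12)
                b = rng.normal(shift, 1, 12)
                _, p = compare_exonic_burden(a, b)
                rej += p < 0.05
            rejections.append(rej)
        assert rejections[0] < rejections[1] < rejections[2]

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            compare_exonic_burden([], [1, 2])
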