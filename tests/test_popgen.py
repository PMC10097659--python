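"""Population differentiation, diversity, PCA, expansion, saturation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strpop.core import ValidationError
from strpop.popgen import (
    diversity_stats,
    expansion_scores,
    highly_variable,
    length_compare,
    pca_dosage,
    population_sharing,
    rst,
    sample_summaries,
    saturation_curve,
    sd_diff_perm,
)
from strpop.synthetic import PopulationModel, simulate_callset, simulate_frequencies

from conftest import build_callset


def meta_for(cs, pops):
    return pd.DataFrame(
        {
            "sample": cs.samples,
            "population": pops,
            "superpopulation": pops,
            "sex": "XX",
            "dataset": "synthetic",
        }
    )


class TestSampleSummaries:
    def test_reference_homozygote_counts_zero(self):
        cs = build_callset([[(10, 10)], [(9, 9)]], refs=[10, 9])
        t = sample_summaries(cs).set_index("sample")
        assert t.loc["S0", "n_nonref"] == 0

    def test_het_hom_ratio(self):
        cs = build_callset(
            [[(10, 12)], [(9, 11)], [(12, 12)]], refs=[10, 9, 10]
        )
        t = sample_summaries(cs).set_index("sample")
        assert t.loc["S0", "n_het_nonref"] == 2
        assert t.loc["S0", "n_hom_nonref"] == 1
        assert t.loc["S0", "het_hom_ratio"] == pytest.approx(2.0)

    def test_motif_split_sums_to_total(self):
        model = PopulationModel(populations={"A": 10}, n_loci=40, sigma=0.4, seed=2)
        freqs, _ = simulate_frequencies(model)
        cs, _, _ = simulate_callset(freqs, model)
        t = sample_summaries(cs)
        split = sum(t[f"n_nonref_motif{ml}"] for ml in range(2, 7))
        assert (split == t["n_nonref"]).all()


class TestDiversity:
    def test_identical_samples_zero(self):
        cs = build_callset([[(10, 12), (10, 12)], [(9, 9), (9, 9)]])
        meta = meta_for(cs, ["P", "P"])
        _, div = diversity_stats(cs, pd.Series(0, index=cs.samples), meta, 1e9)
        assert div["P"] == 0.0

    def test_mean_over_pairs(self):
        # pairwise differing locus counts {2, 4, 6} -> mean 4
        genos = [
            [(10, 10), (11, 11), (12, 12)],
            [(10, 10), (11, 11), (12, 12)],
            [(10, 10), (11, 11), (12, 12)],
            [(10, 10), (11, 11), (12, 12)],
            [(10, 10), (10, 10), (12, 12)],
            [(10, 10), (10, 10), (12, 12)],
        ]
        cs = build_callset(genos, refs=[10] * 6)
        meta = meta_for(cs, ["P"] * 3)
        _, div = diversity_stats(cs, pd.Series(0, index=cs.samples), meta, 1e9)
        # S0 vs S1 differ at loci 0-3 and 4,5 -> recount directly
        a = cs.alleles
        expect = []
        for u in range(3):
            for v in range(u + 1, 3):
                expect.append(int(np.sum((a[:, u] != a[:, v]).any(axis=1))))
        assert div["P"] == pytest.approx(np.mean(expect))

    def test_snp_het_scaling(self):
        cs = build_callset([[(10, 10), (10, 10)]])
        meta = meta_for(cs, ["P", "P"])
        het, _ = diversity_stats(
            cs, pd.Series([2_880_000, 1_440_000], index=cs.samples), meta, 2.88e9
        )
        assert het.set_index("sample").loc["S0", "snp_het"] == pytest.approx(1e-3)

    def test_single_sample_population_undefined(self):
        cs = build_callset([[(10, 10), (10, 12)]])
        meta = meta_for(cs, ["P", "Q"])
        _, div = diversity_stats(cs, pd.Series(0, index=cs.samples), meta, 1e9)
        assert np.isnan(div["P"]) and np.isnan(div["Q"])


class TestPCA:
    def test_major_af_filter(self):
        # locus 0: major AF 0.96 -> excluded; loci 1,2 kept
        genos = [
            [(10, 10)] * 24 + [(10, 12)],
            [(10, 12)] * 13 + [(10, 10)] * 12,
            [(11, 11)] * 12 + [(11, 13)] * 13,
        ]
        cs = build_callset(genos)
        with pytest.raises(ValidationError):
            pca_dosage(cs.subset(loci=[0, 0]) if False else cs.subset(loci=[0]), max_major_af=0.95)
        scores, evr = pca_dosage(cs, max_major_af=0.95)
        assert scores.shape[0] == 25

    def test_duplicate_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        genos = [
            [tuple(sorted(rng.choice([9, 10, 11, 12], 2))) for _ in range(10)]
            for _ in range(8)
        ]
        for row in genos:
            row.append(row[0])  # duplicate of sample 0
        cs = build_callset(genos)
        scores, _ = pca_dosage(cs)
        assert np.allclose(scores.iloc[0].to_numpy(), scores.iloc[-1].to_numpy(), atol=1e-9)

    def test_separates_divergent_populations(self):
        from sklearn.metrics import silhouette_score

        model = PopulationModel(
            populations={"A": 40, "B": 40}, n_loci=150, sigma=0.3,
            divergence={"A": 0.0, "B": 0.45}, seed=9,
        )
        freqs, _ = simulate_frequencies(model)
        cs, meta, _ = simulate_callset(freqs, model)
        scores, _ = pca_dosage(cs)
        labels = meta.set_index("sample").loc[scores.index, "population"]
        sil = silhouette_score(scores[["PC1"]].to_numpy(), labels)
        assert sil > 0.5

    def test_locus_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(3)
        genos = [
            [tuple(sorted(rng.choice([9, 10, 11, 12], 2))) for _ in range(15)]
            for _ in range(10)
        ]
        cs = build_callset(genos)
        s1, _ = pca_dosage(cs)
        order = list(reversed(range(cs.n_loci)))
        # reversing locus order requires re-sorting by coordinate; rebuild
        genos_rev = [genos[i] for i in order]
        cs2 = build_callset(genos_rev)
        s2, _ = pca_dosage(cs2)
        for c in s1.columns:
            assert np.allclose(s1[c].abs(), s2[c].abs(), atol=1e-8)


class TestSharing:
    def test_unique_and_all(self):
        genos = [
            [(10, 12), (10, 10), (10, 10), (10, 10)],   # poly only in A
            [(10, 12), (10, 10), (10, 12), (10, 10)],   # poly in A and B
        ]
        cs = build_callset(genos)
        meta = meta_for(cs, ["A", "A", "B", "B"])
        t = population_sharing(cs, meta).set_index("population")
        assert t.loc["A", "unique"] == 1
        assert t.loc["A", "all"] == 1
        assert t.loc["B", "all"] == 1
        assert t.loc["B", "unique"] == 0

    def test_three_population_bruteforce(self):
        rng = np.random.default_rng(4)
        genos = [
            [tuple(sorted(rng.choice([10, 11], 2, p=[0.8, 0.2]))) for _ in range(18)]
            for _ in range(25)
        ]
        cs = build_callset(genos)
        pops = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        meta = meta_for(cs, pops)
        t = population_sharing(cs, meta).set_index("population")
        # brute force
        poly = {}
        for p in "ABC":
            idx = [j for j, q in enumerate(pops) if q == p]
            poly[p] = [
                len({a for j in idx for a in cs.alleles[i, j] if a >= 0}) > 1
                for i in range(cs.n_loci)
            ]
        for p in "ABC":
            n_poly = [sum(poly[q][i] for q in "ABC") for i in range(cs.n_loci)]
            uniq = sum(1 for i in range(cs.n_loci) if poly[p][i] and n_poly[i] == 1)
            alle = sum(1 for i in range(cs.n_loci) if poly[p][i] and n_poly[i] == 3)
            assert t.loc[p, "unique"] == uniq
            assert t.loc[p, "all"] == alle


class TestLengthCompare:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(5)
        genos = [
            [tuple(sorted(rng.choice([9, 10, 11, 12], 2))) for _ in range(40)]
            for _ in range(15)
        ]
        cs = build_callset(genos)
        groups = {"A": cs.samples[:20], "B": cs.samples[20:]}
        # identical groups: copy group A genotypes into group B
        for i in range(cs.n_loci):
            cs.alleles[i, 20:] = cs.alleles[i, :20]
        t = length_compare(cs, groups)
        assert not t["significant"].any()

    def test_planted_shift_detected_with_sign(self):
        rng = np.random.default_rng(6)
        genos = [
            [tuple(sorted(rng.choice([9, 10, 11, 12], 2))) for _ in range(400)]
            for _ in range(10)
        ]
        cs = build_callset(genos)
        cs.alleles[0, 200:] += 4  # +4 repeats in group B at locus 0
        groups = {"A": cs.samples[:200], "B": cs.samples[200:]}
        t = length_compare(cs, groups).set_index("locus_index")
        assert t.loc[0, "significant"]
        assert t.loc[0, "mean_diff"] == pytest.approx(8.0, abs=0.8)

    def test_low_het_loci_absent(self):
        genos = [[(10, 10)] * 39 + [(10, 11)], [(9, 11)] * 20 + [(9, 9)] * 20]
        cs = build_callset(genos)
        groups = {"A": cs.samples[:20], "B": cs.samples[20:]}
        t = length_compare(cs, groups, min_het=0.1)
        assert 0 not in t["locus_index"].tolist()


class TestRst:
    def test_identical_distributions_exactly_zero(self):
        # both groups carry the same genotype multiset, so pooled and
        # within-group variances coincide
        block = [(10, 10), (10, 12), (12, 12), (10, 12)]
        cs = build_callset([block + block])
        groups = {"A": cs.samples[:4], "B": cs.samples[4:]}
        t, _ = rst(cs, groups, min_het=None)
        assert t.loc[0, "rst"] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_is_one(self):
        genos = [[(10, 10)] * 6 + [(12, 12)] * 6]
        cs = build_callset(genos)
        groups = {"A": cs.samples[:6], "B": cs.samples[6:]}
        t, _ = rst(cs, groups, min_het=None)
        assert t.loc[0, "Sw"] == 0.0
        assert t.loc[0, "rst"] == pytest.approx(1.0)

    def test_bruteforce_oracle_combined(self):
        genos = [[(10, 10), (12, 12), (10, 12), (12, 12)]]
        cs = build_callset(genos)
        groups = {"A": cs.samples[:2], "B": cs.samples[2:]}
        t, _ = rst(cs, groups, min_het=None, observations="combined")
        a_obs = [20.0, 24.0]
        b_obs = [22.0, 24.0]
        st_ = np.var(a_obs + b_obs)
        sw_ = np.mean([np.var(a_obs), np.var(b_obs)])
        assert t.loc[0, "rst"] == pytest.approx((st_ - sw_) / st_, rel=1e-12)

    def test_bruteforce_oracle_pooled_alleles(self):
        genos = [[(10, 10), (12, 12), (10, 12), (12, 12)]]
        cs = build_callset(genos)
        groups = {"A": cs.samples[:2], "B": cs.samples[2:]}
        t, _ = rst(cs, groups, min_het=None, observations="pooled_alleles")
        a_obs = [10, 10, 12, 12]
        b_obs = [10, 12, 12, 12]
        st_ = np.var(a_obs + b_obs)
        sw_ = np.mean([np.var(a_obs), np.var(b_obs)])
        assert t.loc[0, "rst"] == pytest.approx((st_ - sw_) / st_, rel=1e-12)

    def test_per_motif_mean_unweighted(self):
        genos = [
            [(10, 10)] * 3 + [(12, 12)] * 3,
            [(10, 12)] * 3 + [(10, 12)] * 3,
        ]
        cs = build_callset(genos, motifs=["AC", "AC"])
        groups = {"A": cs.samples[:3], "B": cs.samples[3:]}
        t, by_motif = rst(cs, groups, min_het=None)
        assert by_motif[2] == pytest.approx(t["rst"].mean())


class TestHighlyVariable:
    def test_top_fraction_count(self):
        rng = np.random.default_rng(8)
        genos = []
        for i in range(100):
            spread = 1 + i // 10
            genos.append(
                [tuple(sorted(rng.integers(10, 10 + spread + 1, 2))) for _ in range(30)]
            )
        cs = build_callset(genos)
        chosen, table = highly_variable(cs, cs.samples, min_het=0.0, top_frac=0.05)
        assert len(chosen) >= 5
        cutoff = table["variance"].sort_values(ascending=False).iloc[4]
        assert set(chosen) == set(
            table.loc[table["variance"] >= cutoff, "locus_index"]
        )

    def test_monomorphic_never_selected(self):
        genos = [[(10, 10)] * 30] + [
            [tuple(sorted(np.random.default_rng(i).integers(9, 14, 2))) for _ in range(30)]
            for i in range(25)
        ]
        cs = build_callset(genos)
        chosen, _ = highly_variable(cs, cs.samples, min_het=0.0, top_frac=0.05)
        assert 0 not in chosen


class TestSdDiffPerm:
    def test_planted_variance_difference_significant(self):
        rng = np.random.default_rng(9)
        genos = []
        for i in range(5):
            row = []
            for j in range(200):
                if i == 0 and j >= 100:
                    row.append(tuple(sorted(rng.integers(6, 19, 2))))  # wide
                else:
                    row.append(tuple(sorted(rng.integers(10, 13, 2))))  # narrow
            genos.append(row)
        cs = build_callset(genos)
        t = sd_diff_perm(
            cs, cs.samples[:100], cs.samples[100:], min_het=0.0, n_perm=500, seed=0
        ).set_index("locus_index")
        assert t.loc[0, "significant"]
        assert t.loc[0, "sd_diff"] < 0  # group B is wider

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(10)
        genos = [[tuple(sorted(rng.integers(9, 14, 2))) for _ in range(40)]]
        cs = build_callset(genos)
        t1 = sd_diff_perm(cs, cs.samples[:20], cs.samples[20:], min_het=0.0,
                          n_perm=200, seed=5)
        t2 = sd_diff_perm(cs, cs.samples[:20], cs.samples[20:], min_het=0.0,
                          n_perm=200, seed=5)
        assert t1.equals(t2)


class TestExpansion:
    def test_constant_alleles_score_zero(self):
        cs = build_callset([[(10, 10)] * 10])
        t = expansion_scores(cs)
        assert t.loc[0, "score"] == 0.0 and not t.loc[0, "expanded"]

    def test_percentile_oracle_boundary(self):
        # construct pooled alleles with median 10 and P95 exactly 30
        alleles = [10] * 19 + [30]
        genos = [[(alleles[2 * k], alleles[2 * k + 1]) for k in range(10)]]
        pooled = np.array(alleles, dtype=float)
        cs = build_callset(genos)
        t = expansion_scores(cs)
        med, p95 = np.median(pooled), np.percentile(pooled, 95)
        assert t.loc[0, "median"] == med and t.loc[0, "p95"] == p95
        expected = (p95 - med) / med
        assert t.loc[0, "score"] == pytest.approx(expected, rel=1e-12)
        assert bool(t.loc[0, "expanded"]) == (expected >= 2)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        genos = [[tuple(sorted(rng.integers(5, 40, 2))) for _ in range(20)]]
        cs = build_callset(genos)
        t1 = expansion_scores(cs, group=cs.samples)
        t2 = expansion_scores(cs, group=list(reversed(cs.samples)))
        assert t1["score"].equals(t2["score"])


class TestSaturation:
    def test_full_size_matches_exact_count(self):
        model = PopulationModel(populations={"A": 30}, n_loci=60, sigma=0.25, seed=12)
        freqs, _ = simulate_frequencies(model)
        cs, _, _ = simulate_callset(freqs, model)
        t = saturation_curve(cs, step=10, n_reps=2, seed=0)
        n_pstr = sum(
            len({a for j in range(cs.n_samples) for a in cs.alleles[i, j] if a >= 0}) > 1
            for i in range(cs.n_loci)
        )
        assert t.iloc[-1]["mean_pstr"] == n_pstr
        assert t.iloc[-1]["sd_pstr"] == 0.0

    def test_monotone_mean(self):
        model = PopulationModel(populations={"A": 40}, n_loci=80, sigma=0.3, seed=13)
        freqs, _ = simulate_frequencies(model)
        cs, _, _ = simulate_callset(freqs, model)
        t = saturation_curve(cs, step=10, n_reps=4, seed=1)
        assert (np.diff(t["mean_pstr"]) >= -1e-9).all()
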