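"""Ground-truth properties of the synthetic cohort generator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strpop.core import ValidationError, dosage_matrix
from strpop.ld import str_snp_r2
from strpop.synthetic import (
    PopulationModel,
    default_loci,
    geometric_step_pmf,
    simulate_callset,
    simulate_expression,
    simulate_frequencies,
    simulate_layout,
    simulate_linked_snps,
    simulate_trios,
)
from strpop.trio import Trio, mendelian_rate

from conftest import build_callset


def small_model(**kw) -> PopulationModel:
    base = dict(populations={"A": 30}, n_loci=20, sigma=0.3, seed=7,
                missing_rate=0.0, defect_rate=0.0)
    base.update(kw)
    return PopulationModel(**base)


class TestFrequencies:
    def test_sigma_zero_monomorphic(self):
        freqs, truth = simulate_frequencies(small_model(sigma=0.0))
        for spec in freqs["A"]:
            assert len(spec) == 1
            assert list(spec.values()) == [1.0]

    def test_deterministic_given_seed(self):
        f1, _ = simulate_frequencies(small_model(divergence=0.2))
        f2, _ = simulate_frequencies(small_model(divergence=0.2))
        assert f1 == f2

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValidationError):
            simulate_frequencies(small_model(sigma=-0.1))

    def test_sampled_spectrum_converges_to_stated_probabilities(self):
        """Law of large numbers against the analytic geometric-step pmf."""
        model = small_model(n_loci=1, sigma=0.3, seed=11)
        freqs, _ = simulate_frequencies(model)
        stated = freqs["A"][0]
        rng = np.random.default_rng(5)
        alleles = np.fromiter(stated.keys(), dtype=int)
        probs = np.fromiter(stated.values(), dtype=float)
        draws = rng.choice(alleles, size=50_000, p=probs)
        emp = pd.Series(draws).value_counts(normalize=True)
        tv = 0.5 * sum(
            abs(emp.get(a, 0.0) - p) for a, p in stated.items()
        )
        assert tv < 0.02
        # analytic pmf itself is the normalized geometric-step distribution
        ks, pw = geometric_step_pmf(0.3)
        founder = alleles[np.argmax(probs)]
        expected = {int(founder + k): w for k, w in zip(ks, pw) if founder + k >= 1}
        z = sum(expected.values())
        for a, p in stated.items():
            assert p == pytest.approx(expected[a] / z, rel=1e-9)


class TestCallset:
    def test_no_defects_means_clean_qc(self):
        from strpop.qc import FilterConfig, filter_calls

        model = small_model(defect_rate=0.0, missing_rate=0.05)
        freqs, truth = simulate_frequencies(model)
        cs, meta, truth = simulate_callset(freqs, model, truth=truth)
        _, report = filter_calls(cs, FilterConfig())
        assert report.counts["removed_calls"] == 0

    def test_planted_defects_recorded_exactly(self):
        from strpop.qc import FilterConfig, filter_calls

        model = small_model(defect_rate=0.1, populations={"A": 25})
        freqs, truth = simulate_frequencies(model)
        cs, meta, truth = simulate_callset(freqs, model, truth=truth)
        _, report = filter_calls(cs, FilterConfig())
        removed = set(
            map(tuple, report.removed_calls()[["locus_index", "sample"]].itertuples(index=False))
        )
        planted = set(
            map(tuple, truth.defects[["locus_index", "sample"]].itertuples(index=False))
        )
        assert removed == planted and len(planted) > 0

    def test_hardy_weinberg_heterozygote_fraction(self):
        """Observed het fraction matches 2p(1-p) within 3 SE at a bi-allelic locus."""
        n = 5000
        model = PopulationModel(populations={"A": n}, n_loci=1, sigma=0.0, seed=13)
        freqs = {"A": [{10: 0.6, 12: 0.4}]}
        cs, _, _ = simulate_callset(freqs, model)
        het = np.mean(cs.alleles[0, :, 0] != cs.alleles[0, :, 1])
        p_het = 2 * 0.6 * 0.4
        se = np.sqrt(p_het * (1 - p_het) / n)
        assert abs(het - p_het) < 3 * se

    def test_meta_matches_samples(self):
        model = small_model(populations={"A": 4, "B": 3})
        freqs, truth = simulate_frequencies(model)
        cs, meta, _ = simulate_callset(freqs, model, truth=truth)
        assert list(meta["sample"]) == cs.samples
        assert meta["population"].tolist() == ["A"] * 4 + ["B"] * 3


class TestTrios:
    def test_de_novo_zero_is_fully_mendelian(self):
        model = small_model()
        freqs, _ = simulate_frequencies(model)
        cs, trios_df, truth = simulate_trios(freqs, 10, 0.0, seed=3)
        trios = [Trio(r.child, r.father, r.mother) for r in trios_df.itertuples()]
        table, overall = mendelian_rate(cs, trios)
        assert overall == 1.0
        assert (table["rate"] == 1.0).all()
        assert truth.de_novo.empty

    def test_forced_mutation_breaks_monomorphic_locus(self):
        # sigma=0 parents are homozygous for the founder, so any +/-1 step
        # must leave the parental allele set
        model = small_model(sigma=0.0, n_loci=1)
        freqs, _ = simulate_frequencies(model)
        cs, trios_df, truth = simulate_trios(freqs, 5, 1.0, seed=3)
        assert truth.de_novo["breaks_mendel"].all()
        trios = [Trio(r.child, r.father, r.mother) for r in trios_df.itertuples()]
        table, overall = mendelian_rate(cs, trios)
        assert overall == 0.0

    def test_seed_reproducibility(self):
        model = small_model()
        freqs, _ = simulate_frequencies(model)
        cs1, t1, _ = simulate_trios(freqs, 6, 0.3, seed=9)
        cs2, t2, _ = simulate_trios(freqs, 6, 0.3, seed=9)
        assert cs1.equals(cs2) and t1.equals(t2)


class TestLinkedSnps:
    @staticmethod
    def _biallelic_dosage(n=500, seed=2):
        rng = np.random.default_rng(seed)
        a = rng.choice([10, 12], size=(n, 2), p=[0.5, 0.5])
        return (a.sum(axis=1) - 20).astype(float)[None, :]

    def _targets(self, r2):
        return pd.DataFrame(
            {"snp": ["rs1"], "locus_index": [0], "chrom": ["chr01"],
             "pos": [1500], "target_r2": [r2]}
        )

    def test_target_one_nearly_perfect(self):
        dos = self._biallelic_dosage()
        snps, truth = simulate_linked_snps(dos, self._targets(1.0), seed=4)
        r2 = str_snp_r2(dos[0], snps["rs1"].to_numpy(dtype=float))
        assert r2 >= 0.99

    def test_target_zero_near_zero(self):
        dos = self._biallelic_dosage()
        snps, _ = simulate_linked_snps(dos, self._targets(0.0), seed=4)
        r2 = str_snp_r2(dos[0], snps["rs1"].to_numpy(dtype=float))
        assert r2 <= 0.05

    def test_intermediate_target_calibrated(self):
        dos = self._biallelic_dosage()
        snps, truth = simulate_linked_snps(dos, self._targets(0.6), seed=4)
        assert truth.snps["realized_r2"].iloc[0] == pytest.approx(0.6, abs=0.1)

    def test_constant_dosage_rejected(self):
        dos = np.full((1, 100), 4.0)
        with pytest.raises(ValidationError):
            simulate_linked_snps(dos, self._targets(0.5), seed=4)


class TestExpression:
    def test_noiseless_no_effect_constant(self):
        cs = build_callset([[(10, 12), (11, 11), (10, 10)]])
        dos = dosage_matrix(cs).values
        effects = pd.DataFrame({"feature": ["g"], "locus_index": [0], "beta": [0.0]})
        vals, coords, _ = simulate_expression(
            dos, cs.samples, cs.loci, effects, noise_sd=0.0, seed=1
        )
        assert np.ptp(vals.loc["g"].to_numpy()) == 0.0

    def test_noiseless_unit_beta_exact_slope(self):
        from scipy.stats import linregress

        cs = build_callset([[(10, 12), (11, 11), (10, 10), (12, 12)]])
        dos = dosage_matrix(cs).values
        effects = pd.DataFrame({"feature": ["g"], "locus_index": [0], "beta": [1.0]})
        vals, _, _ = simulate_expression(
            dos, cs.samples, cs.loci, effects, noise_sd=0.0, seed=1
        )
        fit = linregress(dos[0], vals.loc["g"].to_numpy())
        assert fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_bounded_values_in_unit_interval(self):
        cs = build_callset([[(10, 12), (11, 11), (10, 10), (14, 14)]])
        dos = dosage_matrix(cs).values
        effects = pd.DataFrame({"feature": ["t"], "locus_index": [0], "beta": [0.8]})
        vals, _, _ = simulate_expression(
            dos, cs.samples, cs.loci, effects, noise_sd=0.5, bounded=True, seed=1
        )
        v = vals.to_numpy()
        assert np.all((v >= 0) & (v <= 1))


class TestLayout:
    def test_seed_reproducibility(self):
        l1, loci1, _ = simulate_layout(2, 12_000_000, 2.0, 500, seed=6)
        l2, loci2, _ = simulate_layout(2, 12_000_000, 2.0, 500, seed=6)
        assert loci1 == loci2

    def test_loci_avoid_centromeres(self):
        layout, loci, _ = simulate_layout(2, 12_000_000, 1.0, 2000, seed=6)
        for lo in loci:
            cs_, ce_ = layout.centromere(lo.chrom)
            assert lo.end <= cs_ or lo.start >= ce_

    def test_arm_too_short_rejected(self):
        with pytest.raises(ValidationError):
            simulate_layout(1, 4_000_000, 1.0, 10, seed=0)
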