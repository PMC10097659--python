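"""Residualization, the windowed dosage scan, and hierarchical FDR."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strpop.assoc import (
    assoc_scan,
    hierarchical_fdr,
    permutation_control,
    residualize,
)
from strpop.core import ValidationError, dosage_matrix
from strpop.synthetic import (
    PopulationModel,
    simulate_callset,
    simulate_expression,
    simulate_frequencies,
)

from conftest import build_callset


def coords_for(cs, features):
    rows = []
    for f, i in features:
        lo = cs.loci[i]
        rows.append({"feature": f, "chrom": lo.chrom, "start": max(0, lo.start - 1000),
                     "end": lo.end + 1000, "strand": "+"})
    return pd.DataFrame(rows)


class TestResidualize:
    def test_exact_linear_fit_gives_zero(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"c1": rng.normal(size=30)}, index=[f"S{j}" for j in range(30)])
        vals = pd.DataFrame(
            [2.0 + 3.0 * cov["c1"].to_numpy()], index=["g"], columns=cov.index
        )
        resid = residualize(vals, cov)
        assert np.allclose(resid.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_covariate_only_centers(self):
        n = 40
        cov = pd.DataFrame(
            {"c1": np.tile([1.0, -1.0], n // 2)}, index=[f"S{j}" for j in range(n)]
        )
        y = np.tile([2.0, 2.0, -2.0, -2.0], n // 4)  # orthogonal to c1
        vals = pd.DataFrame([y + 5.0], index=["g"], columns=cov.index)
        resid = residualize(vals, cov)
        assert np.allclose(resid.loc["g"].to_numpy(), y, atol=1e-10)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(1)
        n = 50
        cov = pd.DataFrame(
            {"c1": rng.normal(size=n), "c2": rng.normal(size=n)},
            index=[f"S{j}" for j in range(n)],
        )
        y = 0.7 * cov["c1"].to_numpy() + rng.normal(size=n)
        vals = pd.DataFrame([y], index=["g"], columns=cov.index)
        resid = residualize(vals, cov).loc["g"].to_numpy()
        for c in ("c1", "c2"):
            x = cov[c].to_numpy()
            assert abs(np.dot(resid - resid.mean(), x - x.mean())) < 1e-8

    def test_rank_deficient_rejected(self):
        cov = pd.DataFrame(
            {"c1": [1.0, 2, 3, 4], "c2": [2.0, 4, 6, 8]},
            index=[f"S{j}" for j in range(4)],
        )
        vals = pd.DataFrame([[1.0, 2, 3, 4]], index=["g"], columns=cov.index)
        with pytest.raises(ValidationError, match="collinear"):
            residualize(vals, cov)


def planted_dataset(n=120, beta=1.0, noise=0.0, seed=4):
    rng = np.random.default_rng(seed)
    genos = [[tuple(sorted(rng.choice([9, 10, 11, 12], size=2))) for _ in range(n)]]
    cs = build_callset(genos)
    dos = dosage_matrix(cs).values
    effects = pd.DataFrame({"feature": ["g"], "locus_index": [0], "beta": [beta]})
    vals, coords, _ = simulate_expression(
        dos, cs.samples, cs.loci, effects, noise_sd=noise, seed=seed
    )
    return cs, vals, coords


class TestAssocScan:
    def test_min_called_drop(self):
        cs, vals, coords = planted_dataset(n=49)
        table, drops = assoc_scan(vals, coords, cs, min_called=50)
        assert table.empty
        assert drops["reason"].tolist() == ["MIN_CALLED"]

    def test_noiseless_planted_beta_exact(self):
        cs, vals, coords = planted_dataset(beta=1.0, noise=0.0)
        table, _ = assoc_scan(vals, coords, cs, min_called=50)
        assert len(table) == 1
        assert table.loc[0, "beta"] == pytest.approx(1.0, abs=1e-10)
        assert table.loc[0, "p"] < 1e-20

    def test_dosage_offset_invariance(self):
        # slope/p identical whether dosage is deviation-sum or repeat-sum,
        # because they differ by a constant per locus
        cs, vals, coords = planted_dataset(beta=0.8, noise=0.5)
        from scipy.stats import linregress

        table, _ = assoc_scan(vals, coords, cs, min_called=50)
        dos_rep = dosage_matrix(cs, "repeat_sum").values[0]
        y = vals.loc["g", cs.samples].to_numpy()
        fit = linregress(dos_rep, y)
        assert table.loc[0, "beta"] == pytest.approx(fit.slope, rel=1e-12)
        assert table.loc[0, "p"] == pytest.approx(fit.pvalue, rel=1e-12)

    def test_feature_outside_window_absent(self):
        cs, vals, _ = planted_dataset()
        lo = cs.loci[0]
        far = pd.DataFrame(
            [{"feature": "g", "chrom": lo.chrom, "start": lo.end + 600_000,
              "end": lo.end + 650_000, "strand": "+"}]
        )
        table, _ = assoc_scan(vals, far, cs, min_called=50)
        assert table.empty

    def test_low_het_locus_dropped(self):
        genos = [[(10, 10)] * 99 + [(10, 11)]]
        cs = build_callset(genos)
        vals = pd.DataFrame(
            [np.arange(100.0)], index=["g"], columns=cs.samples
        )
        table, drops = assoc_scan(vals, coords_for(cs, [("g", 0)]), cs, min_called=50)
        assert drops["reason"].tolist() == ["MIN_HET"]

    def test_beta_recovery_with_noise(self):
        """Planted beta=0.5 at n=445 lands in its 95% CI in >= 90% of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cs, vals, coords = planted_dataset(n=445, beta=0.5, noise=1.0, seed=seed)
            table, _ = assoc_scan(vals, coords, cs, min_called=50)
            b, se = table.loc[0, "beta"], table.loc[0, "se"]
            if abs(b - 0.5) <= 1.96 * se:
                hits += 1
        assert hits >= 90


class TestHierarchicalFdr:
    def test_single_pair_significant(self):
        table = pd.DataFrame(
            [{"feature": "g", "locus_index": 0, "chrom": "chr01", "start": 0,
              "n": 100, "beta": 1.0, "se": 0.1, "p": 0.01}]
        )
        out = hierarchical_fdr(table, alpha=0.1)
        assert out.loc[0, "bonferroni_p_within_feature"] == pytest.approx(0.01)
        assert out.loc[0, "significant"]

    def test_bonferroni_arithmetic(self):
        rows = [
            {"feature": "g", "locus_index": i, "chrom": "chr01", "start": i,
             "n": 100, "beta": 0.0, "se": 1.0, "p": p}
            for i, p in enumerate([0.004] + [0.5] * 9)
        ]
        out = hierarchical_fdr(pd.DataFrame(rows), alpha=0.1)
        best = out.loc[out["p"].idxmin()]
        assert best["bonferroni_p_within_feature"] == pytest.approx(0.04)
        assert out["significant"].sum() == 1

    def test_one_best_pair_per_significant_feature(self):
        rows = []
        for f in ("g1", "g2"):
            for i in range(5):
                rows.append(
                    {"feature": f, "locus_index": i, "chrom": "chr01", "start": i,
                     "n": 100, "beta": 0.0, "se": 1.0,
                     "p": 1e-6 if i == 2 else 0.3}
                )
        out = hierarchical_fdr(pd.DataFrame(rows), alpha=0.1)
        sig = out[out["significant"]]
        assert len(sig) == 2
        assert set(sig["locus_index"]) == {2}

    def test_null_features_controlled(self):
        rng = np.random.default_rng(7)
        false_rates = []
        for _ in range(30):
            rows = [
                {"feature": f"g{k}", "locus_index": 0, "chrom": "chr01", "start": 0,
                 "n": 100, "beta": 0.0, "se": 1.0, "p": rng.uniform()}
                for k in range(20)
            ]
            out = hierarchical_fdr(pd.DataFrame(rows), alpha=0.1)
            false_rates.append(out["significant"].sum() / 20)
        assert np.mean(false_rates) <= 0.1 + 0.05


class TestPermutationControl:
    def test_reproducible(self):
        cs, vals, coords = planted_dataset(beta=1.0, noise=0.5)
        t1 = permutation_control(vals, coords, cs, seed=3, min_called=50)
        t2 = permutation_control(vals, coords, cs, seed=3, min_called=50)
        assert t1.equals(t2)

    def test_shuffling_destroys_planted_signal(self):
        from scipy.stats import kstest

        pvals = []
        for seed in range(25):
            cs, vals, coords = planted_dataset(n=200, beta=1.0, noise=0.5, seed=seed)
            t = permutation_control(vals, coords, cs, seed=seed, min_called=50)
            pvals.extend(t["p"].tolist())
        assert kstest(pvals, "uniform").pvalue > 0.01
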