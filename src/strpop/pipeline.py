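"""End-to-end orchestration: simulate -> filter -> analyze -> report.

A single YAML configuration drives every stage; all randomness derives
from one global seed through named substreams, so a given (config, seed)
pair reproduces byte-identical output tables.  The synthetic cohort is
always (re)generated in memory — it is cheap and keeps stage toggles
independent: enabling or disabling one analysis stage never changes
another stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import density as density_mod
from . import ld as ld_mod
from . import popgen as popgen_mod
from . import qc as qc_mod
from . import trio as trio_mod
from .core import (
    allele_spectrum,
    deviation_spectra,
    dosage_matrix,
    locus_stats,
    write_str_vcf,
)
from .rng import substream
from .synthetic import (
    PopulationModel,
    simulate_callset,
    simulate_expression,
    simulate_frequencies,
    simulate_layout,
    simulate_linked_snps,
    simulate_trios,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "main"]

log = logging.getLogger("strpop")

ALL_STAGES = ("simulate", "filter", "stats", "trio", "density", "ld", "qtl", "popgen")

DEFAULT_CONFIG: dict = {
    "simulate": {
        "populations": {"POPA": 200, "POPB": 200, "POPC": 200},
        "n_loci": 2000,
        "sigma": 0.3,
        "divergence": {"POPA": 0.0, "POPB": 0.05, "POPC": 0.1},
        "missing_rate": 0.02,
        "defect_rate": 0.01,
        "mean_depth": 30.0,
        "n_trios": 20,
        "de_novo_rate": 0.0,
    },
    "filter": {
        "min_call_dp": 20,
        "max_call_dp": 1000,
        "min_sample_call_rate": 0.5,
        "min_locus_call_rate": 0.2,
        "hwe_min_p": 1e-5,
    },
    "density": {
        "n_chrom": 4,
        "arm_length": 30_000_000,
        "telomeric_factor": 2.0,
        "n_layout_loci": 10_000,
        "n_perm": 10_000,
    },
    "ld": {
        "n_snps": 12,
        "window": 250_000,
        "r2_threshold": 0.7,
        "n_resample": 1000,
    },
    "qtl": {
        "n_effect_features": 10,
        "n_null_features": 20,
        "beta": 0.5,
        "noise_sd": 1.0,
        "window": 500_000,
        "min_called": 50,
        "min_het": 0.1,
        "fdr_alpha": 0.1,
    },
    "popgen": {
        "min_het": 0.1,
        "alpha": 0.01,
        "top_frac": 0.05,
        "n_perm": 1000,
        "max_perm_loci": 300,
        "diversity_max_samples": 40,
        "autosome_length": 2.88e9,
        "saturation_step": 100,
        "saturation_reps": 3,
    },
}


def load_config(path: str | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict):
                cfg.setdefault(section, {}).update(values)
            else:
                cfg[section] = values
    return cfg


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


def run_pipeline(
    config: dict,
    outdir: str,
    seed: int,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Execute the requested stages and write their tables under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "stages": list(stages),
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "tables": {},
    }

    sim = config["simulate"]
    model = PopulationModel(
        populations=dict(sim["populations"]),
        n_loci=int(sim["n_loci"]),
        sigma=sim["sigma"],
        divergence=sim["divergence"],
        missing_rate=float(sim["missing_rate"]),
        mean_depth=float(sim.get("mean_depth", 30.0)),
        defect_rate=float(sim["defect_rate"]),
        seed=seed,
    )
    log.info("simulate: %d loci, %s", model.n_loci, model.populations)
    freqs, truth = simulate_frequencies(model)
    callset, meta, truth = simulate_callset(freqs, model, truth=truth)
    trio_set, trio_table, trio_truth = simulate_trios(
        freqs, int(sim["n_trios"]), float(sim["de_novo_rate"]), seed
    )
    if "simulate" in stages:
        write_str_vcf(callset, out / "calls.vcf")
        manifest["tables"]["meta.tsv"] = _write(meta, out / "meta.tsv")
        manifest["tables"]["trios.tsv"] = _write(trio_table, out / "trios.tsv")
        manifest["tables"]["truth_defects.tsv"] = _write(
            truth.defects, out / "truth_defects.tsv"
        )
        write_str_vcf(trio_set, out / "trio_calls.vcf")

    fcfg = qc_mod.FilterConfig(
        min_call_dp=int(config["filter"]["min_call_dp"]),
        max_call_dp=int(config["filter"]["max_call_dp"]),
        min_sample_call_rate=float(config["filter"]["min_sample_call_rate"]),
        min_locus_call_rate=float(config["filter"]["min_locus_call_rate"]),
        hwe_min_p=float(config["filter"]["hwe_min_p"]),
    )
    filtered, call_report = qc_mod.filter_calls(callset, fcfg)
    classified, locus_report = qc_mod.filter_loci(filtered, fcfg)
    if "filter" in stages:
        log.info("filter: %s", locus_report.counts)
        manifest["tables"]["filter_calls.tsv"] = _write(
            call_report.removed_calls(), out / "filter_calls.tsv"
        )
        manifest["tables"]["filter_loci.tsv"] = _write(
            locus_report.locus_table, out / "filter_loci.tsv"
        )
        write_str_vcf(classified, out / "calls_filtered.vcf")
    status = locus_report.locus_table.set_index("locus_index")["status"]
    kept = [i for i in range(callset.n_loci) if status.loc[i] != "removed"]
    pstr_mask = np.array([status.loc[i] == "pSTR" for i in kept])
    pstr_set = classified.subset(loci=list(np.flatnonzero(pstr_mask)))

    if "stats" in stages:
        rates = classified.locus_call_rates()
        rows = []
        for i, lo in enumerate(classified.loci):
            spec = allele_spectrum(classified, i)
            if spec.total == 0:
                continue
            st = locus_stats(spec, rates[i])
            rows.append(
                {
                    "chrom": lo.chrom,
                    "start": lo.start,
                    "motif": lo.motif,
                    "n_alleles": st.n_alleles,
                    "het": st.het,
                    "entropy": st.entropy,
                    "major_allele": st.major_allele,
                    "major_af": st.major_af,
                    "mean_len": st.mean_len,
                    "var_len": st.var_len,
                    "call_rate": st.call_rate,
                }
            )
        manifest["tables"]["locus_stats.tsv"] = _write(
            pd.DataFrame(rows), out / "locus_stats.tsv"
        )
        spectra = deviation_spectra(classified)
        manifest["tables"]["deviation_major_vs_ref.tsv"] = _write(
            spectra["major_vs_ref"], out / "deviation_major_vs_ref.tsv"
        )
        manifest["tables"]["deviation_aggregate.tsv"] = _write(
            spectra["aggregate"], out / "deviation_aggregate.tsv"
        )

    if "trio" in stages:
        trios = [
            trio_mod.Trio(r.child, r.father, r.mother) for r in trio_table.itertuples()
        ]
        rates_df, overall = trio_mod.mendelian_rate(trio_set, trios)
        rates_df["overall_mean"] = overall
        manifest["tables"]["mendelian.tsv"] = _write(rates_df, out / "mendelian.tsv")

    if "density" in stages:
        dcfg = config["density"]
        layout, layout_loci, _ = simulate_layout(
            int(dcfg["n_chrom"]),
            int(dcfg["arm_length"]),
            float(dcfg["telomeric_factor"]),
            int(dcfg["n_layout_loci"]),
            seed,
        )
        track1mb = density_mod.bin_counts(layout_loci, layout, 1_000_000, per="arm")
        enr = density_mod.subtelomere_enrichment(
            track1mb, layout, n_perm=int(dcfg["n_perm"]), seed=seed
        )
        manifest["tables"]["subtelomere.tsv"] = _write(
            pd.DataFrame([enr]), out / "subtelomere.tsv"
        )
        track100kb = density_mod.bin_counts(
            layout_loci, layout, 100_000, per="chromosome"
        )
        prof = density_mod.metachromosome_profile(track100kb, layout)
        manifest["tables"]["metachromosome_curve.tsv"] = _write(
            prof["curve"], out / "metachromosome_curve.tsv"
        )
        manifest["tables"]["metachromosome_contexts.tsv"] = _write(
            prof["contexts"], out / "metachromosome_contexts.tsv"
        )

    if "ld" in stages:
        lcfg = config["ld"]
        rng = substream(seed, "pipeline_ld")
        dos = dosage_matrix(pstr_set, mode="repeat_sum")
        eligible = [
            i
            for i in range(pstr_set.n_loci)
            if np.nanstd(dos.values[i]) > 0
        ]
        n_snps = min(int(lcfg["n_snps"]), len(eligible))
        pick = rng.choice(len(eligible), size=n_snps, replace=False)
        targets = pd.DataFrame(
            {
                "snp": [f"rs{k:06d}" for k in range(n_snps)],
                "locus_index": [eligible[k] for k in pick],
                "chrom": [pstr_set.loci[eligible[k]].chrom for k in pick],
                "pos": [pstr_set.loci[eligible[k]].start + 500 for k in pick],
                "target_r2": np.round(rng.uniform(0.2, 0.95, size=n_snps), 3),
            }
        )
        snps, snp_truth = simulate_linked_snps(
            dos.values, targets, seed, samples=pstr_set.samples
        )
        catalog = pd.DataFrame(
            {
                "snp": targets["snp"],
                "chrom": targets["chrom"],
                "pos": targets["pos"],
                "trait": ["trait_a" if k % 2 == 0 else "trait_b" for k in range(n_snps)],
                "p": 1e-9,
            }
        )
        pairs, per_str = ld_mod.tag_gwas(
            pstr_set,
            snps,
            catalog,
            window=int(lcfg["window"]),
            r2_threshold=float(lcfg["r2_threshold"]),
        )
        manifest["tables"]["ld_pairs.tsv"] = _write(pairs, out / "ld_pairs.tsv")
        manifest["tables"]["ld_per_str.tsv"] = _write(per_str, out / "ld_per_str.tsv")
        tagged = set(per_str.loc[per_str["tagged"], "locus_index"])
        tested = list(range(pstr_set.n_loci))
        focal = sorted(tagged) or tested[: max(1, len(tested) // 10)]
        enr = ld_mod.tag_enrichment(
            tested, focal, tagged, n_resample=int(lcfg["n_resample"]), seed=seed
        )
        manifest["tables"]["ld_enrichment.tsv"] = _write(
            pd.DataFrame([enr]), out / "ld_enrichment.tsv"
        )

    if "qtl" in stages:
        qcfg = config["qtl"]
        rng = substream(seed, "pipeline_qtl")
        dos = dosage_matrix(pstr_set, mode="deviation_sum")
        eligible = [i for i in range(pstr_set.n_loci) if np.nanstd(dos.values[i]) > 0]
        n_eff = min(int(qcfg["n_effect_features"]), len(eligible))
        anchors = rng.choice(len(eligible), size=n_eff, replace=False)
        effects = pd.DataFrame(
            {
                "feature": [f"gene{k:04d}" for k in range(n_eff)],
                "locus_index": [eligible[k] for k in anchors],
                "beta": float(qcfg["beta"]),
            }
        )
        covariates = pd.DataFrame(
            {
                "sex": (meta.set_index("sample").loc[pstr_set.samples, "sex"] == "XY").astype(float),
                "cov1": substream(seed, "pipeline_qtl_cov").standard_normal(
                    pstr_set.n_samples
                ),
            },
            index=pstr_set.samples,
        )
        values, coords, qtl_truth = simulate_expression(
            dos.values,
            pstr_set.samples,
            pstr_set.loci,
            effects,
            covariates=covariates,
            noise_sd=float(qcfg["noise_sd"]),
            seed=seed,
            n_null_features=int(qcfg["n_null_features"]),
        )
        adjusted = assoc_mod.residualize(values, covariates)
        table, drop_log = assoc_mod.assoc_scan(
            adjusted,
            coords,
            pstr_set,
            window=int(qcfg["window"]),
            min_called=int(qcfg["min_called"]),
            min_het=float(qcfg["min_het"]),
        )
        flagged = assoc_mod.hierarchical_fdr(table, alpha=float(qcfg["fdr_alpha"]))
        manifest["tables"]["qtl_assoc.tsv"] = _write(flagged, out / "qtl_assoc.tsv")
        manifest["tables"]["qtl_drops.tsv"] = _write(drop_log, out / "qtl_drops.tsv")
        manifest["tables"]["qtl_truth.tsv"] = _write(
            qtl_truth.effects, out / "qtl_truth.tsv"
        )
        null_table = assoc_mod.permutation_control(
            adjusted, coords, pstr_set, seed=seed,
            window=int(qcfg["window"]),
            min_called=int(qcfg["min_called"]),
            min_het=float(qcfg["min_het"]),
        )
        manifest["tables"]["qtl_permutation.tsv"] = _write(
            null_table, out / "qtl_permutation.tsv"
        )

    if "popgen" in stages:
        pcfg = config["popgen"]
        pops = sorted(meta["population"].unique())
        by_pop = {
            p: [s for s in meta.loc[meta["population"] == p, "sample"] if s in pstr_set.samples]
            for p in pops
        }
        manifest["tables"]["sample_summaries.tsv"] = _write(
            popgen_mod.sample_summaries(pstr_set), out / "sample_summaries.tsv"
        )
        manifest["tables"]["population_sharing.tsv"] = _write(
            popgen_mod.population_sharing(pstr_set, meta), out / "population_sharing.tsv"
        )
        scores, evr = popgen_mod.pca_dosage(pstr_set)
        scores = scores.reset_index(names="sample")
        manifest["tables"]["pca_scores.tsv"] = _write(scores, out / "pca_scores.tsv")
        ga, gb = pops[0], pops[-1]
        manifest["tables"]["length_compare.tsv"] = _write(
            popgen_mod.length_compare(
                pstr_set,
                {ga: by_pop[ga], gb: by_pop[gb]},
                min_het=float(pcfg["min_het"]),
                alpha=float(pcfg["alpha"]),
            ),
            out / "length_compare.tsv",
        )
        rst_table, rst_motif = popgen_mod.rst(pstr_set, by_pop, min_het=float(pcfg["min_het"]))
        manifest["tables"]["rst.tsv"] = _write(rst_table, out / "rst.tsv")
        manifest["tables"]["rst_by_motif.tsv"] = _write(
            rst_motif.rename("mean_rst").reset_index(), out / "rst_by_motif.tsv"
        )
        hv, hv_table = popgen_mod.highly_variable(
            pstr_set, by_pop[ga],
            min_het=float(pcfg["min_het"]), top_frac=float(pcfg["top_frac"]),
        )
        manifest["tables"]["highly_variable.tsv"] = _write(
            hv_table.assign(selected=hv_table["locus_index"].isin(hv)),
            out / "highly_variable.tsv",
        )
        max_loci = int(pcfg["max_perm_loci"])
        perm_subset = pstr_set.subset(loci=list(range(min(max_loci, pstr_set.n_loci))))
        manifest["tables"]["sd_diff.tsv"] = _write(
            popgen_mod.sd_diff_perm(
                perm_subset, by_pop[ga], by_pop[gb],
                min_het=float(pcfg["min_het"]),
                n_perm=int(pcfg["n_perm"]),
                seed=seed,
                alpha=float(pcfg["alpha"]),
            ),
            out / "sd_diff.tsv",
        )
        manifest["tables"]["expansion.tsv"] = _write(
            popgen_mod.expansion_scores(pstr_set), out / "expansion.tsv"
        )
        manifest["tables"]["saturation.tsv"] = _write(
            popgen_mod.saturation_curve(
                pstr_set,
                step=int(pcfg["saturation_step"]),
                n_reps=int(pcfg["saturation_reps"]),
                seed=seed,
            ),
            out / "saturation.tsv",
        )
        # STR diversity on a per-population subsample to keep the O(n^2)
        # pairwise comparison affordable at demo scale
        nmax = int(pcfg["diversity_max_samples"])
        div_samples = {p: ss[:nmax] for p, ss in by_pop.items()}
        div_meta = meta[meta["sample"].isin(sum(div_samples.values(), []))]
        het_counts = pd.Series(0.0, index=div_meta["sample"])
        _, diversity = popgen_mod.diversity_stats(
            pstr_set, het_counts, div_meta, float(pcfg["autosome_length"])
        )
        manifest["tables"]["str_diversity.tsv"] = _write(
            diversity.rename("diversity").rename_axis("population").reset_index(),
            out / "str_diversity.tsv",
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str) -> None:
    """Population-scale STR analysis pipeline on synthetic or provided data."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


def _stage_command(name: str, stages: tuple[str, ...]):
    @main.command(name=name)
    @click.option("--config", "config_path", default=None, type=click.Path(exists=True))
    @click.option("--seed", default=0, show_default=True, type=int)
    @click.option("--outdir", default="strpop_out", show_default=True)
    def _cmd(config_path, seed, outdir, _stages=stages):
        cfg = load_config(config_path)
        run_pipeline(cfg, outdir, seed, stages=_stages)

    return _cmd


for _name in ALL_STAGES:
    _stage_command(_name, ("simulate",) if _name == "simulate" else (_name,))
_stage_command("all", ALL_STAGES)


if __name__ == "__main__":
    main()
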