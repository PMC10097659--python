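"""Synthetic multi-population STR cohorts with known ground truth.

Every downstream stage of the package is testable without access to real
genomes: this module generates allele-frequency spectra under a stepwise
mutation model, diploid call sets with GangSTR-style QC metadata and
planted defects, parent-offspring trios, LD-linked bi-allelic SNPs,
expression / PDUI matrices with planted dosage effects, and genome layouts
with a controllable subtelomeric density factor.

Model sketch.  Each locus has a founder repeat count; a population's allele
distribution is the founder (shifted by a population-specific stepwise
divergence offset) spread by a symmetric geometric ("discrete Laplace")
step distribution P(step = k) proportional to sigma^|k|, the simplest
distribution consistent with the stepwise mutation model under which STRs
gain or lose whole repeat units.  Diploid genotypes are drawn under
Hardy-Weinberg equilibrium within population.  All generators are pure
functions of (parameters, seed); planted defects and effects are recorded
in a :class:`TruthTable` before noise so recovery tests can compare against
the truth only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, STRCallSet, STRLocus, ValidationError
from .density import GenomeLayout, SUBTELOMERE_SPAN
from .rng import substream

__all__ = [
    "PopulationModel",
    "TruthTable",
    "default_loci",
    "simulate_frequencies",
    "simulate_callset",
    "simulate_trios",
    "simulate_linked_snps",
    "simulate_expression",
    "simulate_layout",
]

# motif-length mix roughly matching the genome-wide 2-6 bp STR reference
# panel (di 15%, tri 18%, tetra 43%, penta 20%, hexa 4%)
_MOTIFS = ["AC", "AAT", "AGAT", "AATAG", "AGTATA"]
_MOTIF_WEIGHTS = [0.15, 0.18, 0.43, 0.20, 0.04]

DEFECT_TYPES = ("LOWDP", "HIGHDP", "SPANBOUND", "BADCI")


@dataclass
class PopulationModel:
    """Parameters of the synthetic cohort.

    populations: population code -> number of diploid samples.
    sigma: geometric step parameter in [0, 1) of the within-population
        allele spread; 0 means monomorphic at the founder.  Scalar or
        per-population mapping.
    divergence: scale of the per-population stepwise founder offset (same
        geometric parameterization); 0 means all populations share founders.
    missing_rate: per-call probability of a missing genotype.
    mean_depth: Poisson mean of read depth (emulating ~30x genomes); depths
        of defect-free calls are clipped into the QC-pass range.
    defect_rate: fraction of called genotypes planted with a QC defect
        (low/high depth, span/flank-only support, ML outside CI).
    """

    populations: dict[str, int]
    n_loci: int = 100
    sigma: float | dict[str, float] = 0.3
    divergence: float | dict[str, float] = 0.0
    missing_rate: float = 0.02
    mean_depth: float = 30.0
    defect_rate: float = 0.0
    founder_low: int = 8
    founder_high: int = 20
    seed: int = 0

    def sigma_of(self, pop: str) -> float:
        s = self.sigma[pop] if isinstance(self.sigma, dict) else self.sigma
        if not 0.0 <= s < 1.0:
            raise ValidationError(f"sigma must be in [0, 1), got {s} for {pop}")
        return float(s)

    def divergence_of(self, pop: str) -> float:
        d = self.divergence[pop] if isinstance(self.divergence, dict) else self.divergence
        if not 0.0 <= d < 1.0:
            raise ValidationError(f"divergence must be in [0, 1), got {d} for {pop}")
        return float(d)

    def validate(self) -> None:
        for pop, n in self.populations.items():
            if n < 0:
                raise ValidationError(f"negative sample size for {pop}")
            self.sigma_of(pop)
            self.divergence_of(pop)
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.defect_rate <= 1.0:
            raise ValidationError("defect_rate must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth recorded by the generators before noise injection."""

    # pop -> (n_loci,) arrays of allele supports and probabilities
    pop_freqs: dict[str, list[dict[int, float]]] = field(default_factory=dict)
    founders: np.ndarray | None = None
    # rows: locus_index, sample, defect
    defects: pd.DataFrame = field(default_factory=pd.DataFrame)
    # rows: trio, locus_index, parent, old_allele, new_allele, breaks_mendel
    de_novo: pd.DataFrame = field(default_factory=pd.DataFrame)
    # rows: feature, locus_index, beta
    effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    # rows: snp, locus_index, target_r2, realized_r2
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    telomeric_factor: float | None = None


def geometric_step_pmf(sigma: float, max_step: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric geometric step distribution P(k) ~ sigma^|k| on -K..K."""
    if sigma == 0.0:
        return np.array([0]), np.array([1.0])
    ks = np.arange(-max_step, max_step + 1)
    w = sigma ** np.abs(ks)
    return ks, w / w.sum()


def default_loci(
    n_loci: int,
    seed: int,
    chrom: str = "chr01",
    spacing: int = 10_000,
    founder_low: int = 8,
    founder_high: int = 20,
) -> tuple[list[STRLocus], np.ndarray]:
    """Evenly spaced loci with a realistic motif-length mix; returns founders too."""
    rng = substream(seed, "default_loci")
    motifs = rng.choice(len(_MOTIFS), size=n_loci, p=_MOTIF_WEIGHTS)
    founders = rng.integers(founder_low, founder_high + 1, size=n_loci)
    loci = []
    for i in range(n_loci):
        motif = _MOTIFS[motifs[i]]
        start = 1000 + i * spacing
        ref = int(founders[i])
        loci.append(STRLocus(chrom, start, start + ref * len(motif), motif, ref))
    return loci, founders.astype(np.int64)


def simulate_frequencies(
    model: PopulationModel,
    loci: list[STRLocus] | None = None,
    founders: np.ndarray | None = None,
) -> tuple[dict[str, list[dict[int, float]]], TruthTable]:
    """Per-population allele probability vectors under the stepwise model.

    Each population's founder is the global founder plus a stepwise offset
    drawn with the population's divergence parameter; alleles then spread
    around the population founder by the geometric step distribution,
    truncated to repeat counts >= 1 and renormalized.  Deterministic given
    the model seed.
    """
    model.validate()
    if loci is None:
        loci, founders = default_loci(
            model.n_loci, model.seed,
            founder_low=model.founder_low, founder_high=model.founder_high,
        )
    if founders is None:
        founders = np.array([lo.ref_repeats for lo in loci], dtype=np.int64)
    rng = substream(model.seed, "simulate_frequencies")
    pop_freqs: dict[str, list[dict[int, float]]] = {}
    for pop in model.populations:
        sigma = model.sigma_of(pop)
        div = model.divergence_of(pop)
        ks, pw = geometric_step_pmf(div)
        offsets = rng.choice(ks, size=len(loci), p=pw) if div > 0 else np.zeros(len(loci), dtype=int)
        steps, sw = geometric_step_pmf(sigma)
        freqs = []
        for i in range(len(loci)):
            center = max(1, int(founders[i]) + int(offsets[i]))
            alleles = center + steps
            ok = alleles >= 1
            probs = sw[ok] / sw[ok].sum()
            keep = probs > 1e-12
            freqs.append(
                {int(a): float(p) for a, p in zip(alleles[ok][keep], probs[keep])}
            )
        pop_freqs[pop] = freqs
    truth = TruthTable(pop_freqs=pop_freqs, founders=np.asarray(founders))
    return pop_freqs, truth


def _draw_alleles(
    freqs: list[dict[int, float]], n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """(loci, samples, 2) diploid draws, Hardy-Weinberg within population."""
    L = len(freqs)
    out = np.empty((L, n_samples, 2), dtype=np.int32)
    for i, f in enumerate(freqs):
        alleles = np.fromiter(f.keys(), dtype=np.int32)
        probs = np.fromiter(f.values(), dtype=float)
        probs = probs / probs.sum()
        u = rng.random((n_samples, 2))
        out[i] = alleles[np.searchsorted(np.cumsum(probs), u, side="right").clip(0, len(alleles) - 1)]
    return out


def _qc_fields(
    alleles: np.ndarray,
    mean_depth: float,
    min_dp: int,
    max_dp: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Defect-free depth / read-class / CI / quality fields for called genotypes."""
    L, S, _ = alleles.shape
    depth = rng.poisson(mean_depth, size=(L, S)).astype(np.int32)
    depth = np.clip(depth, min_dp, max_dp)
    encl = np.maximum(1, (0.6 * depth).astype(np.int32))
    span = ((depth - encl) * 0.7).astype(np.int32)
    flank = depth - encl - span
    support = np.stack([encl, span, flank], axis=-1).astype(np.int32)
    ci = np.empty((L, S, 2, 2), dtype=np.int32)
    ci[:, :, 0, 0] = np.maximum(1, alleles[:, :, 0] - 1)
    ci[:, :, 0, 1] = alleles[:, :, 0] + 1
    ci[:, :, 1, 0] = np.maximum(1, alleles[:, :, 1] - 1)
    ci[:, :, 1, 1] = alleles[:, :, 1] + 1
    quality = (0.8 + 0.2 * rng.random((L, S))).astype(np.float32)
    return depth, support, ci, quality


def simulate_callset(
    freqs: dict[str, list[dict[int, float]]],
    model: PopulationModel,
    loci: list[STRLocus] | None = None,
    truth: TruthTable | None = None,
) -> tuple[STRCallSet, pd.DataFrame, TruthTable]:
    """Draw a diploid call set (plus sample metadata) from population spectra.

    A ``defect_rate`` fraction of called genotypes is planted with exactly
    one QC defect each — depth below 20 or above 1000, span/flank-only read
    support, or a maximum-likelihood allele outside its 95% CI — and every
    planted defect is recorded in the truth table.
    """
    model.validate()
    if loci is None:
        loci, _ = default_loci(
            model.n_loci, model.seed,
            founder_low=model.founder_low, founder_high=model.founder_high,
        )
    L = len(loci)
    rng = substream(model.seed, "simulate_callset")
    pops = list(model.populations)
    sample_ids: list[str] = []
    meta_rows = []
    blocks = []
    for pop in pops:
        n = model.populations[pop]
        blocks.append(_draw_alleles(freqs[pop], n, rng))
        for k in range(n):
            sid = f"{pop}_{k:04d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "population": pop,
                    "superpopulation": pop.split("-")[0],
                    "sex": "XX" if (k % 2 == 0) else "XY",
                    "dataset": "synthetic",
                }
            )
    alleles = np.concatenate(blocks, axis=1) if blocks else np.empty((L, 0, 2), np.int32)
    S = alleles.shape[1]

    if model.missing_rate > 0:
        miss = rng.random((L, S)) < model.missing_rate
        alleles[miss] = MISSING
    # canonicalize pairs now so the CI fields align with the sorted alleles
    alleles = np.sort(alleles, axis=2)
    called = alleles[:, :, 0] >= 0

    min_dp, max_dp = 20, 1000
    depth, support, ci, quality = _qc_fields(alleles, model.mean_depth, min_dp, max_dp, rng)

    defect_rows = []
    if model.defect_rate > 0 and called.any():
        flat = np.flatnonzero(called.ravel())
        n_def = int(round(model.defect_rate * flat.size))
        chosen = rng.choice(flat, size=min(n_def, flat.size), replace=False)
        kinds = rng.integers(0, len(DEFECT_TYPES), size=chosen.size)
        for cell, kind in zip(chosen, kinds):
            i, j = divmod(int(cell), S)
            dt = DEFECT_TYPES[kind]
            if dt == "LOWDP":
                depth[i, j] = int(rng.integers(1, min_dp))
            elif dt == "HIGHDP":
                depth[i, j] = int(rng.integers(max_dp + 1, 2 * max_dp))
            elif dt == "SPANBOUND":
                support[i, j] = (0, max(1, int(depth[i, j] * 0.7)),
                                 depth[i, j] - max(1, int(depth[i, j] * 0.7)))
            elif dt == "BADCI":
                a = int(alleles[i, j, 0])
                ci[i, j, 0] = (a + 1, a + 3)
            defect_rows.append(
                {"locus_index": i, "sample": sample_ids[j], "defect": dt}
            )

    callset = STRCallSet(loci, sample_ids, alleles, depth, support, ci, quality)
    meta = pd.DataFrame(meta_rows)
    if truth is None:
        truth = TruthTable(pop_freqs=freqs)
    truth.defects = pd.DataFrame(
        defect_rows, columns=["locus_index", "sample", "defect"]
    )
    return callset, meta, truth


def simulate_trios(
    freqs: dict[str, list[dict[int, float]]],
    n_trios: int,
    de_novo_rate: float,
    seed: int,
    loci: list[STRLocus] | None = None,
    population: str | None = None,
) -> tuple[STRCallSet, pd.DataFrame, TruthTable]:
    """Parent-offspring trios with optional de novo stepwise mutations.

    Parents are drawn from one population's spectra; each child allele is a
    uniformly chosen allele of the corresponding parent and, with
    probability ``de_novo_rate``, takes a +/-1 repeat step (recorded, with
    a flag saying whether the mutated allele escapes both parental allele
    sets and therefore breaks the Mendelian-consistency check).
    """
    if not 0.0 <= de_novo_rate <= 1.0:
        raise ValidationError("de_novo_rate must be in [0, 1]")
    population = population or next(iter(freqs))
    pop_f = freqs[population]
    L = len(pop_f)
    if loci is None:
        loci, _ = default_loci(L, seed)
    rng = substream(seed, "simulate_trios")

    fathers = _draw_alleles(pop_f, n_trios, rng)
    mothers = _draw_alleles(pop_f, n_trios, rng)
    children = np.empty_like(fathers)
    pick_f = rng.integers(0, 2, size=(L, n_trios))
    pick_m = rng.integers(0, 2, size=(L, n_trios))
    children[:, :, 0] = np.take_along_axis(fathers, pick_f[:, :, None], axis=2)[:, :, 0]
    children[:, :, 1] = np.take_along_axis(mothers, pick_m[:, :, None], axis=2)[:, :, 0]

    dn_rows = []
    if de_novo_rate > 0:
        mutate = rng.random((L, n_trios, 2)) < de_novo_rate
        steps = rng.choice([-1, 1], size=(L, n_trios, 2))
        for i, t, w in zip(*np.nonzero(mutate)):
            old = int(children[i, t, w])
            new = max(1, old + int(steps[i, t, w]))
            children[i, t, w] = new
            parental = set(fathers[i, t]) | set(mothers[i, t])
            # consistency can survive a step that lands on another
            # parental allele; record whether it breaks the check
            c0, c1 = (new, int(children[i, t, 1])) if w == 0 else (int(children[i, t, 0]), new)
            ok = _mendel_ok(c0, c1, tuple(fathers[i, t]), tuple(mothers[i, t]))
            dn_rows.append(
                {
                    "trio": t,
                    "locus_index": int(i),
                    "parent": "father" if w == 0 else "mother",
                    "old_allele": old,
                    "new_allele": new,
                    "breaks_mendel": not ok,
                }
            )

    sample_ids = []
    cols = []
    trio_rows = []
    for t in range(n_trios):
        c, f, m = f"trio{t:03d}_child", f"trio{t:03d}_father", f"trio{t:03d}_mother"
        sample_ids += [c, f, m]
        cols += [children[:, t], fathers[:, t], mothers[:, t]]
        trio_rows.append({"child": c, "father": f, "mother": m})
    alleles = (
        np.stack(cols, axis=1) if cols else np.empty((L, 0, 2), np.int32)
    ).astype(np.int32)
    alleles = np.sort(alleles, axis=2)
    depth, support, ci, quality = _qc_fields(alleles, 30.0, 20, 1000, rng)
    callset = STRCallSet(loci, sample_ids, alleles, depth, support, ci, quality)
    truth = TruthTable(
        de_novo=pd.DataFrame(
            dn_rows,
            columns=["trio", "locus_index", "parent", "old_allele", "new_allele", "breaks_mendel"],
        )
    )
    return callset, pd.DataFrame(trio_rows), truth


def _mendel_ok(c0: int, c1: int, fa: tuple, mo: tuple) -> bool:
    return (c0 in fa and c1 in mo) or (c1 in fa and c0 in mo)


def simulate_linked_snps(
    dosage_values: np.ndarray,
    targets: pd.DataFrame,
    seed: int,
    snp_maf: float = 0.5,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Bi-allelic SNP dosages (0/1/2) in calibrated LD with STR dosages.

    ``dosage_values`` is (loci, samples); ``targets`` rows carry snp,
    locus_index, chrom, pos, target_r2.  For each SNP a latent Gaussian is
    mixed from the standardized STR dosage and independent noise, then cut
    into three genotype classes; the mixing weight is calibrated by
    bisection so the realized squared Pearson correlation approximates the
    target (typically within ~0.05; exact when the STR dosage itself has
    three equally spaced levels and the target is 1).  Missing STR dosages
    are mean-imputed for construction only.
    """
    rng = substream(seed, "simulate_linked_snps")
    n = dosage_values.shape[1]
    geno = {}
    rows = []
    for row in targets.itertuples():
        x = dosage_values[row.locus_index].astype(float).copy()
        bad = ~np.isfinite(x)
        if bad.all() or np.nanstd(x) == 0:
            raise ValidationError(
                f"STR dosage constant/empty at locus {row.locus_index}; r2 undefined"
            )
        x[bad] = np.nanmean(x)
        z = (x - x.mean()) / x.std()
        eta = rng.standard_normal(n)
        levels = np.unique(x)
        if len(levels) == 3:
            # cutpoints follow the dosage's own class frequencies so a
            # 3-level dosage can be reproduced exactly at target 1
            f = np.array([(x == v).mean() for v in levels])
            cum = np.cumsum(f)[:2]
        else:
            p = snp_maf
            cum = np.array([(1 - p) ** 2, (1 - p) ** 2 + 2 * p * (1 - p)])

        def realized(a: float) -> tuple[float, np.ndarray]:
            latent = a * z + np.sqrt(max(0.0, 1 - a * a)) * eta
            cuts = np.quantile(latent, cum)
            g = np.digitize(latent, cuts, right=False).astype(float)
            if g.std() == 0 or x.std() == 0:
                return 0.0, g
            r = np.corrcoef(g, x)[0, 1]
            return float(r * r), g

        lo, hi = 0.0, 1.0
        best_g, best_r2 = None, None
        for _ in range(40):
            a = 0.5 * (lo + hi)
            r2, g = realized(a)
            if best_g is None or abs(r2 - row.target_r2) < abs(best_r2 - row.target_r2):
                best_g, best_r2 = g, r2
            if r2 < row.target_r2:
                lo = a
            else:
                hi = a
        for a in (0.0, 1.0):
            r2, g = realized(a)
            if abs(r2 - row.target_r2) < abs(best_r2 - row.target_r2):
                best_g, best_r2 = g, r2
        geno[row.snp] = best_g.astype(np.int8)
        rows.append(
            {
                "snp": row.snp,
                "locus_index": int(row.locus_index),
                "chrom": row.chrom,
                "pos": int(row.pos),
                "target_r2": float(row.target_r2),
                "realized_r2": float(best_r2),
            }
        )
    table = pd.DataFrame(geno, index=samples if samples is not None else [f"S{j}" for j in range(n)])
    truth = TruthTable(snps=pd.DataFrame(rows))
    return table, truth


def simulate_expression(
    dosage_values: np.ndarray,
    samples: list[str],
    loci: list[STRLocus],
    effects: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    noise_sd: float = 1.0,
    bounded: bool = False,
    seed: int = 0,
    n_null_features: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Feature x sample matrix with planted linear dosage effects.

    ``effects`` rows carry feature, locus_index, beta; each feature's value
    is beta * dosage + covariate effects + Gaussian noise.  ``bounded``
    squashes values through a logistic into [0, 1], emulating PDUI
    (distal poly(A)-site usage) indices.  ``n_null_features`` appends
    pure-noise features anchored near randomly chosen loci (beta recorded
    as 0).  Missing dosages are mean-imputed for generation.  Feature
    coordinates are placed at the anchor locus so the feature lies inside
    any reasonable scan window.
    """
    rng = substream(seed, "simulate_expression")
    effects = effects.copy()
    if n_null_features:
        anchors = rng.integers(0, len(loci), size=n_null_features)
        null = pd.DataFrame(
            {
                "feature": [f"null{k:04d}" for k in range(n_null_features)],
                "locus_index": anchors,
                "beta": 0.0,
            }
        )
        effects = pd.concat([effects, null], ignore_index=True)

    n = len(samples)
    gamma = None
    covs = None
    if covariates is not None:
        covs = covariates.loc[samples].to_numpy(dtype=float)
    values = {}
    coords_rows = []
    for row in effects.itertuples():
        x = dosage_values[row.locus_index].astype(float).copy()
        x[~np.isfinite(x)] = np.nanmean(x)
        y = row.beta * x
        if covs is not None:
            gamma = rng.standard_normal(covs.shape[1])
            y = y + covs @ gamma
        if noise_sd > 0:
            y = y + noise_sd * rng.standard_normal(n)
        if bounded:
            y = 1.0 / (1.0 + np.exp(-y))
        values[row.feature] = y
        lo = loci[row.locus_index]
        coords_rows.append(
            {
                "feature": row.feature,
                "chrom": lo.chrom,
                "start": max(0, lo.start - 2_000),
                "end": lo.end + 10_000,
                "strand": "+",
            }
        )
    matrix = pd.DataFrame(values, index=samples).T
    coords = pd.DataFrame(coords_rows)
    truth = TruthTable(effects=effects.reset_index(drop=True))
    return matrix, coords, truth


def simulate_layout(
    n_chrom: int,
    arm_length: int,
    telomeric_factor: float,
    n_loci: int,
    seed: int,
    centromere_width: int = 3_000_000,
    motif: str = "AC",
    ref_repeats: int = 12,
) -> tuple[GenomeLayout, list[STRLocus], TruthTable]:
    """Genome layout with loci placed uniformly, subtelomeres upweighted.

    Each chromosome has equal p and q arms separated by a centromere; locus
    density inside the outermost ``SUBTELOMERE_SPAN`` of every arm is
    multiplied by ``telomeric_factor``.
    """
    if arm_length <= SUBTELOMERE_SPAN:
        raise ValidationError("arm_length must exceed the subtelomeric span")
    rng = substream(seed, "simulate_layout")
    chroms = {}
    segments = []  # (chrom, seg_start, seg_end, weight)
    for c in range(n_chrom):
        name = f"chr{c + 1:02d}"
        length = 2 * arm_length + centromere_width
        cs, ce = arm_length, arm_length + centromere_width
        chroms[name] = (length, cs, ce)
        st = SUBTELOMERE_SPAN
        segments += [
            (name, 0, st, telomeric_factor * st),
            (name, st, cs, float(cs - st)),
            (name, ce, length - st, float(length - st - ce)),
            (name, length - st, length, telomeric_factor * st),
        ]
    weights = np.array([s[3] for s in segments])
    weights = weights / weights.sum()
    pick = rng.choice(len(segments), size=n_loci, p=weights)
    tract = ref_repeats * len(motif)
    positions: dict[str, list[int]] = {c: [] for c in chroms}
    for k in pick:
        chrom, s0, s1, _ = segments[k]
        positions[chrom].append(int(rng.integers(s0, s1 - tract)))
    loci = []
    for chrom in sorted(positions):
        for start in sorted(positions[chrom]):
            loci.append(STRLocus(chrom, start, start + tract, motif, ref_repeats))
    layout = GenomeLayout(chroms)
    return layout, loci, TruthTable(telomeric_factor=telomeric_factor)
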