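"""Population-level STR analyses.

Per-sample variation summaries, SNP heterozygosity and STR diversity, PCA
on STR dosages, cross-population sharing of polymorphic loci, length and
variance differentiation between groups, the Rst fixation index, highly
variable loci, expansion scores, and downsampling saturation curves.

Observation conventions (the field mixes two): where an analysis compares
per-individual repeat "length", the two alleles are combined (a + b) into
one observation per sample — this applies to the rank-sum length
comparison and to Rst.  Where an analysis summarizes the allele
distribution itself (variance/SD of allele length, expansion scores), both
alleles of each individual enter as separate observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    STRCallSet,
    ValidationError,
    allele_spectrum,
    dosage_matrix,
    spectrum_het,
)
from .rng import substream

__all__ = [
    "sample_summaries",
    "diversity_stats",
    "pca_dosage",
    "population_sharing",
    "length_compare",
    "rst",
    "highly_variable",
    "sd_diff_perm",
    "expansion_scores",
    "saturation_curve",
]


def _group_indices(callset: STRCallSet, groups: dict[str, list[str]]) -> dict[str, np.ndarray]:
    pos = {s: j for j, s in enumerate(callset.samples)}
    out = {}
    for g, members in groups.items():
        idx = [pos[s] for s in members if s in pos]
        out[g] = np.array(idx, dtype=int)
    return out


def _pooled_alleles(callset: STRCallSet, i: int, idx: np.ndarray) -> np.ndarray:
    """Both alleles of every called sample in idx, flattened."""
    pairs = callset.alleles[i, idx]
    pairs = pairs[pairs[:, 0] >= 0]
    return pairs.ravel().astype(float)


def _combined_lengths(callset: STRCallSet, i: int, idx: np.ndarray) -> np.ndarray:
    """Per-sample combined length a + b for called samples in idx."""
    pairs = callset.alleles[i, idx]
    pairs = pairs[pairs[:, 0] >= 0]
    return pairs.sum(axis=1).astype(float)


def sample_summaries(callset: STRCallSet) -> pd.DataFrame:
    """Per-sample counts of loci carrying a non-reference allele.

    Split by heterozygous/homozygous state and by motif length, with the
    het/hom ratio (NaN when no homozygous non-reference locus).
    """
    ref = callset.ref_repeats()[:, None]
    a, b = callset.alleles[:, :, 0], callset.alleles[:, :, 1]
    called = a >= 0
    nonref = called & ((a != ref) | (b != ref))
    het = nonref & (a != b)
    hom = nonref & (a == b)
    motif_len = np.array([lo.motif_length for lo in callset.loci])

    rows = []
    for j, s in enumerate(callset.samples):
        row = {
            "sample": s,
            "n_nonref": int(nonref[:, j].sum()),
            "n_het_nonref": int(het[:, j].sum()),
            "n_hom_nonref": int(hom[:, j].sum()),
        }
        row["het_hom_ratio"] = (
            row["n_het_nonref"] / row["n_hom_nonref"] if row["n_hom_nonref"] else np.nan
        )
        for ml in range(2, 7):
            row[f"n_nonref_motif{ml}"] = int(nonref[motif_len == ml, j].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def diversity_stats(
    callset: STRCallSet,
    snp_het_counts: pd.Series,
    meta: pd.DataFrame,
    autosome_length: float,
    group_col: str = "population",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample SNP heterozygosity and per-population STR diversity.

    SNP heterozygosity is the heterozygous bi-allelic SNP count divided by
    the genome length considered.  STR diversity of a population is the
    mean, over unordered sample pairs, of the number of loci at which the
    two genotype multisets differ (loci missing in either member skipped);
    undefined (NaN) for populations with < 2 samples.
    """
    if autosome_length <= 0:
        raise ValidationError("autosome_length must be positive")
    het = pd.DataFrame(
        {
            "sample": snp_het_counts.index,
            "snp_het": snp_het_counts.to_numpy(dtype=float) / autosome_length,
        }
    )
    groups = meta.groupby(group_col)["sample"].apply(list).to_dict()
    gidx = _group_indices(callset, groups)
    a = callset.alleles
    div = {}
    for g, idx in sorted(gidx.items()):
        if len(idx) < 2:
            div[g] = np.nan
            continue
        diffs = []
        for u in range(len(idx)):
            for v in range(u + 1, len(idx)):
                pi, pj = a[:, idx[u]], a[:, idx[v]]
                ok = (pi[:, 0] >= 0) & (pj[:, 0] >= 0)
                diffs.append(int(np.sum((pi[ok] != pj[ok]).any(axis=1))))
        div[g] = float(np.mean(diffs))
    return het, pd.Series(div, name="str_diversity")


def pca_dosage(
    callset: STRCallSet,
    max_major_af: float = 0.95,
    n_components: int = 10,
    mode: str = "repeat_sum",
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the per-sample dosage matrix.

    Loci with major allele frequency >= ``max_major_af`` are removed
    (near-monomorphic loci contribute noise only); missing dosages are
    mean-imputed per locus; columns centered; scores from SVD with a
    deterministic sign convention (the largest-magnitude loading of each
    component is positive).  Returns (samples x PCs scores, explained
    variance ratios).
    """
    keep = []
    for i in range(callset.n_loci):
        spec = allele_spectrum(callset, i)
        if spec.total == 0:
            continue
        if spec.counts[spec.major_allele] / spec.total < max_major_af:
            keep.append(i)
    if len(keep) < 2 or callset.n_samples < 2:
        raise ValidationError("need >= 2 samples and >= 2 loci after the AF filter")
    dos = dosage_matrix(callset.subset(loci=keep), mode=mode)
    X = dos.values.T.copy()  # samples x loci
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(~np.isfinite(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    for c in range(k):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    scores = U[:, :k] * S[:k]
    var = S**2 / np.sum(S**2)
    return (
        pd.DataFrame(
            scores, index=callset.samples, columns=[f"PC{c + 1}" for c in range(k)]
        ),
        var[:k],
    )


def population_sharing(
    callset: STRCallSet, meta: pd.DataFrame, group_col: str = "population"
) -> pd.DataFrame:
    """Unique / Shared / All classification of polymorphic loci per population.

    A locus "exists in" a population when >= 2 distinct alleles are
    observed among that population's called samples.  For each population,
    its polymorphic loci are classed Unique (no other population
    polymorphic), All (polymorphic in every population), or Shared
    (somewhere in between).
    """
    groups = meta.groupby(group_col)["sample"].apply(list).to_dict()
    gidx = _group_indices(callset, groups)
    pops = sorted(gidx)
    poly = np.zeros((callset.n_loci, len(pops)), dtype=bool)
    for c, g in enumerate(pops):
        idx = gidx[g]
        for i in range(callset.n_loci):
            alleles = _pooled_alleles(callset, i, idx)
            poly[i, c] = len(np.unique(alleles)) > 1
    n_pops_poly = poly.sum(axis=1)
    rows = []
    for c, g in enumerate(pops):
        mine = poly[:, c]
        rows.append(
            {
                "population": g,
                "n_polymorphic": int(mine.sum()),
                "unique": int((mine & (n_pops_poly == 1)).sum()),
                "all": int((mine & (n_pops_poly == len(pops))).sum()),
                "shared": int(
                    (mine & (n_pops_poly > 1) & (n_pops_poly < len(pops))).sum()
                ),
            }
        )
    return pd.DataFrame(rows)


def length_compare(
    callset: STRCallSet,
    groups: dict[str, list[str]],
    min_het: float = 0.1,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of combined repeat lengths, two groups.

    Per locus with pooled heterozygosity > ``min_het``: the per-sample
    combined length (a + b, repeat units) distributions of the two groups
    are compared two-sidedly; BH adjustment across loci; significance at
    adjusted p < ``alpha``.  Mean difference is group B minus group A in
    the order given.
    """
    if len(groups) != 2:
        raise ValidationError("length_compare requires exactly two groups")
    (ga, sa), (gb, sb) = groups.items()
    gidx = _group_indices(callset, {ga: sa, gb: sb})
    both = np.concatenate([gidx[ga], gidx[gb]])
    rows = []
    for i, lo in enumerate(callset.loci):
        spec = allele_spectrum(callset, i, list(both))
        if spec.total == 0 or spectrum_het(spec) <= min_het:
            continue
        xa = _combined_lengths(callset, i, gidx[ga])
        xb = _combined_lengths(callset, i, gidx[gb])
        if len(xa) < 2 or len(xb) < 2:
            continue
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            stat, p = 0.0, 1.0
        else:
            # asymptotic normal approximation with tie correction and
            # continuity, the standard large-sample rank-sum treatment
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "locus_index": i,
                "chrom": lo.chrom,
                "start": lo.start,
                "motif": lo.motif,
                "n_a": len(xa),
                "n_b": len(xb),
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "mean_diff": float(xb.mean() - xa.mean()),
                "stat": stat,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["locus_index", "chrom", "start", "motif", "n_a", "n_b",
                 "mean_a", "mean_b", "mean_diff", "stat", "p"],
    )
    if len(table):
        _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table["q"] = q
        table["significant"] = table["q"] < alpha
        table["neg_log10_q"] = -np.log10(np.maximum(table["q"], 1e-300))
    else:
        table["q"] = table["significant"] = table["neg_log10_q"] = pd.Series(dtype=float)
    return table


def rst(
    callset: STRCallSet,
    groups: dict[str, list[str]],
    min_het: float | None = 0.1,
    observations: str = "combined",
) -> tuple[pd.DataFrame, pd.Series]:
    """Rst fixation index per locus and its unweighted mean by motif length.

    Rst = (St - Sw) / St where St is the variance of repeat lengths over
    all individuals pooled and Sw the unweighted mean of the
    within-population variances (population-variance convention,
    denominator N).  Observations are per-individual combined lengths
    (a + b) by default; ``observations="pooled_alleles"`` treats each
    allele separately.  Loci with St = 0 are undefined (NaN).  With
    ``min_het`` set, loci at or below that pooled heterozygosity are
    skipped.
    """
    if observations not in ("combined", "pooled_alleles"):
        raise ValidationError(f"unknown observation mode {observations!r}")
    extract = _combined_lengths if observations == "combined" else _pooled_alleles
    gidx = _group_indices(callset, groups)
    all_idx = np.concatenate(list(gidx.values()))
    rows = []
    for i, lo in enumerate(callset.loci):
        if min_het is not None:
            spec = allele_spectrum(callset, i, list(all_idx))
            if spec.total == 0 or spectrum_het(spec) <= min_het:
                continue
        per_group = [extract(callset, i, idx) for idx in gidx.values()]
        if any(len(v) < 2 for v in per_group):
            continue
        pooled = np.concatenate(per_group)
        st = float(np.var(pooled))
        sw = float(np.mean([np.var(v) for v in per_group]))
        rows.append(
            {
                "locus_index": i,
                "chrom": lo.chrom,
                "start": lo.start,
                "motif_length": lo.motif_length,
                "St": st,
                "Sw": sw,
                "rst": (st - sw) / st if st > 0 else np.nan,
            }
        )
    table = pd.DataFrame(
        rows, columns=["locus_index", "chrom", "start", "motif_length", "St", "Sw", "rst"]
    )
    by_motif = (
        table.dropna(subset=["rst"]).groupby("motif_length")["rst"].mean()
        if len(table)
        else pd.Series(dtype=float)
    )
    return table, by_motif


def highly_variable(
    callset: STRCallSet,
    group: list[str],
    min_het: float = 0.1,
    top_frac: float = 0.05,
) -> tuple[list[int], pd.DataFrame]:
    """Loci in the top ``top_frac`` of within-group allele-length variance.

    Eligibility requires within-group heterozygosity > ``min_het``.
    Variance pools both alleles of each individual.  All loci tied with
    the cutoff variance are included.
    """
    pos = {s: j for j, s in enumerate(callset.samples)}
    idx = np.array([pos[s] for s in group if s in pos])
    rows = []
    for i, lo in enumerate(callset.loci):
        spec = allele_spectrum(callset, i, list(idx))
        if spec.total == 0 or spectrum_het(spec) <= min_het:
            continue
        alleles = _pooled_alleles(callset, i, idx)
        rows.append({"locus_index": i, "variance": float(np.var(alleles))})
    table = pd.DataFrame(rows, columns=["locus_index", "variance"])
    if table.empty:
        return [], table
    n_top = max(1, int(np.ceil(top_frac * len(table))))
    cutoff = table["variance"].sort_values(ascending=False).iloc[n_top - 1]
    chosen = sorted(table.loc[table["variance"] >= cutoff, "locus_index"].tolist())
    return chosen, table


def sd_diff_perm(
    callset: STRCallSet,
    group_a: list[str],
    group_b: list[str],
    min_het: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Permutation test of the allele-length SD difference between groups.

    Per eligible locus (pooled heterozygosity > ``min_het``, >= 2 called
    samples per group): observed diff = SD(group A) - SD(group B) over
    pooled allele lengths; sample labels are shuffled between groups
    (each sample's two alleles travel together) ``n_perm`` times and the
    empirical p is the fraction of permutations with |perm diff| >=
    |observed diff|.  BH adjustment across loci; significant at adjusted
    p < ``alpha``.
    """
    gidx = _group_indices(callset, {"a": group_a, "b": group_b})
    ia, ib = gidx["a"], gidx["b"]
    rng = substream(seed, "sd_diff_perm")
    rows = []
    for i, lo in enumerate(callset.loci):
        both = np.concatenate([ia, ib])
        spec = allele_spectrum(callset, i, list(both))
        if spec.total == 0 or spectrum_het(spec) <= min_het:
            continue
        pa = callset.alleles[i, ia]
        pb = callset.alleles[i, ib]
        pa = pa[pa[:, 0] >= 0]
        pb = pb[pb[:, 0] >= 0]
        na, nb = len(pa), len(pb)
        if na < 2 or nb < 2:
            continue
        obs = float(np.std(pa.ravel()) - np.std(pb.ravel()))
        pool = np.vstack([pa, pb]).astype(float)  # (na+nb, 2)
        # vectorized label shuffles: rows of `order` are permutations
        keys = rng.random((n_perm, na + nb))
        order = np.argsort(keys, axis=1)
        sel_a = order[:, :na]
        sel_b = order[:, na:]
        flat = pool  # alleles travel with their sample
        va = flat[sel_a].reshape(n_perm, -1)
        vb = flat[sel_b].reshape(n_perm, -1)
        perm_diff = va.std(axis=1) - vb.std(axis=1)
        p = float(np.mean(np.abs(perm_diff) >= abs(obs)))
        rows.append(
            {
                "locus_index": i,
                "chrom": lo.chrom,
                "start": lo.start,
                "n_a": na,
                "n_b": nb,
                "sd_a": float(np.std(pa.ravel())),
                "sd_b": float(np.std(pb.ravel())),
                "sd_diff": obs,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["locus_index", "chrom", "start", "n_a", "n_b", "sd_a", "sd_b",
                 "sd_diff", "p"],
    )
    if len(table):
        _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table["q"] = q
        table["significant"] = table["q"] < alpha
    else:
        table["q"] = table["significant"] = pd.Series(dtype=float)
    return table


def expansion_scores(
    callset: STRCallSet, group: list[str] | None = None
) -> pd.DataFrame:
    """Expansion score (P95 - median) / median of pooled allele lengths.

    Percentiles use linear interpolation between order statistics.  A
    locus with score >= 2 is flagged expanded: its long tail reaches at
    least triple the typical repeat length, the pattern of an expanding
    repeat.
    """
    if group is None:
        idx = np.arange(callset.n_samples)
    else:
        pos = {s: j for j, s in enumerate(callset.samples)}
        idx = np.array([pos[s] for s in group if s in pos])
    rows = []
    for i, lo in enumerate(callset.loci):
        alleles = _pooled_alleles(callset, i, idx)
        if len(alleles) < 4:
            continue
        med = float(np.median(alleles))
        p95 = float(np.percentile(alleles, 95))
        score = (p95 - med) / med if med > 0 else np.nan
        rows.append(
            {
                "locus_index": i,
                "chrom": lo.chrom,
                "start": lo.start,
                "motif": lo.motif,
                "median": med,
                "p95": p95,
                "score": score,
                "expanded": bool(np.isfinite(score) and score >= 2.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_index", "chrom", "start", "motif", "median", "p95",
                 "score", "expanded"],
    )


def saturation_curve(
    callset: STRCallSet,
    step: int = 100,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Polymorphic-locus discovery as a function of cohort size.

    For sample sizes step, 2*step, ..., N: draw that many samples without
    replacement and count loci polymorphic (>= 2 distinct observed
    alleles) within the draw, repeated ``n_reps`` times.  The full-cohort
    point is exact by construction.
    """
    N = callset.n_samples
    if step > N:
        raise ValidationError("step exceeds the number of samples")
    sizes = list(range(step, N + 1, step))
    if sizes[-1] != N:
        sizes.append(N)
    rng = substream(seed, "saturation_curve")
    a = callset.alleles
    rows = []
    for k in sizes:
        counts = []
        for _ in range(n_reps):
            pick = rng.choice(N, size=k, replace=False)
            sub = a[:, pick]
            called = sub[:, :, 0] >= 0
            lo = np.where(called, sub[:, :, 0], np.iinfo(np.int32).max).min(axis=1)
            hi = np.where(called, sub[:, :, 1], np.iinfo(np.int32).min).max(axis=1)
            any_called = called.any(axis=1)
            counts.append(int(np.sum(any_called & (hi > lo))))
        rows.append(
            {
                "n_samples": k,
                "mean_pstr": float(np.mean(counts)),
                "sd_pstr": float(np.std(counts, ddof=1)) if n_reps > 1 else 0.0,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
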