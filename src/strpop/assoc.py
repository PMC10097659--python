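"""STR-dosage association with expression and 3'UTR APA, hierarchical FDR.

The scan mirrors the standard cis-eQTL design for tandem repeats: feature
values (log-scale expression, or PDUI alternative-polyadenylation indices)
are first residualized on known covariates (sex, genotype principal
components, hidden factors supplied by the caller); each feature is then
paired with every STR whose tract lies within a window of the feature's
span, and a simple linear model value ~ dosage is fit per pair, where
dosage is the summed deviation of the two repeat counts from the
reference.  Multiple testing is controlled hierarchically: Bonferroni
within feature over its STRs, then Benjamini-Hochberg across features on
each feature's best Bonferroni-adjusted p, at a feature-level FDR of 10%.
Each significant feature reports one best STR, so significant pairs and
significant features are in bijection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import STRCallSet, ValidationError, allele_spectrum, spectrum_het
from .ld import genotype_count_filter
from .rng import substream

__all__ = [
    "residualize",
    "assoc_scan",
    "hierarchical_fdr",
    "permutation_control",
]


def residualize(values: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of each feature (row) on the covariates (+ intercept).

    Raises on a rank-deficient design, naming the collinear columns.
    """
    samples = list(values.columns)
    missing = [s for s in samples if s not in covariates.index]
    if missing:
        raise ValidationError(f"covariates missing for samples: {missing[:5]}")
    X = np.column_stack(
        [np.ones(len(samples)), covariates.loc[samples].to_numpy(dtype=float)]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the correlation scale
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [
            (["intercept"] + list(covariates.columns))[k]
            for k in np.where(diag < 1e-10 * diag.max())[0]
        ]
        raise ValidationError(f"rank-deficient covariate design; collinear: {bad}")
    Y = values.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=values.index, columns=values.columns)


def _locus_filters(
    callset: STRCallSet,
    cohort_idx: np.ndarray,
    min_called: int,
    min_het: float,
    min_genotype_count: int,
    min_distinct_genotypes: int,
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Apply the per-locus dosage filters; returns usable sample masks + drop log."""
    usable: dict[int, np.ndarray] = {}
    drops = []
    for i in range(callset.n_loci):
        pairs = callset.alleles[i, cohort_idx]
        called = pairs[:, 0] >= 0
        if called.sum() < min_called:
            drops.append({"locus_index": i, "reason": "MIN_CALLED"})
            continue
        spec = allele_spectrum(callset, i, list(cohort_idx))
        if spectrum_het(spec) < min_het:
            drops.append({"locus_index": i, "reason": "MIN_HET"})
            continue
        keep = genotype_count_filter(pairs, min_genotype_count)
        distinct = {tuple(p) for p, k in zip(pairs, keep) if k}
        if len(distinct) < min_distinct_genotypes:
            drops.append({"locus_index": i, "reason": "MIN_GENOTYPES"})
            continue
        usable[i] = keep
    return usable, pd.DataFrame(drops, columns=["locus_index", "reason"])


def assoc_scan(
    adjusted: pd.DataFrame,
    coords: pd.DataFrame,
    callset: STRCallSet,
    window: int = 500_000,
    min_called: int = 50,
    min_het: float = 0.1,
    min_genotype_count: int = 3,
    min_distinct_genotypes: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed linear-model scan of features against STR dosages.

    ``adjusted`` is features x samples (already residualized); ``coords``
    carries feature, chrom, start, end, strand.  Filters run in order per
    locus: called in >= ``min_called`` cohort samples; heterozygosity >=
    ``min_het``; unordered genotypes seen < ``min_genotype_count`` times
    removed; locus discarded if < ``min_distinct_genotypes`` genotypes
    remain.  Dosage is deviation-sum (slope and p are invariant to the
    dosage offset).  Returns the association table and a per-locus drop
    log with reason codes.
    """
    cohort = [s for s in callset.samples if s in set(adjusted.columns)]
    if not cohort:
        raise ValidationError("no shared samples between feature matrix and call set")
    pos = {s: j for j, s in enumerate(callset.samples)}
    cohort_idx = np.array([pos[s] for s in cohort])

    usable, drop_log = _locus_filters(
        callset, cohort_idx, min_called, min_het, min_genotype_count,
        min_distinct_genotypes,
    )
    ref = callset.ref_repeats().astype(float)
    rows = []
    coords_idx = coords.set_index("feature")
    for feature in adjusted.index:
        if feature not in coords_idx.index:
            continue
        fc = coords_idx.loc[feature]
        y_full = adjusted.loc[feature, cohort].to_numpy(dtype=float)
        for i, lo in enumerate(callset.loci):
            if i not in usable or lo.chrom != fc["chrom"]:
                continue
            # distance 0 inside the feature span, else the gap
            if lo.end <= fc["start"]:
                dist = fc["start"] - lo.end
            elif lo.start >= fc["end"]:
                dist = lo.start - fc["end"]
            else:
                dist = 0
            if dist > window:
                continue
            pairs = callset.alleles[i, cohort_idx].astype(float)
            x = pairs[:, 0] + pairs[:, 1] - 2.0 * ref[i]
            ok = usable[i] & np.isfinite(y_full)
            if ok.sum() < 3 or np.std(x[ok]) == 0:
                continue
            fit = stats.linregress(x[ok], y_full[ok])
            rows.append(
                {
                    "feature": feature,
                    "locus_index": i,
                    "chrom": lo.chrom,
                    "start": lo.start,
                    "n": int(ok.sum()),
                    "beta": float(fit.slope),
                    "se": float(fit.stderr),
                    "p": float(fit.pvalue),
                }
            )
    table = pd.DataFrame(
        rows, columns=["feature", "locus_index", "chrom", "start", "n", "beta", "se", "p"]
    )
    return table, drop_log


def hierarchical_fdr(table: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Gene-level hierarchical FDR over an association table.

    Per feature: Bonferroni-adjust its pair p-values by the number of STRs
    tested for that feature and take the smallest; BH-adjust these
    feature-level p-values across features; a feature with q < ``alpha``
    is significant and its reported pair is the argmin-p STR (ties broken
    toward the smaller genomic coordinate).
    """
    if table.empty:
        raise ValidationError("hierarchical FDR needs at least one association row")
    out = table.copy()
    m = out.groupby("feature")["p"].transform("size")
    out["bonferroni_p_within_feature"] = np.minimum(1.0, out["p"] * m)

    best_rows = (
        out.sort_values(["p", "chrom", "start"], kind="mergesort")
        .groupby("feature", sort=True)
        .head(1)
        .set_index("feature")
    )
    feature_p = best_rows["bonferroni_p_within_feature"]
    _, qvals, _, _ = multipletests(feature_p.to_numpy(), method="fdr_bh")
    feature_q = pd.Series(qvals, index=feature_p.index)

    out["feature_q"] = out["feature"].map(feature_q)
    out["significant"] = False
    sig_features = feature_q.index[feature_q < alpha]
    best_pair_index = best_rows.loc[best_rows.index.isin(sig_features)]
    # flag only the representative pair of each significant feature
    key = set(zip(best_pair_index.index, best_pair_index["locus_index"]))
    out["significant"] = [
        (f, l) in key for f, l in zip(out["feature"], out["locus_index"])
    ]
    return out


def permutation_control(
    adjusted: pd.DataFrame,
    coords: pd.DataFrame,
    callset: STRCallSet,
    seed: int = 0,
    **scan_kwargs,
) -> pd.DataFrame:
    """Negative control: shuffle sample identifiers once and re-run the scan.

    Breaking the genotype-phenotype link this way leaves every marginal
    distribution intact, so the returned p-values should be uniform.
    """
    rng = substream(seed, "permutation_control")
    perm = rng.permutation(len(adjusted.columns))
    shuffled = adjusted.copy()
    shuffled.columns = [adjusted.columns[k] for k in perm]
    table, _ = assoc_scan(shuffled, coords, callset, **scan_kwargs)
    return table
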