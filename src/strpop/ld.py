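"""STR-SNP linkage disequilibrium, GWAS tagging, and resampling enrichment.

LD between an STR and a SNP is the squared Pearson correlation between the
STR dosage (sum of the two repeat counts) and the SNP dosage (0/1/2),
computed over samples with both genotypes present.  A pair with
r^2 >= 0.7 is in strong LD ("tagged").  Only STRs within 250 kb of a GWAS
risk SNP are considered, and samples carrying an STR genotype seen fewer
than three times in the cohort are dropped before correlation — rare
genotypes are disproportionately genotyping errors and act as leverage
points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import STRCallSet, ValidationError, dosage_matrix
from .rng import substream

__all__ = [
    "DEFAULT_EXCLUDED_TRAITS",
    "read_gwas_catalog",
    "str_snp_r2",
    "genotype_count_filter",
    "tag_gwas",
    "tag_enrichment",
]

#: traits excluded at catalog load (strongly environmentally confounded)
DEFAULT_EXCLUDED_TRAITS = (
    "educational attainment",
    "mathematical ability",
    "intelligence",
)

GWAS_P_THRESHOLD = 5e-8


def read_gwas_catalog(
    path: str,
    p_threshold: float = GWAS_P_THRESHOLD,
    exclude_traits: tuple[str, ...] = DEFAULT_EXCLUDED_TRAITS,
) -> pd.DataFrame:
    """Load a GWAS-catalog-like TSV (snp, chrom, pos, trait, p) and filter.

    Rows with p above ``p_threshold`` are dropped; SNPs whose traits are
    all in ``exclude_traits`` are removed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str, "trait": str})
    for col in ("snp", "chrom", "pos", "trait", "p"):
        if col not in df.columns:
            raise ValidationError(f"GWAS catalog missing column {col!r}")
    df = df[df["p"] <= p_threshold]
    excluded = {t.lower() for t in exclude_traits}
    keep_snps = (
        df.groupby("snp")["trait"]
        .apply(lambda ts: not set(t.lower() for t in ts) <= excluded)
    )
    return df[df["snp"].map(keep_snps)].reset_index(drop=True)


def str_snp_r2(str_dosage: np.ndarray, snp_dosage: np.ndarray) -> float:
    """Squared Pearson correlation over complete-case samples.

    Returns NaN (undefined, not zero) when fewer than 3 complete cases
    remain or either vector is constant.
    """
    x = np.asarray(str_dosage, dtype=float)
    y = np.asarray(snp_dosage, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def genotype_count_filter(
    pairs: np.ndarray, min_count: int = 3
) -> np.ndarray:
    """Mask of samples whose unordered STR genotype occurs >= min_count times.

    ``pairs`` is (n, 2) sorted allele pairs with missing < 0; missing
    samples are masked out.
    """
    called = pairs[:, 0] >= 0
    keys = [tuple(p) for p in pairs]
    counts: dict[tuple, int] = {}
    for k, c in zip(keys, called):
        if c:
            counts[k] = counts.get(k, 0) + 1
    return np.array(
        [c and counts[k] >= min_count for k, c in zip(keys, called)], dtype=bool
    )


def tag_gwas(
    callset: STRCallSet,
    snp_genotypes: pd.DataFrame,
    catalog: pd.DataFrame,
    window: int = 250_000,
    min_genotype_count: int = 3,
    r2_threshold: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LD between every pSTR and GWAS risk SNP within ``window`` bp.

    ``snp_genotypes`` is samples x SNP-id dosages (0/1/2; NaN missing);
    catalog SNPs without genotype columns are skipped.  Returns the
    per-pair table (locus_index, snp, distance, r2, n, tagged, traits) and
    a per-STR summary with the max r^2 over tagging SNPs and the union of
    traits of all tagging SNPs.
    """
    dos = dosage_matrix(callset, mode="repeat_sum")
    sample_order = [s for s in callset.samples if s in snp_genotypes.index]
    snp_mat = snp_genotypes.loc[sample_order]
    pos_in_callset = {s: j for j, s in enumerate(callset.samples)}
    cohort_idx = np.array([pos_in_callset[s] for s in sample_order])

    traits_by_snp = catalog.groupby("snp")["trait"].apply(lambda t: sorted(set(t)))
    snp_info = catalog.drop_duplicates("snp").set_index("snp")

    pair_rows = []
    for snp in snp_info.index:
        if snp not in snp_mat.columns:
            continue
        chrom = snp_info.loc[snp, "chrom"]
        pos = int(snp_info.loc[snp, "pos"])
        y_full = snp_mat[snp].to_numpy(dtype=float)
        for i, lo in enumerate(callset.loci):
            if lo.chrom != chrom:
                continue
            dist = 0 if lo.start <= pos < lo.end else min(
                abs(pos - (lo.end - 1)), abs(lo.start - pos)
            )
            if dist > window:
                continue
            pairs = callset.alleles[i, cohort_idx]
            keep = genotype_count_filter(pairs, min_genotype_count)
            x = dos.values[i, cohort_idx].copy()
            x[~keep] = np.nan
            r2 = str_snp_r2(x, y_full)
            n_used = int(np.sum(np.isfinite(x) & np.isfinite(y_full)))
            pair_rows.append(
                {
                    "locus_index": i,
                    "chrom": lo.chrom,
                    "start": lo.start,
                    "snp": snp,
                    "snp_pos": pos,
                    "distance": int(dist),
                    "r2": r2,
                    "n": n_used,
                    "tagged": bool(np.isfinite(r2) and r2 >= r2_threshold),
                    "traits": ";".join(traits_by_snp.get(snp, [])),
                }
            )
    pairs_df = pd.DataFrame(
        pair_rows,
        columns=["locus_index", "chrom", "start", "snp", "snp_pos", "distance",
                 "r2", "n", "tagged", "traits"],
    )
    if len(pairs_df):
        per_str = (
            pairs_df.groupby("locus_index")
            .apply(
                lambda g: pd.Series(
                    {
                        "max_r2": g["r2"].max(),
                        "tagged": bool(g["tagged"].any()),
                        "traits": ";".join(
                            sorted(
                                set(
                                    t
                                    for ts in g.loc[g["tagged"], "traits"]
                                    for t in ts.split(";")
                                    if t
                                )
                            )
                        ),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
        )
    else:
        per_str = pd.DataFrame(columns=["locus_index", "max_r2", "tagged", "traits"])
    return pairs_df, per_str


def tag_enrichment(
    tested_loci: list,
    focal_subset: list,
    tagged_set: set,
    n_resample: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical enrichment of GWAS-tagged loci in a focal subset.

    Draws |focal_subset| loci without replacement from ``tested_loci``
    ``n_resample`` times and counts draws whose tagged-locus count is >=
    the observed count; p is that fraction.
    """
    tested = list(tested_loci)
    focal = set(focal_subset)
    if not focal <= set(tested):
        raise ValidationError("focal subset must be contained in tested loci")
    tagged_flags = np.array([x in tagged_set for x in tested])
    observed = sum(1 for x in focal if x in tagged_set)
    k = len(focal)
    rng = substream(seed, "tag_enrichment")
    counts = np.empty(n_resample, dtype=int)
    n = len(tested)
    for r in range(n_resample):
        counts[r] = tagged_flags[rng.choice(n, size=k, replace=False)].sum()
    return {
        "observed": int(observed),
        "expected": float(counts.mean()),
        "p": float(np.mean(counts >= observed)),
        "n_resample": n_resample,
        "n_focal": k,
        "n_tested": n,
    }
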