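"""Chromosome-context analyses of STR density.

Three views of where STRs sit along chromosomes:

* subtelomeric enrichment — mean locus count in the outermost 5 Mbp of each
  chromosome arm versus all other 1 Mbp arm bins, with a permutation test
  that exchanges bin sums;
* meta-chromosome profile — 100 kb bin counts smoothed by an 11-bin rolling
  mean, mapped to arm-normalized positions (-1 p-telomere, 0 centromere,
  +1 q-telomere), averaged into 500 uniform intervals and normalized to
  mean 1 ("fold enrichment"), with per-context t-tests;
* bin-level correlation of two numeric tracks on a shared grid.

Acrocentric p arms carry no analyzable sequence and are excluded from the
subtelomere test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import STRLocus, ValidationError
from .rng import substream

__all__ = [
    "Arm",
    "GenomeLayout",
    "BinTrack",
    "bin_counts",
    "subtelomere_enrichment",
    "metachromosome_profile",
    "feature_correlation",
    "SUBTELOMERE_SPAN",
]

#: outermost span of an arm counted as subtelomeric, bp
SUBTELOMERE_SPAN = 5_000_000


@dataclass(frozen=True)
class Arm:
    chrom: str
    name: str        # e.g. "chr01p"
    start: int
    end: int
    telomere_side: str  # "left" (p arm) or "right" (q arm)

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeLayout:
    """Chromosome lengths, centromere intervals and derived arm definitions."""

    def __init__(
        self,
        chromosomes: dict[str, tuple[int, int, int]],
        acrocentric: set[str] | None = None,
    ) -> None:
        """``chromosomes`` maps name -> (length, cen_start, cen_end)."""
        self.chromosomes = dict(sorted(chromosomes.items()))
        self.acrocentric = set(acrocentric or ())
        for chrom, (length, cs, ce) in self.chromosomes.items():
            if not 0 <= cs <= ce <= length:
                raise ValidationError(
                    f"{chrom}: centromere [{cs},{ce}) outside chromosome [0,{length})"
                )

    def arms(self, include_acrocentric: bool = True) -> list[Arm]:
        out = []
        for chrom, (length, cs, ce) in self.chromosomes.items():
            for name, start, end, side in (
                (chrom + "p", 0, cs, "left"),
                (chrom + "q", ce, length, "right"),
            ):
                if end <= start:
                    continue
                if not include_acrocentric and name in self.acrocentric:
                    continue
                out.append(Arm(chrom, name, start, end, side))
        return out

    def chrom_length(self, chrom: str) -> int:
        return self.chromosomes[chrom][0]

    def centromere(self, chrom: str) -> tuple[int, int]:
        _, cs, ce = self.chromosomes[chrom]
        return cs, ce

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": c,
                    "length": l,
                    "cen_start": cs,
                    "cen_end": ce,
                    "acrocentric_p": (c + "p") in self.acrocentric,
                }
                for c, (l, cs, ce) in self.chromosomes.items()
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeLayout":
        chroms = {
            r.chrom: (int(r.length), int(r.cen_start), int(r.cen_end))
            for r in df.itertuples()
        }
        acro = {
            r.chrom + "p"
            for r in df.itertuples()
            if getattr(r, "acrocentric_p", False)
        }
        return cls(chroms, acro)


@dataclass
class BinTrack:
    """Consecutive genomic bins with one numeric value each.

    ``bins`` columns: chrom, start, end, arm (may be empty for
    chromosome-grid tracks), value.  Bins overlapping a centromere are
    absent by construction.
    """

    bins: pd.DataFrame
    width: int

    def __len__(self) -> int:
        return len(self.bins)

    def values(self) -> np.ndarray:
        return self.bins["value"].to_numpy(dtype=float)

    def same_grid(self, other: "BinTrack") -> bool:
        a, b = self.bins, other.bins
        return len(a) == len(b) and (
            a[["chrom", "start", "end"]].reset_index(drop=True).equals(
                b[["chrom", "start", "end"]].reset_index(drop=True)
            )
        )


def _count_in_bins(starts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # half-open bins [edges[k], edges[k+1]); a locus at an edge belongs to
    # the right-hand (containing) bin
    return np.histogram(starts, bins=edges)[0]


def bin_counts(
    loci: list[STRLocus],
    layout: GenomeLayout,
    width: int,
    per: str = "arm",
) -> BinTrack:
    """Count loci (by tract start) in consecutive bins.

    ``per="arm"`` cuts each chromosome arm into ``width`` bins starting at
    the arm boundary (trailing partial bins kept); ``per="chromosome"``
    grids the whole chromosome and drops bins overlapping the centromere.
    """
    if width <= 0:
        raise ValidationError("bin width must be positive")
    by_chrom: dict[str, list[int]] = {}
    for lo in loci:
        if lo.chrom not in layout.chromosomes:
            raise ValidationError(f"locus chromosome {lo.chrom!r} absent from layout")
        by_chrom.setdefault(lo.chrom, []).append(lo.start)

    rows = []
    if per == "arm":
        for arm in layout.arms():
            edges = np.arange(arm.start, arm.end, width, dtype=np.int64)
            edges = np.append(edges, arm.end)
            starts = np.array(by_chrom.get(arm.chrom, []), dtype=np.int64)
            starts = starts[(starts >= arm.start) & (starts < arm.end)]
            counts = _count_in_bins(starts, edges)
            for k in range(len(edges) - 1):
                rows.append(
                    (arm.chrom, int(edges[k]), int(edges[k + 1]), arm.name, int(counts[k]))
                )
    elif per == "chromosome":
        for chrom, (length, cs, ce) in layout.chromosomes.items():
            edges = np.arange(0, length, width, dtype=np.int64)
            edges = np.append(edges, length)
            starts = np.array(by_chrom.get(chrom, []), dtype=np.int64)
            counts = _count_in_bins(starts, edges)
            for k in range(len(edges) - 1):
                b0, b1 = int(edges[k]), int(edges[k + 1])
                if b0 < ce and b1 > cs:  # overlaps centromere
                    continue
                rows.append((chrom, b0, b1, "", int(counts[k])))
    else:
        raise ValidationError(f"unknown binning mode {per!r}")
    return BinTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "arm", "value"]),
        width,
    )


def subtelomere_enrichment(
    track: BinTrack,
    layout: GenomeLayout,
    n_perm: int = 10_000,
    seed: int = 0,
    scope: str = "global",
) -> dict:
    """Fold increase of subtelomeric vs other arm-bin means, permutation p.

    Subtelomeric bins are those lying fully within the outermost
    ``SUBTELOMERE_SPAN`` of each non-acrocentric arm.  The permutation
    exchanges bin values across positions — globally across all arms by
    default, or within each arm with ``scope="per_arm"`` — and recomputes
    the fold; the empirical p is the fraction of permuted folds >= observed.
    """
    arms = {a.name: a for a in layout.arms(include_acrocentric=False)}
    df = track.bins[track.bins["arm"].isin(arms)].reset_index(drop=True)
    if df.empty:
        raise ValidationError("track has no bins on non-acrocentric arms")
    sub = np.zeros(len(df), dtype=bool)
    for k, row in enumerate(df.itertuples()):
        arm = arms[row.arm]
        if arm.telomere_side == "left":
            sub[k] = row.end <= arm.start + SUBTELOMERE_SPAN
        else:
            sub[k] = row.start >= arm.end - SUBTELOMERE_SPAN
    if sub.all() or not sub.any():
        raise ValidationError("need both subtelomeric and other bins on each arm set")
    v = df["value"].to_numpy(dtype=float)

    def fold_of(values: np.ndarray) -> float:
        denom = values[~sub].mean()
        return float(values[sub].mean() / denom) if denom != 0 else np.nan

    observed = fold_of(v)
    rng = substream(seed, "subtelomere_enrichment")
    perm_folds = np.empty(n_perm)
    if scope == "global":
        for r in range(n_perm):
            perm_folds[r] = fold_of(rng.permutation(v))
    elif scope == "per_arm":
        arm_codes = df["arm"].to_numpy()
        groups = [np.flatnonzero(arm_codes == a) for a in dict.fromkeys(arm_codes)]
        for r in range(n_perm):
            vp = v.copy()
            for g in groups:
                vp[g] = rng.permutation(v[g])
            perm_folds[r] = fold_of(vp)
    else:
        raise ValidationError(f"unknown permutation scope {scope!r}")
    pval = float(np.mean(perm_folds >= observed)) if np.isfinite(observed) else np.nan
    return {
        "fold": observed,
        "p": pval,
        "n_subtelomeric_bins": int(sub.sum()),
        "n_other_bins": int((~sub).sum()),
        "n_perm": n_perm,
        "scope": scope,
    }


def _arm_positions(df: pd.DataFrame, layout: GenomeLayout) -> np.ndarray:
    """Signed normalized arm position of each bin center: -1..0 p arm, 0..1 q arm."""
    pos = np.full(len(df), np.nan)
    for k, row in enumerate(df.itertuples()):
        length, cs, ce = layout.chromosomes[row.chrom]
        c = 0.5 * (row.start + row.end)
        if c < cs:
            p_len = cs
            pos[k] = -(cs - c) / p_len if p_len > 0 else np.nan
        elif c >= ce:
            q_len = length - ce
            pos[k] = (c - ce) / q_len if q_len > 0 else np.nan
    return np.clip(pos, -1.0, 1.0)


def metachromosome_profile(
    track: BinTrack,
    layout: GenomeLayout,
    n_intervals: int = 500,
    smooth_bins: int = 11,
    alpha: float = 0.05,
) -> dict:
    """Arm-normalized fold-enrichment curve and chromosome-context tests.

    Expects a chromosome-grid track (typically 100 kb).  Counts are smoothed
    per chromosome with a centered ``smooth_bins`` rolling mean (windows
    shrink at chromosome edges so telomeric bins are retained), positions
    normalized per arm, averaged within ``n_intervals`` uniform position
    intervals across chromosomes, and the curve divided by its own mean.
    Contexts: |pos| >= 0.95 telomeric, |pos| <= 0.05 centromeric, otherwise
    interstitial; each context's fold values are tested against 1 with a
    two-sided one-sample t-test, Bonferroni-adjusted over the 3 contexts.
    """
    df = track.bins.copy()
    smoothed = np.empty(len(df))
    for chrom, idx in df.groupby("chrom", sort=False).groups.items():
        s = df.loc[idx, "value"].astype(float)
        smoothed[df.index.get_indexer(idx)] = (
            s.rolling(smooth_bins, center=True, min_periods=1).mean().to_numpy()
        )
    pos = _arm_positions(df, layout)
    ok = np.isfinite(pos)
    pos, smoothed = pos[ok], smoothed[ok]

    edges = np.linspace(-1.0, 1.0, n_intervals + 1)
    which = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_intervals - 1)
    sums = np.bincount(which, weights=smoothed, minlength=n_intervals)
    counts = np.bincount(which, minlength=n_intervals)
    with np.errstate(invalid="ignore"):
        curve = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    fold = curve / np.nanmean(curve)
    mid = 0.5 * (edges[:-1] + edges[1:])

    context = np.where(
        np.abs(mid) >= 0.95, "telomeric", np.where(np.abs(mid) <= 0.05, "centromeric", "interstitial")
    )
    ctx_rows = []
    for name in ("telomeric", "centromeric", "interstitial"):
        vals = fold[(context == name) & np.isfinite(fold)]
        if len(vals) >= 2 and np.std(vals) > 0:
            t, p = stats.ttest_1samp(vals, 1.0)
        else:
            t, p = np.nan, np.nan
        ctx_rows.append(
            {
                "context": name,
                "n_intervals": int(len(vals)),
                "mean_fold": float(np.mean(vals)) if len(vals) else np.nan,
                "t": float(t),
                "p": float(p),
            }
        )
    ctx = pd.DataFrame(ctx_rows)
    ctx["p_bonf"] = np.minimum(ctx["p"] * len(ctx), 1.0)
    ctx["significant"] = ctx["p_bonf"] < alpha
    return {
        "curve": pd.DataFrame(
            {"pos_lo": edges[:-1], "pos_hi": edges[1:], "pos_mid": mid,
             "fold": fold, "context": context}
        ),
        "contexts": ctx,
    }


def feature_correlation(track_a: BinTrack, track_b: BinTrack) -> dict:
    """Pearson and Spearman correlation of two tracks on an identical grid."""
    if not track_a.same_grid(track_b):
        raise ValidationError("tracks are not on the same bin grid")
    a, b = track_a.values(), track_b.values()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return {"n": int(ok.sum()), "pearson_r": np.nan, "pearson_p": np.nan,
                "spearman_rho": np.nan, "spearman_p": np.nan}
    pr, pp = stats.pearsonr(a[ok], b[ok])
    sr, sp = stats.spearmanr(a[ok], b[ok])
    return {
        "n": int(ok.sum()),
        "pearson_r": float(pr),
        "pearson_p": float(pp),
        "spearman_rho": float(sr),
        "spearman_p": float(sp),
    }
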