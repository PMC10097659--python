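"""Call-level and locus-level quality filtering and pSTR/mSTR classification.

Filtering runs in a fixed order: (1) individual genotypes failing depth,
read-support or confidence-interval checks are set to missing; (2) samples
whose remaining call rate falls below a threshold are dropped entirely;
(3) loci overlapping segmental duplications, with low call rate, or
violating Hardy-Weinberg equilibrium are removed.  Surviving loci with
more than one observed allele are polymorphic (pSTR), otherwise
monomorphic (mSTR).

The Hardy-Weinberg test is an exact two-sided binomial test of the
observed heterozygous-sample count against the expected heterozygosity
1 - sum p_i^2 from pooled allele frequencies.  This is multiallelic-safe:
a genotype-table chi-square is ill-conditioned when a locus carries many
rare alleles, whereas the heterozygote-count summary remains binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    MISSING,
    IntervalSet,
    STRCallSet,
    ValidationError,
    allele_spectrum,
    spectrum_het,
)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "CALL_FLAGS",
    "filter_calls",
    "hwe_test",
    "filter_loci",
]

#: call-level flag codes (0 = pass)
CALL_FLAGS = {0: "PASS", 1: "LOWDP", 2: "HIGHDP", 3: "SPANBOUND", 4: "BADCI"}


@dataclass
class FilterConfig:
    """Thresholds of the QC pipeline (defaults follow the analysis design:
    per-call depth in [20, 1000], genotypes supported only by spanning or
    flanking reads or with ML alleles outside their 95% CI removed, samples
    below 50% call rate dropped, loci below 20% call rate or with exact
    HWE p < 1e-5 or overlapping segmental duplications removed)."""

    min_call_dp: int = 20
    max_call_dp: int = 1000
    drop_spanbound_only: bool = True
    drop_ml_outside_ci: bool = True
    min_sample_call_rate: float = 0.5
    min_locus_call_rate: float = 0.2
    hwe_min_p: float = 1e-5
    segdup: IntervalSet | None = None

    def __post_init__(self) -> None:
        if self.min_call_dp > self.max_call_dp:
            raise ValidationError("min_call_dp > max_call_dp")
        for r in (self.min_sample_call_rate, self.min_locus_call_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("call-rate thresholds must be in [0, 1]")


@dataclass
class FilterReport:
    """Bookkeeping of what each filter removed.

    ``call_flags`` is (loci, input samples) with codes from
    :data:`CALL_FLAGS`.  ``locus_table`` has one row per input locus with
    call rate, HWE p, segdup flag and final status in
    {pSTR, mSTR, removed}.
    """

    call_flags: np.ndarray | None = None
    sample_call_rates: pd.Series | None = None
    removed_samples: list[str] = field(default_factory=list)
    locus_table: pd.DataFrame | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def removed_calls(self) -> pd.DataFrame:
        """(locus_index, sample, flag) rows for every call-level removal."""
        if self.call_flags is None:
            return pd.DataFrame(columns=["locus_index", "sample", "flag"])
        ii, jj = np.nonzero(self.call_flags > 0)
        return pd.DataFrame(
            {
                "locus_index": ii,
                "sample": [self._samples[j] for j in jj],
                "flag": [CALL_FLAGS[int(f)] for f in self.call_flags[ii, jj]],
            }
        )


def filter_calls(
    callset: STRCallSet, config: FilterConfig
) -> tuple[STRCallSet, FilterReport]:
    """Apply call-level filters, then drop low-call-rate samples.

    Failing genotypes become missing (flag recorded); samples whose call
    rate over all loci then falls below ``min_sample_call_rate`` are
    removed from the returned call set.
    """
    called = callset.called_mask
    depth = callset.depth
    if np.any(called & (depth < 0)):
        raise ValidationError("QC field DP missing for called genotypes")
    flags = np.zeros(called.shape, dtype=np.int8)

    low = called & (depth < config.min_call_dp)
    high = called & (depth > config.max_call_dp)
    flags[low] = 1
    flags[high & (flags == 0)] = 2
    if config.drop_spanbound_only:
        spanbound = called & (callset.support[:, :, 0] == 0)
        flags[spanbound & (flags == 0)] = 3
    if config.drop_ml_outside_ci:
        ci = callset.ci
        if np.any(called & (ci[:, :, 0, 1] == 0)):
            raise ValidationError("QC field REPCI missing for called genotypes")
        a, b = callset.alleles[:, :, 0], callset.alleles[:, :, 1]
        bad = called & (
            (a < ci[:, :, 0, 0]) | (a > ci[:, :, 0, 1])
            | (b < ci[:, :, 1, 0]) | (b > ci[:, :, 1, 1])
        )
        flags[bad & (flags == 0)] = 4

    out = callset.copy()
    out.alleles[flags > 0] = MISSING

    sample_rates = pd.Series(out.sample_call_rates(), index=out.samples)
    keep = sample_rates >= config.min_sample_call_rate
    removed_samples = list(sample_rates.index[~keep])
    if removed_samples:
        out = out.subset(samples=list(np.flatnonzero(keep.to_numpy())))

    report = FilterReport(
        call_flags=flags,
        sample_call_rates=sample_rates,
        removed_samples=removed_samples,
        counts={
            "input_calls": int(called.sum()),
            "removed_calls": int((flags > 0).sum()),
            **{
                name: int((flags == code).sum())
                for code, name in CALL_FLAGS.items()
                if code > 0
            },
            "removed_samples": len(removed_samples),
        },
    )
    report._samples = list(callset.samples)
    return out, report


def hwe_test(pairs: np.ndarray) -> float:
    """Exact binomial HWE p-value from diploid genotypes at one locus.

    ``pairs`` is (n, 2) called repeat-count pairs.  The observed number of
    heterozygous samples is compared two-sidedly against
    Binomial(n, 1 - sum p_i^2) with allele frequencies pooled over both
    alleles of every genotype.
    """
    pairs = np.asarray(pairs)
    pairs = pairs[pairs[:, 0] >= 0]
    n = len(pairs)
    if n == 0:
        raise ValidationError("HWE undefined with zero called genotypes")
    _, counts = np.unique(pairs.ravel(), return_counts=True)
    p = counts / counts.sum()
    exp_het = float(1.0 - np.sum(p**2))
    obs_het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    if exp_het <= 0.0:
        return 1.0 if obs_het == 0 else 0.0
    return float(stats.binomtest(obs_het, n, exp_het).pvalue)


def filter_loci(
    callset: STRCallSet,
    config: FilterConfig,
    groups: dict[str, list[str]] | None = None,
) -> tuple[STRCallSet, FilterReport]:
    """Locus-level filters and pSTR/mSTR classification.

    Removal reasons, in precedence order: SEGDUP (any >= 1 bp overlap of
    the repeat tract with a segmental-duplication interval), CALLRATE
    (< ``min_locus_call_rate``), HWE (exact binomial p < ``hwe_min_p``).
    With ``groups`` given, HWE is tested within each sample group and the
    locus removed if any group fails; by default the pooled cohort is
    tested.  Survivors with > 1 distinct observed allele are pSTRs,
    otherwise mSTRs.
    """
    rates = callset.locus_call_rates()
    group_idx = None
    if groups:
        pos = {s: j for j, s in enumerate(callset.samples)}
        group_idx = {g: [pos[s] for s in ss if s in pos] for g, ss in groups.items()}

    rows = []
    keep_indices = []
    for i, lo in enumerate(callset.loci):
        segdup = bool(config.segdup.overlaps(lo.chrom, lo.start, lo.end)) if config.segdup else False
        hwe_p = np.nan
        status, reason = "removed", ""
        if segdup:
            reason = "SEGDUP"
        elif rates[i] < config.min_locus_call_rate:
            reason = "CALLRATE"
        else:
            if group_idx:
                ps = []
                for idx in group_idx.values():
                    sub = callset.alleles[i, idx]
                    sub = sub[sub[:, 0] >= 0]
                    if len(sub):
                        ps.append(hwe_test(sub))
                hwe_p = min(ps) if ps else np.nan
            else:
                pairs = callset.alleles[i]
                pairs = pairs[pairs[:, 0] >= 0]
                hwe_p = hwe_test(pairs) if len(pairs) else np.nan
            if np.isfinite(hwe_p) and hwe_p < config.hwe_min_p:
                reason = "HWE"
            else:
                spec = allele_spectrum(callset, i)
                status = "pSTR" if spec.n_alleles > 1 else "mSTR"
                keep_indices.append(i)
        rows.append(
            {
                "locus_index": i,
                "chrom": lo.chrom,
                "start": lo.start,
                "end": lo.end,
                "motif": lo.motif,
                "call_rate": float(rates[i]),
                "hwe_p": hwe_p,
                "segdup": segdup,
                "status": status,
                "reason": reason,
            }
        )
    table = pd.DataFrame(rows)
    out = callset.subset(loci=keep_indices)
    report = FilterReport(
        locus_table=table,
        counts={
            "input_loci": callset.n_loci,
            "removed_loci": int((table["status"] == "removed").sum()),
            "pSTR": int((table["status"] == "pSTR").sum()),
            "mSTR": int((table["status"] == "mSTR").sum()),
            **{
                r: int((table["reason"] == r).sum())
                for r in ("SEGDUP", "CALLRATE", "HWE")
            },
        },
    )
    return out, report
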