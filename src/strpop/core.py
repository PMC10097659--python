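"""Core domain types, STR-VCF I/O, and per-locus allele-spectrum statistics.

The package works on diploid repeat-count genotypes at short tandem repeat
(STR) loci: each call is an unordered pair of repeat counts plus per-call QC
metadata (read depth, read-class support, per-allele 95% confidence
intervals, a quality score).  Allele lengths are expressed in repeat units
throughout; base pairs are ``repeats * len(motif)``.

Coordinates are 0-based half-open internally; VCF POS is converted on I/O.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "STRVCFParseError",
    "ValidationError",
    "STRLocus",
    "STRCall",
    "STRCallSet",
    "AlleleSpectrum",
    "LocusStats",
    "DosageMatrix",
    "IntervalSet",
    "read_str_vcf",
    "write_str_vcf",
    "read_intervals",
    "read_sample_meta",
    "allele_spectrum",
    "locus_stats",
    "dosage_matrix",
    "deviation_spectra",
]

#: sentinel repeat count marking a missing allele in the call matrix
MISSING = -1

META_COLUMNS = ("sample", "population", "superpopulation", "sex", "dataset")


class STRVCFParseError(ValueError):
    """Malformed STR-VCF input; the message names the offending record."""


class ValidationError(ValueError):
    """Input violates a domain invariant (motif length, interval bounds...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class STRLocus:
    """A reference STR tract.

    ``start``/``end`` are 0-based half-open genomic coordinates of the repeat
    tract; ``ref_repeats`` is the repeat count of the reference allele, so
    ``end - start == ref_repeats * len(motif)``.  Motifs are 2-6 bp: longer
    units are not STRs under this package's definition and mononucleotide
    runs are excluded because their genotypes are not reliably callable from
    short reads.
    """

    chrom: str
    start: int
    end: int
    motif: str
    ref_repeats: int

    def __post_init__(self) -> None:
        if not 2 <= len(self.motif) <= 6:
            raise ValidationError(
                f"motif {self.motif!r} has unit length {len(self.motif)}; "
                "supported unit lengths are 2-6 bp"
            )
        if self.ref_repeats < 1:
            raise ValidationError(f"ref_repeats must be >= 1, got {self.ref_repeats}")
        if self.end - self.start != self.ref_repeats * len(self.motif):
            raise ValidationError(
                f"{self.chrom}:{self.start}-{self.end}: tract length "
                f"{self.end - self.start} != ref_repeats * motif length "
                f"({self.ref_repeats} * {len(self.motif)})"
            )

    @property
    def motif_length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class STRCall:
    """One diploid repeat-count call with its QC metadata.

    Alleles are an unordered pair; this view stores them sorted
    (``allele_a <= allele_b``).  ``support`` counts reads by class
    (enclosing, spanning, flanking).  ``ci_a``/``ci_b`` are the 95%
    confidence intervals of the two maximum-likelihood alleles.
    """

    allele_a: int
    allele_b: int
    depth: int
    support: tuple[int, int, int]
    ci_a: tuple[int, int]
    ci_b: tuple[int, int]
    quality: float
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if self.allele_a < 1 or self.allele_b < 1:
                raise ValidationError("called alleles must be >= 1 repeat unit")
            if self.ci_a[0] > self.ci_a[1] or self.ci_b[0] > self.ci_b[1]:
                raise ValidationError("confidence interval lo > hi")

    @classmethod
    def missing_call(cls) -> "STRCall":
        return cls(MISSING, MISSING, 0, (0, 0, 0), (0, 0), (0, 0), 0.0, missing=True)

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele_a, self.allele_b)


class STRCallSet:
    """Loci x samples matrix of diploid STR calls.

    Internally columnar numpy arrays; ``alleles[i, j]`` holds the sorted
    allele pair of locus ``i`` in sample ``j`` (``MISSING`` when uncalled).
    Loci must be sorted by (chrom, start) and sample ids unique.
    """

    def __init__(
        self,
        loci: Sequence[STRLocus],
        samples: Sequence[str],
        alleles: np.ndarray,
        depth: np.ndarray | None = None,
        support: np.ndarray | None = None,
        ci: np.ndarray | None = None,
        quality: np.ndarray | None = None,
    ) -> None:
        self.loci = list(loci)
        self.samples = list(samples)
        L, S = len(self.loci), len(self.samples)
        if len(set(self.samples)) != S:
            raise ValidationError("sample ids are not unique")
        keys = [(lo.chrom, lo.start) for lo in self.loci]
        if keys != sorted(keys):
            raise ValidationError("loci must be sorted by (chrom, start)")
        self.alleles = np.asarray(alleles, dtype=np.int32)
        if self.alleles.shape != (L, S, 2):
            raise ValidationError(
                f"alleles shape {self.alleles.shape} != ({L}, {S}, 2)"
            )
        # canonicalize the unordered pair
        self.alleles = np.sort(self.alleles, axis=2)
        self.depth = self._field(depth, (L, S), np.int32, 0)
        self.support = self._field(support, (L, S, 3), np.int32, 0)
        self.ci = self._field(ci, (L, S, 2, 2), np.int32, 0)
        self.quality = self._field(quality, (L, S), np.float32, 0.0)

    @staticmethod
    def _field(arr, shape, dtype, fill):
        if arr is None:
            return np.full(shape, fill, dtype=dtype)
        arr = np.asarray(arr, dtype=dtype)
        if arr.shape != shape:
            raise ValidationError(f"field shape {arr.shape} != {shape}")
        return arr

    # -- basic geometry ----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (loci, samples): True where the call is missing."""
        return self.alleles[:, :, 0] < 0

    @property
    def called_mask(self) -> np.ndarray:
        return ~self.missing_mask

    def locus_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return self.called_mask.mean(axis=1)

    def sample_call_rates(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return self.called_mask.mean(axis=0)

    def ref_repeats(self) -> np.ndarray:
        return np.array([lo.ref_repeats for lo in self.loci], dtype=np.int32)

    # -- access ------------------------------------------------------------

    def call(self, locus_index: int, sample: int | str) -> STRCall:
        j = self.samples.index(sample) if isinstance(sample, str) else sample
        a, b = self.alleles[locus_index, j]
        if a < 0:
            return STRCall.missing_call()
        return STRCall(
            int(a),
            int(b),
            int(self.depth[locus_index, j]),
            tuple(int(x) for x in self.support[locus_index, j]),
            tuple(int(x) for x in self.ci[locus_index, j, 0]),
            tuple(int(x) for x in self.ci[locus_index, j, 1]),
            float(self.quality[locus_index, j]),
        )

    def subset(
        self,
        loci: Sequence[int] | None = None,
        samples: Sequence[str] | Sequence[int] | None = None,
    ) -> "STRCallSet":
        li = np.arange(self.n_loci) if loci is None else np.asarray(loci, dtype=int)
        if samples is None:
            sj = np.arange(self.n_samples)
        elif len(samples) and isinstance(samples[0], str):
            pos = {s: j for j, s in enumerate(self.samples)}
            sj = np.array([pos[s] for s in samples], dtype=int)
        else:
            sj = np.asarray(samples, dtype=int) if len(samples) else np.empty(0, dtype=int)
        return STRCallSet(
            [self.loci[i] for i in li],
            [self.samples[j] for j in sj],
            self.alleles[np.ix_(li, sj)],
            self.depth[np.ix_(li, sj)],
            self.support[np.ix_(li, sj)],
            self.ci[np.ix_(li, sj)],
            self.quality[np.ix_(li, sj)],
        )

    def copy(self) -> "STRCallSet":
        return STRCallSet(
            list(self.loci),
            list(self.samples),
            self.alleles.copy(),
            self.depth.copy(),
            self.support.copy(),
            self.ci.copy(),
            self.quality.copy(),
        )

    def equals(self, other: "STRCallSet") -> bool:
        if self.loci != other.loci or self.samples != other.samples:
            return False
        m, om = self.missing_mask, other.missing_mask
        if not np.array_equal(m, om):
            return False
        c = ~m
        return (
            np.array_equal(self.alleles[c], other.alleles[c])
            and np.array_equal(self.depth[c], other.depth[c])
            and np.array_equal(self.support[c], other.support[c])
            and np.array_equal(self.ci[c], other.ci[c])
            and np.array_equal(self.quality[c], other.quality[c])
        )


@dataclass
class AlleleSpectrum:
    """Allele counts at one locus: repeat count -> number of observations.

    Both alleles of every called diploid genotype contribute, so the total
    is twice the number of called samples.
    """

    counts: dict[int, int]

    def __post_init__(self) -> None:
        self.counts = {int(a): int(c) for a, c in self.counts.items() if c > 0}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_alleles(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> dict[int, float]:
        t = self.total
        return {a: c / t for a, c in sorted(self.counts.items())} if t else {}

    @property
    def major_allele(self) -> int:
        """Highest-frequency allele; ties broken toward the smaller count."""
        if not self.counts:
            raise ValidationError("empty spectrum has no major allele")
        return min(self.counts, key=lambda a: (-self.counts[a], a))

    def alleles_array(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=float)

    def probs_array(self) -> np.ndarray:
        t = self.total
        return np.array([self.counts[a] for a in sorted(self.counts)], dtype=float) / t


@dataclass
class LocusStats:
    """Per-locus allele-spectrum summary.

    het is expected heterozygosity ``1 - sum p_i^2``; entropy is the
    bit-entropy ``-sum p_i log2 p_i`` of the allele distribution; length
    moments are in repeat units with population-variance (denominator N)
    convention.
    """

    n_alleles: int
    het: float
    entropy: float
    major_allele: int
    major_af: float
    mean_len: float
    var_len: float
    mode_len: int
    call_rate: float


@dataclass
class DosageMatrix:
    """Per-locus per-sample scalar genotype summary.

    ``deviation_sum`` is ``(a - ref) + (b - ref)`` (the QTL-association
    dosage); ``repeat_sum`` is ``a + b`` (the LD dosage).  The two differ by
    the constant ``2 * ref_repeats`` per locus, so correlations computed
    from either mode are identical.  Missing calls are NaN.
    """

    values: np.ndarray  # (loci, samples) float64, NaN = missing
    mode: str
    loci: list[STRLocus]
    samples: list[str]

    def locus_vector(self, i: int) -> np.ndarray:
        return self.values[i]


class IntervalSet:
    """Named set of 0-based half-open genomic intervals (e.g. segdups)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]], name: str = "") -> None:
        self.name = name
        self.intervals: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise ValidationError(
                    f"degenerate interval {chrom}:{start}-{end} (start >= end)"
                )
            self.intervals.append((chrom, start, end))
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts = {
            c: np.array([s for s, _ in iv], dtype=np.int64) for c, iv in by_chrom.items()
        }
        self._ends = {
            c: np.array([e for _, e in iv], dtype=np.int64) for c, iv in by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any overlap (>= 1 bp) with an interval in the set."""
        if chrom not in self._starts:
            return False
        return bool(np.any((self._starts[chrom] < end) & (self._ends[chrom] > start)))


# ---------------------------------------------------------------------------
# I/O: the STR-VCF dialect, BED intervals, sample metadata
# ---------------------------------------------------------------------------

_FORMAT_KEYS = "REPCN:REPCI:DP:RC:Q"

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=RU,Number=1,Type=String,Description="Repeat motif">',
    '##INFO=<ID=REF_RC,Number=1,Type=Integer,Description="Reference repeat count">',
    '##FORMAT=<ID=REPCN,Number=2,Type=Integer,Description="Diploid repeat counts">',
    '##FORMAT=<ID=REPCI,Number=1,Type=String,Description="95% CI per allele, lo-hi,lo-hi">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=RC,Number=1,Type=String,Description="Read class counts: enclosing,spanning,flanking">',
    '##FORMAT=<ID=Q,Number=1,Type=Float,Description="Call quality in [0,1]">',
]


def read_str_vcf(path: str) -> STRCallSet:
    """Read an STR call set from the package's GangSTR-style VCF dialect.

    VCF POS is 1-based; the returned loci use 0-based half-open starts.
    ``.`` genotypes become missing calls.  The order of the two repeat
    counts in REPCN is not preserved (genotypes are unordered pairs).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[STRLocus] = []
    rows: list[tuple] = []
    for idx, rec in enumerate(vcf, start=1):
        motif = rec.INFO.get("RU")
        ref_rc = rec.INFO.get("REF_RC")
        if motif is None or ref_rc is None:
            raise STRVCFParseError(
                f"record {idx} ({rec.CHROM}:{rec.POS}): missing RU/REF_RC INFO keys"
            )
        locus = STRLocus(rec.CHROM, rec.POS - 1,
                         rec.POS - 1 + int(ref_rc) * len(motif), motif, int(ref_rc))
        n = len(samples)
        repcn = rec.format("REPCN")
        if repcn is None:
            repcn = np.full((n, 2), MISSING, dtype=np.int64)
        repci = rec.format("REPCI")
        dp = rec.format("DP")
        rc = rec.format("RC")
        q = rec.format("Q")
        alleles = np.full((n, 2), MISSING, dtype=np.int32)
        depth = np.zeros(n, dtype=np.int32)
        support = np.zeros((n, 3), dtype=np.int32)
        ci = np.zeros((n, 2, 2), dtype=np.int32)
        qual = np.zeros(n, dtype=np.float32)
        for j in range(n):
            a, b = int(repcn[j, 0]), int(repcn[j, 1])
            if a < 0 or b < 0:  # cyvcf2 missing-int sentinel is large negative
                continue
            alleles[j] = (a, b)
            if dp is not None and int(dp[j, 0]) >= 0:
                depth[j] = int(dp[j, 0])
            if rc is not None and rc[j] != ".":
                try:
                    support[j] = [int(x) for x in rc[j].split(",")]
                except ValueError as exc:
                    raise STRVCFParseError(
                        f"record {idx} sample {samples[j]}: bad RC field {rc[j]!r}"
                    ) from exc
            if repci is not None and repci[j] != ".":
                try:
                    for k, part in enumerate(repci[j].split(",")):
                        lo, hi = part.split("-")
                        ci[j, k] = (int(lo), int(hi))
                except ValueError as exc:
                    raise STRVCFParseError(
                        f"record {idx} sample {samples[j]}: bad REPCI field {repci[j]!r}"
                    ) from exc
            if q is not None and np.isfinite(q[j, 0]):
                qual[j] = q[j, 0]
        loci.append(locus)
        rows.append((alleles, depth, support, ci, qual))

    L = len(loci)
    order = sorted(range(L), key=lambda i: (loci[i].chrom, loci[i].start))
    loci = [loci[i] for i in order]
    rows = [rows[i] for i in order]
    shape = (L, len(samples))
    return STRCallSet(
        loci,
        samples,
        np.stack([r[0] for r in rows]) if L else np.empty((*shape, 2), np.int32),
        np.stack([r[1] for r in rows]) if L else np.empty(shape, np.int32),
        np.stack([r[2] for r in rows]) if L else np.empty((*shape, 3), np.int32),
        np.stack([r[3] for r in rows]) if L else np.empty((*shape, 2, 2), np.int32),
        np.stack([r[4] for r in rows]) if L else np.empty(shape, np.float32),
    )


def write_str_vcf(
    callset: STRCallSet, path: str, locus_filters: Sequence[str] | None = None
) -> None:
    """Write a call set in the STR-VCF dialect; inverse of :func:`read_str_vcf`.

    ``locus_filters`` optionally stamps the FILTER column per locus (e.g.
    SEGDUP, CALLRATE, HWE from a locus filter report); default PASS.
    """
    if locus_filters is not None and len(locus_filters) != callset.n_loci:
        raise ValidationError("locus_filters length must match the number of loci")
    chrom_max: dict[str, int] = {}
    for lo in callset.loci:
        chrom_max[lo.chrom] = max(chrom_max.get(lo.chrom, 0), lo.end)
    with open(path, "w") as fh:
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        for chrom in sorted(chrom_max):
            fh.write(f"##contig=<ID={chrom},length={chrom_max[chrom] + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(callset.samples)
            + "\n"
        )
        for i, lo in enumerate(callset.loci):
            ref_seq = lo.motif * lo.ref_repeats
            cols = [
                lo.chrom,
                str(lo.start + 1),
                ".",
                ref_seq,
                ".",
                ".",
                (locus_filters[i] or "PASS") if locus_filters is not None else "PASS",
                f"RU={lo.motif};REF_RC={lo.ref_repeats}",
                _FORMAT_KEYS,
            ]
            for j in range(callset.n_samples):
                a, b = callset.alleles[i, j]
                if a < 0:
                    cols.append(".:.:.:.:.")
                    continue
                ci = callset.ci[i, j]
                cols.append(
                    f"{a},{b}"
                    f":{ci[0, 0]}-{ci[0, 1]},{ci[1, 0]}-{ci[1, 1]}"
                    f":{callset.depth[i, j]}"
                    f":{','.join(str(x) for x in callset.support[i, j])}"
                    # %.9g is lossless for the float32 quality field
                    f":{callset.quality[i, j]:.9g}"
                )
            fh.write("\t".join(cols) + "\n")


def read_intervals(path: str, name: str = "") -> IntervalSet:
    """Read a 3+ column BED file (0-based half-open) into an IntervalSet."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise STRVCFParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise STRVCFParseError(f"{path}:{lineno}: bad coordinates") from exc
    return IntervalSet(intervals, name=name or str(path))


def read_sample_meta(path: str) -> pd.DataFrame:
    """Read sample metadata TSV (sample, population, superpopulation, sex, dataset)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample metadata missing columns: {missing}")
    if df["sample"].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    return df


# ---------------------------------------------------------------------------
# Spectrum statistics and dosage conversion
# ---------------------------------------------------------------------------


def allele_spectrum(
    callset: STRCallSet,
    locus_index: int,
    sample_subset: Sequence[str] | Sequence[int] | None = None,
) -> AlleleSpectrum:
    """Pooled allele counts at one locus (2 observations per called sample)."""
    if sample_subset is None:
        idx = slice(None)
    elif len(sample_subset) and isinstance(sample_subset[0], str):
        pos = {s: j for j, s in enumerate(callset.samples)}
        idx = [pos[s] for s in sample_subset]
    else:
        idx = list(sample_subset)
    pairs = callset.alleles[locus_index, idx]
    called = pairs[:, 0] >= 0
    vals, counts = np.unique(pairs[called].ravel(), return_counts=True)
    return AlleleSpectrum(dict(zip(vals.tolist(), counts.tolist())))


def spectrum_het(spectrum: AlleleSpectrum) -> float:
    """Expected heterozygosity 1 - sum p_i^2."""
    p = spectrum.probs_array()
    return float(1.0 - np.sum(p**2))


def spectrum_entropy(spectrum: AlleleSpectrum) -> float:
    """Bit-entropy -sum p_i log2 p_i."""
    p = spectrum.probs_array()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def locus_stats(spectrum: AlleleSpectrum, call_rate: float) -> LocusStats:
    """Summary statistics of one locus's allele spectrum.

    Raises if the spectrum is empty: stats are undefined with no
    observations (such loci fall to the call-rate filter first).
    """
    if spectrum.total == 0:
        raise ValidationError("locus statistics undefined for empty spectrum")
    alleles = spectrum.alleles_array()
    p = spectrum.probs_array()
    major = spectrum.major_allele
    mean_len = float(np.sum(alleles * p))
    var_len = float(np.sum((alleles - mean_len) ** 2 * p))
    return LocusStats(
        n_alleles=spectrum.n_alleles,
        het=spectrum_het(spectrum),
        entropy=spectrum_entropy(spectrum),
        major_allele=major,
        major_af=spectrum.counts[major] / spectrum.total,
        mean_len=mean_len,
        var_len=var_len,
        mode_len=major,
        call_rate=float(call_rate),
    )


def dosage_matrix(callset: STRCallSet, mode: str = "deviation_sum") -> DosageMatrix:
    """Convert diploid repeat-count calls to per-sample scalar dosages."""
    if mode not in ("deviation_sum", "repeat_sum"):
        raise ValidationError(f"unknown dosage mode {mode!r}")
    a = callset.alleles.astype(np.float64)
    vals = a[:, :, 0] + a[:, :, 1]
    if mode == "deviation_sum":
        vals = vals - 2.0 * callset.ref_repeats()[:, None]
    vals[callset.missing_mask] = np.nan
    return DosageMatrix(vals, mode, list(callset.loci), list(callset.samples))


def deviation_spectra(callset: STRCallSet) -> dict[str, pd.DataFrame]:
    """Per-locus deviation tables describing the shape of STR variation.

    Returns ``major_vs_ref`` (major allele minus reference repeat count, one
    row per locus with any called allele), ``allele_vs_major`` (per-allele
    repeat difference from the locus major allele, with within-locus
    frequency), and ``aggregate`` (genome-wide histogram of allele-vs-major
    differences weighted by observation counts).
    """
    mvr_rows, avm_rows = [], []
    agg: Counter[int] = Counter()
    grand_total = 0
    for i, lo in enumerate(callset.loci):
        spec = allele_spectrum(callset, i)
        if spec.total == 0:
            continue
        major = spec.major_allele
        mvr_rows.append(
            {
                "locus_index": i,
                "chrom": lo.chrom,
                "start": lo.start,
                "ref_repeats": lo.ref_repeats,
                "major_allele": major,
                "major_minus_ref": major - lo.ref_repeats,
            }
        )
        for allele, count in sorted(spec.counts.items()):
            avm_rows.append(
                {
                    "locus_index": i,
                    "allele": allele,
                    "delta_from_major": allele - major,
                    "frequency": count / spec.total,
                }
            )
            agg[allele - major] += count
            grand_total += count
    aggregate = pd.DataFrame(
        {
            "delta_from_major": sorted(agg),
            "count": [agg[d] for d in sorted(agg)],
        }
    )
    if grand_total:
        aggregate["frequency"] = aggregate["count"] / grand_total
    else:
        aggregate["frequency"] = pd.Series(dtype=float)
    return {
        "major_vs_ref": pd.DataFrame(mvr_rows),
        "allele_vs_major": pd.DataFrame(avm_rows),
        "aggregate": aggregate,
    }
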