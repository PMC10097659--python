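"""Shared fixtures and call-set builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from strpop.core import MISSING, STRCallSet, STRLocus

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_locus(i: int = 0, chrom: str = "chr01", motif: str = "AC", ref: int = 10,
               spacing: int = 10_000) -> STRLocus:
    start = 1000 + i * spacing
    return STRLocus(chrom, start, start + ref * len(motif), motif, ref)


def build_callset(genotypes, refs=None, samples=None, motifs=None) -> STRCallSet:
    """Build a call set from nested genotype lists.

    ``genotypes[i][j]`` is a (a, b) pair or None for missing; QC fields are
    filled in as clean (depth 30, enclosing reads present, ML inside CI).
    """
    L = len(genotypes)
    S = len(genotypes[0])
    refs = refs or [10] * L
    motifs = motifs or ["AC"] * L
    samples = samples or [f"S{j}" for j in range(S)]
    loci = [make_locus(i, motif=motifs[i], ref=refs[i]) for i in range(L)]
    alleles = np.full((L, S, 2), MISSING, dtype=np.int32)
    depth = np.full((L, S), 30, dtype=np.int32)
    support = np.tile(np.array([20, 5, 5], dtype=np.int32), (L, S, 1))
    ci = np.zeros((L, S, 2, 2), dtype=np.int32)
    quality = np.full((L, S), 0.9, dtype=np.float32)
    for i in range(L):
        for j in range(S):
            g = genotypes[i][j]
            if g is None:
                continue
            a, b = sorted(g)
            alleles[i, j] = (a, b)
            ci[i, j, 0] = (max(1, a - 1), a + 1)
            ci[i, j, 1] = (max(1, b - 1), b + 1)
    return STRCallSet(loci, samples, alleles, depth, support, ci, quality)


@pytest.fixture
def tiny_callset() -> STRCallSet:
    """3 loci x 4 samples with one missing call and mixed zygosity."""
    return build_callset(
        [
            [(10, 10), (10, 12), (12, 12), None],
            [(8, 9), (9, 9), (8, 8), (8, 9)],
            [(15, 15), (15, 15), (15, 15), (15, 15)],
        ],
        refs=[10, 9, 15],
        motifs=["AC", "AAT", "AGAT"],
    )
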