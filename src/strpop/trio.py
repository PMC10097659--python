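"""Mendelian inheritance over trios and inter-caller genotype concordance.

A locus in a trio is Mendelian-consistent if the child's unordered allele
pair can be split so one allele matches any paternal allele and the other
any maternal allele (genotypes are unphased, so both orderings are tried).

Genotype concordance between two callers scores a sample 1 when both
alleles match, 0.5 when exactly one matches, and 0 when neither does; the
matching is a maximum multiset matching, so a homozygote {10,10} against
{10,12} contributes exactly one shared allele (0.5), never two.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import STRCall, STRCallSet, ValidationError

__all__ = ["Trio", "mendelian_rate", "call_concordance", "locus_concordance", "read_trios"]


@dataclass(frozen=True)
class Trio:
    child: str
    father: str
    mother: str


def read_trios(path: str) -> list[Trio]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("child", "father", "mother"):
        if col not in df.columns:
            raise ValidationError(f"trio table missing column {col!r}")
    return [Trio(r.child, r.father, r.mother) for r in df.itertuples()]


def _consistent(child: tuple, father: tuple, mother: tuple) -> bool:
    c0, c1 = child
    return (c0 in father and c1 in mother) or (c1 in father and c0 in mother)


def mendelian_rate(
    callset: STRCallSet, trios: list[Trio]
) -> tuple[pd.DataFrame, float]:
    """Per-trio Mendelian inheritance rate and the mean over trios.

    The denominator for a trio counts loci where all three members are
    called; trios with no jointly-called locus get a missing rate and are
    excluded from the mean.
    """
    pos = {s: j for j, s in enumerate(callset.samples)}
    rows = []
    for t in trios:
        for member in (t.child, t.father, t.mother):
            if member not in pos:
                raise ValidationError(f"trio member {member!r} absent from call set")
        cj, fj, mj = pos[t.child], pos[t.father], pos[t.mother]
        child = callset.alleles[:, cj]
        father = callset.alleles[:, fj]
        mother = callset.alleles[:, mj]
        called = (child[:, 0] >= 0) & (father[:, 0] >= 0) & (mother[:, 0] >= 0)
        idx = np.flatnonzero(called)
        n_ok = 0
        for i in idx:
            if _consistent(tuple(child[i]), tuple(father[i]), tuple(mother[i])):
                n_ok += 1
        rows.append(
            {
                "child": t.child,
                "father": t.father,
                "mother": t.mother,
                "loci_tested": int(len(idx)),
                "loci_consistent": int(n_ok),
                "rate": n_ok / len(idx) if len(idx) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    overall = float(table["rate"].mean()) if len(table) else np.nan
    return table, overall


def call_concordance(gt_a, gt_b) -> float:
    """Concordance of two diploid calls: shared alleles (multiset) / 2."""
    a = gt_a.alleles if isinstance(gt_a, STRCall) else tuple(gt_a)
    b = gt_b.alleles if isinstance(gt_b, STRCall) else tuple(gt_b)
    if isinstance(gt_a, STRCall) and gt_a.missing:
        raise ValidationError("concordance undefined for missing calls")
    if isinstance(gt_b, STRCall) and gt_b.missing:
        raise ValidationError("concordance undefined for missing calls")
    ca, cb = Counter(a), Counter(b)
    shared = sum(min(ca[k], cb[k]) for k in ca)
    return shared / 2.0


def locus_concordance(
    callset_a: STRCallSet, callset_b: STRCallSet, locus_index: int
) -> float:
    """Mean per-sample concordance at one locus over samples called in both."""
    shared_samples = [s for s in callset_a.samples if s in set(callset_b.samples)]
    pos_a = {s: j for j, s in enumerate(callset_a.samples)}
    pos_b = {s: j for j, s in enumerate(callset_b.samples)}
    scores = []
    for s in shared_samples:
        pa = callset_a.alleles[locus_index, pos_a[s]]
        pb = callset_b.alleles[locus_index, pos_b[s]]
        if pa[0] < 0 or pb[0] < 0:
            continue
        scores.append(call_concordance(tuple(pa), tuple(pb)))
    if not scores:
        return float("nan")
    return float(np.mean(scores))
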