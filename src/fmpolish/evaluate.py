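"""Residual-error evaluation of polished assemblies.

Residual errors are defined by a minimum-edit-distance global alignment
(unit costs) between an assembly sequence and the matching reference:
``edit_distance = mismatches + insertions + deletions``. Rates are
normalized per 100 kbp of reference. Replicate assemblies without a
reference are compared by the sum of all pairwise edit distances.

Alignment uses edlib (banded Myers bit-vector, exact); classification of
columns comes from its extended CIGAR. Among co-optimal alignments the
traceback is deterministic but the mismatch/indel split may differ from
other aligners; the edit distance itself is unique.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ErrorSummary:
    """Classified residual errors of one assembly/reference pair."""

    mismatches: int
    insertions: int  # bases present in the assembly but not the reference
    deletions: int  # reference bases missing from the assembly
    ref_len: int

    @property
    def edit_distance(self) -> int:
        return self.mismatches + self.insertions + self.deletions

    @property
    def indels(self) -> int:
        return self.insertions + self.deletions

    @property
    def rate_mismatch(self) -> float:
        return per_100kbp(self.mismatches, self.ref_len)

    @property
    def rate_indel(self) -> float:
        return per_100kbp(self.indels, self.ref_len)

    @property
    def rate_combined(self) -> float:
        return self.rate_mismatch + self.rate_indel


def global_align_errors(asm_seq: str, ref_seq: str) -> ErrorSummary:
    """Classify a unit-cost global alignment of assembly vs reference."""
    if not asm_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    result = edlib.align(asm_seq, ref_seq, mode="NW", task="path")
    mm = ins = dels = 0
    for count, op in _CIGAR_OP.findall(result["cigar"]):
        n = int(count)
        if op == "X":
            mm += n
        elif op == "I":
            ins += n
        elif op == "D":
            dels += n
    summary = ErrorSummary(mm, ins, dels, ref_len=len(ref_seq))
    assert summary.edit_distance == result["editDistance"]
    return summary


def per_100kbp(count: float, ref_len: int) -> float:
    """Errors per 100,000 reference bases."""
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")
    return count * 100_000 / ref_len


def combine_rates(rate_mismatch: float, rate_indel: float) -> float:
    """Combined residual error rate = mismatch rate + indel rate."""
    if rate_mismatch < 0 or rate_indel < 0:
        raise ValueError("rates must be non-negative")
    return rate_mismatch + rate_indel


def pairwise_distance_sum(assemblies: Sequence[str]) -> int:
    """Sum of edit distances over all unordered pairs of replicate sequences."""
    if len(assemblies) < 2:
        raise ValueError("need at least two assemblies")
    total = 0
    for a, b in itertools.combinations(assemblies, 2):
        total += edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return total


def evaluate_assembly(
    assembly: Mapping[str, str] | Sequence[tuple[str, str]],
    reference: Mapping[str, str] | Sequence[tuple[str, str]],
) -> ErrorSummary:
    """Evaluate a (possibly multi-contig) assembly against a reference.

    Contigs are matched by shared name when every assembly name occurs in
    the reference; otherwise greedily by smallest edit distance. Summaries
    are aggregated over matched pairs; ref_len is the total reference
    length of the matched contigs.
    """
    asm = dict(assembly)
    ref = dict(reference)
    if not asm or not ref:
        raise ValueError("empty assembly or reference")
    pairs: list[tuple[str, str]] = []
    if set(asm) <= set(ref):
        pairs = [(asm[name], ref[name]) for name in asm]
    else:
        remaining = dict(ref)
        for name, seq in asm.items():
            best = min(
                remaining,
                key=lambda r: edlib.align(
                    seq, remaining[r], mode="NW", task="distance"
                )["editDistance"],
            )
            pairs.append((seq, remaining.pop(best)))
            if not remaining:
                break
    mm = ins = dels = ref_len = 0
    for a, r in pairs:
        s = global_align_errors(a, r)
        mm += s.mismatches
        ins += s.insertions
        dels += s.deletions
        ref_len += s.ref_len
    return ErrorSummary(mm, ins, dels, ref_len)
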