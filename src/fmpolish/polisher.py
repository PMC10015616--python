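"""Draft-assembly polishing by k-mer segmentation and de Bruijn bridging.

A draft contig is scanned with the short-read FM-index: positions whose
k-mers are well supported ("solid") are trusted, maximal runs of bases
covered by no solid k-mer ("weak" regions) are reassembled by bounded
depth-first search through the implicit de Bruijn graph of the reads,
anchored on the nearest solid k-mers. The sweep is repeated once per k in
an ascending k list, each pass consuming the previous pass's output; small
k resolves dense errors, large k resolves repeats.

The solidity threshold combines an absolute floor (``min_count``) with a
fraction of the median non-zero count of the current fragment
(``min_frac``), so it adapts to local copy number: in repeat-rich genomes
the median is inflated by multi-copy k-mers and a genuinely distinct repeat
copy can fall below the relative component — the ``eukaryote`` preset
(k = 21, 59, 80 and ``min_frac = 0``) disables it for exactly that case.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import edlib
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .bwt import FmIndex, ShortReadSet, build_index, revcomp

# Documented search constants (the published interface exposes only
# branch_factor; these multipliers fix the remaining budgets).
BRIDGE_LENGTH_MULTIPLIER = 2  # bridge length cap = 2 * (weak span + k)
END_EXTENSION_SLACK = 1.25  # head/tail cap = ceil(1.25 * flank length)

_NON_ACGTN = re.compile(r"[^ACGTN]")
_N_RUN = re.compile(r"(N+)")


def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass(frozen=True)
class PolishParams:
    """Polishing parameters; the defaults suit bacterial-scale genomes."""

    k_list: tuple[int, ...] = (21, 59)
    min_count: int = 5
    min_frac: float = 0.1
    branch_factor: int = 4
    cache_size: int = 8

    def __post_init__(self):
        ks = tuple(int(k) for k in self.k_list)
        object.__setattr__(self, "k_list", ks)
        if not ks or any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k_list must be non-empty and strictly ascending")
        if any(k <= self.cache_size for k in ks):
            raise ValueError("every k must exceed cache_size")
        if not 0.0 <= self.min_frac <= 1.0:
            raise ValueError("min_frac must lie in [0, 1]")
        if self.min_count < 1 or self.branch_factor < 1:
            raise ValueError("min_count and branch_factor must be positive")

    @classmethod
    def eukaryote(cls) -> "PolishParams":
        """Repeat-tolerant preset: k = 21, 59, 80 and min_frac = 0."""
        return cls(k_list=(21, 59, 80), min_frac=0.0)


@dataclass(frozen=True)
class Block:
    """Half-open interval of bases sharing one solidity label."""

    start: int
    end: int
    solid: bool


@dataclass
class Segmentation:
    """Alternating solid/weak base blocks jointly covering a sequence."""

    blocks: list[Block]
    seq_len: int

    def weak_regions(self) -> list[tuple[int, int]]:
        return [(b.start, b.end) for b in self.blocks if not b.solid]


@dataclass
class CountProfile:
    """Per-position k-mer counts of a fragment plus its solidity cutoff."""

    counts: np.ndarray
    k: int
    threshold: int


def dynamic_threshold(counts: np.ndarray, min_count: int, min_frac: float) -> int:
    """Solidity cutoff: max(min_count, ceil(min_frac * median non-zero count)).

    The median ignores zero-count k-mers so that error deserts do not drag
    the relative component to zero; with min_frac = 0 the cutoff is exactly
    min_count.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count profile")
    nonzero = counts[counts > 0]
    if nonzero.size == 0 or min_frac == 0:
        return int(min_count)
    rel = math.ceil(min_frac * float(np.median(nonzero)))
    return int(max(min_count, rel))


def segment_solid_weak(
    counts: np.ndarray, k: int, seq_len: int, threshold: int
) -> Segmentation:
    """Label bases: weak iff covered by no solid k-mer; merge into blocks."""
    counts = np.asarray(counts)
    solid_base = np.zeros(seq_len, dtype=bool)
    if counts.size:
        solid_kmer = counts >= threshold
        # dilate each solid k-mer start over its k bases
        diff = np.zeros(seq_len + 1, dtype=np.int64)
        starts = np.flatnonzero(solid_kmer)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + k, -1)
        solid_base = np.cumsum(diff[:-1]) > 0
    blocks: list[Block] = []
    if seq_len:
        edges = np.flatnonzero(np.diff(solid_base)) + 1
        bounds = np.concatenate(([0], edges, [seq_len]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            blocks.append(Block(int(s), int(e), bool(solid_base[s])))
    return Segmentation(blocks, seq_len)


@dataclass
class BridgeCandidate:
    """A proposed replacement path through the read de Bruijn graph."""

    sequence: str


@dataclass
class BridgeResult:
    candidates: list[BridgeCandidate]
    nodes_explored: int
    truncated: bool

    def sequences(self) -> list[str]:
        return [c.sequence for c in self.candidates]


def bridge(
    index: FmIndex,
    left_anchor: str,
    right_anchor: str,
    threshold: int,
    branch_factor: int,
    max_length: int,
) -> BridgeResult:
    """Reassemble the sequence between two solid anchor k-mers.

    Depth-first search over single-base right extensions of the current
    k-suffix, keeping only extensions whose k-mer count meets the threshold
    (extension order A < C < G < T, so results are deterministic). A path
    terminates successfully when its k-suffix equals ``right_anchor``.
    ``max_length`` caps the number of appended bases; the node budget is
    ``branch_factor * max_length``. Every candidate starts with the left
    anchor, ends with the right anchor, and consists solely of
    above-threshold k-mers.
    """
    k = len(left_anchor)
    if len(right_anchor) != k:
        raise ValueError("anchors must share one k")
    if index.count(left_anchor) < threshold or index.count(right_anchor) < threshold:
        raise ValueError("anchor k-mer below threshold")
    budget = branch_factor * max_length
    nodes = 0
    truncated = False
    found: list[BridgeCandidate] = []
    stack = [left_anchor]
    while stack:
        path = stack.pop()
        nodes += 1
        if nodes > budget:
            truncated = True
            break
        if len(path) - k >= max_length:
            truncated = True
            continue
        suffix = path[-(k - 1) :] if k > 1 else ""
        for base in "TGCA":  # LIFO stack: A is explored first
            kmer = suffix + base
            if kmer == right_anchor:
                found.append(BridgeCandidate(path + base))
            elif index.count(kmer) >= threshold:
                stack.append(path + base)
    return BridgeResult(found, nodes, truncated)


def extend_end(
    index: FmIndex,
    anchor: str,
    direction: str,
    target_len: int,
    threshold: int,
    branch_factor: int,
) -> BridgeResult:
    """Rebuild a contig head or tail from a single flanking anchor.

    Same search as :func:`bridge` but with no terminal anchor: paths are
    emitted when they reach exactly ``target_len`` (and exploration
    continues), when they reach the length cap ``ceil(1.25 * target_len)``,
    or when they dead-end with at least one appended base. Returned
    sequences are the extensions only (anchor excluded), oriented as they
    would be inserted; ``direction='left'`` is run as a right extension in
    reverse-complement space.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    if target_len < 0:
        raise ValueError("target_len must be >= 0")
    if index.count(anchor) < threshold:
        raise ValueError("anchor k-mer below threshold")
    cap = math.ceil(END_EXTENSION_SLACK * target_len)
    if cap == 0:
        return BridgeResult([BridgeCandidate("")], 0, False)
    work_anchor = revcomp(anchor) if direction == "left" else anchor
    k = len(anchor)
    budget = branch_factor * cap
    nodes = 0
    truncated = False
    found: list[str] = []
    stack = [""]
    while stack:
        ext = stack.pop()
        nodes += 1
        if nodes > budget:
            truncated = True
            break
        state = work_anchor + ext
        suffix = state[-(k - 1) :] if k > 1 else ""
        children = [b for b in "ACGT" if index.count(suffix + b) >= threshold]
        if not children:
            if ext:
                found.append(ext)
            continue
        for base in reversed(children):
            child = ext + base
            if len(child) >= cap:
                found.append(child)
            else:
                if len(child) == target_len:
                    found.append(child)
                stack.append(child)
    if direction == "left":
        found = [revcomp(e) for e in found]
    return BridgeResult([BridgeCandidate(e) for e in found], nodes, truncated)


def choose_candidate(
    candidates: Sequence[str | BridgeCandidate], original_segment: str
) -> str | None:
    """Candidate closest to the draft segment by edit distance.

    Ties break toward shorter, then lexicographically smaller sequences;
    returns None when there is no candidate (region left unchanged).
    """
    seqs = [c.sequence if isinstance(c, BridgeCandidate) else c for c in candidates]
    if not seqs:
        return None
    return min(seqs, key=lambda s: (_edit_distance(s, original_segment), len(s), s))


@dataclass
class PassReport:
    """Per-pass correction tallies; bridged + failed == found."""

    k: int
    regions_found: int = 0
    regions_bridged: int = 0
    regions_failed: int = 0
    head_tail_extensions: int = 0
    bases_changed: int = 0

    def merge(self, other: "PassReport") -> None:
        assert self.k == other.k
        self.regions_found += other.regions_found
        self.regions_bridged += other.regions_bridged
        self.regions_failed += other.regions_failed
        self.head_tail_extensions += other.head_tail_extensions
        self.bases_changed += other.bases_changed


@dataclass
class CorrectionReport:
    passes: list[PassReport] = field(default_factory=list)

    @property
    def bases_changed(self) -> int:
        return sum(p.bases_changed for p in self.passes)

    def to_rows(self) -> list[dict]:
        return [vars(p).copy() for p in self.passes]


def _weak_kmer_runs(counts: np.ndarray, threshold: int, k: int) -> list[tuple[int, int]]:
    """Maximal runs of below-threshold k-mer positions, merging runs whose
    intervening solid stretch is shorter than k (too short to trust)."""
    weak = np.asarray(counts) < threshold
    edges = np.flatnonzero(np.diff(weak.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [len(weak)]))
    runs = [
        (int(s), int(e))
        for s, e in zip(bounds[:-1], bounds[1:])
        if weak[s]
    ]
    merged: list[tuple[int, int]] = []
    for rs, re_ in runs:
        if merged and rs - merged[-1][1] < k:
            merged[-1] = (merged[-1][0], re_)
        else:
            merged.append((rs, re_))
    return merged


def correct_pass(
    index: FmIndex, seq: str, k: int, params: PolishParams
) -> tuple[str, PassReport]:
    """One correction sweep of a single ACGT fragment at one k.

    Repair regions are maximal runs of weak k-mer positions; the anchors
    are the immediately flanking solid k-mers (runs of weak k-mers shorter
    than k — e.g. an isolated deletion — leave every base nominally covered
    by a solid k-mer, so regions are taken in k-mer space, not base space).
    Replacements are applied right to left so earlier coordinates stay
    valid; a region with no accepted candidate is left unchanged.
    """
    report = PassReport(k=k)
    if len(seq) < k:
        return seq, report
    counts = index.profile(seq, k)
    threshold = dynamic_threshold(counts, params.min_count, params.min_frac)
    regions = _weak_kmer_runs(counts, threshold, k)
    report.regions_found = len(regions)
    if not regions:
        return seq, report
    L = len(seq)
    n_kmers = len(counts)
    out = seq
    for rs, re_ in reversed(regions):  # right-to-left keeps left coords valid
        head = rs == 0
        tail = re_ == n_kmers
        replacement: str | None = None
        rep_start = rep_end = 0
        if head and tail:
            replacement = None  # no solid anchor at all
        elif head:
            # rebuild seq[0:re_] leftward from the first solid k-mer
            anchor = seq[re_ : re_ + k]
            flank = seq[:re_]
            res = extend_end(
                index, anchor, "left", re_, threshold, params.branch_factor
            )
            best = choose_candidate(res.candidates, flank)
            # a dead-ended extension shorter than the flank would truncate
            # sequence that merely lost read coverage at the contig end;
            # require full length
            if (
                best is not None
                and len(best) >= re_
                and 2 * _edit_distance(best, flank) <= max(len(flank), 2)
            ):
                replacement = best
                rep_start, rep_end = 0, re_
                report.head_tail_extensions += 1
        elif tail:
            la = rs - 1
            anchor = seq[la : la + k]
            flank = seq[la + k :]
            target = L - la - k
            res = extend_end(
                index, anchor, "right", target, threshold, params.branch_factor
            )
            best = choose_candidate(res.candidates, flank)
            if (
                best is not None
                and len(best) >= target
                and 2 * _edit_distance(best, flank) <= max(len(flank), 2)
            ):
                replacement = best
                rep_start, rep_end = la + k, L
                report.head_tail_extensions += 1
        else:
            la, ra = rs - 1, re_
            span = ra - la  # bases between anchor starts
            max_length = BRIDGE_LENGTH_MULTIPLIER * (span + k)
            res = bridge(
                index,
                seq[la : la + k],
                seq[ra : ra + k],
                threshold,
                params.branch_factor,
                max_length,
            )
            original = seq[la : ra + k]
            best = choose_candidate(res.candidates, original)
            if best is not None and _edit_distance(best, original) <= len(original):
                replacement = best
                rep_start, rep_end = la, ra + k
        if replacement is None:
            report.regions_failed += 1
            continue
        report.regions_bridged += 1
        report.bases_changed += _edit_distance(replacement, out[rep_start:rep_end])
        out = out[:rep_start] + replacement + out[rep_end:]
    return out, report


def _normalize_contig(seq: str) -> str:
    """Uppercase; any symbol outside {A,C,G,T,N} becomes N."""
    return _NON_ACGTN.sub("N", seq.upper())


def polish(
    index: FmIndex,
    assembly: Sequence[tuple[str, str]] | dict[str, str] | Sequence[str],
    params: PolishParams | None = None,
) -> tuple[list[tuple[str, str]], CorrectionReport]:
    """Polish an assembly: per contig, split at N runs, run one correction
    pass per k (ascending), rejoin with the original N runs preserved.

    The index derives from short reads only, so it is constant across
    passes. Contig order and names are preserved.
    """
    if params is None:
        params = PolishParams()
    if isinstance(assembly, dict):
        items = list(assembly.items())
    else:
        items = [
            (f"contig_{i}", c) if isinstance(c, str) else (c[0], c[1])
            for i, c in enumerate(assembly)
        ]
    if not isinstance(index, FmIndex):
        raise TypeError("index must be an FmIndex")
    report = CorrectionReport([PassReport(k=k) for k in params.k_list])
    polished: list[tuple[str, str]] = []
    for name, contig in items:
        pieces = _N_RUN.split(_normalize_contig(contig))
        fixed: list[str] = []
        for piece in pieces:
            if not piece or piece[0] == "N":
                fixed.append(piece)  # N runs pass through verbatim
                continue
            frag = piece
            for pass_report, k in zip(report.passes, params.k_list):
                frag, pr = correct_pass(index, frag, k, params)
                pass_report.merge(pr)
            fixed.append(frag)
        polished.append((name, "".join(fixed)))
    return polished, report


class Polisher(BaseEstimator, TransformerMixin):
    """Scikit-learn style polishing estimator.

    ``fit`` builds the short-read FM-index (the evidence base); ``transform``
    polishes draft contigs against it. Parameters mirror
    :class:`PolishParams`; ``eukaryote=True`` overrides ``k_list`` and
    ``min_frac`` with the repeat-tolerant preset.

    Examples
    --------
    >>> p = Polisher().fit(short_reads)          # doctest: +SKIP
    >>> polished = p.transform(draft_contigs)    # doctest: +SKIP
    """

    def __init__(
        self,
        k_list=(21, 59),
        min_count=5,
        min_frac=0.1,
        branch_factor=4,
        cache_size=8,
        eukaryote=False,
    ):
        self.k_list = k_list
        self.min_count = min_count
        self.min_frac = min_frac
        self.branch_factor = branch_factor
        self.cache_size = cache_size
        self.eukaryote = eukaryote

    def _params(self) -> PolishParams:
        base = PolishParams(
            k_list=tuple(self.k_list),
            min_count=self.min_count,
            min_frac=self.min_frac,
            branch_factor=self.branch_factor,
            cache_size=self.cache_size,
        )
        if self.eukaryote:
            base = replace(base, k_list=(21, 59, 80), min_frac=0.0)
        return base

    def fit(self, X, y=None):
        """Build the FM-index from short reads (iterable of ACGT(N) strings,
        or a ShortReadSet, or a prebuilt FmIndex)."""
        params = self._params()  # validates
        if isinstance(X, FmIndex):
            self.index_ = X
        else:
            reads = X if isinstance(X, ShortReadSet) else ShortReadSet(list(X))
            self.index_ = build_index(reads, cache_size=params.cache_size)
        self.n_strings_ = self.index_.n_strings
        self.n_indexed_symbols_ = int(len(self.index_))
        return self

    def transform(self, X):
        """Polish draft contigs; accepts and returns the shapes `polish` does.

        The per-pass tallies of the most recent call are stored on
        ``report_``.
        """
        if not hasattr(self, "index_"):
            raise RuntimeError("Polisher is not fitted; call fit() first")
        keep_strings = bool(X) and not isinstance(X, dict) and isinstance(
            next(iter(X)), str
        )
        polished, report = polish(self.index_, X, self._params())
        self.report_ = report
        if keep_strings:
            return [seq for _, seq in polished]
        return polished
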