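"""Multi-string BWT / FM-index over short accurate reads.

The index is the sole source of k-mer evidence for polishing: it stores the
Burrows-Wheeler transform of every sanitized read fragment *and* its reverse
complement, each terminated by a sentinel, together with rank checkpoints (the
FM-index) and a fixed-depth q-mer interval cache. A single backward search
therefore returns strand-agnostic k-mer support.

Construction is sort-based (numpy prefix doubling over the concatenated
text), which is exact and comfortably handles the tens-of-megabases scale the
polisher targets. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import _kernels

ALPHABET = "$ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_MAGIC = b"FMPLIDX1"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA to uint8 codes ($=0, A=1 ... T=4); other symbols -> 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def sanitize_read(read: str) -> list[str]:
    """Uppercase and split a read at N runs, returning ACGT-only fragments.

    Raises ValueError on symbols outside {A, C, G, T, N}.
    """
    up = read.upper()
    frags: list[str] = []
    start = None
    for i, ch in enumerate(up):
        if ch in "ACGT":
            if start is None:
                start = i
        elif ch == "N":
            if start is not None:
                frags.append(up[start:i])
                start = None
        else:
            raise ValueError(f"invalid symbol {ch!r} in read {read!r}")
    if start is not None:
        frags.append(up[start:])
    return frags


@dataclass
class ShortReadSet:
    """An ordered collection of DNA short reads destined for indexing."""

    reads: list[str]
    source_names: list[str] | None = None

    def sanitized_fragments(self) -> list[str]:
        """ACGT-only fragments after uppercasing and splitting at N runs."""
        frags: list[str] = []
        for idx, read in enumerate(self.reads):
            try:
                frags.extend(sanitize_read(read))
            except ValueError as exc:
                name = (
                    self.source_names[idx]
                    if self.source_names is not None
                    else f"read #{idx}"
                )
                raise ValueError(f"{exc} ({name})") from None
        return frags


def _suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of a uint8 code array via prefix doubling.

    Initial ranks pack 8 symbols (3 bits each) into one key, so doubling
    starts at depth 8; out-of-range positions rank below every symbol.
    """
    n = len(text)
    t = text.astype(np.int64)
    packed = np.zeros(n, dtype=np.int64)
    for j in range(8):
        shifted = np.zeros(n, dtype=np.int64)
        shifted[: n - j] = t[j:]
        packed = (packed << 3) | shifted
    order = np.argsort(packed, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    keys = packed[order]
    changed = np.empty(n, dtype=bool)
    changed[0] = True
    changed[1:] = keys[1:] != keys[:-1]
    rank[order] = np.cumsum(changed) - 1
    k = 8
    while rank[order[-1]] != n - 1:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        combined = rank * np.int64(n + 2) + (key2 + 1)
        order = np.argsort(combined, kind="stable")
        keys = combined[order]
        changed[0] = True
        changed[1:] = keys[1:] != keys[:-1]
        rank[order] = np.cumsum(changed) - 1
        k *= 2
    return order


class FmIndex:
    """FM-index over a multi-string BWT of read fragments + reverse complements.

    Attributes
    ----------
    bwt : uint8 array of symbol codes (decoded form; run-length encoding is
        the on-disk representation).
    symbol_totals : per-symbol counts in the BWT (== counts in the text).
    n_strings : number of indexed strings (2 x sanitized fragments).
    cache_size : depth q of the q-mer interval cache (0 disables it).
    """

    def __init__(self, bwt: np.ndarray, n_strings: int, cache_size: int = 8):
        if bwt.dtype != np.uint8:
            raise ValueError("bwt must be uint8 codes")
        self.bwt = bwt
        self.n_strings = int(n_strings)
        self.cache_size = int(cache_size)
        self.symbol_totals = np.bincount(bwt, minlength=5).astype(np.int64)
        # C array: cum[c] = # symbols < c
        self.cum = np.zeros(6, dtype=np.int64)
        self.cum[1:] = np.cumsum(self.symbol_totals)
        self._ckpt = self._build_checkpoints(bwt)
        if self.cache_size > 0:
            self._cache_lo, self._cache_hi = _kernels.build_cache(
                self.bwt, self._ckpt, self.cum, self.cache_size
            )
        else:
            self._cache_lo = np.zeros(0, dtype=np.int64)
            self._cache_hi = np.zeros(0, dtype=np.int64)

    @staticmethod
    def _build_checkpoints(bwt: np.ndarray) -> np.ndarray:
        n = len(bwt)
        blk = _kernels.BLOCK
        n_blocks = (n + blk - 1) // blk
        padded = np.zeros(n_blocks * blk, dtype=np.uint8)
        padded[:n] = bwt
        padded[n:] = 255  # never matches a real symbol
        blocks = padded.reshape(n_blocks, blk)
        ckpt = np.zeros((n_blocks + 1, 5), dtype=np.uint32)
        for c in range(5):
            per_block = (blocks == c).sum(axis=1, dtype=np.uint32)
            ckpt[1:, c] = np.cumsum(per_block, dtype=np.uint32)
        return ckpt

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.bwt)

    def count(self, kmer: str) -> int:
        """Exact occurrence count of kmer in the indexed text (both strands)."""
        if len(kmer) == 0:
            raise ValueError("empty k-mer")
        pat = encode(kmer)
        if (pat == 0).any() or (pat > 4).any():
            raise ValueError(f"k-mer contains non-ACGT symbol: {kmer!r}")
        return int(
            _kernels.count_kmer_codes(
                self.bwt,
                self._ckpt,
                self.cum,
                pat,
                self._cache_lo,
                self._cache_hi,
                self.cache_size,
            )
        )

    def profile(self, seq: str, k: int) -> np.ndarray:
        """Counts of every k-mer window of seq; windows touching N count 0.

        Returns an empty array when len(seq) < k (caller decides how to
        treat the degenerate case).
        """
        if k < 1:
            raise ValueError("k must be positive")
        n = len(seq)
        if n < k:
            return np.zeros(0, dtype=np.int64)
        codes = encode(seq)
        out = np.zeros(n - k + 1, dtype=np.int64)
        _kernels.profile_kernel(
            self.bwt,
            self._ckpt,
            self.cum,
            codes,
            k,
            self._cache_lo,
            self._cache_hi,
            self.cache_size,
            out,
        )
        return out

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Write the index as a run-length-encoded binary file.

        Layout: 8-byte magic, uint64 n_strings, uint64 n_runs, then
        ``n_runs`` uint8 run symbols and ``n_runs`` uint32 run lengths
        (little endian). The q-mer cache is rebuilt on load.
        """
        sym, lengths = _rle_encode(self.bwt)
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<QQ", self.n_strings, len(sym)))
            fh.write(sym.tobytes())
            fh.write(lengths.astype("<u4").tobytes())

    @classmethod
    def load(cls, path, cache_size: int = 8) -> "FmIndex":
        with open(path, "rb") as fh:
            data = fh.read()
        if len(data) < len(_MAGIC) + 16 or data[: len(_MAGIC)] != _MAGIC:
            raise ValueError(f"{path}: not an fmpolish index (bad magic)")
        n_strings, n_runs = struct.unpack_from("<QQ", data, len(_MAGIC))
        off = len(_MAGIC) + 16
        expect = off + n_runs + 4 * n_runs
        if len(data) != expect:
            raise ValueError(
                f"{path}: truncated or corrupt index "
                f"(expected {expect} bytes, got {len(data)})"
            )
        sym = np.frombuffer(data, dtype=np.uint8, count=n_runs, offset=off)
        lengths = np.frombuffer(
            data, dtype="<u4", count=n_runs, offset=off + n_runs
        )
        if n_runs and sym.max() > 4:
            raise ValueError(f"{path}: invalid symbol code in run list")
        bwt = np.repeat(sym, lengths.astype(np.int64))
        return cls(bwt, n_strings=n_strings, cache_size=cache_size)


def _rle_encode(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(arr) == 0:
        return np.zeros(0, dtype=np.uint8), np.zeros(0, dtype=np.uint32)
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(arr)]))
    return arr[starts].copy(), (ends - starts).astype(np.uint32)


def build_index(
    reads: ShortReadSet | Iterable[str], cache_size: int = 8
) -> FmIndex:
    """Build the FM-index from short reads.

    Every sanitized fragment is indexed in both orientations, each string
    terminated by a sentinel that sorts before A. Deterministic given input
    order.
    """
    if not isinstance(reads, ShortReadSet):
        reads = ShortReadSet(list(reads))
    frags = reads.sanitized_fragments()
    if not frags:
        raise ValueError("no indexable reads after sanitization")
    strings: list[str] = []
    for f in frags:
        strings.append(f)
        strings.append(revcomp(f))
    total = sum(len(s) for s in strings) + len(strings)
    text = np.zeros(total, dtype=np.uint8)
    pos = 0
    for s in strings:
        text[pos : pos + len(s)] = encode(s)
        pos += len(s) + 1  # leave a 0 sentinel
    sa = _suffix_array(text)
    prev = sa - 1
    prev[prev < 0] = total - 1
    bwt = text[prev]
    return FmIndex(bwt, n_strings=len(strings), cache_size=cache_size)


def count_kmer(index: FmIndex, kmer: str) -> int:
    """Occurrences of kmer in the indexed text (fragments + reverse complements)."""
    return index.count(kmer)


def kmer_count_profile(index: FmIndex, seq: str, k: int) -> np.ndarray:
    """Vectorized count_kmer over every window of seq (see FmIndex.profile)."""
    return index.profile(seq, k)


def save_index(index: FmIndex, path) -> None:
    index.save(path)


def load_index(path, cache_size: int = 8) -> FmIndex:
    return FmIndex.load(path, cache_size=cache_size)
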