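"""Numba-compiled hot loops for FM-index rank queries and backward search.

All kernels operate on the packed representation used by
:class:`fmpolish.bwt.FmIndex`:

* ``bwt`` — uint8 symbol codes (0 = sentinel, 1..4 = A,C,G,T),
* ``ckpt`` — exclusive occurrence checkpoints every ``BLOCK`` positions,
  shape ``(n_blocks + 1, 5)`` uint32,
* ``cum`` — the C array: ``cum[c]`` is the number of symbols with code
  < c in the text, length 6.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BLOCK = 64
BLOCK_SHIFT = 6


@njit(cache=True, nogil=True)
def _rank(bwt, ckpt, c, i):
    """Occurrences of symbol code c in bwt[0:i]."""
    blk = i >> BLOCK_SHIFT
    r = np.uint32(ckpt[blk, c])
    for j in range(blk << BLOCK_SHIFT, i):
        if bwt[j] == c:
            r += np.uint32(1)
    return r


@njit(cache=True, nogil=True)
def _step(bwt, ckpt, cum, lo, hi, c):
    """One backward-search step: refine [lo, hi) by prepending symbol c."""
    new_lo = cum[c] + _rank(bwt, ckpt, c, lo)
    new_hi = cum[c] + _rank(bwt, ckpt, c, hi)
    return new_lo, new_hi


@njit(cache=True, nogil=True)
def count_range(bwt, ckpt, cum, pat, lo, hi, upto):
    """Backward search of pat[0:upto] (right to left) from interval [lo, hi).

    Returns the refined (lo, hi); empty intervals short-circuit.
    """
    for j in range(upto - 1, -1, -1):
        lo, hi = _step(bwt, ckpt, cum, lo, hi, pat[j])
        if lo >= hi:
            return lo, lo
    return lo, hi


@njit(cache=True, nogil=True)
def count_kmer_codes(bwt, ckpt, cum, pat, cache_lo, cache_hi, q):
    """Occurrence count of a code-encoded pattern, seeded from the q-mer cache.

    ``cache_lo``/``cache_hi`` hold suffix-array intervals for every q-mer,
    indexed by big-endian base-4 code; q == 0 disables the cache.
    """
    m = pat.shape[0]
    if q > 0 and m >= q:
        code = 0
        for j in range(m - q, m):
            code = (code << 2) | (pat[j] - 1)
        lo = cache_lo[code]
        hi = cache_hi[code]
        if lo >= hi:
            return 0
        lo, hi = count_range(bwt, ckpt, cum, pat, lo, hi, m - q)
    else:
        c = pat[m - 1]
        lo = cum[c]
        hi = cum[c + 1]
        lo, hi = count_range(bwt, ckpt, cum, pat, lo, hi, m - 1)
    return hi - lo


@njit(cache=True, nogil=True)
def profile_kernel(bwt, ckpt, cum, seq, k, cache_lo, cache_hi, q, out):
    """Per-position k-mer counts of seq (codes; >4 marks an invalid base).

    Windows containing an invalid base count 0.
    """
    n = seq.shape[0]
    last_bad = -1  # rightmost invalid position seen so far
    for j in range(k - 1):
        if seq[j] > 4:
            last_bad = j
    for i in range(n - k + 1):
        j = i + k - 1
        if seq[j] > 4:
            last_bad = j
        if last_bad >= i:
            out[i] = 0
        else:
            out[i] = count_kmer_codes(
                bwt, ckpt, cum, seq[i : i + k], cache_lo, cache_hi, q
            )


@njit(cache=True, nogil=True)
def build_cache(bwt, ckpt, cum, q):
    """Suffix-array intervals for all 4**q q-mers, by big-endian base-4 code."""
    size = 1
    los = np.empty(4, dtype=np.int64)
    his = np.empty(4, dtype=np.int64)
    for c in range(4):
        los[c] = cum[c + 1]
        his[c] = cum[c + 2]
    size = 4
    level = 1
    while level < q:
        new_size = size * 4
        nlos = np.empty(new_size, dtype=np.int64)
        nhis = np.empty(new_size, dtype=np.int64)
        for a in range(4):
            off = a * size
            for s in range(size):
                lo = los[s]
                hi = his[s]
                if lo >= hi:
                    nlos[off + s] = lo
                    nhis[off + s] = lo
                else:
                    lo2, hi2 = _step(bwt, ckpt, cum, lo, hi, a + 1)
                    nlos[off + s] = lo2
                    nhis[off + s] = hi2
        los = nlos
        his = nhis
        size = new_size
        level += 1
    return los, his
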