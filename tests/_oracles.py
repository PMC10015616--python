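"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's FM-index and edlib code paths:
substring counting is literal scanning, edit distance is the textbook
Wagner–Fischer dynamic program, and bridging is exhaustive enumeration.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_count(fragments: list[str], kmer: str) -> int:
    """Overlapping occurrences of kmer over fragments + reverse complements."""
    total = 0
    k = len(kmer)
    for frag in fragments:
        for s in (frag, rc(frag)):
            total += sum(1 for i in range(len(s) - k + 1) if s[i : i + k] == kmer)
    return total


def edit_distance_dp(a: str, b: str) -> int:
    """Unit-cost global edit distance by the classic row-rolling DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def enumerate_bridges(
    fragments: list[str],
    left_anchor: str,
    right_anchor: str,
    threshold: int,
    max_extension: int,
) -> set[str]:
    """All strings starting at left_anchor whose every k-mer occurs with
    count >= threshold, terminating the first time the k-suffix equals
    right_anchor, with at most max_extension appended bases."""
    k = len(left_anchor)
    out: set[str] = set()

    def walk(path: str) -> None:
        if len(path) - k > max_extension:
            return
        for base in "ACGT":
            kmer = path[len(path) - k + 1 :] + base
            if kmer == right_anchor:
                out.add(path + base)
            elif brute_count(fragments, kmer) >= threshold:
                walk(path + base)

    walk(left_anchor)
    return out
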