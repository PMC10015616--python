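import random

import pytest

from fmpolish import build_index


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def tiny_index():
    """Index over a handful of fixed reads (deterministic)."""
    reads = ["ACGTACGTAA", "TTGCAACGTT", "CCCCGGGGAT"]
    return build_index(reads, cache_size=4), reads


def tiling_reads(
    genome: str, read_len: int = 150, step: int = 3, reinforce_ends: int = 10
) -> list[str]:
    """Evenly tiled exact reads covering a genome end to end.

    The terminal windows are duplicated ``reinforce_ends`` times so that
    k-mer counts stay flat right up to the sequence ends (random fragment
    sampling, by contrast, ramps down there)."""
    n = len(genome)
    reads = [genome[i : i + read_len] for i in range(0, n - read_len + 1, step)]
    if (n - read_len) % step:
        reads.append(genome[n - read_len :])
    reads += [genome[:read_len]] * reinforce_ends
    reads += [genome[n - read_len :]] * reinforce_ends
    return reads
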