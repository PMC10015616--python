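"""Seeded synthetic data: truth genomes, short reads, and error-injected drafts.

The generator emulates the statistical structure of the polishing study
conditions: ~100x coverage of 150 bp paired short reads drawn from
400 +/- 50 bp fragments, and a draft whose errors are indel-dominated (the
signature of long-read consensus sequence), preferentially placed inside
homopolymer runs. Every output is reproducible bit-exactly from
(parameters, seed), and each draft ships with a ground-truth manifest whose
replay reconstructs it exactly — so polishing can be scored without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bwt import ShortReadSet, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


@dataclass(frozen=True)
class RepeatSpec:
    """A dispersed repeat family: count copies of unit_len bases, each copy
    independently mutated at the given per-base divergence."""

    count: int
    unit_len: int
    divergence: float = 0.0


@dataclass
class Genome:
    sequence: str
    repeat_copies: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def simulate_genome(
    length: int,
    repeat_spec: RepeatSpec | None = None,
    gc: float = 0.5,
    seed: int = 0,
) -> Genome:
    """Random genome with an optional non-overlapping dispersed repeat family."""
    if length < 1000:
        raise ValueError("genome length must be at least 1 kb")
    rng = _rng(seed)
    seq = np.frombuffer(_random_dna(rng, length, gc).encode(), dtype=np.uint8).copy()
    copies: list[tuple[int, int]] = []
    if repeat_spec is not None:
        total = repeat_spec.count * repeat_spec.unit_len
        if total > length:
            raise ValueError("repeat family does not fit in the genome")
        unit = np.frombuffer(
            _random_dna(rng, repeat_spec.unit_len, gc).encode(), dtype=np.uint8
        )
        free = length - total
        gaps = rng.multinomial(free, [1.0 / (repeat_spec.count + 1)] * (repeat_spec.count + 1))
        pos = 0
        for i in range(repeat_spec.count):
            pos += int(gaps[i])
            copy = unit.copy()
            if repeat_spec.divergence > 0:
                hits = np.flatnonzero(
                    rng.random(repeat_spec.unit_len) < repeat_spec.divergence
                )
                for h in hits:
                    copy[h] = _mutate_base(rng, copy[h])
            seq[pos : pos + repeat_spec.unit_len] = copy
            copies.append((pos, pos + repeat_spec.unit_len))
            pos += repeat_spec.unit_len
    return Genome(seq.tobytes().decode(), copies)


def _mutate_base(rng: np.random.Generator, base: int) -> int:
    choices = _BASES[_BASES != base]
    return int(choices[rng.integers(3)])


def simulate_short_reads(
    genome: Genome | str,
    coverage: float = 100.0,
    read_len: int = 150,
    frag_mean: float = 400.0,
    frag_sd: float = 50.0,
    per_base_error: float = 0.0,
    seed: int = 0,
) -> ShortReadSet:
    """Paired short reads from normally distributed fragments.

    Mate 1 is the fragment's 5' read, mate 2 the reverse complement of its
    3' end. The pair count is chosen so that total bases / genome length
    matches the requested coverage exactly (within rounding); substitution
    errors are applied per base at ``per_base_error``.
    """
    g = genome.sequence if isinstance(genome, Genome) else genome
    L = len(g)
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_mean < read_len:
        raise ValueError("fragment mean must be at least the read length")
    rng = _rng(seed)
    n_pairs = int(round(coverage * L / (2 * read_len)))
    frags = np.clip(
        np.rint(rng.normal(frag_mean, frag_sd, size=n_pairs)).astype(np.int64),
        read_len,
        L,
    )
    starts = rng.integers(0, L - frags + 1)
    arr = np.frombuffer(g.encode(), dtype=np.uint8)
    reads: list[str] = []
    names: list[str] = []
    for i in range(n_pairs):
        s, f = int(starts[i]), int(frags[i])
        r1 = g[s : s + read_len]
        r2 = revcomp(g[s + f - read_len : s + f])
        reads.append(r1)
        reads.append(r2)
        names.append(f"sim_{i}/1")
        names.append(f"sim_{i}/2")
    if per_base_error > 0:
        for j, read in enumerate(reads):
            hits = np.flatnonzero(rng.random(len(read)) < per_base_error)
            if hits.size:
                b = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                for h in hits:
                    b[h] = _mutate_base(rng, b[h])
                reads[j] = b.tobytes().decode()
    del arr
    return ShortReadSet(reads, names)


@dataclass(frozen=True)
class DraftErrorProfile:
    """Per-base error rates for draft injection; defaults are indel-dominated
    at a combined 365 errors per 100 kbp (mismatch 65.9, indel 299.5, the
    indel share split 40/60 insertion/deletion), with indels placed 5x more
    readily inside homopolymer runs of length >= 3."""

    sub_rate: float = 65.9e-5
    ins_rate: float = 119.8e-5
    del_rate: float = 179.7e-5
    homopolymer_multiplier: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.sub_rate, self.ins_rate, self.del_rate) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class ManifestRecord:
    """One injected draft error in truth coordinates.

    ``sub``: ref base replaced by alt; ``ins``: alt inserted immediately
    before the ref position (ref empty); ``del``: ref base removed (alt
    empty).
    """

    position: int
    type: str
    ref: str
    alt: str


def _homopolymer_mask(seq: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs of >= min_run."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    boundaries = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def inject_draft_errors(
    genome: Genome | str, profile: DraftErrorProfile
) -> tuple[str, list[ManifestRecord]]:
    """Inject substitutions and indels into a truth genome.

    At most one event is placed per truth position; indel probabilities are
    re-weighted toward homopolymer positions by ``homopolymer_multiplier``
    and renormalized so the realized genome-wide rates match the requested
    ones in expectation. Applying the manifest to the truth reproduces the
    draft exactly.
    """
    g = genome.sequence if isinstance(genome, Genome) else genome
    L = len(g)
    total_rate = profile.sub_rate + profile.ins_rate + profile.del_rate
    if total_rate * 10 > 1:
        raise ValueError("error rates too high to inject faithfully")
    rng = _rng(profile.seed)
    arr = np.frombuffer(g.encode(), dtype=np.uint8)
    hp = _homopolymer_mask(arr)
    w = np.where(hp, profile.homopolymer_multiplier, 1.0)
    w *= L / w.sum()  # indel weights with unit mean
    p_sub = np.full(L, profile.sub_rate)
    p_ins = profile.ins_rate * w
    p_del = profile.del_rate * w
    u = rng.random(L)
    manifest: list[ManifestRecord] = []
    hit = u < (p_sub + p_ins + p_del)
    for pos in np.flatnonzero(hit):
        pos = int(pos)
        x = u[pos]
        ref = g[pos]
        if x < p_sub[pos]:
            alt = chr(_mutate_base(rng, arr[pos]))
            manifest.append(ManifestRecord(pos, "sub", ref, alt))
        elif x < p_sub[pos] + p_ins[pos]:
            # inside a homopolymer, duplicate the run base; otherwise random
            alt = ref if hp[pos] else chr(int(_BASES[rng.integers(4)]))
            manifest.append(ManifestRecord(pos, "ins", "", alt))
        else:
            manifest.append(ManifestRecord(pos, "del", ref, ""))
    return apply_manifest(g, manifest), manifest


def apply_manifest(truth: str, manifest: list[ManifestRecord]) -> str:
    """Replay a manifest against the truth genome (exact reconstruction)."""
    parts: list[str] = []
    cursor = 0
    for rec in sorted(manifest, key=lambda r: r.position):
        parts.append(truth[cursor : rec.position])
        if rec.type == "sub":
            parts.append(rec.alt)
            cursor = rec.position + 1
        elif rec.type == "ins":
            parts.append(rec.alt)
            cursor = rec.position
        elif rec.type == "del":
            cursor = rec.position + 1
        else:
            raise ValueError(f"unknown manifest record type {rec.type!r}")
    parts.append(truth[cursor:])
    return "".join(parts)


@dataclass
class SyntheticDataset:
    """Truth genome + short reads + error-injected draft + its manifest."""

    truth: Genome
    reads: ShortReadSet
    draft: str
    manifest: list[ManifestRecord]


def make_dataset(
    genome_len: int = 100_000,
    coverage: float = 100.0,
    read_len: int = 150,
    frag_mean: float = 400.0,
    frag_sd: float = 50.0,
    per_base_error: float = 0.0,
    profile: DraftErrorProfile | None = None,
    repeat_spec: RepeatSpec | None = None,
    gc: float = 0.5,
    seed: int = 0,
) -> SyntheticDataset:
    """One complete study condition: genome, reads, draft, manifest.

    Sub-seeds for the genome, the reads, and the draft errors are spawned
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_reads, s_draft = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    truth = simulate_genome(genome_len, repeat_spec=repeat_spec, gc=gc, seed=s_genome)
    reads = simulate_short_reads(
        truth,
        coverage=coverage,
        read_len=read_len,
        frag_mean=frag_mean,
        frag_sd=frag_sd,
        per_base_error=per_base_error,
        seed=s_reads,
    )
    if profile is None:
        profile = DraftErrorProfile(seed=s_draft)
    else:
        profile = DraftErrorProfile(
            sub_rate=profile.sub_rate,
            ins_rate=profile.ins_rate,
            del_rate=profile.del_rate,
            homopolymer_multiplier=profile.homopolymer_multiplier,
            seed=profile.seed if profile.seed else s_draft,
        )
    draft, manifest = inject_draft_errors(truth, profile)
    return SyntheticDataset(truth, reads, draft, manifest)


def repeat_rescue_genome(
    n_copies: int = 30,
    unit_len: int = 500,
    flank: int = 500,
    seed: int = 0,
) -> tuple[Genome, int]:
    """Repeat-array genome for the low-frequency-variant scenario.

    ``n_copies`` tandem-adjacent copies of one repeat unit between two
    unique flanks; a single copy (the middle one) carries one true variant
    base. Because the other copies are identical, the variant copy's
    k-mer support is ~1/(n_copies - 1) of the array median — far below a
    10% relative threshold. Returns the genome and the variant's position.
    """
    rng = _rng(seed)
    unit = _random_dna(rng, unit_len)
    left = _random_dna(rng, flank)
    right = _random_dna(rng, flank)
    variant_copy = n_copies // 2
    offset = unit_len // 2
    arr = np.frombuffer(unit.encode(), dtype=np.uint8).copy()
    arr[offset] = _mutate_base(rng, arr[offset])
    variant_unit = arr.tobytes().decode()
    copies = [variant_unit if i == variant_copy else unit for i in range(n_copies)]
    seq = left + "".join(copies) + right
    variant_pos = flank + variant_copy * unit_len + offset
    starts = [flank + i * unit_len for i in range(n_copies)]
    genome = Genome(seq, [(s, s + unit_len) for s in starts])
    return genome, variant_pos


def badread_like_longreads(
    genome: Genome | str,
    n_reads: int = 100,
    length_mean: float = 20_000.0,
    length_sd: float = 12_000.0,
    identity_mean: float = 90.0,
    identity_max: float = 98.0,
    identity_sd: float = 4.0,
    seed: int = 0,
) -> list[str]:
    """Demo long-read sampler: gamma-like lengths, clipped-normal identities.

    Errors at rate (1 - identity/100) are split 25/25/50 between
    substitutions, insertions, and deletions. Convenience for end-to-end
    demonstrations only; polishing never requires long-read simulation.
    """
    g = genome.sequence if isinstance(genome, Genome) else genome
    L = len(g)
    rng = _rng(seed)
    shape = (length_mean / length_sd) ** 2
    scale = length_sd**2 / length_mean
    lengths = np.clip(
        np.rint(rng.gamma(shape, scale, size=n_reads)).astype(np.int64), 100, L
    )
    idents = np.clip(rng.normal(identity_mean, identity_sd, size=n_reads), 50.0, identity_max)
    reads: list[str] = []
    for i in range(n_reads):
        ln = int(lengths[i])
        start = int(rng.integers(0, L - ln + 1))
        frag = g[start : start + ln]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        err = 1.0 - idents[i] / 100.0
        if err > 0:
            arr = np.frombuffer(frag.encode(), dtype=np.uint8)
            out: list[str] = []
            # per-base: substitute / insert / delete with probability err,
            # split 25/25/50 (long-read consensus is deletion-heavy)
            for pos in range(len(arr)):
                x = rng.random()
                if x >= err:
                    out.append(chr(arr[pos]))
                elif x < err * 0.25:
                    out.append(chr(_mutate_base(rng, arr[pos])))
                elif x < err * 0.5:
                    out.append(chr(int(_BASES[rng.integers(4)])))
                    out.append(chr(arr[pos]))
                # else: deletion
            frag = "".join(out)
        reads.append(frag)
    return reads
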