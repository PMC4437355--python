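"""Synthetic founder genomes, serial-passage lineages and error-bearing reads.

This module emulates the laboratory design the rest of the toolkit is tested
against: a single clonal founder genome is split into parallel lineages, each
lineage is propagated through a series of single-colony bottlenecks (one genome
survives each passage, accumulating substitutions), and single-end reads with a
uniform per-base substitution error are drawn from mixtures of the resulting
genomes.  Every operation is deterministic under its seed, and a machine-readable
truth table (the full list of mutation events) allows each terminal genome to be
reconstructed from the founder.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from ._dna import BASES, codes_to_seq, seq_to_codes

__all__ = [
    "GenomeRecord",
    "PassagingDesign",
    "MutationEvent",
    "ReadSimConfig",
    "ReadSet",
    "generate_genome",
    "apply_mutations",
    "simulate_passaging",
    "replay_mutations",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
    "write_truth_table",
]

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence, optionally tagged with the lineage it belongs to."""

    genome_id: str
    sequence: str
    lineage_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r}: sequence must be non-empty")
        if not _ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise ValueError(
                f"genome {self.genome_id!r}: alphabet restricted to A/C/G/T, found {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PassagingDesign:
    """Parameters of the parallel-lineage, serial-bottleneck passaging experiment.

    Defaults reproduce the study design: 12 parallel lineages carried through
    8 single-colony bottleneck passages.  ``mutations_per_passage`` is the mean
    of a Poisson draw per passage, or an exact per-passage count when
    ``deterministic`` is set.  ``founder_mutation_pool`` models pre-existing
    variation in the clonal source culture: pool variants are drawn once and
    assigned at passage 0 to random subsets of lineages.
    """

    n_lineages: int = 12
    n_passages: int = 8
    mutations_per_passage: float = 2.0
    founder_mutation_pool: int = 80
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if self.mutations_per_passage < 0:
            raise ValueError("mutations_per_passage must be non-negative")
        if self.founder_mutation_pool < 0:
            raise ValueError("founder_mutation_pool must be non-negative")


@dataclass(frozen=True)
class MutationEvent:
    """One substitution: lineage, passage at which it arose, 0-based position."""

    lineage_id: str
    passage_index: int
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")


@dataclass(frozen=True)
class ReadSimConfig:
    """Single-end read simulation settings for a genome mixture."""

    read_length: int
    coverage: float
    proportions: dict[str, float]
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must satisfy 0 <= e < 1")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1 (got {total})")


@dataclass
class ReadSet:
    """Simulated single-end reads, held as a base-code matrix for fast k-mer work.

    ``names`` encode the truth for each read (source genome, 0-based start on the
    forward strand, strand) — a simulator convention for bookkeeping, not a claim
    about real read headers.  ``n_errors`` is the realized number of substituted
    bases across the whole set.
    """

    names: list[str]
    codes_matrix: np.ndarray  # (n_reads, read_length) uint8
    n_errors: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.names)

    @property
    def read_length(self) -> int:
        return int(self.codes_matrix.shape[1]) if self.codes_matrix.size else 0

    def sequences(self) -> Iterator[str]:
        for row in self.codes_matrix:
            yield codes_to_seq(row)

    def records(self) -> Iterator[tuple[str, str]]:
        for name, row in zip(self.names, self.codes_matrix):
            yield name, codes_to_seq(row)


# ---------------------------------------------------------------------------
# genome generation and mutation


def generate_genome(length: int, seed: int, genome_id: str = "genome") -> GenomeRecord:
    """Generate an i.i.d.-uniform random genome of the given length."""
    if length < 1:
        raise ValueError("length must be a positive integer")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return GenomeRecord(genome_id=genome_id, sequence=codes_to_seq(codes))


def _mutate_codes(
    codes: np.ndarray, n_mut: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Substitute ``n_mut`` distinct positions in-place; return (positions, ref, alt)."""
    positions = np.sort(rng.choice(codes.size, size=n_mut, replace=False))
    ref = codes[positions].copy()
    shift = rng.integers(1, 4, size=n_mut, dtype=np.uint8)
    alt = (ref + shift) % 4
    codes[positions] = alt
    return positions, ref, alt


def apply_mutations(
    genome: GenomeRecord,
    n_mut: int,
    seed: int,
    *,
    lineage_id: str | None = None,
    passage_index: int = 0,
) -> tuple[GenomeRecord, list[MutationEvent]]:
    """Substitute exactly ``n_mut`` distinct positions; the input is untouched."""
    if n_mut < 0:
        raise ValueError("n_mut must be non-negative")
    if n_mut > len(genome):
        raise ValueError(f"n_mut ({n_mut}) exceeds genome length ({len(genome)})")
    lid = lineage_id if lineage_id is not None else (genome.lineage_id or genome.genome_id)
    if n_mut == 0:
        return dataclasses.replace(genome, lineage_id=lid), []
    rng = np.random.default_rng(seed)
    codes = seq_to_codes(genome.sequence).copy()
    positions, ref, alt = _mutate_codes(codes, n_mut, rng)
    events = [
        MutationEvent(lid, passage_index, int(p), chr(BASES[r]), chr(BASES[a]))
        for p, r, a in zip(positions, ref, alt)
    ]
    mutated = GenomeRecord(
        genome_id=genome.genome_id, sequence=codes_to_seq(codes), lineage_id=lid
    )
    return mutated, events


def simulate_passaging(
    founder: GenomeRecord, design: PassagingDesign
) -> tuple[list[GenomeRecord], list[MutationEvent]]:
    """Run the parallel-lineage serial-bottleneck experiment.

    Each lineage propagates exactly one genome through every passage (the
    single-colony bottleneck), accumulating per-passage substitutions.  Founder
    pool variants (passage_index 0) are drawn once and shared by random subsets
    of lineages, modelling variation already present in the source culture.
    Returns the terminal genome of every lineage plus the full truth table.
    """
    rng = np.random.default_rng(design.seed)
    L = len(founder)
    founder_codes = seq_to_codes(founder.sequence)
    lineage_ids = [f"L{i + 1:02d}" for i in range(design.n_lineages)]

    # Founder pool: (position, alt) drawn once, each assigned to a random subset.
    pool: list[tuple[int, np.uint8, np.uint8, np.ndarray]] = []
    if design.founder_mutation_pool:
        pool_pos = rng.choice(L, size=min(design.founder_mutation_pool, L), replace=False)
        for p in np.sort(pool_pos):
            ref = founder_codes[p]
            alt = (ref + rng.integers(1, 4)) % 4
            members = rng.random(design.n_lineages) < 0.5
            pool.append((int(p), ref, np.uint8(alt), members))

    genomes: list[GenomeRecord] = []
    events: list[MutationEvent] = []
    for li, lid in enumerate(lineage_ids):
        codes = founder_codes.copy()
        for p, ref, alt, members in pool:
            if members[li]:
                codes[p] = alt
                events.append(
                    MutationEvent(lid, 0, p, chr(BASES[ref]), chr(BASES[alt]))
                )
        for passage in range(1, design.n_passages + 1):
            if design.deterministic:
                n = int(design.mutations_per_passage)
            else:
                n = int(rng.poisson(design.mutations_per_passage))
            if n == 0:
                continue
            positions, ref, alt = _mutate_codes(codes, n, rng)
            events.extend(
                MutationEvent(lid, passage, int(p), chr(BASES[r]), chr(BASES[a]))
                for p, r, a in zip(positions, ref, alt)
            )
        genomes.append(
            GenomeRecord(
                genome_id=f"{founder.genome_id}:{lid}",
                sequence=codes_to_seq(codes),
                lineage_id=lid,
            )
        )
    return genomes, events


def replay_mutations(
    founder: GenomeRecord, events: Sequence[MutationEvent], lineage_id: str
) -> GenomeRecord:
    """Reconstruct a terminal genome from the founder and its truth-table events."""
    codes = seq_to_codes(founder.sequence).copy()
    mine = [e for e in events if e.lineage_id == lineage_id]
    mine.sort(key=lambda e: e.passage_index)
    for e in mine:
        if chr(BASES[codes[e.position]]) != e.ref_base:
            raise ValueError(
                f"truth table inconsistent at position {e.position} for {lineage_id}"
            )
        codes[e.position] = seq_to_codes(e.alt_base)[0]
    return GenomeRecord(
        genome_id=f"{founder.genome_id}:{lineage_id}",
        sequence=codes_to_seq(codes),
        lineage_id=lineage_id,
    )


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(genomes: Sequence[GenomeRecord], config: ReadSimConfig) -> ReadSet:
    """Draw uniform single-end reads from a genome mixture with substitution errors.

    Per genome, the read count is round(coverage * proportion * L / read_length);
    each read starts uniformly on the forward strand and is reported from either
    strand with equal probability.  Each base is flipped to one of the three
    other bases with probability ``error_rate``.  Deterministic under the seed.
    """
    by_id = {g.genome_id: g for g in genomes}
    for gid in config.proportions:
        if gid not in by_id:
            raise ValueError(f"proportions name unknown genome {gid!r}")
    rl = config.read_length
    for gid in config.proportions:
        if rl > len(by_id[gid]):
            raise ValueError(
                f"read_length {rl} exceeds genome {gid!r} length {len(by_id[gid])}"
            )

    rng = np.random.default_rng(config.seed)
    chunks: list[np.ndarray] = []
    names: list[str] = []
    total_errors = 0
    for gid in sorted(config.proportions):
        genome = by_id[gid]
        L = len(genome)
        n_reads = int(round(config.coverage * config.proportions[gid] * L / rl))
        if n_reads == 0:
            continue
        gcodes = seq_to_codes(genome.sequence)
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        reads = gcodes[starts[:, None] + np.arange(rl)[None, :]].copy()
        reverse = rng.random(n_reads) < 0.5
        if reverse.any():
            reads[reverse] = 3 - reads[reverse][:, ::-1]
        if config.error_rate > 0:
            flip = rng.random(reads.shape) < config.error_rate
            n_flip = int(flip.sum())
            if n_flip:
                shift = rng.integers(1, 4, size=n_flip, dtype=np.uint8)
                reads[flip] = (reads[flip] + shift) % 4
            total_errors += n_flip
        strand = np.where(reverse, "-", "+")
        names.extend(
            f"{gid}|p{int(s)}|{st}|r{i}" for i, (s, st) in enumerate(zip(starts, strand))
        )
        chunks.append(reads)

    matrix = (
        np.concatenate(chunks, axis=0) if chunks else np.empty((0, rl), dtype=np.uint8)
    )
    return ReadSet(names=names, codes_matrix=matrix, n_errors=total_errors)


def expected_false_snps(genome_length: int, coverage: float, error_rate: float) -> float:
    """Expected erroneous-base count: error_rate * coverage * genome_length.

    At a 0.1% per-base error rate this is one false SNP per 1,000 sequenced
    bases — 5,000 over a 5 Mb genome at 1x coverage.
    """
    return error_rate * coverage * genome_length


# ---------------------------------------------------------------------------
# writers


def write_fasta(genomes: Sequence[GenomeRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def write_fastq(reads: ReadSet, path: str | Path, quality_char: str = "I") -> None:
    """Write Sanger Phred+33 FASTQ with a constant quality score."""
    qual = quality_char * reads.read_length
    with open(path, "w") as fh:
        for name, seq in reads.records():
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_truth_table(events: Sequence[MutationEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lineage_id\tpassage\tposition\tref\talt\n")
        for e in events:
            fh.write(
                f"{e.lineage_id}\t{e.passage_index}\t{e.position}\t{e.ref_base}\t{e.alt_base}\n"
            )


def write_manifest(design: PassagingDesign, config: ReadSimConfig | None, path: str | Path) -> None:
    payload = {"design": dataclasses.asdict(design)}
    if config is not None:
        payload["reads"] = dataclasses.asdict(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
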