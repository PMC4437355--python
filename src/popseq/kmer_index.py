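"""Canonical k-mer signatures for genomes and strand-aware multisets for reads.

A genome's *signature* is the set of all canonical k-mers it contains — the
sparse form of the 0/1 presence vector over the 4^k possible k-mers (the dense
vector is never materialized).  A k-mer is canonical if it is the
lexicographically smaller of itself and its reverse complement, so presence is
strand-collapsed; read counting nevertheless tallies how often each canonical
k-mer was seen in its forward versus reverse-complement orientation, which the
variant caller uses for strand confirmation.

Internally k-mers are 2-bit packed integers held in sorted numpy arrays; all
set operations are vectorized.  The string-facing API (``canonicalize``,
``KmerSet.kmers`` ...) is intended for small inputs and tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import seq_to_codes
from .synthetic_data import GenomeRecord, ReadSet
from .taxonomy_scorer import Lineage, parse_lineage

logger = logging.getLogger("popseq")

__all__ = [
    "DEFAULT_K",
    "canonicalize",
    "encode_kmer",
    "decode_kmers",
    "revcomp_codes",
    "kmer_space_size",
    "KmerSet",
    "KmerSignature",
    "KmerMultiset",
    "ReferenceIndex",
    "build_signature",
    "count_read_kmers",
    "build_reference_index",
    "read_fasta",
    "load_taxonomy",
]

DEFAULT_K = 12
MIN_K, MAX_K = 4, 31

INDEX_FORMAT_VERSION = 1


def _check_k(k: int) -> None:
    if not (1 <= k <= MAX_K):
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")


def kmer_space_size(k: int = DEFAULT_K) -> int:
    """Number of possible k-mer vector elements, 4^k (16,777,216 at k = 12)."""
    _check_k(k)
    return 4**k


# ---------------------------------------------------------------------------
# integer k-mer codes


def encode_kmer(kmer: str) -> int:
    codes = seq_to_codes(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def decode_kmers(codes: np.ndarray | Iterable[int], k: int) -> list[str]:
    """Vectorized decoding of packed k-mer codes back to strings."""
    arr = np.asarray(list(codes) if not isinstance(codes, np.ndarray) else codes, dtype=np.int64)
    if arr.size == 0:
        return []
    chars = np.empty((arr.size, k), dtype=np.uint8)
    for j in range(k):
        digit = (arr >> (2 * (k - 1 - j))) & 3
        chars[:, j] = digit
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)[chars]
    flat = letters.reshape(arr.size, k).view(f"S{k}").ravel()
    return [b.decode("ascii") for b in flat]


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes, vectorized."""
    tmp = np.asarray(codes, dtype=np.int64).copy()
    rc = np.zeros_like(tmp)
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def canonicalize(kmer: str) -> str:
    """Return min(kmer, reverse_complement(kmer)) lexicographically.

    Rejects non-ACGT characters; callers scanning sequences skip such windows
    instead of calling this.
    """
    code = np.array([encode_kmer(kmer)], dtype=np.int64)
    k = len(kmer)
    canon = np.minimum(code, revcomp_codes(code, k))
    return decode_kmers(canon, k)[0]


def _window_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of every valid (all-ACGT) length-k window, in genome order."""
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid_base = base_codes < 4
    cs = np.concatenate(([0], np.cumsum(valid_base)))
    valid = (cs[k:] - cs[:-k]) == k
    c = np.where(valid_base, base_codes, 0).astype(np.int64)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = (code << 2) | c[j : j + n]
    return code[valid]


def _window_codes_with_mask(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Like _window_codes but returns (codes for all windows, validity mask)."""
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    valid_base = base_codes < 4
    cs = np.concatenate(([0], np.cumsum(valid_base)))
    valid = (cs[k:] - cs[:-k]) == k
    c = np.where(valid_base, base_codes, 0).astype(np.int64)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = (code << 2) | c[j : j + n]
    return code, valid


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class KmerSet:
    """A set of canonical k-mers, stored as a sorted array of packed codes."""

    k: int
    codes: np.ndarray  # sorted unique int64

    def __post_init__(self) -> None:
        _check_k(self.k)

    @classmethod
    def from_strings(cls, kmers: Iterable[str], k: int | None = None) -> "KmerSet":
        kmers = list(kmers)
        if k is None:
            if not kmers:
                raise ValueError("cannot infer k from an empty k-mer collection")
            k = len(kmers[0])
        canon = []
        for s in kmers:
            if len(s) != k:
                raise ValueError(f"k-mer {s!r} does not have length {k}")
            canon.append(encode_kmer(canonicalize(s)))
        return cls(k=k, codes=np.unique(np.asarray(canon, dtype=np.int64)))

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str | int) -> bool:
        code = encode_kmer(canonicalize(kmer)) if isinstance(kmer, str) else int(kmer)
        i = np.searchsorted(self.codes, code)
        return bool(i < self.codes.size and self.codes[i] == code)

    @property
    def kmers(self) -> frozenset[str]:
        """Materialize the set of canonical k-mer strings (O(n); for small sets)."""
        return frozenset(decode_kmers(self.codes, self.k))

    def intersection_size(self, other: "KmerSet") -> int:
        return int(
            np.intersect1d(self.codes, other.codes, assume_unique=True).size
        )

    def intersection(self, other: "KmerSet") -> "KmerSet":
        return KmerSet(self.k, np.intersect1d(self.codes, other.codes, assume_unique=True))

    def difference(self, other: "KmerSet") -> "KmerSet":
        return KmerSet(self.k, np.setdiff1d(self.codes, other.codes, assume_unique=True))

    def union(self, other: "KmerSet") -> "KmerSet":
        return KmerSet(self.k, np.union1d(self.codes, other.codes))

    def member_mask(self, codes: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the given packed codes are in this set."""
        if self.codes.size == 0:
            return np.zeros(np.asarray(codes).size, dtype=bool)
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.clip(idx, 0, self.codes.size - 1)
        return self.codes[idx_c] == codes


@dataclass(frozen=True)
class KmerSignature(KmerSet):
    """A genome's canonical k-mer presence set (its sparse 0/1 vector)."""

    genome_id: str = ""


@dataclass
class KmerMultiset:
    """Canonical k-mer counts over a read set, with per-orientation tallies.

    ``codes`` is sorted/unique; ``totals[i]`` = times codes[i] was observed;
    ``as_forward[i]`` = observations where the window equalled its canonical
    form as read (reverse-complement observations make up the rest).
    """

    k: int
    codes: np.ndarray
    totals: np.ndarray
    as_forward: np.ndarray
    n_reads: int
    n_kmers_total: int

    @property
    def as_reverse(self) -> np.ndarray:
        return self.totals - self.as_forward

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    def get(self, kmer: str) -> tuple[int, int, int]:
        """(total, as_forward, as_reverse) for one canonical k-mer (0s if absent)."""
        code = encode_kmer(canonicalize(kmer))
        i = np.searchsorted(self.codes, code)
        if i < self.codes.size and self.codes[i] == code:
            return int(self.totals[i]), int(self.as_forward[i]), int(self.as_reverse[i])
        return 0, 0, 0

    def counts(self) -> dict[str, tuple[int, int, int]]:
        """Materialize the full map canonical k-mer -> (total, fwd, rev)."""
        keys = decode_kmers(self.codes, self.k)
        return {
            key: (int(t), int(f), int(t - f))
            for key, t, f in zip(keys, self.totals, self.as_forward)
        }

    def distinct(self) -> KmerSet:
        return KmerSet(self.k, self.codes)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int | tuple[int, int]], k: int | None = None, n_reads: int = 0
    ) -> "KmerMultiset":
        """Build from a small map k-mer -> total or (total, as_forward); for tests."""
        if not counts:
            raise ValueError("counts must be non-empty")
        if k is None:
            k = len(next(iter(counts)))
        codes, totals, fwd = [], [], []
        for kmer, v in counts.items():
            total, f = (v, v) if isinstance(v, int) else (v[0], v[1])
            codes.append(encode_kmer(canonicalize(kmer)))
            totals.append(total)
            fwd.append(f)
        order = np.argsort(codes)
        codes_a = np.asarray(codes, dtype=np.int64)[order]
        if np.unique(codes_a).size != codes_a.size:
            raise ValueError("counts map contains non-canonical duplicates")
        totals_a = np.asarray(totals, dtype=np.int64)[order]
        fwd_a = np.asarray(fwd, dtype=np.int64)[order]
        return cls(
            k=k,
            codes=codes_a,
            totals=totals_a,
            as_forward=fwd_a,
            n_reads=n_reads,
            n_kmers_total=int(totals_a.sum()),
        )


# ---------------------------------------------------------------------------
# builders


def build_signature(genome: GenomeRecord, k: int = DEFAULT_K) -> KmerSignature:
    """All canonical k-mers of a genome; empty (with a warning) when shorter than k."""
    _check_k(k)
    if len(genome) < k:
        logger.warning(
            "genome %s shorter than k=%d: empty signature", genome.genome_id, k
        )
        return KmerSignature(k=k, codes=np.empty(0, dtype=np.int64), genome_id=genome.genome_id)
    base_codes = seq_to_codes(genome.sequence)
    fwd = _window_codes(base_codes, k)
    canon = np.minimum(fwd, revcomp_codes(fwd, k))
    return KmerSignature(k=k, codes=np.unique(canon), genome_id=genome.genome_id)


def _reads_to_buffer(reads, k: int) -> tuple[np.ndarray, int]:
    """Concatenate read base codes with invalid separators; return (buffer, n_reads)."""
    if isinstance(reads, ReadSet) or hasattr(reads, "codes_matrix"):
        matrix = reads.codes_matrix
        n_reads = matrix.shape[0]
        if n_reads == 0:
            return np.empty(0, dtype=np.uint8), 0
        sep = np.full((n_reads, 1), 255, dtype=np.uint8)
        return np.hstack([matrix, sep]).ravel(), n_reads
    if isinstance(reads, (str, Path)):
        with open(reads) as fh:
            seqs = []
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    seqs.append(seq)
            except ValueError as exc:
                raise ValueError(
                    f"unreadable FASTQ record around entry {len(seqs) + 1} in {reads}: {exc}"
                ) from exc
    else:
        seqs = []
        for item in reads:
            seqs.append(item[1] if isinstance(item, tuple) else str(item))
    if not seqs:
        return np.empty(0, dtype=np.uint8), 0
    buffer = seq_to_codes("N".join(seqs))
    return buffer, len(seqs)


def count_read_kmers(reads, k: int = DEFAULT_K) -> KmerMultiset:
    """Count canonical k-mers across a read set with per-orientation tallies.

    ``reads`` may be a FASTQ path, a :class:`~popseq.synthetic_data.ReadSet`,
    or an iterable of sequence strings / (name, sequence) tuples.  Windows
    containing non-ACGT characters are skipped (counted in aggregate in a log
    message).  A window observed in its canonical orientation increments
    ``as_forward``; observed as the reverse complement, ``as_reverse``.
    """
    _check_k(k)
    buffer, n_reads = _reads_to_buffer(reads, k)
    fwd = _window_codes(buffer, k)
    n_windows_all = max(buffer.size - k + 1, 0)
    skipped = n_windows_all - fwd.size
    if skipped > 0:
        logger.info(
            "count_read_kmers: skipped %d windows (non-ACGT bases or read boundaries)",
            skipped,
        )
    if fwd.size == 0:
        return KmerMultiset(
            k=k,
            codes=np.empty(0, dtype=np.int64),
            totals=np.empty(0, dtype=np.int64),
            as_forward=np.empty(0, dtype=np.int64),
            n_reads=n_reads,
            n_kmers_total=0,
        )
    rc = revcomp_codes(fwd, k)
    canon = np.minimum(fwd, rc)
    is_forward = fwd <= rc
    codes, inverse, totals = np.unique(canon, return_inverse=True, return_counts=True)
    fwd_counts = np.bincount(inverse, weights=is_forward).astype(np.int64)
    return KmerMultiset(
        k=k,
        codes=codes,
        totals=totals.astype(np.int64),
        as_forward=fwd_counts,
        n_reads=n_reads,
        n_kmers_total=int(totals.sum()),
    )


# ---------------------------------------------------------------------------
# reference index


@dataclass
class ReferenceIndex:
    """Signatures for a set of reference genomes plus their taxonomy.

    Lookup of a k-mer returns exactly the genomes whose signatures contain it;
    the ``inverted`` map (k-mer string -> set of genome ids) is the literal
    transpose of the signatures, materialized lazily and meant for small
    indexes — ``genomes_with`` answers the same query via binary search.
    """

    k: int
    signatures: list[KmerSignature]
    lineages: dict[str, Lineage]

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("reference index needs at least one genome")
        for sig in self.signatures:
            if sig.genome_id not in self.lineages:
                raise KeyError(f"genome {sig.genome_id!r} has no lineage row")

    @property
    def genome_ids(self) -> list[str]:
        return [s.genome_id for s in self.signatures]

    @property
    def vector_space_size(self) -> int:
        return kmer_space_size(self.k)

    def get_signature(self, genome_id: str) -> KmerSignature:
        for s in self.signatures:
            if s.genome_id == genome_id:
                return s
        raise KeyError(f"no signature for genome {genome_id!r}")

    def genomes_with(self, kmer: str | int) -> set[str]:
        code = encode_kmer(canonicalize(kmer)) if isinstance(kmer, str) else int(kmer)
        return {s.genome_id for s in self.signatures if code in s}

    @cached_property
    def inverted(self) -> dict[str, set[str]]:
        table: dict[str, set[str]] = {}
        for sig in self.signatures:
            for kmer in decode_kmers(sig.codes, self.k):
                table.setdefault(kmer, set()).add(sig.genome_id)
        return table

    # -- persistence (versioned JSON container; codes as 2-bit-packed hex) --

    def save(self, path: str | Path) -> None:
        width = (2 * self.k + 3) // 4
        payload = {
            "format": "popseq-index",
            "version": INDEX_FORMAT_VERSION,
            "k": self.k,
            "genomes": [
                {
                    "genome_id": s.genome_id,
                    "lineage": self.lineages[s.genome_id].joined(),
                    "kmers_hex": [format(int(c), f"0{width}x") for c in s.codes],
                }
                for s in self.signatures
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceIndex":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "popseq-index":
            raise ValueError(f"{path}: not a popseq index file")
        if payload.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported index version {payload.get('version')}")
        k = payload["k"]
        signatures = []
        lineages = {}
        for entry in payload["genomes"]:
            codes = np.asarray([int(h, 16) for h in entry["kmers_hex"]], dtype=np.int64)
            signatures.append(KmerSignature(k=k, codes=codes, genome_id=entry["genome_id"]))
            lineages[entry["genome_id"]] = parse_lineage(entry["lineage"])
        return cls(k=k, signatures=signatures, lineages=lineages)


def build_reference_index(
    genomes: Sequence[GenomeRecord],
    lineages: Mapping[str, Lineage | str] | str | Path,
    k: int = DEFAULT_K,
) -> ReferenceIndex:
    """Build signatures plus taxonomy for a non-empty list of reference genomes."""
    if not genomes:
        raise ValueError("reference index needs at least one genome")
    if isinstance(lineages, (str, Path)):
        lineage_map = load_taxonomy(lineages)
    else:
        lineage_map = {
            gid: (lin if isinstance(lin, Lineage) else parse_lineage(lin))
            for gid, lin in lineages.items()
        }
    for g in genomes:
        if g.genome_id not in lineage_map:
            raise KeyError(f"genome {g.genome_id!r} has no lineage row")
    signatures = [build_signature(g, k) for g in genomes]
    return ReferenceIndex(k=k, signatures=signatures, lineages=dict(lineage_map))


# ---------------------------------------------------------------------------
# file readers


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (possibly line-folded) multi-record FASTA into GenomeRecords."""
    records = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            records.append(GenomeRecord(genome_id=title.split()[0], sequence=seq.upper()))
    return records


def load_taxonomy(path: str | Path) -> dict[str, Lineage]:
    """Read a TSV of ``genome_id<TAB>term1;term2;...;termN`` (root -> leaf)."""
    table: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            table[parts[0]] = parse_lineage(parts[1])
    return table
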