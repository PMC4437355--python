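"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles deliberately use plain Python strings and sets so they share no
code path with the vectorized implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import popseq as pq

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def brute_signature(seq: str, k: int) -> set[str]:
    """Window-scan signature oracle over plain strings."""
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            out.add(brute_canonical(w))
    return out


def brute_count(seqs: list[str], k: int) -> dict[str, tuple[int, int, int]]:
    """Counting oracle: canonical k-mer -> (total, as_forward, as_reverse)."""
    counts: dict[str, list[int]] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if not set(w) <= set("ACGT"):
                continue
            c = brute_canonical(w)
            entry = counts.setdefault(c, [0, 0, 0])
            entry[0] += 1
            if w == c:
                entry[1] += 1
            else:
                entry[2] += 1
    return {k_: tuple(v) for k_, v in counts.items()}


def dense_cosine(a: set[str], b: set[str], k: int) -> float:
    """Cosine of the dense 0/1 vectors over the full canonical k-mer space."""
    from itertools import product

    space = sorted({brute_canonical("".join(p)) for p in product("ACGT", repeat=k)})
    va = np.array([1.0 if x in a else 0.0 for x in space])
    vb = np.array([1.0 if x in b else 0.0 for x in space])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


@pytest.fixture(scope="session")
def small_genome() -> pq.GenomeRecord:
    return pq.generate_genome(1000, seed=7, genome_id="g1")


@pytest.fixture(scope="session")
def trio_index() -> pq.ReferenceIndex:
    """Three unrelated 5 kb genomes with a simple taxonomy."""
    genomes = [pq.generate_genome(5000, seed=s, genome_id=f"g{s}") for s in (1, 2, 3)]
    lineages = {
        "g1": "Bacteria;Firmicutes;Bacillus;anthracis;Ames",
        "g2": "Bacteria;Firmicutes;Bacillus;cereus;ATCC14579",
        "g3": "Bacteria;Proteobacteria;Escherichia;coli;K12",
    }
    return pq.build_reference_index(genomes, lineages, k=12)
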