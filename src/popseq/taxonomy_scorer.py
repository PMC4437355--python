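"""Position-weighted, frequency-driven scoring of taxonomic lineages.

A lineage is an ordered list of taxon terms, root first (kingdom ... species /
strain).  Terms are weighted by their average *relative* position across all
lineages under consideration rather than by absolute rank: broad terms near the
start of lineages get weights near 1, narrow terms near the end get small
weights (floored at an epsilon so strain-level terms still contribute).  A
lineage's score is the weight-normalized mean of the cosine-mass support of its
terms among the matched references, so lineages supported by many / strong
matches score high and phylogenetically close lineages score similarly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .matcher import MatchScore

__all__ = [
    "Lineage",
    "TermWeightTable",
    "LineageScore",
    "parse_lineage",
    "compute_term_weights",
    "score_lineages",
]

DEFAULT_LEAF_EPSILON = 0.05


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic terms, root -> leaf."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lineage must contain at least one term")
        if any(not t for t in self.terms):
            raise ValueError("lineage terms must be non-empty strings")

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def joined(self) -> str:
        return ";".join(self.terms)


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited root->leaf lineage string."""
    return Lineage(tuple(t.strip() for t in text.strip().split(";")))


@dataclass(frozen=True)
class TermWeightTable:
    """Per-term average relative position, weight (1 - avg position) and frequency."""

    entries: Mapping[str, tuple[float, float, int]]  # term -> (avg_rel_pos, weight, freq)

    def weight(self, term: str) -> float:
        return self.entries[term][1]

    def __contains__(self, term: str) -> bool:
        return term in self.entries


@dataclass(frozen=True)
class LineageScore:
    """Scores in [0, 1] keyed by joined lineage string, comparable within a sample."""

    scores: Mapping[str, float]

    def __getitem__(self, lineage: str) -> float:
        return self.scores[lineage]


def compute_term_weights(
    lineages: Sequence[Lineage], epsilon: float = DEFAULT_LEAF_EPSILON
) -> TermWeightTable:
    """Weight each term by 1 minus its average relative position across lineages.

    The relative position of the term at 0-based index i in an N-term lineage is
    i / (N - 1), taken as 0 for single-term lineages; averaging over relative
    rather than absolute positions normalizes for lineages that carry different
    numbers of intermediate terms.  Weights are floored at ``epsilon`` so leaf
    terms keep a nonzero say.
    """
    if not lineages:
        raise ValueError("need at least one lineage")
    positions: dict[str, list[float]] = {}
    for lin in lineages:
        n = len(lin)
        for i, term in enumerate(lin.terms):
            rel = 0.0 if n == 1 else i / (n - 1)
            positions.setdefault(term, []).append(rel)
    entries = {}
    for term, rels in positions.items():
        avg = sum(rels) / len(rels)
        entries[term] = (avg, max(1.0 - avg, epsilon), len(rels))
    return TermWeightTable(entries=entries)


def score_lineages(
    matches: Sequence["MatchScore"],
    lineages: Mapping[str, Lineage],
    weights: TermWeightTable | None = None,
) -> LineageScore:
    """Score every lineage attached to the matched references.

    Term support f(term) is the fraction of total cosine mass carried by matches
    whose lineage contains the term; a lineage scores the weighted mean
    sum(w(t) * f(t)) / sum(w(t)) over its terms.  Unanimously supported lineages
    score 1; unsupported ones score 0; the score is invariant to rescaling all
    cosines by a positive constant.

    ``lineages`` maps genome_id -> Lineage (a ReferenceIndex's ``lineages``
    mapping works directly).
    """
    if not matches:
        raise ValueError("need at least one match to score lineages")
    lineages = getattr(lineages, "lineages", lineages)  # accept a ReferenceIndex
    for m in matches:
        if m.genome_id not in lineages:
            raise KeyError(f"match {m.genome_id!r} has no lineage entry")
    match_lineages = [lineages[m.genome_id] for m in matches]
    if weights is None:
        weights = compute_term_weights(match_lineages)

    total_mass = sum(m.cosine for m in matches)
    support: dict[str, float] = {}
    for m, lin in zip(matches, match_lineages):
        for term in set(lin.terms):
            support[term] = support.get(term, 0.0) + m.cosine

    scores: dict[str, float] = {}
    for lin in {l.joined(): l for l in match_lineages}.values():
        num = 0.0
        den = 0.0
        for term in lin.terms:
            w = weights.weight(term) if term in weights else DEFAULT_LEAF_EPSILON
            f = (support.get(term, 0.0) / total_mass) if total_mass > 0 else 0.0
            num += w * f
            den += w
        scores[lin.joined()] = num / den if den > 0 else 0.0
    return LineageScore(scores=scores)


def score_for(
    lineage: Lineage,
    matches: Sequence["MatchScore"],
    lineages: Mapping[str, Lineage],
    weights: TermWeightTable,
) -> float:
    """Score one arbitrary lineage (possibly absent from the matches) directly."""
    total_mass = sum(m.cosine for m in matches)
    support: dict[str, float] = {}
    for m in matches:
        for term in set(lineages[m.genome_id].terms):
            support[term] = support.get(term, 0.0) + m.cosine
    num = 0.0
    den = 0.0
    for term in lineage.terms:
        w = weights.weight(term) if term in weights else DEFAULT_LEAF_EPSILON
        f = (support.get(term, 0.0) / total_mass) if total_mass > 0 else 0.0
        num += w * f
        den += w
    return num / den if den > 0 else 0.0
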