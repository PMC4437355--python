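"""End-to-end sample profiles, variant confirmation, gap analysis and attribution.

A sample profile is the self-contained genetic fingerprint of one read set: the
calibrant-thresholded canonical k-mer set, ranked reference matches with
posteriors and abundances, lineage scores and strand-confirmed novel k-mers.
Profiles are serialized to versioned JSON (retained k-mers as sorted
2-bit-packed hex strings) and can be compared to each other — reference-free —
by binary cosine of their retained sets: the sample itself is the database.
Samples whose profile cosine clears the relatedness threshold are attributed to
a common source.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrant import (
    CalibrantMethod,
    CalibrantThreshold,
    apply_threshold,
    fit_calibrant,
    multiplicity_histogram,
)
from .kmer_index import (
    DEFAULT_K,
    KmerMultiset,
    KmerSet,
    KmerSignature,
    ReferenceIndex,
    count_read_kmers,
    decode_kmers,
)
from .matcher import (
    DEFAULT_MIN_COSINE,
    AbundanceEstimate,
    MatchScore,
    TaxonPosterior,
    cosine_match,
    estimate_abundance,
    rank_references,
    taxon_posterior,
)
from .synthetic_data import GenomeRecord
from .taxonomy_scorer import LineageScore, compute_term_weights, score_lineages

logger = logging.getLogger("popseq")

__all__ = [
    "ProfileConfig",
    "SampleProfile",
    "VariantCall",
    "ProfileDistance",
    "GapReport",
    "build_profile",
    "confirm_variants",
    "gap_analysis",
    "compare_profiles",
    "profile_distance_matrix",
    "cluster_related",
    "DEFAULT_RELATEDNESS_THRESHOLD",
]

PROFILE_FORMAT_VERSION = 1
DEFAULT_RELATEDNESS_THRESHOLD = 0.95


@dataclass(frozen=True)
class ProfileConfig:
    """Knobs of the profile pipeline, recorded in every profile for replay."""

    k: int = DEFAULT_K
    calibrant_method: CalibrantMethod | str = CalibrantMethod.VALLEY
    min_cosine: float = DEFAULT_MIN_COSINE
    relatedness_threshold: float = DEFAULT_RELATEDNESS_THRESHOLD
    n_bootstrap: int = 100
    seed: int = 0


@dataclass(frozen=True)
class VariantCall:
    """A retained sample k-mer absent from every matched reference signature.

    ``confirmed`` requires observation in both orientations and a multiplicity
    at or above the calibrant threshold — the strand-confirmation rule that
    separates candidate variants from sequencing noise.
    """

    kmer: str
    total: int
    as_forward: int
    as_reverse: int
    confirmed: bool


@dataclass(frozen=True)
class ProfileDistance:
    """Binary cosine between two profiles' retained k-mer sets."""

    cosine: float
    distance: float
    related: bool
    threshold: float


@dataclass(frozen=True)
class GapReport:
    """Zero-coverage runs along a reference's ordered k-mer windows."""

    gaps: tuple[int, ...]
    n_windows: int
    n_covered: int
    unmatched_sample_kmers: int

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gaps):
            raise ValueError("gap lengths must be positive")
        if self.n_covered + sum(self.gaps) != self.n_windows:
            raise ValueError("covered + gap windows must equal total windows")


@dataclass
class SampleProfile:
    """The per-sample genetic profile; self-contained and re-comparable."""

    sample_id: str
    k: int
    retained: KmerSet
    calibrant: CalibrantThreshold
    matches: list[MatchScore] = field(default_factory=list)
    posteriors: TaxonPosterior | None = None
    abundances: AbundanceEstimate | None = None
    lineage_scores: LineageScore | None = None
    variants: list[VariantCall] = field(default_factory=list)
    run_metadata: dict = field(default_factory=dict)

    # -- serialization --

    def to_dict(self) -> dict:
        width = (2 * self.k + 3) // 4
        return {
            "format": "popseq-profile",
            "version": PROFILE_FORMAT_VERSION,
            "sample_id": self.sample_id,
            "k": self.k,
            "retained_hex": [format(int(c), f"0{width}x") for c in self.retained.codes],
            "calibrant": self.calibrant.to_dict(),
            "matches": [m.to_dict() for m in self.matches],
            "posteriors": dict(self.posteriors.posteriors) if self.posteriors else None,
            "abundances": (
                {
                    "proportions": dict(self.abundances.proportions),
                    "unassigned": self.abundances.unassigned,
                    "ci": {g: list(v) for g, v in (self.abundances.ci or {}).items()},
                    "flags": dict(self.abundances.flags),
                }
                if self.abundances
                else None
            ),
            "lineage_scores": dict(self.lineage_scores.scores) if self.lineage_scores else None,
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "run_metadata": self.run_metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=None)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "SampleProfile":
        if payload.get("format") != "popseq-profile":
            raise ValueError("not a popseq profile payload")
        if payload.get("version") != PROFILE_FORMAT_VERSION:
            raise ValueError(f"unsupported profile version {payload.get('version')}")
        k = payload["k"]
        codes = np.asarray([int(h, 16) for h in payload["retained_hex"]], dtype=np.int64)
        cal = CalibrantThreshold(
            t=payload["calibrant"]["t"],
            noise_mean=payload["calibrant"]["noise_mean"],
            signal_mean=payload["calibrant"]["signal_mean"],
            method=CalibrantMethod(payload["calibrant"]["method"]),
            degenerate=payload["calibrant"]["degenerate"],
        )
        matches = [MatchScore(**m) for m in payload.get("matches", [])]
        posteriors = None
        if payload.get("posteriors"):
            pattern = matches[0].sample_size if matches else len(codes)
            posteriors = TaxonPosterior(posteriors=payload["posteriors"], pattern_size=pattern)
        abundances = None
        if payload.get("abundances"):
            a = payload["abundances"]
            abundances = AbundanceEstimate(
                proportions=a["proportions"],
                unassigned=a["unassigned"],
                ci={g: tuple(v) for g, v in a.get("ci", {}).items()} or None,
                flags=a.get("flags", {}),
            )
        lineage_scores = (
            LineageScore(scores=payload["lineage_scores"]) if payload.get("lineage_scores") else None
        )
        variants = [VariantCall(**v) for v in payload.get("variants", [])]
        return cls(
            sample_id=payload["sample_id"],
            k=k,
            retained=KmerSet(k=k, codes=codes),
            calibrant=cal,
            matches=matches,
            posteriors=posteriors,
            abundances=abundances,
            lineage_scores=lineage_scores,
            variants=variants,
            run_metadata=payload.get("run_metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SampleProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# pipeline


def build_profile(
    reads,
    index: ReferenceIndex | None = None,
    config: ProfileConfig = ProfileConfig(),
    sample_id: str = "sample",
) -> SampleProfile:
    """Run the full pipeline: count -> calibrate -> threshold -> rank -> score.

    With an index, the profile carries ranked matches, taxon posteriors,
    abundance estimates, lineage scores and strand-confirmed variants; without
    one (reference-free mode) it carries the retained k-mer set only, which is
    all profile-to-profile comparison needs.  Deterministic: identical inputs
    and config give byte-identical JSON.
    """

    def stage(name):
        logger.debug("profile %s: stage %s", sample_id, name)

    try:
        stage("count")
        ms = count_read_kmers(reads, k=config.k)
        stage("calibrate")
        hist = multiplicity_histogram(ms)
        cal = fit_calibrant(hist, method=config.calibrant_method)
        stage("threshold")
        retained = apply_threshold(ms, cal)
    except Exception as exc:
        raise RuntimeError(f"profile {sample_id}: counting/calibration failed: {exc}") from exc

    matches: list[MatchScore] = []
    posteriors = None
    abundances = None
    lineage_scores = None
    variants: list[VariantCall] = []
    if index is not None:
        stage("rank")
        matches = rank_references(retained, index, min_cosine=config.min_cosine)
        if matches:
            stage("posterior")
            posteriors = taxon_posterior(matches)
            stage("abundance")
            identified = [m.genome_id for m in matches]
            abundances = estimate_abundance(
                ms, identified, index, cal, n_bootstrap=config.n_bootstrap, seed=config.seed
            )
            stage("lineage")
            weights = compute_term_weights(list(index.lineages.values()))
            lineage_scores = score_lineages(matches, index, weights)
            stage("variants")
            matched_sigs = [index.get_signature(g) for g in identified]
            variants = confirm_variants(ms, matched_sigs, cal)

    return SampleProfile(
        sample_id=sample_id,
        k=config.k,
        retained=retained,
        calibrant=cal,
        matches=matches,
        posteriors=posteriors,
        abundances=abundances,
        lineage_scores=lineage_scores,
        variants=variants,
        run_metadata={
            "k": config.k,
            "calibrant_method": CalibrantMethod(config.calibrant_method).value,
            "min_cosine": config.min_cosine,
            "n_bootstrap": config.n_bootstrap,
            "seed": config.seed,
            "n_reads": ms.n_reads,
            "n_kmers_total": ms.n_kmers_total,
            "n_distinct": ms.n_distinct,
        },
    )


def confirm_variants(
    ms: KmerMultiset,
    matched_sigs: Sequence[KmerSignature],
    cal: CalibrantThreshold,
) -> list[VariantCall]:
    """Call novel k-mers (absent from every matched signature) with strand checks.

    Every distinct novel sample k-mer is reported; it is ``confirmed`` only when
    seen in both the forward and the reverse orientation AND at a multiplicity
    at or above the calibrant threshold — otherwise it stays an unconfirmed
    candidate (sequencing noise until proven otherwise).
    """
    for sig in matched_sigs:
        if sig.k != ms.k:
            raise ValueError(f"k mismatch: multiset k={ms.k}, signature k={sig.k}")
    if matched_sigs:
        union = matched_sigs[0].codes
        for sig in matched_sigs[1:]:
            union = np.union1d(union, sig.codes)
        novel_mask = ~np.isin(ms.codes, union, assume_unique=True)
    else:
        novel_mask = np.ones(ms.codes.size, dtype=bool)
    codes = ms.codes[novel_mask]
    totals = ms.totals[novel_mask]
    fwd = ms.as_forward[novel_mask]
    rev = totals - fwd
    confirmed = (fwd >= 1) & (rev >= 1) & (totals >= cal.t)
    kmers = decode_kmers(codes, ms.k)
    return [
        VariantCall(
            kmer=s,
            total=int(t),
            as_forward=int(f),
            as_reverse=int(r),
            confirmed=bool(c),
        )
        for s, t, f, r, c in zip(kmers, totals, fwd, rev, confirmed)
    ]


def gap_analysis(retained: KmerSet, reference: GenomeRecord, k: int) -> GapReport:
    """Walk the reference's windows in order and report zero-coverage runs.

    A window is covered iff its canonical k-mer is in the retained sample set;
    maximal uncovered runs are the gaps.  ``unmatched_sample_kmers`` counts the
    retained k-mers absent from the reference signature — the unmatched "spike"
    on the sample side.
    """
    if len(reference) < k:
        raise ValueError(f"reference {reference.genome_id!r} shorter than k={k}")
    from .kmer_index import build_signature, revcomp_codes, _window_codes

    from ._dna import seq_to_codes

    base_codes = seq_to_codes(reference.sequence)
    fwd = _window_codes(base_codes, k)
    canon = np.minimum(fwd, revcomp_codes(fwd, k))
    covered = retained.member_mask(canon)
    # maximal runs of uncovered windows
    gaps: list[int] = []
    if covered.size:
        padded = np.concatenate(([True], covered, [True]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == -1)
        ends = np.flatnonzero(diff == 1)
        gaps = [int(e - s) for s, e in zip(starts, ends)]
    sig = build_signature(reference, k)
    unmatched = len(retained) - retained.intersection_size(sig)
    return GapReport(
        gaps=tuple(gaps),
        n_windows=int(covered.size),
        n_covered=int(covered.sum()),
        unmatched_sample_kmers=int(unmatched),
    )


def compare_profiles(
    p1: SampleProfile,
    p2: SampleProfile,
    relatedness_threshold: float = DEFAULT_RELATEDNESS_THRESHOLD,
) -> ProfileDistance:
    """Reference-free attribution: binary cosine between retained k-mer sets.

    Symmetric; a profile compared to itself has distance 0.  ``related`` is
    True when the cosine reaches the relatedness threshold.
    """
    if p1.k != p2.k:
        raise ValueError(f"profiles built with different k ({p1.k} vs {p2.k})")
    score = cosine_match(p1.retained, p2.retained)
    return ProfileDistance(
        cosine=score.cosine,
        distance=1.0 - score.cosine,
        related=score.cosine >= relatedness_threshold,
        threshold=relatedness_threshold,
    )


def profile_distance_matrix(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Pairwise profile cosine matrix (symmetric, unit diagonal)."""
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c = compare_profiles(profiles[i], profiles[j]).cosine
            mat[i, j] = mat[j, i] = c
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_related(
    profiles: Sequence[SampleProfile],
    relatedness_threshold: float = DEFAULT_RELATEDNESS_THRESHOLD,
) -> list[set[str]]:
    """Single-linkage clusters at the relatedness threshold (union-find)."""
    ids = [p.sample_id for p in profiles]
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            if compare_profiles(profiles[i], profiles[j], relatedness_threshold).related:
                parent[find(ids[i])] = find(ids[j])
    clusters: dict[str, set[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), set()).add(i)
    return sorted(clusters.values(), key=lambda s: sorted(s)[0])
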