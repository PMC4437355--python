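"""Match a sample's retained k-mer set against reference signatures.

The sample's thresholded k-mer set (the "test pattern" R) and each reference
signature are 0/1 vectors over the 4^k k-mer space; similarity is the binary
cosine |A ∩ B| / sqrt(|A|·|B|), computed sparsely but identical to the dense
dot-product cosine.  Containment |A ∩ B| / |A| serves as the likelihood
P(R | taxon) in a Bayesian posterior over the candidate references, and genome
proportions are estimated from the observation rates of each genome's
discriminating (pan-genome-unique) k-mers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import poisson

from .calibrant import CalibrantThreshold
from .kmer_index import KmerMultiset, KmerSet, KmerSignature, ReferenceIndex

logger = logging.getLogger("popseq")

__all__ = [
    "MatchScore",
    "TaxonPosterior",
    "AbundanceEstimate",
    "cosine_match",
    "rank_references",
    "taxon_posterior",
    "estimate_abundance",
    "DEFAULT_MIN_COSINE",
]

DEFAULT_MIN_COSINE = 0.05


@dataclass(frozen=True)
class MatchScore:
    """Binary-cosine similarity of a sample k-mer set to one reference signature."""

    genome_id: str
    cosine: float
    shared: int
    sample_size: int
    signature_size: int
    containment: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "cosine": self.cosine,
            "shared": self.shared,
            "sample_size": self.sample_size,
            "signature_size": self.signature_size,
            "containment": self.containment,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class TaxonPosterior:
    """Posterior probabilities P(taxon | R) over the candidate references."""

    posteriors: Mapping[str, float]
    pattern_size: int

    def __post_init__(self) -> None:
        total = sum(self.posteriors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors must sum to 1 (got {total})")

    def top(self) -> tuple[str, float]:
        gid = max(self.posteriors, key=lambda g: (self.posteriors[g], g))
        return gid, self.posteriors[gid]


@dataclass(frozen=True)
class AbundanceEstimate:
    """Per-genome sample proportions; proportions + unassigned sum to 1."""

    proportions: Mapping[str, float]
    unassigned: float
    ci: Mapping[str, tuple[float, float]] | None = None
    flags: Mapping[str, str] = field(default_factory=dict)
    rates: Mapping[str, float] = field(default_factory=dict)
    raw_means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values()) + self.unassigned
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions + unassigned must sum to 1 (got {total})")


def _as_kmerset(obj, k: int | None = None) -> KmerSet:
    if isinstance(obj, KmerSet):
        return obj
    return KmerSet.from_strings(obj, k=k)


def cosine_match(sample, sig) -> MatchScore:
    """Binary cosine |A∩B| / sqrt(|A|·|B|) between sample set and signature.

    Symmetric in its sets and equal to the cosine of the implied dense 0/1
    vectors.  An empty set on either side gives cosine 0 with the degenerate
    flag (no division by zero).
    """
    sample = _as_kmerset(sample)
    sig = _as_kmerset(sig, k=sample.k)
    if sample.k != sig.k:
        raise ValueError(f"k mismatch: sample k={sample.k}, signature k={sig.k}")
    gid = getattr(sig, "genome_id", "")
    if len(sample) == 0 or len(sig) == 0:
        return MatchScore(
            genome_id=gid,
            cosine=0.0,
            shared=0,
            sample_size=len(sample),
            signature_size=len(sig),
            containment=0.0,
            degenerate=True,
        )
    shared = sample.intersection_size(sig)
    return MatchScore(
        genome_id=gid,
        cosine=min(shared / math.sqrt(len(sample) * len(sig)), 1.0),
        shared=shared,
        sample_size=len(sample),
        signature_size=len(sig),
        containment=shared / len(sample),
    )


def rank_references(
    sample, index: ReferenceIndex, min_cosine: float = DEFAULT_MIN_COSINE
) -> list[MatchScore]:
    """Score the sample against every reference, descending by cosine.

    Ties break by larger containment, then lexicographic genome id; entries
    below ``min_cosine`` are dropped.  Reference order never affects the result.
    """
    sample = _as_kmerset(sample, k=index.k)
    if sample.k != index.k:
        raise ValueError(f"k mismatch: sample k={sample.k}, index k={index.k}")
    scores = [cosine_match(sample, sig) for sig in index.signatures]
    scores = [s for s in scores if s.cosine >= min_cosine]
    scores.sort(key=lambda s: (-s.cosine, -s.containment, s.genome_id))
    return scores


def taxon_posterior(
    scores: Sequence[MatchScore],
    priors: Mapping[str, float] | None = None,
    floor: float = 0.0,
) -> TaxonPosterior:
    """Bayesian posterior over candidate taxa given the sample test pattern.

    The likelihood P(R | taxon) is taken as the taxon's containment (fraction of
    retained sample k-mers found in its signature); the posterior is
    prior x likelihood, normalized over candidates.  Uniform prior by default.
    """
    candidates = [s for s in scores if s.containment > floor]
    if not candidates:
        raise ValueError("no score above floor: no supported taxon")
    weights = {}
    for s in candidates:
        prior = priors.get(s.genome_id, 0.0) if priors is not None else 1.0
        weights[s.genome_id] = prior * s.containment
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all likelihoods zero: no supported taxon")
    pattern_size = candidates[0].sample_size
    return TaxonPosterior(
        posteriors={g: w / total for g, w in weights.items()},
        pattern_size=pattern_size,
    )


def _truncated_poisson_rate(mean_obs: float, t: int) -> float:
    """Invert E[X | X >= t] = mean_obs for the rate of a Poisson variate.

    With hard thresholding at multiplicity t, the observable count mean is the
    t-truncated Poisson mean lam * P(X >= t-1) / P(X >= t); inverting removes
    the upward truncation bias from the rate estimate.  As lam -> 0 the
    truncated mean tends to t, so observed means at or below t map to rate ~ 0.
    """
    if t <= 0:
        return mean_obs

    def trunc_mean(lam: float) -> float:
        return lam * poisson.sf(t - 2, lam) / poisson.sf(t - 1, lam)

    if mean_obs <= t + 1e-9:
        return 0.0
    lo, hi = 1e-9, max(mean_obs, float(t)) + 1.0
    while trunc_mean(hi) < mean_obs:
        hi *= 2
    return float(brentq(lambda lam: trunc_mean(lam) - mean_obs, lo, hi, xtol=1e-9))


def estimate_abundance(
    ms: KmerMultiset,
    identified: Sequence[str],
    index: ReferenceIndex,
    cal: CalibrantThreshold,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> AbundanceEstimate:
    """Estimate sample proportions of the identified genomes.

    Each genome's coverage rate is estimated from its *discriminating* k-mers
    (signature k-mers present in no other identified genome, restricted to the
    retained set): the mean retained multiplicity is corrected for threshold
    truncation by inverting the truncated-Poisson mean, and rates are
    normalized into proportions.  Genomes with no discriminating k-mers share
    their common mass equally and are flagged ``shared_mass``.  ``unassigned``
    is the fraction of retained sample k-mers matching no identified genome;
    proportions are scaled so proportions + unassigned = 1.  A seeded bootstrap
    over each genome's discriminating k-mer counts yields percentile CIs.
    """
    if not identified:
        raise ValueError("identified genome list must be non-empty")
    known = set(index.genome_ids)
    for gid in identified:
        if gid not in known:
            raise KeyError(f"identified genome {gid!r} not in index")

    t = cal.t
    keep = ms.totals >= t
    retained_codes = ms.codes[keep]
    retained_totals = ms.totals[keep]
    if retained_codes.size == 0:
        raise ValueError("no retained k-mers: cannot estimate abundance")

    sigs = {gid: index.get_signature(gid) for gid in identified}
    union_all = reduce(np.union1d, (sigs[g].codes for g in identified))
    assigned_mask = np.isin(retained_codes, union_all, assume_unique=True)
    unassigned = 1.0 - float(assigned_mask.sum()) / retained_codes.size

    disc_counts: dict[str, np.ndarray] = {}
    flags: dict[str, str] = {}
    raw_means: dict[str, float] = {}
    shared_counts: dict[str, np.ndarray] = {}
    for gid in identified:
        others = [g for g in identified if g != gid]
        if others:
            others_union = reduce(np.union1d, (sigs[g].codes for g in others))
            disc = np.setdiff1d(sigs[gid].codes, others_union, assume_unique=True)
        else:
            disc = sigs[gid].codes
        mask = np.isin(retained_codes, disc, assume_unique=True)
        disc_counts[gid] = retained_totals[mask]
        if disc_counts[gid].size == 0:
            shared_mask = sigs[gid].member_mask(retained_codes)
            shared_counts[gid] = retained_totals[shared_mask]
            flags[gid] = "shared_mass" if shared_counts[gid].size else "no_support"

    def rates_from(counts: Mapping[str, np.ndarray]) -> dict[str, float]:
        out = {}
        for gid in identified:
            c = counts[gid]
            if gid in flags:
                shared = shared_counts[gid]
                if shared.size == 0:
                    out[gid] = 0.0
                    continue
                # Split the shared mass equally among the genomes carrying it.
                shared_set = retained_codes[sigs[gid].member_mask(retained_codes)]
                sharers = sum(
                    1
                    for g2 in identified
                    if sigs[g2].member_mask(shared_set).all()
                )
                rate = _truncated_poisson_rate(float(shared.mean()), t)
                out[gid] = rate / max(sharers, 1)
            else:
                out[gid] = _truncated_poisson_rate(float(c.mean()), t)
        return out

    for gid in identified:
        src = disc_counts[gid] if gid not in flags else shared_counts.get(gid, np.array([]))
        raw_means[gid] = float(src.mean()) if src.size else 0.0

    rates = rates_from(disc_counts)
    total_rate = sum(rates.values())
    if total_rate <= 0:
        raise ValueError("no genome has retained support: cannot estimate abundance")
    assigned_frac = 1.0 - unassigned
    proportions = {g: assigned_frac * r / total_rate for g, r in rates.items()}

    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples: dict[str, list[float]] = {g: [] for g in identified}
        for _ in range(n_bootstrap):
            boot_counts = {}
            for gid in identified:
                c = disc_counts[gid] if gid not in flags else shared_counts.get(gid, np.array([]))
                if c.size:
                    resampled = rng.choice(c, size=c.size, replace=True)
                else:
                    resampled = c
                boot_counts[gid] = resampled
            # flagged genomes reuse the shared-mass path inside rates_from
            boot_disc = {
                g: (boot_counts[g] if g not in flags else disc_counts[g])
                for g in identified
            }
            saved = {g: shared_counts.get(g) for g in flags}
            for g in flags:
                shared_counts[g] = boot_counts[g]
            r = rates_from(boot_disc)
            for g in flags:
                shared_counts[g] = saved[g]
            tot = sum(r.values())
            if tot <= 0:
                continue
            for g in identified:
                samples[g].append(assigned_frac * r[g] / tot)
        ci = {
            g: (
                float(np.percentile(samples[g], 2.5)),
                float(np.percentile(samples[g], 97.5)),
            )
            for g in identified
            if samples[g]
        }

    return AbundanceEstimate(
        proportions=proportions,
        unassigned=unassigned,
        ci=ci,
        flags=flags,
        rates=rates,
        raw_means=raw_means,
    )
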