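# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `popseq`. It states nothing the test suite and
`scripts/acceptance.py` do not themselves compute.

## The k-mer presence model

A genome of length L over {A,C,G,T} is reduced to its **signature**: the set
of canonical k-mers among its L − k + 1 windows (0-based, half-open windows
throughout). Canonical means the lexicographic minimum of a k-mer and its
reverse complement, so a genome and its reverse complement have identical
signatures. The signature is the sparse support of a 0/1 vector over the 4^k
k-mer space; the dense vector is never materialized (at the default k = 12 the
space has 4^12 = 16,777,216 elements, and a bacterial genome occupies well
under 10 % of it). k is configurable from 4 to 31 — larger k costs memory and
loses error tolerance (any error corrupts k windows), smaller k loses match
specificity; 12 is the default trade-off. Windows containing non-ACGT
characters are skipped, not errors: an N acts as a window separator, which is
also how read boundaries are handled internally.

Read counting records, for every canonical k-mer, the total multiplicity and
how many observations were in the forward (canonical-as-read) versus
reverse-complement orientation. Orientation does not affect presence — it is
kept solely for the strand-confirmation rule in variant calling. Internally
k-mers are 2-bit-packed int64 codes in sorted numpy arrays; all set and
counting operations are vectorized, which is what makes megabase-scale
simulations testable in seconds.

## The calibrant

With per-base error rate e, each erroneous base corrupts up to k windows into
k-mers that are (almost always) absent from any genome in the sample and are
each seen once or twice. True genomic k-mers from a genome at per-base depth c
are observed ~Poisson(λ) times with λ ≈ c·(r − k + 1)/r for read length r. The
multiplicity histogram (count of distinct k-mers per multiplicity m ≥ 1) is
therefore a mixture: an error mode at m = 1 and one coverage mode per
abundance class, and the distinct-noise count grows roughly linearly with read
count while the distinct-signal count saturates at the signature size (both
asserted by simulation in the test suite).

**valley (default).** The histogram for m ≥ 1 is smoothed by a centered
moving average (window 3 — enough to damp small-sample raggedness at low
coverage without shifting the valley materially). If the smoothed histogram
rises immediately (s[1] < s[2]) there is no separable error mode and t = 1 is
returned with a warning — the correct answer for error-free data, whose
histogram is unimodal at the coverage mode. Otherwise the scan walks down the
error mode to the first rise; t is the smallest multiplicity attaining the
minimum in between (ties broken toward smaller t, retaining more signal).
Single-bin histograms return t = 1 flagged degenerate.

**poisson_mix (fallback).** A two-component Poisson mixture is fitted to the
(multiplicity, count) pairs by EM (500 iterations, tolerance 1e-10,
components ordered so λ_noise < λ_signal); t is the smallest m at which the
posterior odds favor the signal component. Zero truncation is ignored in the
fit; at the coverage regimes where the calibrant matters (λ_signal ≥ 10) the
missing zero class of the signal component is negligible, and for the noise
component it only biases λ_noise upward slightly, moving t by at most one in
the simulated regimes tested.

The calibrant is recomputed per run/sample because both modes move with
coverage. Signal/noise sweep curves report retention fractions relative to
the unfiltered (t = 1) sets; an SNR with zero retained noise is reported as a
+inf sentinel rather than an error.

## Matching and posterior confidence

The thresholded (retained) sample set R is scored against each reference
signature S by binary cosine |R ∩ S| / √(|R|·|S|), computed sparsely on sorted
code arrays and equal (to 1e-12, verified against a dense oracle) to the
cosine of the dense 0/1 vectors. The cosine is presence-based, not
multiplicity-weighted, matching the 0/1 vector construction; ranking ties
break by larger containment then lexicographic genome id, and matches below
`min_cosine` (default 0.05, chosen to suppress incidental shared-core k-mers;
tunable) are dropped.

The Bayesian assignment names two factors — P(tᵢ|R), the probability an
organism showing test pattern R belongs to taxon tᵢ, and P(R|tᵢ), the
probability that members of tᵢ show R — without committing to a likelihood
form. This implementation takes **P(R|tᵢ) := containment** |R ∩ Sᵢ| / |R|,
the simplest consistent choice, and computes the posterior as prior ×
likelihood normalized over the candidate set (uniform prior by default). This
is documented as an interpretation, not a derivation.

## Abundance estimation

For each identified genome g, the **discriminating** k-mers are the signature
k-mers of g present in no other identified genome (the strain-specific
"cloud" as opposed to the shared core), intersected with the retained set.
Their counts are ~Poisson(λ_g) with λ_g proportional to g's read share, but
retention truncates the sample at t, so the naive mean multiplicity of
retained k-mers is biased upward — severely for minor constituents whose λ is
near or below t. The estimator therefore inverts the truncated-Poisson mean
E[X | X ≥ t] = λ·P(X ≥ t−1)/P(X ≥ t) (Brent root-finding; observed means ≤ t
map to rate 0) and normalizes the corrected rates into proportions. Without
this correction a simulated 90:10 mixture reads ~85:15; with it the test
suite recovers ~88:12 to ~91:9 across seeds. The residual bias comes from the
inversion being ill-conditioned when λ ≪ t (the truncated mean is flat in λ)
and from repeated k-mers within a genome; it stays within the ±5-point band
asserted in the tests.

Genomes with no discriminating k-mers at all (e.g. identical references) get
the truncation-corrected rate of their shared retained k-mers split equally
among the genomes carrying that mass, flagged `shared_mass` rather than
dropped. `unassigned` is the fraction of retained k-mers matching no
identified genome, and proportions are scaled so proportions + unassigned = 1.
Confidence intervals are percentile bootstrap (default 100 replicates,
seeded) over each genome's retained discriminating-count array; this captures
estimation noise given the identified set, not identification uncertainty.

## Lineage probability scores

Lineages are ordered term lists, root first, parsed from semicolon-delimited
strings. A term at 0-based index i of an N-term lineage has relative position
i/(N − 1) (0 for single-term lineages); averaging relative rather than
absolute positions normalizes for lineages with different numbers of
intermediate ranks, and weight = 1 − average relative position, floored at
ε = 0.05 so leaf (strain) terms retain influence — without the floor, strain
resolution vanishes whenever a leaf term sits at the end of every lineage.
Term support f(term) is the fraction of total match-cosine mass carried by
matches whose lineage contains the term; a lineage scores
Σ w(term)·f(term) / Σ w(term). The divisor form was chosen for the
"normalizes for total number of terms" requirement (the alternative,
truncating lineages to a common length, discards exactly the strain-level
terms the method needs). Consequences verified by test: unanimous support
scores 1, lineages differing only at the leaf differ by at most
w_leaf/Σw, duplicate support never lowers a score, and scores are invariant
to rescaling all cosines.

## Variant confirmation, gaps, and profile comparison

Variant candidates are distinct sample k-mers absent from every matched
reference signature — reported at k-mer level, not genome coordinates, since
no alignment is performed. A candidate is **confirmed** only if observed in
both orientations and at multiplicity ≥ t; single-orientation k-mers at any
depth stay unconfirmed (a strand-biased pile-up is the signature of a
systematic artifact, not a variant). Gap analysis walks a reference's windows
in order, marks each covered iff its canonical k-mer is retained, and reports
maximal uncovered runs; covered + gap windows = L − k + 1 by construction,
and a deleted interior segment of length d produces a d + k − 1 window gap.

A sample profile (retained set, calibrant, matches, posteriors, abundances,
lineage scores, variants, run metadata) is serialized as versioned JSON with
the retained k-mers as sorted 2-bit-packed hex strings; serialization is
byte-deterministic under fixed seeds. Profile-to-profile comparison is the
binary cosine of retained sets — entirely reference-free — with a relatedness
threshold (default 0.95; the appropriate value depends on genome size,
coverage and k, and is reported alongside every call) and single-linkage
clustering at that threshold for multi-sample attribution. Note that chance
canonical 12-mer collisions between unrelated genomes give an expected cosine
of roughly n / (4^12/2) for n-k-mer genomes — negligible at 50 kb (~0.006)
but material above ~1 Mb, another reason the threshold is a parameter and not
a constant.

## The synthetic-data generator

The simulator emulates the laboratory design the method is validated on: a
single clonal founder genome (i.i.d. uniform bases) is split into 12 parallel
lineages, each propagated through 8 single-colony bottleneck passages —
exactly one genome survives each passage and accumulates substitutions. The
defaults are the experimental design itself (12 lineages, 8 passages).
Per-passage substitution counts are Poisson with mean 2.0 by default (the
passaging protocol fixes no rate; ~16 substitutions per terminal lineage over
the experiment matches the tens-of-variants scale observed in such serial
stress-passaging experiments, and a deterministic fixed-count mode exists for
exact tests). Pre-existing variation in the "clonal" source culture is
modelled by a founder pool (default 80 variants, the scale reported for the
source population in the motivating experiment) drawn once and assigned at
passage 0 to random half-probability subsets of lineages. The full mutation
event table is emitted and replaying it over the founder reproduces every
terminal genome byte-for-byte (asserted in tests).

Reads are single-ended, uniform-start, strand-symmetric, with each base
flipped to one of the other three with probability `error_rate` (default
0.001); read names encode source, position and strand for truth tracking — a
simulator convention only. Not modelled: quality-score profiles, amplification
or GC bias, paired ends, indels and structural variants, contamination. Tests
passing on this generator therefore demonstrate the k-mer statistics and
estimators under idealized uniform sampling with substitution-only error;
real-platform artifacts (strand-biased systematic errors are the one class
the strand rule explicitly targets) are out of its scope.

## Problem sizes used in the automated runs

The simulations behind the test suite use desk-scale genomes chosen so each
regime is still well inside its asymptotic behavior: 1 Mb genomes for the
90:10 mixture (≈ 10⁶-k-mer signatures, 20× coverage, 1 % divergence), 50 kb
founders for the 12-lineage attribution run and the acceptance script, 5 Mb
for the single error-model arithmetic check, and ≤ 20 kb for unit-level
properties. Smaller genomes at the same coverage and error rate preserve the
per-k-mer Poisson statistics that drive every estimator; only the collision
terms (∝ n/4^k) shrink, and those are separately characterized above.
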