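# popseq

Population-sequencing toolkit for metagenomic sample characterization and
forensic attribution.

Real samples — environmental, clinical, or evidentiary — are *populations* of
genomes, not clonal isolates. `popseq` characterizes such samples directly
from shotgun sequencing reads, without culture purification or assembly: it
identifies the genomes present, assigns probabilistic confidence to major and
minor constituents, estimates their proportions, calls strand-confirmed novel
variants, and compares whole-sample genetic profiles to each other so that two
samples can be attributed to a common source even when no reference database
covers them. It is aimed at microbial-forensics and biosurveillance
bioinformaticians, and ships a fully truth-tracked simulator (serial-passage
lineages, error-bearing reads) so every claim is testable on synthetic data.

## Method

**k-mer vector space.** Every genome is represented by its *signature*: the
set of canonical k-mers (default k = 12, a space of 4¹² = 16,777,216 possible
elements) it contains, i.e. a sparse 0/1 vector. A k-mer is canonical if it is
the lexicographic minimum of itself and its reverse complement, so presence is
strand-collapsed; per-orientation observation tallies are kept separately.

**Calibrant.** Sequencing error (≈ 0.1 % per base on a good run — one false
SNP per 1,000 bases, 5,000 over a 5 Mb genome at 1×) generates noise k-mers
whose count grows linearly with read depth, while true genomic k-mers recur at
the coverage rate. The *calibrant* is a per-run observation-multiplicity
threshold *t* separating the two: the first local minimum of the smoothed
multiplicity histogram between the error mode and the coverage mode (or, as a
fallback, the crossover of a two-component Poisson mixture fitted by EM).
Sample k-mers observed ≥ *t* times form the retained set *R*, the sample's
test pattern.

**Matching and confidence.** *R* is scored against each reference signature
by binary cosine, |A ∩ B| / √(|A|·|B|) — the dot-product cosine of the implied
0/1 vectors. Bayesian posteriors P(tᵢ | R) over candidate taxa use containment
(the fraction of R found in taxon tᵢ's signature) as the likelihood P(R | tᵢ).
Constituent proportions are estimated from the observation rates of each
genome's *discriminating* k-mers (signature k-mers unique to it among the
identified genomes), with truncated-Poisson correction for the threshold and
bootstrap confidence intervals. Lineage probability scores weight taxonomy
terms by 1 minus their average relative position across lineages, so broad
terms (kingdom, phylum) dominate and related organisms score similarly.

**Attribution.** Novel k-mers are confirmed as variants only when seen in both
read orientations at a rate above the calibrant. The whole retained set is the
sample's profile; two profiles are compared reference-free by binary cosine,
and samples above a relatedness threshold (default 0.95) are clustered by
single linkage — the sample itself is the database.

## Worked example

```python
import popseq as pq

# 1. Simulate the passaging experiment: a clonal founder split into 12
#    lineages, each through 8 single-colony bottleneck passages
founder = pq.generate_genome(50_000, seed=7, genome_id="founder")
lineages, events = pq.simulate_passaging(founder, pq.PassagingDesign(seed=8))

# 2. Sequence a 90:10 mixture of two lineages at 20x with 0.1% error
mix = pq.ReadSimConfig(read_length=100, coverage=20.0, error_rate=0.001,
                       proportions={lineages[0].genome_id: 0.9,
                                    lineages[1].genome_id: 0.1}, seed=9)
reads = pq.simulate_reads(lineages[:2], mix)

# 3. Count k-mers, fit the calibrant, threshold
ms = pq.count_read_kmers(reads, k=12)
cal = pq.fit_calibrant(pq.multiplicity_histogram(ms))
retained = pq.apply_threshold(ms, cal)

# 4. Match against a reference index and estimate proportions
tax = {g.genome_id: f"Bacteria;Firmicutes;Bacillus;anthracis;{g.lineage_id}"
       for g in lineages}
index = pq.build_reference_index(lineages, tax, k=12)
matches = pq.rank_references(retained, index)
est = pq.estimate_abundance(ms, [m.genome_id for m in matches[:2]], index, cal,
                            n_bootstrap=100, seed=10)
```

Output:

```
12 terminal lineages, 667 recorded mutation events
10000 reads, 1004 substitution errors
calibrant t=5 (noise mean 1.05, signal mean 17.63); 49807 of 60996 distinct k-mers retained
  founder:L01  cosine=0.9991  containment=0.9996
  founder:L02  cosine=0.9862  containment=0.9867
  founder:L08  cosine=0.9834  containment=0.9839
  founder:L01: 91.9%  (95% CI 88.5-96.8%)
  founder:L02: 8.1%  (95% CI 3.2-11.5%)
```

The 1,004 realized substitution errors match the 0.1 % model (10,000 reads ×
100 bp × 0.001 ≈ 1,000 expected). The calibrant lands at t = 5, discarding
11,189 mostly error-derived singleton k-mers while keeping the genomic signal.
Both mixture members are recovered — the true 90:10 blend is estimated at
91.9 : 8.1 with bootstrap intervals covering the truth — and the sister
lineages score almost as high as the true sources, as phylogenetically close
genomes should.

The same pipeline is available from the shell: `popseq simulate`,
`popseq index`, `popseq calibrate`, `popseq profile`, `popseq compare`
(see `popseq --help`).

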