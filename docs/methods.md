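# Methods

## Coordinate conventions

Transcript models use 1-based inclusive genomic coordinates (GTF
convention). CDS position 1 is the first base of the start codon; on the
minus strand it corresponds to the highest genomic coordinate of the CDS.
The CDS length L includes the stop codon. Relative positions are half-open,
r = (cds_pos − 1)/L ∈ [0, 1), and quintiles are ⌊5r⌋ + 1, so every CDS base
maps to exactly one quintile and position L never spills into a sixth bin;
bin sizes are ⌊L/5⌋ or ⌈L/5⌉ and always sum to L. Only exonic CDS bases have
coordinates: splice-site, intronic and UTR positions map to nothing and the
corresponding variants are dropped before profiling. Indels are localised by
their first (5′-most in transcript orientation) altered CDS base after
left-alignment, with `-` denoting an absent allele in the TSV dialect.

## Profiles

Variant identity for deduplication is (transcript, CDS position, ref, alt)
within a dataset; allele frequency plays no role. The primary analysis pools
pLoF SNVs and frameshift indels into one class; a sensitivity mode restricts
to SNVs so patterns cannot be driven by indels spanning quintile boundaries.
Genes with no variants of a class carry the all-zero proportion vector —
this encoding, not a missing row, is what the clustering maps to the
no-variants role. Reporting is restricted to genes with ≥ 5 variants of
every class (`min_per_class`, default 5), but the clustering trains on all
profiles including sparse and zero ones: the training universe is
deliberately broader than the reporting universe. Genes whose synonymous or
missense profile is assigned a non-uniform role are excluded from pLoF
interpretation, since a skewed background class signals coverage or
annotation artefacts rather than selection.

## Clustering model

Profiles pooled across the three classes are reduced by PCA and clustered
with a Gaussian mixture (k = 7 by default, full covariance, 1e-6 diagonal
regularisation). Seven components leave room for several distinct
non-uniform patterns, a few uniform ones and the no-variants component; k is
a parameter and sensitivity analyses over k are a one-line loop.

Two numerical choices matter and are worth recording:

* **Retained PCA dimension.** Observed proportion vectors live on the
  4-degree-of-freedom simplex, so 4 components suffice — *unless* zero
  vectors are present, which add a fifth direction (total mass). With only
  4 components the zero vector back-projects onto the profile mean and the
  no-variants component could never be labelled `empty` from its centroid.
  The estimator therefore retains 5 components whenever zero profiles are in
  the training pool (PCA is then a lossless rotation) and 4 otherwise.
* **Initialisation of the no-variants component.** The zero profiles are
  one exactly repeated point. At realistic cohort scale that point sits
  inside the multinomial noise cloud of low-count uniform genes, and plain
  k-means initialisation (even with many restarts) routinely fails to give
  it its own component. Fitting therefore pins one component at the zero
  point with a tight initial covariance and seeds the remaining k−1
  components by k-means on the observed profiles; EM keeps the pinned
  component because its degenerate likelihood contribution dominates. With
  no zero profiles present, standard k-means initialisation with 10
  restarts (best log-likelihood kept) is used. Either way the fit is fully
  deterministic given `random_state`.

Roles are assigned per component from its back-projected centroid (inverse
PCA transform of the component mean, clipped to [0, 1]): `empty` when the
centroid mass sums below 0.5, `non_uniform` when some quintile holds less
than 0.05 of it, `uniform` otherwise. Both thresholds are constructor
parameters. Auxiliary sets — possible stop-gains, clinical variants,
simulations, alternative transcript tiers — are only ever projected through
the fitted model; nothing is refitted on them.

Profiles are not z-scaled before PCA: the five proportions are already on a
common scale, and standardising would inflate the low-variance quintiles.

## Possible stop-gains

`enumerate_stop_gains` scans each codon (excluding codons that already are
stops and the annotated terminal stop codon) for single-base substitutions
yielding TAA/TAG/TGA under the standard code. Splice-disrupting SNVs are
intronic and out of scope by the exonic-only restriction; start-loss SNVs
create no premature stop. The per-transcript profile of these sites is the
sequence-intrinsic null against which observed pLoF clustering is compared.

## Resampling null

The position pool is the relative positions of *all* observed variants of
all classes. Each replicate redraws, for every gene, its observed pLoF count
of positions from the pool with replacement (the distributional choice is
immaterial for exchangeability, and with-replacement sampling keeps
replicates independent of pool size). Replicates are projected through the
fitted model; the per-count non-uniform fraction is the chance
("false-positive") rate, which decreases steeply with variant count because
the probability of an empty quintile under a uniform multinomial vanishes as
n grows. The enrichment p-value uses the add-one convention
p = (1 + #{reps ≥ observed})/(n_reps + 1), strictly positive and exactly
super-uniform when the observed cohort is itself a null draw.

## Rescue annotation

Translation re-initiation: the first in-frame ATG at codon index ≥ 2
(codon 1 being the canonical start; out-of-frame ATG trinucleotides are
ignored). Variants with cds_pos < 3(c − 1) + 1 are flagged
`upstream_of_alt_start`. NMD escape defaults to plain final-exon membership
(the 3′-most exon in transcript orientation); the stricter
50-bp-upstream-of-the-last-junction rule is available behind
`last50bp_rule=True` but off by default.

## Statistical comparisons

Cross-dataset comparison restricts to genes with ≥ 5 pLoFs in both datasets
(both projected through the same fitted model) and tests the uniform
fraction of one against the other's as an exact two-sided binomial
(minimum-likelihood two-sidedness, via `scipy.stats.binomtest`). Gene-set
enrichment of non-uniform roles uses Fisher's exact test against the
complement of the set among non-empty eligible genes; a resampling p-value
restricted to the set can be attached when a matching simulation is run.

## Synthetic data

The generator emulates the structure the analysis assumes: multi-exon
transcripts (2–8 exons, CDS 300–1500 bp, GC 0.45, random strand, each gene
on its own contig) whose CDS starts with ATG, ends with a stop and contains
no internal in-frame stop; and per-gene variant sets whose positions follow
the configured regime (uniform, start-/end-depleted, end-clustered over
stated quintiles, or zero). In sequence-consistent mode (default) alleles
are drawn from the actual substitution sites of each consequence kind, so
pLoF SNVs really create stops, synonymous variants preserve the protein and
missense variants change exactly one residue — verified by translation in
the tests. Per-gene pLoF counts default to a negative binomial with mean 15
and dispersion 1 truncated at ≥ 5 (note the truncation raises the realised
mean to ≈ 20); synonymous and missense means default to 40 and 80, chosen
once as realistic relative magnitudes for an exome cohort. What the
generator deliberately does *not* emulate: allele frequencies, sequencing
error, depth-based QC, codon usage bias, overlapping transcripts or
alternative isoform expression. Passing tests on this cohort therefore
demonstrate the correctness of the pipeline's computations and the
separability of the encoded regimes — not calling quality or annotation
robustness on real exomes.

## Problem sizes and determinism

The reference cohort used by the test suite and the acceptance script is
500 uniform + 100 start-depleted + 50 zero genes with 10–50 pLoFs per gene;
the null calibration check uses 200 trials of 500 replicates over 30 genes,
and the false-positive-rate curves use 100–200 genes per count level. All
generators, fits and simulations are seeded; rerunning any entry point with
the same seed reproduces every output byte-for-byte, and the pipeline writes
a manifest (config, seed, output hashes) sufficient to verify that.

## Known limitations

Quintile resolution hides sub-quintile patterns; borderline genes near
cluster boundaries can change role across refit seeds when counts are small
(the resampling null is the tool for judging how often that happens by
chance); role labels depend on the two declared thresholds; and the
clustering is per-transcript, so genes whose pLoF tolerance is
isoform-specific need the alternative-tier projection rather than the
primary MANE Select universe.
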