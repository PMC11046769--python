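# lofclust

Positional clustering of predicted loss-of-function (pLoF) variants within
coding sequences.

## The problem

Genes in which haploinsufficiency causes disease should be depleted of pLoF
variants (stop-gains, frameshifts) in healthy population cohorts — yet many
such genes harbour pLoFs in apparently unaffected carriers. One explanation
is *where* those variants fall: a truncating variant 5′ of a downstream
in-frame ATG can be rescued by translation re-initiation, and one in the
final exon usually escapes nonsense-mediated decay (NMD) and may leave a
functional C-terminally truncated protein. `lofclust` identifies genes whose
pLoFs are non-uniformly distributed along the coding sequence (CDS), a
signature of such region-dependent tolerance, and annotates the candidate
rescue mechanisms.

## The method

For each gene (one representative transcript, MANE Select by default) and
each consequence class *c* ∈ {synonymous, missense, pLoF}, every distinct
variant is mapped to its CDS position and the CDS is divided into quintiles,
ignoring exon boundaries. The profile of a (gene, class) pair is the vector

p = (n₁, …, n₅) / n,  with relative position r = (cds_pos − 1)/L and quintile ⌊5r⌋ + 1,

or the all-zero vector when the gene has no variants of the class. Pooled
profiles of all three classes are reduced by PCA and clustered with a
k = 7 full-covariance Gaussian mixture; each component is labelled from its
back-projected centroid c⁽ᵏ⁾:

* **empty** if Σᵢ cᵢ⁽ᵏ⁾ < 0.5 — the no-variants component;
* **non_uniform** if min cᵢ⁽ᵏ⁾ < 0.05 — at least one fifth of the CDS is
  (almost) devoid of variants;
* **uniform** otherwise.

Auxiliary profile sets are projected through the fitted model unchanged:
all *possible* stop-gain SNVs of each transcript (to show observed patterns
are not dictated by the sequence), clinical pathogenic variants (to contrast
population and disease ascertainment), and a resampling null in which each
gene's pLoF count is redrawn from the pooled empirical positions of all
observed variants. The null yields the chance rate of non-uniform calls as a
function of variant count and an empirical enrichment p-value
p = (1 + #{replicates ≥ observed}) / (n_reps + 1).

## Worked example

Everything below runs on a synthetic cohort generated by the package itself
(160 genes: 120 with uniformly placed pLoFs, 30 depleted of pLoFs in the
first two quintiles, 10 with none at all):

```python
from lofclust.synthetic import (SyntheticSpec, generate_dataset, start_depleted,
                                uniform_regime, zero_regime)
from lofclust.profiles import build_profiles
from lofclust.cluster import fit_clusterer, assign
from lofclust.simulate import PositionPool, run_null_simulation

spec = SyntheticSpec(
    plof_regimes=((uniform_regime(), 120), (start_depleted(), 30), (zero_regime(), 10)),
    seed=1,
)
cohort = generate_dataset(spec)
profiles = build_profiles(cohort.variants, cohort.models)
pop = profiles[profiles["dataset"] == "population"]

model = fit_clusterer(pop, n_clusters=7, random_state=1)
print("cluster roles:", model.roles_)

assignments = assign(pop, model)
plof = assignments[assignments["class"] == "plof_all"]
print(plof["role"].value_counts().to_string())

pool = PositionPool.from_variants(cohort.variants, cohort.models)
counts = {r.gene_id: int(r.n) for r in plof.itertuples() if r.n >= 1}
observed = int((plof["role"] == "non_uniform").sum())
null = run_null_simulation(pool, counts, model, n_reps=2000, seed=1,
                           observed_nonuniform=observed)
print(f"observed non-uniform genes: {observed}")
print(f"empirical enrichment p: {null.empirical_p:.5f}")
```

Output:

```
cluster roles: ['empty', 'uniform', 'uniform', 'non_uniform', 'uniform', 'uniform', 'uniform']
role
uniform        107
non_uniform     43
empty           10
observed non-uniform genes: 43
empirical enrichment p: 0.00050
```

The mixture recovers the three kinds of structure: a no-variants cluster
(the 10 zero-regime genes), a non-uniform cluster capturing the 30
start-depleted genes, and uniform clusters for the rest. 43 genes are called
non-uniform rather than 30 because genes with few pLoFs land in non-uniform
clusters by chance — exactly the effect the resampling null quantifies (its
false-positive rate is ~32% at 5 variants per gene and falls to ~0 by 100).
The enrichment p ≈ 0.0005 says the observed excess of non-uniform genes is
far beyond that chance rate.

The same analysis runs from the shell:

```bash
lofclust synth --n-uniform 120 --n-start-depleted 30 --n-zero 10 --seed 1 --outdir data
lofclust run-all --exons data/exons.tsv --cds-fasta data/cds.fasta \
    --variants data/variants.tsv --outdir results --seed 1
```

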