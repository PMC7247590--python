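# gvburden

Gene-wise variant burden (GVB) scoring of personal genomes, with rank-based
validation against catalogs of known variant–drug associations.

## The problem

A large share of known pharmacogenetic risk variants are common *noncoding*
markers whose functional role is unclear: they may act directly on gene
regulation, or they may merely sit on haplotypes that also carry
functionally relevant *coding* variants (a "synthetic association").
`gvburden` tests this hypothesis computationally.  It aggregates an
individual's deleterious coding variants into per-gene and per-drug burden
scores and asks whether drugs linked to the noncoding markers the
individual carries are ranked among that individual's most burdened drugs.
It is aimed at pharmacogenomics researchers who want to run or stress-test
this kind of burden-vs-catalog validation without assembling
population-scale genome, drug-target, and association resources first.

## The score

Raw scores from six in-silico deleteriousness predictors (SIFT,
MutationTaster, PolyPhen-2 HDIV, PolyPhen-2 HVAR, phyloP, GERP++) are
normalized to a common scale $S_v \in [0, 1]$ with lower = more
deleterious, and nonsynonymous coding variants with $S_v \le 0.7$ are
retained.  For individual $i$ and gene $j$, with $G_j$ the set of retained
variants carried in the gene:

$$\mathrm{GVB}(G_j) = \begin{cases}1 & |G_j| = 0\\\\ \left(\prod_{v \in G_j} S_v\right)^{1/|G_j|} & |G_j| > 0\end{cases}$$

and for a drug $k$ with PK/PD gene set $D_k$ (targets, enzymes,
transporters, carriers):

$$\mathrm{GVB}(D_k) = \left(\prod_{g \in D_k} \mathrm{GVB}(g)\right)^{1/|D_k|}$$

Drugs are ranked ascending by $\mathrm{GVB}(D_k)$.  Against the
individual's gold-standard drug set $GS$ (drugs whose noncoding catalog
variants the individual carries — optionally restricted to associations
reported in the individual's own OMB ethnicity group), the rank threshold
sweep

$$\mathrm{sensitivity} = \frac{|D_L \cap GS|}{|GS|}, \qquad
\mathrm{specificity} = 1 - \frac{|D_L - GS|}{|D - GS|}$$

yields a per-individual ROC curve and AUC (trapezoidal; equals
Mann–Whitney concordance with ties counted ½), aggregated as mean ± SD per
population, superpopulation, or ATC anatomical main group.

Because the real inputs (population genome panels, drug–target databases,
association catalogs, genome-wide score annotations) cannot ship with a
package, `gvburden` includes a deterministic synthetic-cohort generator
that plants synthetic associations directly: each planted noncoding marker
tags a deleterious coding variant in one of the associated drug's genes
with configurable linkage fidelity, optionally only within one target
population.

## Worked example

```python
from gvburden import SyntheticConfig, simulate_cohort, evaluate_inputs, GSMode

config = SyntheticConfig(seed=11, linkage_fidelity=1.0, frac_ethnicity_specific=1.0)
bundle = simulate_cohort(config, "study")          # writes VCF + TSV inputs
summaries, _ = evaluate_inputs(
    bundle.cohort(), bundle.variants, bundle.dgmap, bundle.catalog,
    methods=("SIFT",),
    modes=(GSMode.NON_SPECIFIC, GSMode.ETHNICITY_SPECIFIC),
    strata=("all", "superpopulation"),
)
for s in summaries:
    print(f"{s.mode.value:>19}  {s.stratum:<4} n={s.n_samples:<3} "
          f"AUC = {s.auc_mean:.3f} ± {s.auc_sd:.3f}")
```

```
       non_specific  all  n=198 AUC = 0.640 ± 0.125
       non_specific  AFR  n=68  AUC = 0.656 ± 0.141
       non_specific  EAS  n=66  AUC = 0.661 ± 0.107
       non_specific  EUR  n=64  AUC = 0.601 ± 0.115
 ethnicity_specific  all  n=170 AUC = 0.880 ± 0.079
 ethnicity_specific  AFR  n=58  AUC = 0.892 ± 0.086
 ethnicity_specific  EAS  n=63  AUC = 0.889 ± 0.066
 ethnicity_specific  EUR  n=49  AUC = 0.854 ± 0.080
```

The cohort here has 200 individuals from three populations, and every
planted association is ethnicity-specific with perfect marker–causal
linkage.  Burden ranks recover the planted associations well above chance
(AUC 0.64 under the non-specific gold standard), and restricting each
individual's gold standard to associations from their own ethnicity group
raises the AUC in every population (0.85–0.89): associations reported in
*other* groups carry no marker–causal linkage for this individual, so the
non-specific gold standard dilutes the signal.  `n` counts individuals
with a nonempty gold standard; the ethnicity-specific rows lose the
individuals who carry only other-group markers.

The same pipeline runs from the shell on the written files:

```
gvb simulate --seed 11 --out study
gvb score    --config run.yaml --method SIFT --out scored
gvb evaluate --config run.yaml --out evaluated
```

where `run.yaml` lists the input paths (`vcf`, `sample_sheet`,
`annotation`, `drug_gene`, `vda_catalog`) and optional settings (methods,
cutoff, modes, strata, ethnicity_map).

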