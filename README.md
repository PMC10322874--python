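# glyconiche

Glycan-niche analysis of metagenomic CAZyme annotations.

Heterotrophic marine bacteria partition the polysaccharide pool — laminarin,
starch, pectin, alginate, peptidoglycan, sulfated fucose/rhamnose
heteropolysaccharides — according to the carbohydrate-active enzymes
(CAZymes) their genomes encode. `glyconiche` turns flat, gene-level
annotation tables (one row per predicted ORF with read counts, taxonomy,
CAZy family labels and transporter KO ids) into quantitative *glycan niche*
descriptions per taxon, for microbial ecologists comparing size fractions,
depths or habitats in shotgun metagenomes.

## What it computes

Gene abundance is normalized as RPKM = 10⁶ · (reads mapped / gene length in
kbp) / library size, restricted to degradative CAZyme classes (GH, PL, CE,
AA, CBM — glycosyltransferases excluded) on contigs > 500 bp. For each taxon
*i* with family proportions *p*ᵢⱼ (family *j* RPKM over the taxon's total
degradative RPKM *N*ᵢ):

- **Levins niche width** B = 1 / Σⱼ p²ᵢⱼ, and its standardization
  B_A = (B − 1)/(n − 1) to [0, 1], where *n* is the dataset-wide number of
  predicted degradative families;
- **Shannon–Wiener evenness** Bᵢ = −Σⱼ pᵢⱼ ln pᵢⱼ;
- **Morisita–Horn niche overlap** between taxa *i* and *k*:
  O(i,k) = 2 Σⱼ pᵢⱼ pₖⱼ / (Σⱼ p²ᵢⱼ + Σⱼ p²ₖⱼ), 1 for identical profiles,
  0 for disjoint family support.

Around these sit the supporting stages: lowest-common-ancestor taxonomy
from per-hit lineages, substrate-category aggregation (bundled
family→substrate map, user-overridable), transporter profiling by KEGG KO
into ABC / PTS / MFS / TonB / SusC classes with sharer / scavenger /
selfish strategy labels, and group statistics (exact/asymptotic
Wilcoxon–Mann–Whitney with Benjamini–Hochberg control, Bray–Curtis, PCoA,
seeded PERMANOVA with 999 permutations). A synthetic community generator
plants known proportions, overlap and group effects, and reports their
exact closed-form metric values for recovery testing.

## Worked example

Generate a community and measure it (also available as the numbered scripts
under `analysis/`):

```sh
python analysis/01_simulate_community.py
python analysis/02_profiles_and_niche.py
```

which prints, for the default 5-taxon, 40-family community at 10⁵ reads per
sample:

```
estimated vs true standardized niche width (B_A):
                  B     B_i     B_A  truth_B_A  abs_err_B_A
taxon
Simgenus01  35.3257  3.6286  0.8801     0.8829       0.0028
Simgenus02  34.7100  3.6245  0.8644     0.8647       0.0004
Simgenus03  28.7281  3.5076  0.7110     0.7143       0.0033
Simgenus04  26.1606  3.4751  0.6451     0.6442       0.0009
Simgenus05  24.2839  3.3867  0.5970     0.5917       0.0053

overlap matrix written (max |O_hat - O| = 0.0073)
```

`B` is each genus's effective number of exploited CAZyme families, `B_A`
its position between pure specialist (0) and even generalist (1), and the
last columns compare the pipeline's estimate against the generator's exact
truth — here every width is recovered within 0.006. `03_group_comparison.py`
then detects a planted free-living vs particle-associated difference
(PERMANOVA R² = 0.997, p = 0.003; all 8 planted 4-fold families flagged),
and `04_transporter_strategies.py` recovers the planted scavenger / selfish /
sharer transporter archetypes.

The same stages are exposed as a CLI (`glyconiche validate|lca|profile|
niche|overlap|substrate|transporters|compare|simulate|run`) for use on real
annotation tables.

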