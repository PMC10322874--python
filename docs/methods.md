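# Methods

## Model and scope

`glyconiche` treats a taxon's *glycan niche* as its distribution of
degradative CAZyme gene abundance over enzyme families. The unit of
observation is an annotated ORF with per-sample mapped-read counts; all
upstream steps (assembly, ORF calling, read mapping, dbCAN/KO annotation,
secretion prediction) are assumed done and flattened into a TSV contract.
Abundance is RPKM = 10⁶ · (reads / gene length in kbp) / library size.
"Library size" is taken from the sample metadata (the post-QC read total),
not the mapped-read total; the two conventions differ only by a
sample-level constant, which cancels in all proportion-based metrics, and
the denominator source is configurable.

Niche width uses Levins' B (inverse Simpson concentration of the
proportion vector), its (B−1)/(n−1) standardization, and Shannon–Wiener
evenness with natural logs and 0·ln 0 = 0. Overlap is the standard
Morisita–Horn index over the family axis. Profiles restrict to the
degradative classes (GH, PL, CE, AA, CBM); GT families are dropped as
biosynthetic. The contig filter is strict (>500 bp passes at 501). Because
the input type carries gene rather than contig coordinates, an optional
`contig_bp` column feeds the filter and defaults to the gene length — a
conservative lower bound on the true contig length.

Decisions where the design was genuinely open:

- **n for standardization** is the dataset-wide count of predicted
  degradative families, not the per-taxon family count (a per-taxon option
  exists). With per-taxon n, B_A of a taxon observed in few families would
  be inflated toward 1.
- **Multi-domain genes** contribute their full RPKM to every family they
  carry, mirroring family-level tallies of domain annotations; an
  equal-split mode exists and is the one that conserves totals under
  aggregation.
- **Gene frequency** is gene-count based over the GH+CBM+CE+PL class set
  (AA inclusion configurable), reported as a percentage.
- **Overlap display**: printed lower-triangle tables conventionally render
  the diagonal as 0.00; in memory the diagonal is the mathematical value 1,
  and the writer's `table1_style` layout reproduces the display convention
  only.
- **LCA window**: hits within a top fraction (default 0.1) of the best
  score are retained, ties at the boundary kept, and the deepest shared
  lineage prefix returned. The window is exposed because annotation
  pipelines vary in this choice.
- **Normalization tolerance**: proportion vectors must sum to 1 within
  1e-6 and are renormalized internally before metric evaluation.

## Strategy labels

The sharer / scavenger / selfish typology of polysaccharide processing is
qualitative in origin; the package operationalizes it transparently:
transporter RPKM fractions are grouped as f_ABC, f_specific (PTS + MFS +
TonB) and f_SusC, the label is the strict argmax, a sharer additionally
requires that ≥ 25% of the taxon's degradative CAZyme RPKM is on
secretion-flagged genes, and any tie yields "mixed". The rule and its
threshold are echoed in every output so results cannot be detached from
the definition that produced them. The bundled KO→class map covers the
sugar-transporter KOs of the five classes; susC (K21573) stays distinct
from generic tonB (K03832) because SusC-like TBDTs are the selfish-mode
marker.

## Statistics

The Wilcoxon–Mann–Whitney test uses the exact null distribution of U
(computed by the classic count recursion, which the test suite checks
against full enumeration of all C(n+m, n) arrangements) when n + m ≤ 12
and the data are tie-free; otherwise a normal approximation with
mid-ranks, tie-corrected variance and a 0.5 continuity correction. The
exact two-sided p is min(1, 2·min(P(U ≤ u), P(U ≥ u))). Per-family screens
control FDR by Benjamini–Hochberg at 0.05 and report raw p alongside q.

PCoA is classical scaling: double-centering of −½D², eigendecomposition,
axes ordered by descending eigenvalue; negative eigenvalues (semimetric
input such as Bray–Curtis) are reported and their axes dropped. PERMANOVA
uses the one-way pseudo-F on squared distances with free label
permutations (no strata), p = (1 + #{F* ≥ F}) / (1 + permutations),
default 999 permutations, and a mandatory seed. With semimetric distances
the between-group sum of squares can be marginally negative on
structureless data, so R² may dip slightly below 0 there; this is a known
property of the Anderson decomposition, not an error, and R² ∈ [0, 1]
whenever real group structure exists.

## Synthetic data generator

The generator emulates exactly the structure the metrics assume, so every
pipeline stage can be validated against closed-form truth:

- per taxon, family proportions are drawn from a symmetric Dirichlet whose
  concentration α sets evenness (α → 0 specialist, α → ∞ even generalist);
- pairwise overlap is planted as a shared-component mixture
  p = (1 − s)·private + s·shared (shared uniform over the pair's common
  families). The Morisita–Horn value of the mixture is computable from the
  realized vectors, and the *exact planted value* is recorded rather than
  the nominal s;
- each supported family gets at least one gene (extras drawn ∝ p; a
  family's mass splits equally over its genes), so planted masses are
  always representable;
- reads per sample are multinomial over genes with expected weight
  mass × length × group multiplier; a Dirichlet-multinomial switch adds
  overdispersion for robustness checks;
- gene lengths are log-normal (median 1 kb, σ = 0.35 — typical prokaryotic
  ORF scale) clipped to [500, 5000] bp; contigs extend 150 bp beyond the
  gene so every real gene passes the strict >500 bp filter, while explicit
  spike-ins on 400 bp contigs exercise it;
- transporter genes follow per-taxon KO spectra shaped like the scavenger
  (ABC), selfish (SusC/TonB) and sharer (MFS/PTS/TonB) archetypes; GT
  decoy genes exercise the class exclusion; optional background genes
  (no CAZyme/KO labels) provide the gene-frequency denominator;
- all truth metrics are computed by an independent naive oracle (plain
  Python loops, `math.fsum`), never by the production code, and a single
  mandatory seed makes outputs byte-identical across runs.

The bundled conditions are 5 taxa × 40 degradative families, 200 CAZyme
genes per taxon, equal taxon weights, 10⁵ reads per sample, planted
overlaps s = 0.6 and s = 0.3. At these sizes a replicate simulates and
profiles in ~0.15 s, so recovery studies run 100 replicates in well under
a minute and the statistical calibrations (200 null PERMANOVA datasets at
999 permutations) in a few seconds.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: taxonomic misassignment and chimeric contigs,
shared families between unrelated genes on one ORF (each synthetic CAZyme
gene carries one family), mapping ambiguity and coverage bias along genes,
compositional coupling between CAZyme and non-CAZyme fractions of the
metagenome, and real CAZy family inventories (labels are synthetic
class-prefixed names). Estimator recovery statements therefore quantify
statistical, not annotation, error.

## Numerical choices and degenerate inputs

Proportion vectors are validated (non-negative, |Σp − 1| ≤ 1e-6) then
renormalized; a taxon with zero degradative abundance has no niche and is
an error rather than a silent NaN. Overlap alignment uses the union of
families across profiles, zero-filled. Matrix round-trips are exact to
< 1e-12 (full float precision in TSV). The profile aggregation keeps an
explicit `unclassified_<rank>` bucket so column marginals equal
sample-wide family totals, and substrate aggregation accumulates unmapped
families in an `unmapped` column — conservation is auditable, nothing is
dropped silently.

## Known limitations

The bundled family→substrate map is a curated reconstruction of commonly
published family–substrate designations, intended as a sensible default,
not an authority; real analyses should supply their own table. Sulfatase
profiling is reduced to an ordinary annotation column. PERMANOVA supports
only one-way free-permutation designs. The strategy rule is an explicit
heuristic; its labels are only as meaningful as the secretion flags and KO
annotations fed to it.
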