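# Methods

## Scan model and assumptions

The scan treats three populations — focal *f*, close *c*, distant *d* —
as leaves of a three-taxon tree.  Per-SNP pairwise FST is estimated from
allele counts with Hudson's estimator,

    num = (p1 - p2)^2 - [ p1(1-p1)/(n1-1) + p2(1-p2)/(n2-1) ]
    den = p1(1-p2) + p2(1-p1) ,

with p = alt/total and n the total called allele count.  Hudson's
estimator is used by default because it is robust to unequal sample
sizes, which is unavoidable when a focal group of ~100 individuals is
contrasted with metapopulation references of ~600.  A two-population
Weir–Cockerham estimator (allele-frequency formulation, random union of
gametes) is available behind `estimator="weir-cockerham"`; with allele
counts only, the observed-heterozygosity term of the genotype-level
form cannot be computed, so the frequency form is the appropriate one.

Branch lengths are T = −log(1 − FST) with FST clamped to
[0, 1 − 1e−8] first, so T is finite and non-negative; negative FST
estimates (common at undifferentiated SNPs) map to T = 0.  PBS values
are clamped at 0 before normalisation, which guarantees PBSn1 ∈ [0, 1).
Neither clamping rule affects strongly differentiated SNPs; both remove
sign pathologies at the null.

No demographic correction or significance threshold is applied: the
scan ranks windows by differentiation regardless of whether drift,
admixture or selection produced it, and retains a fixed top fraction.
This is a deliberate design stance, not an omission — the downstream
trait meta-test is the inferential step.

### Windows

Windows contain exactly `size` SNPs (default 20) and advance by `step`
SNPs (default 5, i.e. 15-SNP overlap); a chromosome with L usable SNPs
yields floor((L − size)/step) + 1 windows and trailing partial windows
are dropped, keeping window scores comparable.  The window score is the
arithmetic mean of member PBSn1; SNPs with any undefined pairwise FST
(total allele count < 2, or a monomorphic pair giving a zero
denominator) are removed before windowing and counted in the logs.
Retention keeps k = ceil(fraction × W) windows; ties at the cutoff
break by (chromosome, start position) so the selection is deterministic
and permutation-invariant.

### Numerical conventions

* The Hudson numerator subtracts the two sampling corrections as a
  single sum, making the estimator — and therefore PBS_f — bitwise
  symmetric under exchange of the two populations.
* Window means use sequential left-to-right summation rather than
  numpy's pairwise summation, so an independent accumulation loop
  reproduces them to exact floating-point equality.
* Peak-SNP ties inside a window resolve to the lowest position.
* Degenerate inputs (chromosome shorter than a window, a gene list with
  no member in the background, a 2×2 table with an empty margin) return
  empty/flagged results rather than raising, and are logged.

## Annotation

Genes whose 1-based inclusive interval lies within 5,000 bp (inclusive
boundary) of a retained window's single peak SNP are collected; the
distance is 0 inside the interval.  Strand is ignored — this is
proximity annotation.  The per-focal-population gene list is the
deduplicated union over that population's comparisons, with a
long-format provenance table preserving which comparison and window
produced each hit.  The deliberately short 5 kb radius avoids pulling
in genes only distantly linked to the differentiation peak, at the cost
of missing regulatory targets; radius is a parameter.

## Enrichment

Over-representation of the gene list in each set of a GMT database uses
the exact hypergeometric upper tail P(X ≥ k) with N the background
universe size, K the set size in the background, n the effective list
size, k the overlap.  The background defaults to the union of all genes
in the source database; an explicit universe can be supplied (the
platform the study used keeps its own background, which is not
reproducible from outside, so the union default is the honest
approximation).  Sets with overlap below `min_overlap` (default 2) are
excluded from reporting but still count toward the Benjamini–Hochberg
denominator: the BH m is the *total* number of sets in the source
(5,246-style), since the database is fixed before any data are seen.
The step-up is computed directly because standard implementations do not
accept m larger than the number of supplied p-values; it is verified in
the tests against a padded step-up and a brute-force loop.

## Trait meta-test

Two 2×2 constructions:

* **Population vs universe** — among the source's full trait universe,
  cross-classify by "enriched for this population" and "curated as
  relevant": a = both, b = enriched only, c = relevant only, d = rest.
* **Population pair** — over the curated relevant traits alone, rows
  are the two populations and columns are detected / not detected.
  The original report does not state its between-population table
  layout; this reconstruction is adopted because it reproduces both
  published P/OR pairs from the published match counts.

Both use the one-tailed Fisher exact test (alternative: greater on
cell a).  The odds ratio is the conditional maximum-likelihood estimate
under the noncentral hypergeometric model given all margins — the
estimate R's `fisher.test` prints, and slightly shrunk toward 1
relative to the sample cross-product ad/bc, which is reported
alongside.  Trait names are matched by exact string equality after
whitespace normalisation.  No correction across meta-tests is applied;
they are reported individually.

## Synthetic-data generator

The generator emulates the statistical structure the scan assumes, not
any particular cohort:

* **Drift.**  Each SNP draws an ancestral frequency p uniform on
  (0.05, 0.95) (avoiding rare-allele degeneracies); each population
  draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) — the
  Balding–Nichols model — with F = 0 meaning the ancestral frequency
  exactly.  E[p_pop] = p and Var(p_pop − p) = F·p(1−p).  A useful
  closed form for calibration: for two populations drifting
  independently with the same F, E[(p1−p2)²] = 2Fp(1−p) and
  E[p1(1−p2)+p2(1−p1)] = 2p(1−p), so the Hudson ratio-of-averages
  converges to F.
* **Defaults.**  3 chromosomes × 2,000 SNPs on 2 Mb chromosomes
  (roughly chip-like SNP spacing), five populations in the study's
  roles with the study's diploid sample sizes — focal 100, close 74,
  alternative close 42, African reference 618, Eurasian reference
  569 — and drift F of 0.01/0.01/0.02/0.02/0.15, giving realistic
  pairwise FST (~0.02 within the region, ~0.15 intercontinental).
  This desk scale runs the whole pipeline in seconds; at ~1,190
  windows per comparison the retained fraction is raised to 2% so that
  at least 20 windows are kept, the desk-scale analogue of the
  genome-scale 0.1%.
* **Planting.**  Ten loci (default) receive a +0.5 shift of the focal
  frequency, applied post-drift and pre-genotype-sampling so the truth
  is exact at the frequency level.  Planted SNPs are chosen, evenly
  spaced, among SNPs where the shift acts in full (post-drift focal
  frequency ≤ 0.5 for a positive shift): a shift truncated by clipping
  at an already-high frequency would silently shrink the effect size
  and the locus would no longer be the "known high-differentiation
  locus" the truth table claims.  Clipping to [0, 1] remains the
  defined behaviour of the planting operation itself.
* **Genotypes.**  Diploid genotypes are Binomial(2, p) per sample,
  written as a GT-only VCF 4.2 with contig headers and a two-column
  population map; an optional uniform missing rate masks calls to
  `./.`, and missing calls reduce the per-SNP allele denominator.
* **Annotation and sets.**  A gene of 2 kb is placed 200 bp from each
  planted SNP (well inside the 5 kb radius); 40 background genes per
  chromosome are tiled non-overlappingly.  Eight of sixty gene sets are
  "relevant": each draws ~60% of its 5–15 members from planted genes
  (at least one); background sets draw uniformly.  The vote table gives
  relevant sets 2–4 rater votes and 30% of background sets exactly one,
  so thresholding at ≥2 votes recovers exactly the relevant sets.
* **Seeding.**  One user seed; each stage (frequencies, genotypes,
  sets) derives its own generator from (seed, stage-index), so outputs
  are byte-identical across reruns and stages are independently
  reproducible.

What the generator does **not** emulate: linkage disequilibrium,
recombination, admixture, ascertainment bias of genotyping chips, or a
realistic site-frequency spectrum.  Passing recovery tests therefore
show that the pipeline's plumbing and statistics behave as specified
under exchangeable drift with independent sites — not that the scan has
any particular power on real, LD-structured data.

## Pipeline and sensitivity sweep

`run_pipeline` executes scan → annotate → enrich → meta per focal
population, persists every intermediate table, and emits a JSON summary
with attrition counts (SNPs used/excluded, windows, retained windows,
genes, enriched sets, trait matches, P, OR) so the arithmetic is
auditable; reruns are byte-identical.  Optional head-to-head pair tests
compare two focal groups' match counts.  `sensitivity_sweep` enumerates
the cartesian grid of window geometry (20/5 and 30/10 by default),
retained fraction, and the trait-vote threshold (≥2 vs ≥3), one row per
combination per focal population; the cell matching the base
configuration reproduces the single run exactly.

## Known limitations

* Per-SNP FST estimator choice (Hudson vs Weir–Cockerham) shifts
  PBSn1 values slightly; rankings are stable in practice but the choice
  is exposed rather than hidden.
* The enrichment background is the database union, not the original
  web platform's internal universe; absolute P-values on real data
  will differ from that platform's output accordingly.
* Chromosome ordering in window retention ties is lexicographic on the
  chromosome label, which is fine for the generated `chr1..chrN` but
  would order `chr10` before `chr2` on real genome builds; ties across
  chromosomes at exactly equal window means are vanishingly rare.
* The trait meta-test treats gene sets as exchangeable units; it
  inherits any redundancy among sets (overlapping traits) present in
  the source database.
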