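# Methods

This note records the models implemented in `qtlhotspot`, the parameter
choices behind them, and the places where the design was genuinely open.

## Variation index and gene prioritization

For one SNP and one bulk of accessions scored against a reference line,

    VI = (# accessions with a non-reference call) / (# non-missing calls)

and the contrast is ΔVI = VI(highest-phenotype bulk) − VI(lowest bulk).
Choices made here:

* **Denominator = non-missing calls only.** Germplasm panels routinely
  contain failed calls; dividing by the nominal bulk size would deflate
  VI at poorly covered sites. With 20-accession bulks, contrasts that are
  not multiples of 1/20 arise naturally from this choice.
* **Heterozygous calls count as non-reference.** An accession with any
  allele different from the reference line harbours variation at the
  site. The alternative (excluding hets) would silently shrink the
  denominator; the chosen convention is logged at read time so it can be
  audited. Inbred-line panels are nearly fully homozygous, so the two
  conventions rarely diverge in practice.
* **Filter inequalities are strict.** A SNP is kept iff VI > 0.3 in at
  least one bulk. The filter's two clauses ("below 0.3 in both: drop";
  "above 0.3 in any one: keep") leave VI exactly 0.3 unassigned; it is
  resolved as *dropped* and the kept/dropped counts are logged.
* **Gene score = max |ΔVI| over the gene's variants**, with ties broken
  to the smaller position, and gene ranks tied on |ΔVI| broken
  lexicographically — a stable, reproducible ordering. A gene is removed
  only when all of its variants fail the filter. Per-variant filtering is
  applied first; variants assigned to no gene are reported separately
  but never ranked.
* A variant is assigned to a gene when its position falls within the
  gene span, 1-based inclusive at both ends (VCF/GFF3 convention, used
  for all interval arithmetic in the package). Multi-allelic VCF records
  are rejected rather than split: the screen concerns biallelic SNPs,
  and silently splitting records would double-count sites.

No confidence envelope is attached to ΔVI; with 20-accession bulks the
statistic is coarse (granularity ≥ 1/20) and the intended use is ranking,
not testing.

## Substitution mapping

Families fixed (homozygous) for recombinant haplotypes are classified by
a **progeny test**: family trait means are sorted and split at the
largest gap between consecutive means; the gap size and the ratio of the
largest to the second-largest gap are reported as a measure of how
decisive the split is. Equal means raise an error rather than inventing
a threshold. The largest-gap rule was chosen because the two classes are
expected to be well separated when a single major locus segregates; the
rule is symmetric, parameter-free and deterministic. (Note that the rule
needs the within-group spread to be populated: two groups represented
only by their range endpoints can place the largest gap inside a group.)

A marker **cosegregates** when every high family is donor-homozygous (B)
and every low family recipient-homozygous (A) at it. The delimited
interval is the maximal contiguous run of cosegregating markers plus its
immediate flanking non-cosegregating (or terminal) markers; the physical
span is measured **flank-to-flank**. Rationale: the causal locus is known
to lie strictly inside the flanking markers that break cosegregation, so
the conservative interval is bounded by them, not by the innermost
cosegregating markers. Two disjoint cosegregating runs are geometrically
possible on arbitrary data but cannot be resolved without more families;
this surfaces as an error listing the runs rather than a guess. Absence
of any cosegregating marker is likewise an error.

Heterozygous or missing calls among the family representatives violate
the method's premise (fixed lines) and are rejected with the offending
family and marker named.

**Graphical genotypes** place segment boundaries at the physical midpoint
between adjacent discordant markers — marker data cannot localize a
breakpoint more finely, and the midpoint is the minimax choice. Missing
calls are imputed to the shared state of the nearest non-missing
neighbours when they agree; disagreeing neighbours leave an explicit
`unknown` segment rather than a guess.

**Genome recovery** is marker-count based: percent =
100·(n_A + 0.5·n_H)/n_called over background (non-target) markers,
heterozygotes counting half. Physical-length weighting would require
marker positions to be representative of the whole genome, which SSR
background panels do not guarantee; equal weighting is stated and simple.

## Trait derivations

* **Water-use partitioning.** Daily windows are half-open `[start, end)`:
  pre-anthesis = [stress imposition, flowering start), post-anthesis =
  [flowering end, harvest). "Until flowering" therefore excludes the
  flowering-start day itself, making the decomposition exact: water used
  within the flowering window belongs to neither phase and is reported
  as a third component, so pre + flowering + post = cumulative always
  (property-tested). Weekly weighings are assumed to have been
  interpolated to daily values upstream; the functions operate on daily
  series.
* **Flowering date.** The phenology trait available is days to 50%
  flowering; "until flowering" is taken to mean that date.
* **Residual yield** is the residual of an ordinary-least-squares fit of
  yield on days-to-50%-flowering and harvest index with an intercept
  (normal-equations solution via `numpy.linalg.lstsq`). Residuals sum to
  zero and are orthogonal to both predictors by construction; a
  rank-deficient design (collinear predictors) is an error.
* **Broad-sense heritability** uses one-way random-effects ANOVA by the
  method of moments: σ²_e = MS_within, σ²_g = (MS_between − MS_within)/n₀
  truncated at zero, with n₀ the effective replicate count for unbalanced
  designs. REML/BLUP machinery is deliberately out of scope; at the
  package's design point (tens of genotypes, 3–5 replicates, balanced
  trials) the moment estimator is accurate — simulations recover a
  planted h² = 0.5 within ±0.05 at 50 genotypes × 5 replicates — though
  the ratio estimator carries a small finite-sample bias at few
  genotypes.
* **NTR rules.** Net transpiration ratio = stressed / well-watered daily
  transpiration; the first strictly-below crossing of 0.10 triggers the
  stressed-set harvest, and 0.20 is the threshold used when sampling
  tissue for expression assays. Both thresholds are exposed as
  parameters.
* **Relative expression** follows 2^−ΔΔCt with per-sample ΔCt computed
  from replicate-mean target and control (GAPDH) Ct values and the
  calibrator sample mapping to fold change 1.

## SNP-effect annotation

Effects are computed directly from the gene model and genomic sequence:
the spliced CDS is walked in transcription order (strand-aware), the
affected codon is rebuilt, both alleles are translated with the standard
nuclear code, and the change is reported reference-residue-first in
one-letter, 1-based protein coordinates (`I149S`). The genome base at the
variant position must match the stated reference allele, otherwise the
call is refused — a cheap guard against coordinate-frame mistakes, which
are the dominant failure mode in gene-relative vs genome-relative SNP
notation. Protein masses are **average** (not monoisotopic) residue
masses plus one water per chain, in kDa. Translation accepts a non-ATG
start with a warning, treats a trailing stop as chain end, errors on
internal stops and emits `X` (with a warning) for ambiguous codons.

## Simulators

All generators consume a single `numpy.random.Generator` (PCG64), so a
fixed seed reproduces every output bit-for-bit across platforms.

* **Crossover model: Haldane** (no interference), r = (1 − e^(−2d/100))/2
  for map distance d in cM — the simplest defensible model at
  sub-centimorgan scale, where interference is unidentifiable anyway;
  Kosambi is available as an option. Gametes are generated
  marker-by-marker with switch probability r between adjacent markers.
* **Cross plan.** The default plan is six backcrosses to the recipient
  followed by one selfing, matching the derivation of the study
  population; each intermediate generation retains one offspring
  heterozygous at the QTL marker, emulating marker-assisted carrier
  selection. The default map holds 12 evenly spaced markers across the
  0.23-cM / 139.22-kb target sub-region.
* **Phenotype model.** Per-QTL-class Gaussians with means 20.88 g
  (donor-homozygous) and 13.27 g (recipient-homozygous) — the observed
  homozygous-class means. Only standard errors are reported for those
  classes, so SDs are reconstructed as SE·√n under an assumed n = 10
  plants per class (SD ≈ 2.43 g and 0.82 g); the assumption is a config
  field, not a constant. The heterozygote mean defaults to midparent
  (additive model — no dominance information exists in homozygous-class
  data) with the average of the two SDs.
* **Recombinant families** carry a single breakpoint uniform in the
  mapped region with the donor segment on a random side, and are
  homozygous throughout. The causal locus sits *at* a marker — the
  diagnostic-marker situation, where a KASP assay tags the causal SNP
  itself — which guarantees at least one cosegregating marker and makes
  the delimited interval provably contain the causal position in
  noiseless data (verified 200/200 in the acceptance suite).
* **Bulk panel.** 1712 accessions (the composite-collection size), each
  homozygous at the causal SNP with non-reference allele frequency 0.5;
  phenotype is a two-component Gaussian mixture whose component gap
  equals the homozygous-class mean difference (7.61 g) with a common
  within-component SD of 2.4 g. The 20 highest and 20 lowest ranked
  accessions form the bulks ("selection by extreme phenotype"). Twelve
  decoy SNPs — one per non-causal fixture gene — are drawn at a
  background non-reference frequency of 0.5 independent of phenotype,
  and 5% of calls are masked missing, mimicking the failed calls visible
  in real panels. The true within-panel phenotype distribution is not
  asserted (only its observed range is known); all mixture parameters
  are exposed in `BulkModel`.
* **Annotation fixture.** Thirteen non-overlapping genes tiled across a
  113,040-bp region, with 50-bp UTRs, GT..AG introns and random
  stop-free CDSs; the last gene mimics the candidate transcription
  factor: seven exons, minus strand, a 1020-bp CDS (339 residues + stop)
  whose codon 149 is ATT, so the planted plus-strand A→C SNP in exon 6
  produces I149S. The fixture is deterministic at a fixed seed and is
  emitted as GFF3 + FASTA. Its random CDS composition means the fixture
  protein's molecular weight (~37.5 kDa) is only in the neighbourhood of
  a real 339-residue protein, not equal to any particular one.

### What the simulators do and do not establish

The generators reproduce the *statistical structure* of the study inputs
— population design, bulk sizes, class means, missingness — not real
linkage disequilibrium, genotyping-error profiles, multi-allelic sites,
population structure within the germplasm collection, or environmental
covariance between traits. Passing recovery tests therefore demonstrates
that the estimators are correct under their stated models, not that real
data meet those models.

## Problem sizes

The shipped test and acceptance runs use 10,000 phenotype draws per
class, 100 seeded bulk simulations, 200 family-set replicates, 500
heritability simulations and 1000-instance brute-force comparisons —
sizes at which the Monte-Carlo error of every checked quantity is an
order of magnitude below its tolerance.

## Known limitations

* Variant-to-gene assignment uses gene spans only (no nearest-gene or
  promoter logic); a variant inside two overlapping genes would be
  assigned to the first by position, though the fixture never produces
  overlaps.
* `delimit_interval` expects one marker per map position and markers of
  a single chromosome; multi-chromosome scans should be run per region.
* The heritability estimator assumes uncorrelated residuals (no spatial
  or temporal design effects) and a single environment.
* The CLI's pipeline schema validation is structural (required fields,
  known stage names), not a full JSON-schema engine.
* Sliding-window ΔSNP-index scans along whole chromosomes and
  LOD-based interval mapping are out of scope by design.
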