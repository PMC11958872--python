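# Methods

## Scope and data model

`mdgkit` models the life cycle of a mid-density genotyping (MDG) assay
for an allotetraploid crop: selecting a few thousand informative SNPs
from a high-density candidate pool, classifying each marker's
relationship to the two homoeologous sub-genomes, calling dosage
genotypes from targeted amplicon read counts, and running the standard
downstream analyses (diversity, ordination, trees, backcross
selection). The genome layout is groundnut's: 20 chromosomes
(Arahy.01–10 = sub-genome A, Arahy.11–20 = B). Genotypes are stored as
alternate-allele dosages: 0–2 for markers amplifying a single
sub-genome, 0–4 for markers amplifying both, with −1 as the missing
sentinel. Coordinates are 1-based inclusive everywhere (hapmap
convention), and all alleles are assumed reported on the forward
strand of the tetraploid reference; no strand flipping is attempted.

### Hapmap dialect

Tetraploid dosages 0–4 have no diploid IUPAC encoding, so the writer
emits numeric dosage strings ("0".."4", "NA") under the standard
11-column hapmap metadata header, with per-marker dosage scales in a
`<file>.ploidy.tsv` sidecar. This is a deliberate, lossless divergence
from strict diploid hapmap; a lossy diploidized export was considered
and rejected because no collapse rule for the five-state dosage is
canonical.

### Ambiguity removal

When two marker ids occupy one (chromosome, position) or one id
occurs at two positions, the *whole* conflict group is removed; no
keeper is chosen. This is conservative and makes the operation
idempotent and order-independent, at the cost of discarding a record
that a curated tie-break might have kept.

## Panel design

Per-marker statistics are computed from dosage columns: MAF as the
dosage-weighted alternate-allele frequency over called samples, folded
to ≤ 0.5; heterozygosity as the fraction of called samples with an
intermediate dosage; PIC in the Botstein form
PIC = 1 − Σpᵢ² − ΣΣ_{i<j} 2pᵢ²pⱼ², which for a biallelic marker is
bounded by 0.375 (attained at p = 0.5) — strictly below the 0.5 bound
on gene diversity.

Candidate filters use the assay's published thresholds with literal
boundary semantics: missingness strictly < 0.2; heterozygosity ≤ 0.05
(markers with *more* than 5% heterozygous calls are removed);
PIC ≥ 0.374. Rejections are attributed to the first failing rule in
the fixed order missing → het → PIC. The 200 bp spacing rule is
symmetric: both members of a close same-chromosome pair are "crowded",
with the window boundary inclusive.

Selection ranks by descending PIC. Trait-associated markers are always
selected, bypassing the statistical filters (their value is the trait
linkage, not their PIC). "Uniform genome coverage" is operationalized
as largest-remainder apportionment of slots across chromosomes
proportional to candidate availability, filled by PIC rank within each
chromosome; the reserve is ranked globally. Ties break on
(chromosome, position, id) — selection is deterministic and invariant
to input row order, and no randomness is used anywhere in design.

## Sub-genome classification

Alignments of marker context sequences are *inputs* (named-column TSV,
with a converter for 12-column BLAST-style tables); bundling an
aligner would pin unstated parameters and make the module
non-deterministic across aligner versions. The 95% mapping threshold
is applied to both identity and query coverage — which of the two the
original pipeline thresholded is not documented, so both are
configurable separately. Per sub-genome, a marker is unmapped / unique
(with or without a resolved variant position) / multi-locus; combined:
unique on exactly one sub-genome → Category 1, unique on both →
Category 2, multi-locus on either or > 2 loci overall → Category 3
(flagged for exclusion from assay design). A unique hit without a
resolved variant position still counts as unique but the assignment is
flagged `position_unresolved`.

## Dosage calling

The caller is a small Bayesian classifier over genotype-state clusters
in alt-read-fraction space. Category 1 uses means 0 / 0.5 / 1
(AA/AB/BB). Category 2 markers are modelled with three states — the
high set 0.5 / 0.75 / 1 (AABB/ABBB/BBBB) or the mirrored low set
0 / 0.25 / 0.5 — reflecting that in a breeding panel one sub-genome's
locus is normally fixed; a five-state model (0, 0.25, 0.5, 0.75, 1) is
available for markers segregating in both sub-genomes. For each state
with mean *f*, the likelihood is Bin(alt | depth, f′) with
f′ = f(1−e) + (1−f)e folding the sequencing error rate e (default
0.01) into the cluster mean; the posterior is prior × likelihood,
normalized (uniform prior by default, overridable per marker, as are
the cluster means).

Gates: depth < 5× (the assay's minimum-coverage target, applied as a
hard gate) → no-call `low_depth`; best posterior < 0.95 (our choice;
the underlying commercial callers do not publish one) → no-call
`low_posterior`. At depth 100 and e = 0.01 the 0.5 and 0.75 clusters
are ~2.8 binomial SDs apart: accuracy among calls made exceeds 99.9%
per state, while about 2% of boundary replicates of the middle states
are no-called at the 0.95 gate. We therefore report state-recovery
accuracy over calls made, alongside the call rate — the convention
used for genotyping concordance.

QC metrics follow amplicon-sequencing practice: mean depth
(target ≥ 100×), fraction of observations ≥ 5×, uniformity = fraction
of observations at ≥ 0.2× the mean depth, and per-marker call rate
with markers under 90% flagged (not dropped). On-target fraction is
only computable when total read counts are supplied, since count
tables carry on-target reads only.

## Simulation

The generators define the study conditions for every test.

* **Populations** (Balding–Nichols two-level model): ancestral MAFs
  uniform on [0.05, 0.5] (the alt allele is minor with probability ½);
  set frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) for set-level
  differentiation F > 0. Inbreeding: with probability F_inbreeding an
  individual is fully homozygous at a locus (one Bernoulli draw scaled
  to full dosage), else binomial in the ploidy — giving the classic
  homozygote excess, with zero heterozygotes at F = 1. Defaults mimic
  the published panel's contrast between a diverse reference set
  (F_ST ≈ 0.1–0.15, low inbreeding) and advanced breeding lines (high
  inbreeding). Missing calls are inserted uniformly at the configured
  rate.
* **Reads**: depth negative-binomial (gamma-Poisson, dispersion 10)
  around a 100× mean, matching the assay's coverage target; alt reads
  binomial at the true state's error-adjusted cluster mean.
* **Backcrosses**: per chromosome, Poisson(λ = 1 crossover/meiosis ≈
  100 cM) crossovers placed uniformly on the physical map (positions
  rescaled to [0, 1] per chromosome), random starting phase. BC₃F₄
  means three backcrosses then three selfing generations (BCₙF₁ is the
  backcross product). Expected donor fraction after n backcrosses is
  0.5ⁿ⁺¹ (6.25% at BC₃); selfing halves heterozygosity per generation.

What the simulator does *not* emulate: linkage disequilibrium beyond
crossover placement, allele-specific amplification bias, locus-specific
depth profiles, genotyping batch effects, and null alleles. Tests
passing on these simulations therefore validate the algorithms and
their contracts, not the field performance of a physical assay.

## Diversity analysis

Filtering applies sites first, then samples (present-fraction computed
over the *surviving* sites). The two presets are kept exactly as
published for this assay: strict = sites ≥ 2,000 calls then samples
≥ 0.95 present; less-strict = sites ≥ 2,700 calls then samples ≥ 0.90.
That the "less strict" preset carries the higher site threshold is
how the presets were published; we reproduce both verbatim rather than
"correcting" them.

IBS distance: sharing at a marker is 1 − |dᵢ − dⱼ| / ploidy, so
intermediate tetraploid dosages contribute partial sharing; distance
is 1 − mean sharing over pairwise non-missing markers, NaN for pairs
with no overlap (surfaced, never silently zeroed). MDS is Torgerson
principal coordinates: double-centre the squared distances,
eigendecompose, keep the top-k positive eigenvalues; variance
explained excludes negative eigenvalues from the denominator and
reports their count. Neighbor joining is the Saitou–Nei algorithm with
Q-matrix ties broken on the smallest index pair; negative limb lengths
are clamped to zero with the deficit moved to the sibling limb
(preserving their sum where possible). Additive matrices are recovered
exactly; an independent NJ implementation (scikit-bio's) serves as a
cross-check in the tests, never as the implementation.

## Backcross selection

A marker is informative only if both parents are called, homozygous,
and different — heterozygous or missing parents make ancestry
ambiguous, so those markers are excluded with the reason recorded.
RPG% = 100 (n_recurrent_hom + ½ n_het) / n_informative_called per
chromosome and overall (the overall value is the
informative-marker-weighted mean of per-chromosome values). Missing
line calls drop out of numerator and denominator; a chromosome with no
informative called marker is reported as missing, not zero. Foreground
trait markers are classified by the same rule
(donor/recurrent/het/missing).

## Numerical and size choices

Likelihoods are computed in log space with log-sum-exp normalization.
MDS eigenvalue sign tests use a relative 1e-12 tolerance. Test and
acceptance problem sizes (hundreds of markers, tens-to-hundreds of
samples/lines, 10,000 read replicates) are chosen so each stochastic
check has at least ~3-sigma resolution against its expectation while
the whole suite stays fast; stochastic assertions use tolerance bands
derived from the Monte-Carlo standard error, never tuned constants.
All generators take explicit integer seeds and are byte-reproducible.

## Known limitations

* No VCF ingestion, no BAM parsing, no read mapping or de-multiplexing;
  read counts are the entry point for calling.
* No primer design (GC/Tm modelling) — classification consumes
  alignment hits and stops where the proprietary assay-design pipeline
  begins.
* Category-2 calling assumes one sub-genome fixed unless the five-state
  model is requested; it does not learn per-marker cluster positions
  from data.
* No imputation; missing genotypes propagate as missing.
* Indels are handled as biallelic markers on counts, without
  realignment.
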