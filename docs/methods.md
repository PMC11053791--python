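# Methods

## Trio origin classification

The central operation assigns each SNP of an improved line to one of four
mutually exclusive origin categories by comparing diploid genotypes at the
same reference position across the trio:

1. improved line heterozygous → **heterozygous**;
2. receptor parent homozygous for the same alternate allele → **receptor**;
3. otherwise, donor homozygous for the same alternate allele → **donor**;
4. otherwise → **unknown** (third origin).

Rules are evaluated in that order. Receptor precedence on alleles shared by
both parents is deliberate: such sites are uninformative for introgression
mapping, and in a backcross-style pedigree the shared background belongs
with the recurrent parent. Sites where the improved line is homozygous
reference or missing are excluded from the table entirely — the unit of
analysis is "SNPs of the improved line". A site absent from a parent's call
set is treated as homozygous reference in that parent, which is the correct
reading of single-sample VCFs that only report variant sites; a strict mode
drops such sites instead for call sets where absence is ambiguous. Only
strictly biallelic SNP records enter classification: multi-allelic records
are split at read time and InDels are routed to marker design.

Assumptions: all three call sets are mapped to the same reference; the
material is essentially inbred, so parental heterozygosity is not modelled
(an improved-line het is categorized as such regardless of parental state);
no imputation or phasing is attempted.

Category percentages are reported on the 0–100 scale rounded half-up to two
decimals via exact decimal arithmetic. Half-up is applied uniformly;
published tables assembled by hand sometimes mix rounding conventions, and
this package does not attempt to reproduce such artefacts.

## Hard filtering

`hard_filter` reimplements the conventional per-record SNP hard filter:
QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0. A record is removed iff any *present* annotation
violates its bound; a missing annotation never fails a record (rank-sum
annotations are undefined for sites without heterozygous reads, and failing
them would silently discard most hom-alt calls). Filtering is idempotent
and always returns a subset.

## KASP genotype calling

Wells are reduced to x = FAM/ROX, y = HEX/ROX. Wells with ROX ≤ 0 or
normalized magnitude √(x²+y²) below `signal_threshold` (default 0.2) are
flagged low-signal and reported as `no_call` — this captures no-template
controls and failed reactions. Remaining wells are clustered on the angle
θ = atan2(y, x), the one coordinate along which allele clusters separate
regardless of per-plate gain.

The cluster count k is selected by silhouette score over k = 2..k_expected;
k = 1 is used when the angular spread of signal wells is below 0.05 rad
(silhouette is undefined for a single cluster). The 1-D k-means is fully
deterministic: initial centers are spread evenly over the observed angle
range. Even-range seeding rather than quantile seeding matters on
unbalanced plates — with one dominant genotype class, quantile seeds
collapse into the large cluster and the heterozygous cluster is absorbed
into a homozygous one. Clusters are ordered by centroid angle: smallest →
`allele1_hom` (FAM allele), largest → `allele2_hom` (HEX), middle (k = 3) →
`het`; centroid ties break on mean x. Confidence is
1 − d_own/d_nearest-other in [0, 1]; calls under `min_confidence`
(default 0.1) become `no_call`. Both thresholds are package choices, not
measured constants, and are configurable.

Panel summaries count a variety as a carrier only when homozygous for the
mutant allele (screened panels are inbred lines); heterozygous calls are
reported and can be counted with `count_het=True`. Conflicting duplicate
wells collapse to `no_call` with a logged warning. Frequencies are
carriers/total as half-up 2-decimal percentages.

## Introgression blocks

Origin categories are aggregated in fixed-size, fixed-step windows tiling
each chromosome (1-based closed internally; BED/bedGraph conversion happens
only at export). Defaults are window 500 kb, step 250 kb on rice-scale
chromosomes; `scaled_window_params` shrinks both in proportion to mean
chromosome length so synthetic megabase-scale genomes keep ~60 windows per
chromosome. A window qualifies when its category fraction ≥ `min_fraction`
(0.5) and its category count ≥ `min_snps` (10); blocks are maximal runs of
≥ `min_windows` (2) consecutive qualifying windows, merged across the
genomic overlap introduced by step < window, and clipped to the outermost
qualifying SNP when the site table is supplied (block `n_snps` is then
recounted from sites, not windows). These thresholds are package defaults —
the visual clustering they formalize has no published numeric criterion —
and raising `min_fraction` is monotone: it can only remove or shrink
blocks. The same caller with `category="unknown"` locates clusters of
third-origin SNPs; centromeres are not masked, since pericentromeric donor
clusters can be genuine signal.

## Marker design

*InDel markers*: fixed-length (20 bp) exact-match primers are chosen by GC
window (40–60%) and single-site uniqueness on both allele templates;
candidate pairs are accepted when in-silico PCR yields products of 80–300 bp
whose allele size difference equals the InDel length and falls in 20–80 bp
(resolvable on 2.5% agarose). No thermodynamic Tm model is used — primer QC
beyond these constraints is delegated to external tools by design.

*In-silico PCR* requires each primer to bind exactly once (ambiguous
binding is reported as an explicit failure status, as are missing sites and
inverted orientation); the product spans the forward primer's 5′ end to the
3′ end of the reverse primer site.

*In-silico digest* accepts IUPAC motifs with a cut offset (HinfI = G^ANTC,
offset 1). Digestion runs to completion left to right; a motif instance
split by an earlier cut is not re-cut, matching physical digestion.
Fragment lengths always partition the input. A small editable enzyme table
(HinfI, EcoRI, HindIII, TaqI, DdeI, MseI, AluI) ships with the package.

*CAPS markers*: a SNP is a candidate when some enzyme's recognition site
overlaps it in exactly one allele and the two alleles' fragment multisets
differ; predictions for both alleles are attached.

*KASP primer sets*: both allele-specific forwards end exactly at the SNP
(3′ terminus = ref vs alt base) and differ nowhere else; the standard FAM
(`GAAGGTGACCAAGTTCATGCT`) and HEX (`GAAGGTCGGAGTCAACGGATT`) tails are
prepended. The common reverse is the first window on the opposite strand
giving a product within 50–120 bp at 35–65% GC, falling back to the largest
feasible product when no window passes GC.

*CDS annotation* reports codon number ⌈pos/3⌉, ref/alt codons and amino
acids under the standard genetic code, and a synonymous/missense/nonsense
effect class, validating the supplied reference base against the CDS.

## Synthetic data

The trio generator emulates the structure of a resequenced breeding trio,
not its read-level noise. Donor and receptor SNPs are independent Poisson
processes per chromosome (default 7×10⁻⁴/bp each, scaled from
hundreds of thousands of SNPs over a ~374 Mb genome); reference bases are a
deterministic function of position so the three samples stay consistent.
The improved line copies receptor genotypes outside the configured
introgression segments and donor genotypes inside them. Defaults: 12
chromosomes × 2 Mb (so full-pipeline tests run in seconds) with one 600 kb
donor segment on chr02 — ~30% of the synthetic chromosome, the scaled
analogue of a 5–10 Mb block around a target locus on a ~36 Mb chromosome.

Third-origin ("unknown") SNPs — alleles carried by neither parent — are
added at a configurable fraction of improved-line sites (default 0.07,
matching the observed share in real improved lines) and are placed in
sub-clusters (default 4 clusters of 100 kb) rather than uniformly: real
third-origin alleles arrive via an intermediate cross and arrive in blocks,
and the block caller must label them `unknown`, not `donor`. A flat
fraction of sites (default 0.004) is emitted heterozygous; the generator
does not distinguish residual heterozygosity from genotyping error. Truth
labels apply the same receptor-before-donor precedence as the classifier,
so donor/receptor allele collisions (rare, position-level) are labelled
consistently.

What the simulator does **not** model: read depth and genotype likelihoods,
reference bias, mapping artefacts, recombination maps, LD, or SNP-density
heterogeneity along chromosomes. Passing tests therefore demonstrate the
correctness of the classification/detection logic under clean calls, not
robustness to upstream calling noise — the hard filter exists precisely
because real call sets need cleaning first.

Plate simulation draws normalized cluster coordinates from isotropic
Gaussians (defaults: homozygous clusters at (1.0, 0.15)/(0.15, 1.0), het at
(0.75, 0.75), NTC at (0.04, 0.04); dispersion 0.03) and multiplies by a
per-well ROX level (mean 1000, CV 5%). Default cluster separation is tens
of angular dispersions, comfortably beyond the ≥6σ regime where exact
recovery is expected. Amplicon simulation plants a single deletion or a
single enzyme-site-destroying SNP per reference/donor pair, scrubbing
accidental motif copies and keeping primer landing sites untouched.

All generators are pure functions of (config, seed); substreams are spawned
from one `SeedSequence`, so outputs are byte-reproducible.

## Numerical and degenerate-input choices

- Percentages: exact `Decimal` arithmetic, half-up, two decimals.
- Coordinates: 1-based closed everywhere internally; conversion to 0-based
  half-open only in BED/bedGraph writers.
- VCF INFO floats are single precision on disk; values are rounded to six
  significant digits on read so write∘read is an identity.
- Empty windows have undefined (NaN) category fractions and never qualify
  for blocks; ROX = 0 wells are flagged, never fatal; an empty origin table
  is an error for summaries (there is no meaningful denominator).
- k-means centroid order ties break on mean x; all clustering is
  deterministic by construction (fixed init, single restart).

## Problem sizes

Default test-suite simulations use the 24 Mb synthetic genome (~18,000
improved-line SNPs per trio), 20-seed sweeps for block recall/precision,
and 96–196-well plates. The acceptance script builds three fixtures of
344,551–391,478 sites, screens one 194-variety plate, and runs a 10-seed
block-detection sweep; one full run takes tens of seconds on a single CPU.

## Known limitations

- Origin classification is site-wise; no HMM smoothing across sites, so
  isolated allele-sharing collisions can dot a donor block with receptor
  labels (window aggregation absorbs this).
- The KASP caller assumes at most three genuine clusters and will map a
  two-cluster plate to the two homozygous classes even if the true pair is
  hom/het; supply `k_expected=3` when hets are possible.
- Primer design checks uniqueness only within the supplied template, not
  genome-wide, and uses no melting-temperature model.
- Block boundaries are resolved to the outermost supporting SNP, so they
  systematically underestimate segment ends by roughly one inter-SNP
  distance on each side.
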