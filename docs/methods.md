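# Methods

## Scope and shape

`melscape` harmonizes per-sample somatic/germline variant tables, segmented
copy-number data, and structural-variant junction lists from a two-subtype
melanoma cohort into one driver landscape. It deliberately consumes the
outputs of upstream tools as inputs — caller status and filter labels,
orientation-artifact flags, ClinVar/OncoKB annotations, segment log2 ratios
— and implements everything downstream of them: consensus filtering,
absolute copy number, pathogenicity classification, grouping, and cohort
statistics. Read alignment, raw variant calling, segmentation,
significance-of-recurrence scoring (GISTIC-style), and de novo signature
extraction are out of scope.

## Purity, ploidy, and absolute copy number

The specimen is modelled as a two-component mixture: tumor cells at
fraction ρ ∈ (0, 1] with genome-wide ploidy φ, and diploid normal cells.
The observed log2 ratio of a segment with tumor total copy number n is
log2(((1−ρ)2 + ρn) / ((1−ρ)2 + ρφ)); the denominator is the specimen's
average copy number, so segments at the tumor's ploidy sit at ratio 0.
Inversion gives n = (2^r·((1−ρ)2 + ρφ) − (1−ρ)2)/ρ, clamped at 0 and
rounded half away from zero for the integer call (symmetric and
deterministic across platforms). The degenerate case ρ = 1, n = 0 returns
−∞ for the forward ratio, which is the model's true limit and round-trips
exactly.

Noise propagation sets the practical accuracy limit of integer calls: log2
noise of σ maps to σ·ln2·2^r·((1−ρ)2+ρφ)/ρ copies after inversion, which
grows with n. At σ = 0.05 a segment at n = 8 mis-rounds ≈ 8% of the time
even at ρ = 0.9; near-exact integer recovery (≥ 99% across ρ ≥ 0.3, n ≤ 8)
requires σ ≲ 0.02. The tests state this scaling explicitly; it is a
property of the measurement model, not of the implementation.

Purity re-estimation uses two closed forms: ρ = 2·median(MAF) over clonal
mutations in diploid regions (each sits on one of two tumor copies), and
ρ = 2 − 1/median(folded VAF) over germline heterozygous variants in
single-copy (hemizygous) regions, where the retained allele's read fraction
is 1/(2−ρ). Both require a configurable minimum of 20 informative loci and
clamp into (0, 1]; a folded hemizygous median ≤ 0.5 is non-informative and
yields 0.

Event definitions: focal amplification is integer n > 2φ on a segment
≤ 10 Mb (both boundaries tested); homozygous deletion is integer n = 0
(the literature rarely defines it numerically; 0 is the only value
consistent with "both copies lost"); LOH is minor copy 0 with at least one
copy retained, which includes copy-neutral LOH. Genes follow the segment
covering the larger share of their span, ties broken toward the segment
departing further from ploidy; segments beyond 10 Mb with n > 2φ are
reported as gains, not amplifications, per the focal definition.

## Consensus somatic filter

Candidates from the two caller channels are merged by
(sample, chromosome, position, ref, alt); when both channels report, read
counts are taken from channel 1 deterministically (reproducibility over
averaging). Rules, applied to every merged record:

* population SNPs: drop if the maximum allele fraction in any
  database/population exceeds 1% (strict >, so exactly 1% is kept; missing
  databases count as 0);
* orientation-bias artifacts (flag consumed from upstream): drop SNVs;
* indels carrying the first caller's "clustered_events" or
  "clustered_events;haplotype" filter label (exact string match): drop;
* noncoding: keep only if PASS in both channels;
* coding/splice, PASS in both: keep if ≥ 4 tumor alt reads. The 4-read
  floor is interpreted as alt-supporting reads, parallel to the 6-read
  requirement in the single-tool branch — a 4-read total-coverage reading
  would sit below the cohort QC floor and be uninformative;
* coding/splice, PASS in exactly one: keep if tumor and normal depth ≥ 10,
  tumor alt ≥ 6, and normal alt ≤ 1 or normal MAF ≤ 3% (a literal OR; zero
  normal depth fails the contamination arm — no evidence of absence);
* records PASSed by neither channel are dropped (reason NOT_PASSED_ANY — a
  case the published branches do not reach, resolved conservatively).

Decisions carry enumerated reason codes; keep is true exactly when no
reason fires, the filter is idempotent, and raising tumor alt support never
flips keep to drop (property-tested).

Germline variants need ≥ 4 alt reads and ≥ 25% allele fraction (both
inclusive) and must not be common SNPs. Candidate pathogenic germline
variants additionally must not be ClinVar benign/likely-benign, OncoKB
neutral/inconclusive, or truncations near the protein C-terminus, and must
satisfy the pathogenicity rules below. A germline call at high blood allele
fraction with zero alt reads in a tumor that retained both alleles (minor
copy ≥ 1, tumor depth ≥ 20) is flagged as likely clonal hematopoiesis; the
depth floor of 20 is a package choice calibrated well below the worked
62-read case, and LOH suppresses the flag because allele loss explains the
absence.

Sample QC excludes samples under 25-fold coverage or 20% purity (strict
"under"), then keeps one sample per patient: the highest-purity metastasis,
falling back to the highest-purity sample when no metastasis remains.

## Pathogenicity, grouping, biallelic hits

A mutation in a catalogued cancer gene is pathogenic if annotated
oncogenic/likely-oncogenic/hotspot, or if its class is damaging (nonsense,
stoploss, frameshift, splice site) in a gene whose role includes tumor
suppressor. In-frame indels therefore qualify only through annotation.
BRAF mutations split into class 1 (V600E/V600K) versus other pathogenic
BRAF mutations; class-1 carriers are not double-counted in the generic
group. Alteration groups merge TSG damaging mutations with homozygous
deletions into one inactivation group per gene, keep oncogene mutation and
amplification separate, drop groups under a configurable carrier minimum
(default 10), and order columns by count descending then name — so the
matrix is invariant under event and sample reordering. A pathogenic
germline variant counts as biallelically inactivated when the carrier's
tumor shows LOH or homozygous deletion over the gene.

## Cohort statistics

Subtype and clinical comparisons are two-sided Fisher exact tests per
group on the carrier × class 2×2, Benjamini–Hochberg-corrected across the
tested groups ("FDR" with no named procedure in common usage; BH is the
standard choice). The pairwise interdependence scan tests all unordered
group pairs, excluding amplification–amplification pairs on the same
chromosomal arm (their co-occurrence reflects shared arm-level gains, not
selection), and reports the effect as log2((o+½)/(e+½)) with e = nₐ·n_b/N —
the analytic independence expectation; the ½ pseudo-count keeps exclusive
pairs finite. The two-sided Fisher convention is probability-mass ordering
with 1e-7 relative slack on ties, verified exhaustively against a
hypergeometric enumeration oracle for all tables with N ≤ 30.

Rank-sum tests (burden, SBS7 fraction, junction counts) use the exact null
when the pooled sample is ≤ 20 and tie-free, otherwise the normal
approximation with tie correction. Survival uses the standard two-group
log-rank statistic and Kaplan–Meier curves (via lifelines). Mutation burden
is mutations per megabase over the genome model's mappable size. Signature
analysis tabulates SNVs into the 96 pyrimidine-strand substitution classes
(purine-reference records are reverse-complement-folded; inconsistent
contexts are skipped and counted) and refits catalogs by nonnegative least
squares against a fixed column-normalized reference matrix — refitting
only, no de novo extraction. Structural-variant summaries count junctions
with one endpoint in each of two query regions, either orientation.

## Synthetic cohort generator

The generator emulates the study conditions end to end: 147 + 93 samples
of two subtypes; purity uniform on [0.3, 0.9] (the QC floor is 0.2, and
informative cohorts sit above it); ploidy drawn from {2, 3.1, 4} with
weights 0.7/0.2/0.1; per-sample mutation rates uniform on 1–3 per Mb
(bracketing the reported subtype medians near 2); read depths negative
binomial with mean 80 and dispersion 10 (well above the 25-fold QC floor);
caller channels with independent 2% miss rates, 2% low-support false
positives, 1% orientation artifacts and 0.5% clustered-indel contaminants;
segment noise σ = 0.05; germline drivers in 18% of patients with second
hits in 20% of carriers; occasional clonal-hematopoiesis lookalikes; SV
junction counts averaging 234 (136 in BRAF-class-1 carriers), with planted
cross-region junction clusters in samples co-amplifying the two planted
regions. Alteration-group frequencies default to a landscape shaped like
the recurrent acral/mucosal groups, including one mucosal-exclusive
hotspot group, and planted pairwise structure (an exclusive pair and two
co-occurring pairs) with margins preserved.

All mutations are clonal with one mutated copy by default, so
MAF = ρm/(2(1−ρ)+ρn) holds exactly and the median-MAF purity estimator's
assumption is met by construction. Depths, positions, and carrier draws
flow from one seed through spawned generator streams (per sample and
purpose), making outputs bit-reproducible and independent of call order.

The genome model is deliberately scaled down: 8 chromosomes, ≈ 1.1 Gb,
with real arm structure and melanoma-relevant gene names at synthetic
coordinates. Burden is always computed against the model's own size, so
per-Mb rates are scale-free; cohorts of 240 samples generate in seconds.
The reference signature matrix is likewise synthetic — one UV-like C>T
dipyrimidine-heavy column (named SBS7 for its role) plus Dirichlet
backgrounds — because curated signature catalogs are data, not code.

What the generator does not model — and therefore what passing tests do
not establish about real data: subclonal populations and evolving clones,
germline haplotypes beyond hemizygous-region allele fractions, sequencing
context biases between exomes and genomes, caller-specific error profiles
beyond flat miss/false-positive rates, and segmentation error (segment
boundaries are observed exactly; only ratios are noisy).

## Numerical and design choices

* Integer rounding: half away from zero; negative inverted copy numbers
  clamp to 0 before rounding.
* Median of an even-length list is the mean of the central pair, including
  the length-weighted segment median used for centering.
* Coordinates: 0-based half-open internally; SEG converts from 1-based
  inclusive at the I/O boundary; variants are 1-based.
* Fisher p-values, BH, rank-sum, log-rank, Kaplan–Meier and NNLS are
  delegated to scipy/statsmodels/lifelines behind the module interfaces;
  the enumeration oracle in the tests is independent of all of them.
* Thresholds are all surfaced in configuration; nothing is hard-coded.

## Problem sizes

Default test and acceptance runs use cohorts of 10–35 samples for
fixtures, the full 240-sample default for the end-to-end pipeline summary,
100 simulated cohorts for co-occurrence calibration and power, exhaustive
table enumeration to N = 30 for the Fisher oracle, and 20 replicates at
5000 mutations for signature refitting. These sizes are the package's
chosen operating points for routine verification; all are configurable.

## Known limitations

Purity re-estimation assumes clonal, single-copy mutations in diploid
regions; subclonality or multiplicity > 1 biases it downward/upward
respectively. The co-occurrence expectation is analytic (nₐn_b/N), not a
permutation null, and conditions only on group margins. Gene-level rollup
ignores intragenic breakpoints below the majority-overlap rule. The
generator's caller-noise model is flat per channel and cannot reproduce
caller-specific artifact spectra.
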