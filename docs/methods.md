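# Methods

This note documents the models and procedures the package implements,
the defaults it ships, and the choices made where the design was open.

## Coordinate and file conventions

Internal coordinates are 0-based half-open everywhere. The VCF-like
dialect is 1-based on disk (positions converted on read/write); BEDPE
is 0-based half-open. Chromosome names are normalised to the bare
`1, 2, …, X` style. Caller provenance travels as a token list — in a
dedicated `CALLERS` key, comma-separated inside VCF INFO (semicolons
delimit INFO keys) and semicolon-separated in the plain TSV dialect;
both separators are accepted on input. Indels are left-aligned against
a supplied reference window by the standard trim-and-extend algorithm;
when no reference is available positions are taken verbatim and the
record is flagged unnormalised. Junctions whose breakends lie on one
chromosome ≤ 100 bp apart are not structural variants and are rejected
on input.

## The tumour simulator

The simulator is first-class, tested code: its outputs define the truth
every downstream stage is measured against.

**Genome and copy number.** A toy genome of 4 × 50 Mb chromosomes
(configurable) keeps runtimes desk-scale while preserving the event
anatomy that matters; positions, not sequence content, carry the
signal. Baseline copy number is (1,1) — (2,2) under whole-genome
duplication — with one whole-arm gain per tumour so pre-/post-gain
timing is always exercised. Copy-number edits from simulated SVs split
segments exactly at junction breakends, so simulated junctions and
segments are jointly consistent by construction.

**Burdens.** Background SNVs/indels/SVs are Poisson with means set by
per-year slopes times age at diagnosis: 190 SNVs, 22 indels and 1.5 SVs
per year (defaults; explicit counts override). The default age is 56,
matching the cohort mean the demographic summaries use.

**Clonal structure.** A configurable fraction of mutations (default
0.2) is subclonal at configurable CCFs (default one subclone at 0.4);
subclonal mutations carry multiplicity 1 — the dominant biological case,
and it keeps truth bookkeeping simple. Clonal mutations in gained
regions are pre-gain (m = major) or post-gain (m = 1) with probability
0.5 each.

**Clustered events.** Kataegis foci are 8 strand-coordinated C>N
substitutions in TpC context with successive gaps ≤ 1 kb, placed
≤ 1 kb from a deletion junction injected as anchor. Chromothripsis
regions put 30 breakends in a 2 Mb window with total copy number
alternating between two states, junction types assigned in balanced
rotation (the "random stitching" signature, guaranteed to pass a
uniformity test) and breakend spacing of 5–67 kb. Chromoplexy chains
are closed cycles of 3 translocations across 3 chromosomes with 2–8 kb
deletion bridges. Events reserve genomic windows so they never collide.

**Callers.** Each caller profile detects a true variant independently
with probability `sens(expected VAF)`, reports its own
Poisson-depth/binomial-alt read counts (depth scaled by local copy
number over ploidy), never reports zero alt reads, and adds false
positives uniformly at `fp_per_mb` with VAF ~ U(0.02, 0.15) — the
low-fraction artefact regime. Indel sensitivity takes a multiplicative
homopolymer penalty (default 0.4), and simulated false-positive indels
fall in homopolymer context with probability 0.7, reflecting slippage
artefacts; this is what makes the homopolymer flag informative to the
stacker. Junction breakends get Gaussian jitter. All randomness flows
from one integer seed through a single generator.

**What the simulator does not model** — and hence what passing tests do
not show about real data: read-level errors and mapping artefacts, real
trinucleotide mutation spectra beyond the kataegis contexts, correlated
caller errors (callers are conditionally independent given the truth),
subclonal copy number, and germline variation. Closure results
(recall/false positives of the detectors) certify detector–generator
consistency, not field performance.

## Consensus rules

* SNVs: exact-key agreement by ≥ 2 callers; MNVs are decomposed to
  SNVs for voting and re-composed only when every constituent reaches
  consensus (the merge rule for MNVs is not standardised; decomposition
  makes the vote well-defined).
* Indels: `IndelStacker`, a scikit-learn-style logistic regression
  (fit/predict_proba, `coef_`, deterministic given seed) over one 0/1
  flag per caller, mean observed VAF, depth, homopolymer flag.
  Threshold 0.5 by default; ties at threshold are retained; threshold 0
  recovers the union.
* SVs: single-linkage clustering where both canonical breakends lie
  within 100 bp (default; unstated in the field, exposed as config)
  with identical orientations; clusters with ≥ 2 distinct callers emit
  a consensus junction at the median breakend positions.
* Copy number: per-caller boundaries within 1 kb of a consensus
  breakend snap onto it; atomic intervals take the majority
  (major, minor) state, ties resolved toward the sample ploidy.
* SV validation: a junction is consistent when total copy number steps
  at a segment boundary within 10 kb of either breakend (integer step
  ≥ 1), or when a reciprocal partner (same chromosome pair, breakends
  within 1 kb, opposite orientations at both ends) balances it.
  Junctions with uncovered breakends are excluded from the denominator.
* Accuracy: sensitivity TP/(TP+FN), precision TP/(TP+FP),
  F1 = 2sp/(s+p) with F1 := 0 when s + p = 0; Clopper–Pearson binomial
  intervals at a configurable level (default 90%). Tumour-in-normal QC
  flags contamination strictly above 5%.

## Drivers

The background expectation is deliberately reduced to a pluggable
`rate × element length × cohort size`; covariate-adjusted background
models live upstream of this interface. Functional-consequence scores
are supplied in [0, 1] (truncating 1, missense 0.5, synonymous 0 by
convention). The ranking score is
`w_r · log2(1 + recurrence) + w_f · functional + w_p · prior` with
weights (1, 1, 0.5) — the relative weighting is not standardised; it is
configuration with these defaults — and deterministic position
tie-breaks. Excess rounds to the nearest integer, halves up. A
recurrent mutation labelled driver absorbs all its occurrences against
the excess. Biallelic precedence: germline PTV + any somatic hit →
germline+somatic; point driver + minor CN 0 → point+deletion; ≥ 2
point drivers → point+point; disrupting junction + another hit →
SV-mediated; uncovered gene → unknown.

## Clustered-event detectors

Kataegis uses the field-standard run definition (≥ 6 members, each
inter-mutation gap ≤ 1 kb); classification requires a ≥ 60% context
majority, with purine-reference members reverse-complemented into the
pyrimidine frame. Hotspots require foci from *distinct* samples (≥ 3
within 1 kb, single linkage) so one sample cannot vote a locus in.

Chromothripsis candidates are breakend clusters (single linkage, gap
≤ 100 kb — matching the simulator's intra-event spacing while keeping
unrelated SVs apart) with ≥ 10 breakends. Calls require the two
dominant total-CN states to cover ≥ 50% of overlapping segments (a
monotonic copy-number staircase spreads over many states and fails
this) and a chi-square goodness-of-fit p > 0.05 of the four
intrachromosomal junction classes against uniform — the random-
stitching signature. The five-characteristic categorisation
(multichromosomal, amplification [total ≥ 5], homozygous deletion,
telomere adjacency [≤ 5 Mb from a chromosome end], mean
interbreakpoint distance < 10 kb) is this package's concrete rendering
of a multi-feature scheme whose canonical form lives elsewhere; output
metadata should be read with that in mind.

Chromoplexy clusters breakends on one chromosome within the 10 kb
bridge limit into footprints, joins footprints by junction edges, and
reports cycles of ≥ 3 junctions spanning ≥ 2 chromosomes; parallel
interchromosomal edge pairs with opposite orientations at both ends are
balanced translocations, kept distinct from chromoplexy. Recurrent
footprints need ≥ 2 distinct samples within 10 kb.

## Timing

Multiplicity `m = clamp(round(VAF/ρ · (ρ·n_t + 2(1−ρ))), 1, major)` and
`CCF = VAF · (ρ·n_t + 2(1−ρ)) / (ρ·m)`; CCF > 1 is clipped and flagged
rather than rejected (it is sampling noise). The Clopper–Pearson
interval on VAF propagates linearly to CCF. A mutation is clonal when
its CCF interval reaches 1 — the data cannot exclude clonality — or its
point estimate is ≥ 0.9; the interval arm of the rule is what keeps
true-clonal mutations at 30–60× depth from leaking into the subclonal
class. Gain timing is defined only where major ≥ 2: m ≥ 2 → early
(pre-gain), m = 1 → late; major = 1 can never be early.

Clustered events inherit the majority epoch of their member SNVs
(kataegis), SNVs inside the region (chromothripsis) or within 10 kb of
footprints (chromoplexy). Relative odds against the genome-wide epoch
background use Haldane's +0.5 correction when a cell is empty (flagged
in the output) and a seeded percentile bootstrap over events (1,000
replicates default). Amplification timing (total CN ≥ 4) counts SNVs at
maximum multiplicity (pre-amplification), m = 1 (post) and intermediate
m; the verdict is early when pre-amplification density ≤ 5 per Mb. The
intermediate-excess test needs a null for how many intermediate-m
assignments arise from noise alone; no standard value exists, so a
configurable noise floor of 5% of timeable SNVs is used with a
one-sided binomial test at α = 0.05.

## Statistics

Boschloo's unconditional test maximises, over a 200-point grid on the
nuisance success probability (accuracy/speed balance), the
two-independent-binomial probability of a table whose two-sided Fisher
p is at most the observed one. Raw Fisher ordering is used (not mid-p);
validity of the Fisher p-value guarantees p_Boschloo ≤ p_Fisher on
every table, which the tests assert. Mann–Whitney uses exact
enumeration for both samples ≤ 8 without ties, otherwise the normal
approximation with tie correction. The burden–age likelihood-ratio test
is the Gaussian closed form `n·log(RSS0/RSS1) ~ χ²(1)`. Multiple
testing in the enrichment scan uses Benjamini–Hochberg. Printed
percentages round half away from zero.

## Problem sizes and tolerances in the validation suite

Detector closure runs 100 genomes with injected events (recall) and 100
event-free genomes (false positives) at default burdens; the acceptance
script uses 30 + 30, which it reports as its `n`. The two-of-three
consensus experiment uses 10,000 clonal SNVs at purity 1 (tolerance
±0.01 around the closed form). Bootstrap coverage uses 200 replicates
of 50 events (band 95 ± 5). The Mann–Whitney calibration band
[0.03, 0.07] at α = 0.05 reflects Monte-Carlo error at 2,000 null
replicates. These sizes keep the full suite within a few minutes on one
CPU while leaving the Monte-Carlo bands meaningful.

## Known limitations

Consensus purity/ploidy estimation and multi-tier copy-number
confidence are reduced to majority voting with a ploidy tie-break.
Panel-of-normals artefact filtering is documented but not implemented:
recurrent driver mutations carried by occult haematopoietic clones in
blood normals can enter such panels and suppress real somatic calls —
a known failure mode for hotspot drivers in myeloproliferative
neoplasms. Caller errors are simulated as independent across callers,
which flatters consensus precision relative to real pipelines with
shared alignment artefacts. The chromothripsis statistics are
deliberately simpler than dedicated tools; this package categorises,
it does not assign confidence tiers.
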