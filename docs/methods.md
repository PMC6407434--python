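# Methods

## The assay and its data model

A single-molecule molecular inversion probe (smMIP) hybridizes two
targeting arms to a cDNA template and gap-fills the window between them;
each captured molecule carries a random unique molecule identifier (UMI).
After PCR and sequencing, all copies of one molecule share the same
(probe, UMI) pair, so collapsing on that pair recovers the number of
original molecules ("unique reads") rather than amplification products.

The package works entirely in **transcript coordinates** (0-based,
half-open). Panels target transcripts, so genome alignment and liftover
add nothing but failure modes at this scale; splice-variant-specific
references are simply additional transcripts.

Read layout is fixed and shared by the simulator and the quantifier:
`UMI | extension arm | gap fill | ligation arm`, single-ended. The UMI is
the first `umi_length` bases (default 8, giving a 4⁸ = 65,536 tag space).
Quality strings are constant; quality-aware processing is out of scope.

## Quantification

- **Assignment** anchors on the arms: after stripping the UMI, the read
  must match a probe's extension arm and its tail the ligation arm, each
  within a Hamming budget (default 1 mismatch per arm). The unique
  lowest-mismatch probe wins; ties are reported `ambiguous`, non-matches
  `no_match`, reads shorter than any probe's geometry `too_short`. An
  exact-arm hash index makes the common (error-free) case O(1) per read.
- **Consensus** is per-position majority vote over the copies of one
  (probe, UMI) group. Ties fall back to the reference base when it is among
  the tied candidates, else `N` — conservative, so consensus can never
  invent a non-reference allele from a split vote. If copies disagree in
  length, the vote runs over the majority length.
- **No UMI error correction** (no 1-mismatch merging): counts stay
  well-defined; at desk-scale error rates the bias is a slight overcount
  proportional to `umi_length × error_rate`.
- **FPM** divides each probe's unique count by the sample's total assigned
  unique count and scales by 10⁶; columns therefore sum to 10⁶ exactly.
  Unassigned reads never enter the denominator. FPM is a *relative*
  measure: shifting part of the panel moves every other transcript in the
  opposite direction (compositional bias). With ~40 of 150 transcripts
  shifted the drag is ~1.2-fold; analyses of FPM differences measure
  relative, not absolute, abundance.
- **Transcript expression** is the arithmetic mean FPM over all probes
  targeting the transcript, explicitly including zero-count probes.

## Variant calling

Pileups are built from unique consensus reads only. Reference-length fills
are compared positionally; length-changed fills are globally aligned to the
reference window (bounded gap, default 10 nt — larger discrepancies are
skipped and tallied) and indels are anchored VCF-style on the preceding
base, then left-aligned through repeats to a canonical position. `N`
consensus bases count toward coverage but carry no allele.

Calls require VAF ≥ `min_vaf` (default 0.10 — the conventional reporting
floor for this assay, interpreted as variant unique reads / total unique
reads) and coverage ≥ `min_coverage` (default 10 unique reads). The
coverage floor is this package's addition: at single-digit unique coverage
a 10% threshold is dominated by shot noise, and the matched-normal
comparison below needs an explicit "cannot tell" state. Raising `min_vaf`
can only remove calls (monotone nesting), a property asserted in tests.

**Somatic classification** compares each tumor call with the patient's
healthy-tissue pileup: somatic when the allele is at ≤ `max_normal_vaf`
(default 0.02) in the normal at coverage ≥ `min_coverage`; `not_evaluable`
(None) when normal coverage is below the floor — low coverage is a known
source of false negatives in this design, and the tri-state keeps that
hazard visible instead of silently calling "germline".

## Differential expression

Expression is log₂(FPM + 0.01); the pseudocount is the conventional guard
for zero FPM and puts "absent" at ≈ −6.64. Samples are clustered
unsupervised: pairwise Manhattan distance over transcripts, UPGMA (average
linkage) agglomeration — an ultrametric tree whose merge heights are
non-decreasing, asserted on every simulated run. The tree is cut at the
root merge into two head clusters; when tissue labels exist, cluster (a)
is the side with the larger share of healthy samples, mirroring the
healthy-vs-tumor reading of the dendrogram.

Per transcript, a two-sided Wilcoxon Mann–Whitney U test compares the
clusters. The test runs on FPM values: rank tests are invariant under the
monotone log transform, so the choice of scale cannot change p, while the
cluster means reported next to it stay on the interpretable FPM scale.
Exact enumeration is used when both groups have ≤ 8 observations and the
pooled sample is tie-free; otherwise the normal approximation with tie and
continuity corrections. A constant pooled sample returns p = 1. P-values
are Benjamini–Hochberg adjusted; `significant` requires p < 0.05 **and**
FDR < `alpha_fdr` (default 0.05; both thresholds are parameters since
conventions differ between 0.01 and 0.05).

Fold changes use the signed convention: FC = mean_b/mean_a when ≥ 1, else
−mean_a/mean_b, so |FC| ≥ 1 always and −4 reads "4-fold down in the tumor
cluster". Zero means map to signed infinity; both-zero is an error.
Antisymmetry (FC(a,b) = −FC(b,a)) holds wherever both means are positive.

## Drug synergy (median-effect analysis)

Each dose–response curve is fit by least squares on the median-effect
plot: log₁₀(fa/(1−fa)) against log₁₀(D), giving slope m (sigmoidicity)
and Dm = 10^(−intercept/m) (median-effect dose); the plot's linear
correlation r is reported as the standard fit diagnostic. Points with fa
exactly 0 or 1 are excluded (optionally clipped to [10⁻⁶, 1−10⁻⁶] first,
the usual treatment of saturated viability readouts); replicates are
averaged per dose before fitting.

For a constant-ratio combination fitted on **total** dose, the dose of the
mixture reaching effect fa is split by the ratio into components d_a, d_b,
and

    CI(fa)  = d_a/Dx_a(fa) + d_b/Dx_b(fa)      (mutually-exclusive form)
    DRI_i   = Dx_i(fa) / d_i

so CI = 1/DRI_a + 1/DRI_b identically — asserted on every computation. The
non-exclusive variant (adding d_a·d_b/(Dx_a·Dx_b)) is available behind a
flag; the two-term form is the default because it is the classic CI used
with such tables. Verbal classes follow the conventional bands (strong
synergism < 0.3 … additive 0.9–1.1 … antagonism ≥ 1.45); published band
endpoints overlap, so intervals are treated half-open on the upper end
(0.85 → slight synergism). Display precision is 2 d.p. for CI and 1 d.p.
for DRI, matching how such tables are printed; raw values are retained.

## The simulator: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:

- **Cohort design**: `n_patients` (default 5) × (1 healthy +
  `tumor_biopsies_per_patient`, default 3) = 20 samples by default.
- **Counts**: unique molecules per (probe, sample) are Poisson with mean
  `baseline_molecules_per_probe` × effect. The default baseline of 300
  molecules/probe is a desk-scale working depth chosen so that Poisson
  noise is clearly subdominant to the designed effects while a full-panel
  cohort simulates in seconds; real libraries run deeper (~10⁶ unique
  reads/sample), which only tightens every estimate.
- **Effects**: a signed fold-change map applied in tumor samples only
  (+4 → ×4, −4 → ×0.25), by default a block of up-shifted
  (glycolysis-like) and down-shifted (TCA-cycle-like) transcripts.
- **Duplication**: each molecule is sequenced Geometric(1/duplication_mean)
  times (support ≥ 1, mean = `duplication_mean`, default 3).
- **Errors**: each base flips uniformly at `error_rate` (default 10⁻³),
  independently per PCR copy.
- **Variants**: spiked at molecule level at a target VAF, optionally
  tumor-only; the realized molecule fraction is recorded as ground truth.
  A variant outside every probe window is rejected as unobservable.
- **UMIs** are drawn *distinct within each (sample, probe) cell*, so the
  true molecule count is exactly identifiable from the reads. At the 4⁸
  tag space this differs from independent draws by a vanishing amount
  (birthday collision ≈ n²/2·4⁻⁸), but it makes "unique counts = true
  molecules at error_rate 0" an exact identity rather than an
  almost-always one.
- **Dose–response**: fa(D) = (D/Dm)^m / (1+(D/Dm)^m) with multiplicative
  lognormal noise (σ = `noise_sd`), clipped into the open unit interval.

Not modeled: per-probe capture-efficiency variation beyond a scalar,
index hopping, quality-score structure, strand bias, RNA degradation, and
genome-scale off-target reads. Passing tests therefore demonstrate the
*pipeline's* correctness under the stated generative assumptions, not
robustness to every artifact of real libraries.

## Numerical and design choices

- Deterministic everything: one seed drives panel, counts, reads, and
  noise; identical configs give byte-identical FASTQ output.
- UPGMA follows the standard nearest-pair agglomeration; ties in merge
  order are resolved by the library's stable ordering, making runs
  deterministic for fixed input order.
- Consensus/N handling, the variant coverage floor, and the tri-state
  somatic status are deliberately conservative defaults; all are
  parameters.
- Problem sizes in the test suite (panels of 10–898 probes, cohorts of
  4–20 samples, 50–200 replicate seeds) were chosen as the smallest sizes
  at which the checked properties are statistically meaningful.

## Known limitations

- Arm-anchored assignment requires intact arms (up to the mismatch
  budget); reads with indels inside an arm are lost rather than rescued by
  alignment.
- Protein-level (HGVS p.) annotation is out of scope; calls are reported
  at transcript nucleotide level, VCF POS 1-based.
- FPM compositionality (above) means fold changes between clusters are
  relative; strongly asymmetric designs shift null transcripts away from
  FC = 1.
- The two-cluster cut assumes the head split is the biological one; with
  weak effects or batch structure the top split can be driven by other
  variation.
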