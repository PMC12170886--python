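# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention) internally; GFF3
input is converted on read. The midpoint of an interval `[start, end)` is
`floor((start + end − 1) / 2)`, so even-length intervals floor to the lower
base, and midpoint-in-span matching uses half-open containment
`start ≤ mid < end`. These tie-breaks are deterministic design choices;
peak-matching by midpoint gives no canonical convention, so the brute-force
pairwise oracle in the test suite is the semantic reference. Promoters
(default 2 kb upstream of the TSS of protein-coding genes) are clipped at
chromosome edges rather than rejected because the synthetic genomes are
small; non-protein-coding genes yield no promoter (a skip, not an error).

## Consensus peaks and amplitude scaling

Two peaks match when the midpoint of one falls within the span of the
other; connected components of the match graph over all samples' peaks form
one consensus interval spanning min(start)–max(end). Matching pairs
necessarily overlap, so the implementation unions candidates found by a
single coordinate sweep; it is tested for exact equality against an O(n²)
brute-force oracle.

Amplitude is the summed per-base coverage over the consensus span divided
by read length — an estimated fragment count, the only dimensionally
sensible reading of "scaled on the read length"; sum-vs-maximum is
otherwise unstated, and the choice is isolated in `quantify`.

The signal/noise floor (default 20) uses floor-then-drop semantics: values
below the floor are raised to it, and rows floored in every sample are
dropped. Both actions are recorded in the matrix provenance log.

Mode scaling estimates the mode of each sample's log2-amplitude
distribution from a fixed-width histogram (bin 0.1 log2 units, ties to the
lowest bin — deterministic and robust to the heavy right tail) and
multiplies each sample by 2^(mode_control − mode_sample), each knockdown
sample pairing with its own IP's control. After scaling, per-sample modes
agree with their control's within one bin; the residual quantisation (≤ 0.1
log2 units) is well inside the 0.5 log2FC decision margin.

"Disappearing" means reduced in knockdown: log2(control/kd) ≥ 0.5,
boundary inclusive. A peak is "reduced under knockdown X" when it
disappears in at least one IP under X; reduced under A only → A-specific,
B only → B-specific, both → shared (co-dependent), neither → unchanged.
Whether "reduced by either knockdown" should instead mean at-least-one
knockdown is genuinely ambiguous; the `shared_policy` switch (`both`,
default, vs `either`) exposes the alternative rather than inferring it.

Gene pairing has two documented presets because the source protocol is
self-inconsistent: 5 kb flanks (methods-mode, `flank_bp`) and ±1 kb
vicinity (results-mode, `vicinity_bp`, used for the ChIP–RNA
intersection).

Quantile normalisation (ATAC arm) is the classic order-statistic-mean
transform; ties receive the mean over their rank span, making column
multisets exactly equal afterwards.

## Motif enrichment

Counting is per-sequence presence (not occurrence) of canonical 6-mers — a
k-mer and its reverse complement pool under the lexicographically smaller
key, because ChIP peaks are unstranded; k-mers containing N are skipped.
Presence avoids sequence-length confounding in the 2×2 tables. Enrichment
is a one-sided (greater) Fisher exact test; odds ratios apply a 0.5 Haldane
correction when any cell is zero; raw p < 0.05 labels significance, with
Benjamini–Hochberg values always reported alongside. The "upstream
regions" background is the 2-kb promoter set. Significant k-mers export as
unit-probability PWMs in MEME minimal format for external motif matching.

## DE integration

Significance is consumed, not computed: DE tables carry adjusted p values
and one shared alpha (default 0.05). Quadrants split genes significant in
both tables by fold-change sign. Sign vocabulary: log2FC is always
knockdown-vs-control, so a co_up gene (up on both knockdowns) is repressed
by both proteins and a co_down gene activated by both; report headers use
the regulation-by-protein phrasing to avoid double negatives. The trend is
B-on-A ordinary least squares; R² = 1 − SSres/SStot. ΔΔCt follows the
standard form: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt relative to
the control-group mean, fold change 2^(−ΔΔCt); samples missing either Ct
are excluded.

## SPR analysis

Double referencing computes (active − reference) − (blank_active −
blank_reference) on the active cycle's time grid (linear interpolation),
then subtracts the pre-injection baseline mean; a missing blank yields a
single-referenced output with an explicit flag. The equilibrium response is
the mean over the final 5 s of the association phase; a within-window slope
above 0.1 RU/s flags a cycle as not equilibrated (slow kinetics truncate
Req below true equilibrium, monotonically in truncation severity — a tested
property of the closed form R(t) = Req·(1 − e^(−(ka·C + kd)·t))).

The 1:1 isotherm fit is unweighted nonlinear least squares, initialised at
Rmax₀ = 1.1·max(Req) and KD₀ = the concentration nearest half-max, bounded
KD ∈ (0, 100·Cmax], Rmax ∈ (0, 10·max(Req)]. With no curvature (responses
proportional to concentration) only the ratio Rmax/KD is identifiable; the
fit then pins a parameter at a bound and is reported non-converged with KD
lower-bound-censored. A half-max reading of KD (log-linear interpolation of
the concentration at Rmax/2) is provided as an alternative estimator, since
an equilibrium half-max annotation cannot distinguish the two. Percent
inhibition is 100·(1 − R_with/R_alone); negative values are reported as
enhancement, not clamped.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (defaults: 2 chromosomes × 1 Mb, 200 genes tiled one per 10-kb
slot, 560 binding loci, all stages in seconds). Coverage is simulated
directly as expected fragment pileup — a triangular profile whose integral
equals amplitude × read length — rather than per-read sampling, for speed
and exactness of the planted fold changes.

Planted structure and the reasoning behind the defaults:

- **Peak classes** (100 A-specific, 60 B-specific, 100 shared, 300
  unchanged): shared loci lose signal (survival factor 0.5 → log2FC 1) in
  both IPs under either knockdown; specific loci only in their own IP under
  their own knockdown. Unchanged loci outnumber any perturbed subset so the
  per-sample log2-amplitude mode is anchored by unperturbed peaks.
- **Noise**: multiplicative log-normal on amplitudes (matches count
  positivity), default σ_ln = 0.05. At that level the 0.5 log2FC threshold
  sits about 4 standard deviations from both the unchanged (0) and reduced
  (1) class centres even after worst-case mode quantisation, so planted
  classes are recovered reliably; σ_ln = 0 gives exact recovery. Per-sample
  library-size factors (0.8–1.25) exercise mode scaling. No noise
  magnitudes are inherited from any protocol; they are testability choices
  exposed in config.
- **DE tables**: 237 shared genes up on both knockdowns, 130 down, 1
  discordant (down on A, up on B), plus 158/98 A-only up/down, 266/186
  B-only and 2000 nulls — giving per-knockdown totals of 624 (395 up, 229
  down) and 820 (504 up, 316 down). This is the unique sign assignment
  consistent with those printed totals. Shared genes draw a common effect
  magnitude (1.5 ± 0.4) with per-table noise scaled against the variance of
  the full signed mixture so the realised A/B correlation matches the
  target (0.95, hence R² ≈ 0.90); signs are enforced by reflection so
  quadrant recovery is exact. Null adjusted p values are drawn on [0.1, 1):
  a fully uniform null would leak false positives into the planted counts,
  and the generator's purpose is exact bookkeeping recovery. 38 + 40 of
  the co_down/co_up genes are "linked": their promoters host shared binding
  loci, so the ChIP–RNA intersection recovers exactly 78 genes.
- **ATAC**: accessibility sites at every protein-coding promoter and at all
  non-linked binding loci, with a wide log-normal amplitude spread
  (σ_ln = 0.5). Linked promoters lose half their signal only under the B
  knockdown. The wide spread keeps the per-condition distributions
  overlapping, which quantile normalisation needs to be approximately
  shape-preserving: the planted log2FC of 1 survives normalisation at ≈ 0.8
  (the residual compression is an inherent property of quantile
  normalisation when ~10% of regions shift, and the A-knockdown contrast
  stays at 0).
- **Interactome** (7 group-A runs, 2 group-B): one planted candidate in
  every A bait run and nowhere else; each background A protein is omitted
  from at least one run so the candidate is the unique all-A intersection;
  contaminants appear in bait and IgG lists of every run and vanish under
  per-run IgG subtraction.
- **SPR**: closed-form 1:1 kinetics (ka = 1e4 M⁻¹s⁻¹, kd = 8.7e-3 s⁻¹,
  true KD = 870 nM, Rmax = 250 RU) over the eight-point 1:3 series from
  5737.5 nM plus a blank cycle; both flow cells share a linear drift and
  the active cell adds a bulk injection jump present in the blank, so
  double referencing removes both. Sensorgram noise is additive Gaussian
  (default 1 RU).

A fixed seed makes every output byte-identical. What the generator does
*not* emulate: read-level sequencing error, mapping artefacts, peak-caller
behaviour, copy-number or GC bias, mass-spectrum acquisition, and
instrument-specific SPR artefacts beyond drift/bulk. Passing
truth-recovery tests therefore demonstrates correctness of the analysis
logic under the assumed statistical structure, not robustness to real-data
pathologies upstream of these inputs.

## Pipeline

Stages exchange data only through files; a JSON manifest records parameter
snapshots and SHA-256 output hashes so deterministic stages can be verified
to reproduce byte-identically. Exit codes: 0 success, 2 config error, 3
data validation error, 4 stage failure. The full default run completes in
well under a minute on one CPU.

## Known limitations

- The headline peak-class cardinalities of the original full-scale datasets
  are not reproducible at desk scale; the co-dependency pathway is
  validated by oracle equivalence and planted-truth recovery instead.
- Inverse kinetic (ka, kd) fitting is deliberately absent: the forward
  simulation exists, but slow-kinetics cycles are flagged rather than
  fitted, matching the steady-state-only analysis scope.
- The GFF3 reader covers the gene/exon subset only; BAM/bigWig inputs are
  out of scope (bedGraph is the coverage interchange, chosen for plain-text
  diffability at desk scale).
- Quantile normalisation attenuates genuine global shifts by construction;
  the pre-normalisation fold change is the unbiased reading of planted ATAC
  effects and both are reported in tests.
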