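# Methods

## Measurement model

A NanoSIMS acquisition is modelled as a set of co-registered 2-D grids of
raw integer ion counts, one per detected species, with pixel size (μm) and
dwell time (ms) as metadata. Counts are kept unsigned-integer end to end;
files containing non-integral or negative pixel values are rejected rather
than rounded, because every uncertainty in the package is a Poisson counting
error and is only meaningful on raw counts. Each acquisition is treated as a
single pre-accumulated frame (no plane-resolved depth profiling). The vendor
raw format is not parsed; inputs are multi-page TIFF + YAML sidecar or
per-channel text matrices.

Two detector configurations are assumed: a platinum run (¹⁹⁴Pt⁻, ¹²C₂⁻,
³¹P⁻, ³⁴S⁻, ¹⁹F⁻) and a nitrogen-isotope run (¹²C¹⁴N⁻, ¹²C¹⁵N⁻, ¹²C₂⁻),
acquired sequentially on the same field.

## ROI statistics and counting errors

ROIs are supplied as label images (hand-drawn in practice; generated by the
phantom in validation) with mutually exclusive compartments; the nucleus
label excludes the nucleolus. All ratios are formed from ROI-summed counts,
never from means of per-pixel ratios: per-pixel ratios are undefined at zero
counts and biased at low counts, while ROI sums of independent Poisson
variates remain Poisson. First-order propagation gives
`σ_R = R·sqrt(1/n_num + 1/n_ref)` for a count ratio; a zero numerator is
reported as 0 with a one-sided upper bound of `1/n_ref` and a flag. The
propagated σ is validated against Monte-Carlo resampling (within 5% for
counts ≥ 100; at ~100 counts the second-order ratio-bias terms are of order
1% and negligible against the tolerance).

## Label fraction

The ¹⁵N abundance of an ROI is `a = n15/(n14+n15)` with binomial error
`sqrt(a(1−a)/(n14+n15))`. The fraction of nitrogen originating from the
labelled compound follows from two-endpoint mixing between the untreated
control (`a_ctr`, default: pooled over all control ROIs; a fixed value,
e.g. the terrestrial natural abundance 0.003676, can be configured) and the
compound's label purity (`a_cddp`, default 0.99 — isotopic purities of
commercial ¹⁵N reagents are typically 98–99%):

    x = (a_tot − a_ctr) / (a_cddp − a_ctr),  σ_x = σ_a / (a_cddp − a_ctr)

This is the unique expression consistent with the endpoint behaviour
(x = 0 at the control abundance, x = 1 at pure compound nitrogen) and is
exact because a measured abundance is the atom-weighted mean of the two
nitrogen pools. Reported physical values are clipped at 0 when noise pushes
`a_tot` marginally below `a_ctr` (always flagged, never silent; abundances
below `a_ctr − 5σ` are treated as errors). Regression across an exposure
series, however, uses the *unclipped* values: clipping a noisy unbiased
estimator at zero inflates low-concentration means and systematically
flattens fitted slopes. Both values are carried in the results table
(`x` unclipped for fitting, `x_per_mil` clipped for display).

## Pt/N index

The index `q = [I(Pt)/I(C₂)]_pt-run ÷ [I(CN)/I(C₂)]_avg` uses ¹²C₂⁻ as the
internal reference of both runs. The `avg` bracket is the arithmetic mean of
the per-run CN/C₂ ratios over whichever runs record CN channels — forming
ratios *within* a run first makes `q` exactly invariant under per-run
multiplicative gains, which is essential because the two runs are separate
acquisitions with independent detector states. In the standard detector
configuration only the nitrogen run records CN, so the average has one term;
the runs used are recorded in the result. Where only ¹²C¹⁴N⁻ is available it
stands in for total CN with a flag (the relative bias equals the ¹⁵N
abundance, < 0.4%, below counting error at tracer-level enrichment). σ_q is
first-order propagation over all contributing counts; the small covariance
through a shared C₂ sum (only possible if a run recorded both Pt and CN) is
neglected.

## Registration

The sequential runs are aligned with a translation-only model (stage drift;
no rotation/scale), estimated by phase correlation on the shared ¹²C₂⁻
channel — never on drug channels, which can be empty in controls. The
whole-pixel part is applied with zero-fill at exposed borders (count of
affected pixels logged); the sub-pixel residual is reported but never
resampled, since interpolation would destroy the integer Poisson statistics.
Default search bound: 20 px.

## Curves and slope fits

Per compartment and concentration, ROI replicates are averaged; the
across-ROI standard deviation (the error-bar quantity) is kept separate from
the mean counting error (the precision measure). Slopes of `x` on `q` are
ordinary or inverse-variance-weighted least squares (statsmodels WLS);
weights use the ROI dispersion of the point mean, falling back to the
counting error for unreplicated points. Both a free-intercept fit (the
intercept should include 0 after control subtraction — a QC diagnostic) and
a restricted through-origin slope are reported. ROIs are kept separate and
aggregated only at this layer.

With count rates `I_Pt = RSF_Pt·n_Pt` and `I_CN = RSF_CN·n_N`,
`q = (RSF_Pt/RSF_CN)·(n_Pt/n_N)` while `x` is the drug-nitrogen atom
fraction itself, so the calibration is `N:Pt = slope · RSF_Pt / RSF_CN`.
No `(a_cddp − a_ctr)` factor appears: it is already absorbed by the label
fraction's denominator. The calibration is exact on noise-free inputs and
invariant under consistent rescaling of both RSFs; without known RSFs the
result is flagged uncalibrated and carries the raw slope (the real-data
case, where only between-compartment slope comparisons are meaningful).

## Group tests and colocalisation

Treated-vs-control comparisons of ROI ratio values use the classical
pooled-variance two-tailed Student's t-test (Welch exposed as an option,
off by default; no multiple-testing correction) — mirroring how such ROI
analyses are conventionally reported. Colocalisation of two channels within
a compartment is the Pearson correlation of in-scope pixels plus Manders
M1/M2 with per-channel Otsu thresholds by default (recorded in the output;
fixed thresholds selectable — with thresholds at 0 the classic Manders
definition is obtained).

## The phantom

The generator emulates semi-thin-section ion images of cultured cells: a
36 μm field at 256–512 px per side, three ~10 μm cells with nested
cytoplasm / nucleus / nucleolus geometry, an uneven chromatin rim along the
inner nuclear membrane, and S-rich cytoplasmic aggregate discs. Every pixel
count is an independent Poisson draw from its compartment's per-channel
rate; streams are spawned deterministically per run and channel from one
seed. Drug exposure adds ¹⁹⁴Pt⁻ counts (default: linear in concentration,
reaching 1–5 counts/px at 150 μM, the per-pixel scale typical of published
maps) and, through the retained ligands, ¹⁵N-enriched nitrogen entering
only the CN⁻ channels with the mixing abundance
`a = a_ctr + x(a_cddp − a_ctr)`. Absolute CN⁻/C₂⁻ rates are set so ROI sums
span 10³–10⁶ counts — the regime in which sub-per-mil isotope shifts are
resolvable, as the per-mil-scale label fractions of the study design
require; with the default loads the true label fraction stays below
0.4 per mil everywhere. Relative sensitivity factors (defaults
RSF_Pt = 90, RSF_CN = 10 in common arbitrary atom units) close the loop
between configured ligand retention and recoverable stoichiometry. The
nitrogen run can be translated by a whole-pixel inter-run shift.

Deliberately not simulated: detector dead time, quasi-simultaneous-arrival
effects, beam drift within a frame, depth sputtering, chemical matrix
effects, drug chloride/aquation chemistry, and biological ROI-to-ROI
variability beyond counting noise. Passing recovery tests therefore
demonstrates the correctness and statistical calibration of the evaluation
chain under shot-noise conditions — not robustness to instrumental
artefacts, which real data would add on top.

## Validation experiments and problem sizes

`nanostoich.validation` runs the full chain on phantom exposure series
(eight concentrations, 0–150 μM, with the control pooled for `a_ctr`).
The intact-drug experiment (ligand retention 2 everywhere, true RSFs)
recovers N:Pt = 2; the cleavage experiment (nucleolus retains 1 of 2
ligands) recovers the slope-ratio signature 0.5. Default problem sizes —
256×256 px fields, 3 cells ≈ 15 ROIs per sample, 20–50 seeded replicates —
were chosen so each experiment completes in seconds-to-a-minute while
leaving the replicate-mean standard error well below the effect sizes being
checked. `scripts/acceptance.py` reruns the intact-drug experiment from
scratch (20 replicates derived from `--seed`) and writes the replicate-mean
calibrated ratio.

## Known limitations

- Translation-only registration; rotation, scale or nonlinear distortion
  between runs is out of scope.
- The slope regression ignores noise in the abscissa `q`; attenuation bias
  is negligible at the default count scales (relative σ_q a few percent of
  the q range) but would matter for very small ROIs.
- Per-ROI label fractions in nitrogen-rich compartments are individually
  noise-dominated at low exposure; only the series-level fit is
  interpretable there.
- No absolute platinum quantification (fg/cell) and no molarity conversion;
  on real samples results are relative (uncalibrated slopes).
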