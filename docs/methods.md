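# Methods

This note documents the algorithms implemented in mzflow, the
parameters that matter, the synthetic benchmark's design, and the
numerical choices made where the methods themselves leave latitude.

## Data model and units

Retention time is kept in seconds and m/z in Da everywhere. A `Scan` is
one spectrum (parallel m/z / intensity arrays, MS level, continuous or
centroid mode); a `Chromatogram` is one m/z trace over scans; a
`Feature` is one resolved chromatographic peak (apex RT, apex height,
trapezoidal area in intensity·seconds); an `AlignedPeakList` holds rows
of matched features, at most one per sample per row, with row m/z and RT
the running averages of the members. Only mzML (1.0/1.1) is read;
binary arrays may be 32- or 64-bit floats, plain or zlib-compressed.
Scan mode is taken from the file's metadata when declared, otherwise
inferred: a spectrum with ≥ 50 points whose median m/z gap is below
0.1 Da is treated as continuous.

## Mass detection

Five detectors share a parameter object (`noise_level` in intensity
units gates everything):

- **local_maxima** — every strict interior local maximum. Boundary
  points are never maxima (avoids spurious edge peaks); on an exact
  plateau the leftmost plateau point is the maximum. These two
  conventions are used by every detector that scans for maxima.
- **centroid** — pass-through thresholding for centroided data.
- **recursive** — contiguous above-noise regions are split recursively
  at their lowest-intensity interior point until no wider than
  `max_mz_width` (Da); regions narrower than `min_mz_width` are
  discarded; each survivor yields one peak at its apex. Defaults
  0.001/0.1 Da suit high-resolution orbitrap-like spectra.
- **exact_mass** — full-width-at-half-maximum centroiding: the two
  half-maximum crossings are located by linear interpolation between
  adjacent profile points and the reported m/z is their midpoint. An
  apex whose crossing runs off the spectrum edge (or into a rising
  overlapping peak) falls back to the apex m/z and is flagged.
- **wavelet** — the spectrum is convolved with a Mexican-hat kernel
  ψ(x) = (1 − (x/a)²)·exp(−x²/2a²) at a single user-set scale `a`
  (`wavelet_scale`, Da) over a window of ± `wavelet_window` Da; maxima
  of the transform above the noise level are reported at the nearest
  raw local maximum. A single fixed scale is deliberate; multi-scale
  search is out of scope, so the scale should be set near the expected
  peak σ.

**Shoulder-peak filter.** FTMS spectra carry Fourier-artifact
"shoulder" peaks flanking true peaks, typically below 5% of the parent
intensity. Peaks are processed in decreasing-intensity order; around
each survivor a model of height h and FWHM = m/z / R is erected
(resolution R, default 50 000) and any remaining peak below the model at
its m/z is removed. Model shapes: Gaussian
I(Δ) = h·exp(−4 ln 2 (Δ/FWHM)²) or Lorentzian
I(Δ) = h / (1 + (2Δ/FWHM)²) — the FWHM parameterisation is ours; by
construction the model passes through half maximum at Δ = FWHM/2. The
globally most intense peak can never be removed.

## Chromatogram building

Centroids are consumed in global decreasing-intensity order (ties:
lower scan number, then lower m/z); each either extends the trace whose
running intensity-weighted mean m/z is nearest within `mz_tolerance`
(one point per scan per trace) or seeds a new trace. Because
consumption is intensity-ordered rather than scan-ordered, the
`max_missing_scans` gap rule (default 1) is applied afterwards: each
assembled trace is split wherever consecutive member scans are further
apart than the allowance. Finally traces must span ≥ `min_time_span`
seconds and reach `min_height` at their apex — the height criterion
applies to the apex, not to every point.

## Deconvolution

- **baseline** — maximal runs of points ≥ `baseline`; a run becomes a
  feature iff it lasts `min_duration` seconds (measured at the
  baseline, not at half height) and its apex reaches `min_height`.
- **noise_amplitude** — the baseline is placed per chromatogram: an
  intensity window of height `noise_amplitude` is evaluated with its
  bottom at every distinct intensity value (exact O(n log n) search,
  ties to the lowest window) and the baseline is the top of the
  densest window; then as **baseline**.
- **savitzky_golay** — the second derivative of the intensity trace is
  estimated by a Savitzky-Golay filter (polynomial order 2, odd window
  ≥ 5 points). Peak cores are runs where it falls below
  −(apex/w²)·k, with w the smoothing-window duration in seconds and
  k = 0.05; borders extend to the surrounding zero crossings. For a
  Gaussian of height h and width σ the apex second derivative is
  −h/σ², so the threshold sits well below it whenever the window is
  within a few σ.
- **local_minimum** — interior points minimal within ± `search_window`
  seconds are candidate borders. Each segment must pass: apex ≥
  `min_height`; apex ≥ `min_relative_height` × chromatogram maximum;
  apex/edge ≥ `min_ratio` at both edges; duration ≥ `min_duration`;
  and an interior apex (monotone segments yield nothing). Segments
  failing the edge-ratio test are merged with the neighbour across
  their higher-intensity border and re-tested until stable.

**Peak-shape modeler (experimental).** A resolved feature can be refit
with a Gaussian (h, c, σ; ≥ 4 points) or exponentially modified
Gaussian (additional decay constant τ; ≥ 5 points) by non-linear least
squares, initialised from intensity-weighted moments. If the optimiser
fails or worsens the residual relative to the initial guess, the
moment-based parameters (or, on failure, the original feature with a
non-converged model) are returned — the fit never increases the
residual. Refitted points replace raw points only when explicitly
requested in the pipeline config; the modeler's value on real noisy
data is unvalidated, which is why it is opt-in.

## Deisotoping and isotope patterns

Isotopologues are spaced by 1.00335/z Da (the ¹³C−¹²C mass difference
over the charge). For each feature in decreasing-intensity order the
grouper tries every charge 1..`max_charge` (default 3), chaining
features up and down in m/z within `mz_tolerance` whose RTs agree
within `rt_tolerance`; the charge giving the longest chain wins (ties
to the lower charge). A chain is replaced by its most intense member
(configurably the lowest-m/z member), which carries the measured
pattern and charge. Charge from a measured pattern alone is
round(1.00335 / median successive spacing), clamped to [1, max].

Theoretical patterns are computed by exact convolution of per-element
isotope distributions (bundled IUPAC 2013 masses/abundances for C, H,
N, O, P, S, Na, K, Cl), aggregated into nominal-mass bins with
abundance-weighted bin masses, normalised to base peak 1, pruned below
`prune_below`; m/z = mass/charge with the electron mass neglected.
Fine structure within a nominal isotopologue is out of scope.

Pattern similarity: entries matched greedily by m/z distance within a
tolerance; score = 1 − (Σ|Δabundance| over matches + unmatched
abundances)/2, floored at 0. The formula is ours (the comparison idea
is standard, a specific formula is not); it is symmetric and equals 1
exactly for identical patterns. When a measured ion pattern is compared
against a neutral-formula prediction, the prediction is first shifted
onto the measured base peak so adduct mass and calibration offsets do
not defeat the matching. The identification filter's default minimum
score of 0.7 is likewise an artifact choice.

## Identification

Neutral mass m = (m/z × z) ∓ m_adduct (minus in positive, plus in
negative mode), with the adduct mass applied **once** regardless of z —
the literal convention; chemically z protonations carry z proton
masses, so a `per_charge_adduct` flag provides m = (m/z × z) ∓
z·m_adduct for users who want it. Bundled adducts: H⁺ 1.00728, Na⁺
22.98922, K⁺ 38.96316, NH₄⁺ 18.03383, and H loss for negative mode.
Candidates from a local CSV compound table (name, formula and/or
neutral mass, optional RT) are ranked by absolute mass error (ties by
name); an RT gate applies when both sides know an RT; the isotope
filter only removes candidates, never reorders survivors. Online
database connectivity is deliberately absent — the search interface is
pluggable and the bundled implementation is the local table.

## Alignment

`RansacParams` defaults mirror the synthetic-benchmark settings:
`rm0` = 0.05 Da, `rr0` = 50 s (RANSAC window; should be at least the
largest expected RT deviation), `ar0` = 25 s (alignment window after
correction), `k` = 5000 iterations, `min_points_fraction` = 20%
(acceptance floor on the inlier count relative to the candidate
count), `t` = 4 s (inlier residual threshold), non-linear model on.

Numerical choices the procedure itself leaves open:

- **4-point model.** Non-linear mode fits the exact cubic through the 4
  sampled candidates (Vandermonde solve); linear mode a least-squares
  line. Draws with fewer than the required distinct master RTs are
  rejected and redrawn. Model ties on inlier count are broken by the
  smaller total inlier residual. The per-sample RNG stream is derived
  from the seed and the sample index, so runs are bit-reproducible.
- **Local optimisation.** A minimal 4-point model rarely tracks drift
  across the whole RT range within t = 4 s, so the raw consensus can
  leave coverage holes. After selection, the support is re-collected
  against the LOESS-smoothed curve with an annealed threshold
  (8t → 6t → 4t → 3t → 2t → 1.5t → t → t → t), letting the support
  grow across under-covered regions while the final rounds tighten it
  back to genuine inliers. This is standard RANSAC refinement
  (locally-optimised RANSAC).
- **LOESS bandwidth.** The smoother is local-linear
  (`statsmodels` lowess). Span default 0.2 of the support, floored so
  each local fit sees ≥ 8 points. The bandwidth must be narrow enough
  to resolve drift with structure on the scale of a fraction of the
  run: a local-linear fit over a half-window h incurs a bias of order
  f″·h²/2, which for sine-like drift (amplitude tens of seconds,
  period comparable to the run) exceeds the 4 s inlier threshold
  already at spans near 0.5. Robustness iterations are disabled
  (it = 0): outlier rejection is RANSAC's job, and bisquare
  reweighting would down-weight genuine support at drift-curvature
  peaks.
- **Extrapolation.** Outside the support range the correction
  extrapolates linearly with a slope estimated by least squares over a
  10-point boundary band — a two-point boundary slope amplifies
  point-level jitter into tens of seconds of error when extrapolating
  far beyond the support.
- **Join scoring.** "Best candidate" = lowest |Δm/z|/mz_tol +
  |ΔRT|/rt_tol, ties by smaller |Δm/z| then m/z and RT; matches are
  assigned greedily over the per-sample score list, which makes the
  Join aligner invariant to within-sample feature order. Unmatched
  features open new rows (sorted by m/z then RT for determinism).
- **Fallback.** If no model reaches the inlier floor (or fewer than 4
  candidates exist), the sample is joined without correction using the
  wide `rr0` window, and the event is logged.

## The synthetic benchmark

`generate_synthetic_dataset` emulates a multi-sample alignment study in
which every sample carries identical peak content and differs only by
retention-time deviation. Defaults (the benchmark's study conditions):
20 samples; 200 seed peaks uniform over m/z 100–1000 Da × RT
60–1200 s with log-normal heights (median 10⁴, σ_log = 1); per-sample
smooth warp r′ = r + a·sin(2πr/T + φ) + b·(r − r_min) with the total
deviation budget drawn between 30% and 100% of `max_rt_deviation`
(default 40 s), split randomly between the sine and linear terms, and
period 0.6–1.8 × the RT span; Gaussian RT jitter of σ = 0.5 s per
peak (scan-to-scan apex variability; the warp bound applies to the
warp, jitter rides on top); zero decoy peaks by default — decoys with
no cross-sample identity are available for stress tests. Everything is
deterministic under the seed.

What the generator does **not** emulate: peak-height variation between
samples, m/z calibration drift, missing peaks, co-eluting isobars,
detector saturation, or any raw-signal-level effects (features are
generated directly, not via the detection chain). Perfect scores on
this benchmark therefore demonstrate the RT-correction and matching
machinery, not robustness to detection noise — the real-data behaviour
of the full chain is exercised separately by the pipeline tests on
synthetic raw files.

Evaluation counts **pairs**: an alignment is an unordered cross-sample
pair of features sharing a row; precision = true pairs/produced pairs
(undefined, reported as None, when nothing was aligned), recall = true
pairs/all same-identity cross-sample pairs in the truth. Row-wise
counting was the alternative; pairwise matches the ground-truth-pair
formulation used by the established alignment-evaluation framework.

## Problem sizes and determinism

The acceptance script runs five replicate 20-sample × 200-peak datasets
at 2000 RANSAC iterations; the test suite uses 500 iterations for the
same benchmark and smaller instances elsewhere. These sizes were chosen
so the whole suite completes in seconds while keeping the benchmark at
its full 20-sample × 200-peak geometry; iteration count barely affects
the result here because ~200 candidates per sample make good 4-point
draws frequent. All randomness flows through explicit seeds.

## Known limitations

- With per-sample warps bounded at ±40 s, two samples can disagree by
  up to 80 s — beyond the 50 s RANSAC window — at the extremes of the
  RT range early in the incremental alignment (when the master list
  still reflects a single sample's warp). Rare replicates can
  therefore lose a fraction of a percent of recall on peaks warped
  past the RT range boundary; precision is unaffected, as split rows
  still pair like with like.
- The wavelet detector uses one fixed scale; badly mis-set scales miss
  narrow or merge wide peaks.
- LOESS is local-linear; strongly curved drift is handled by the
  narrow span rather than local polynomials of higher degree.
- The XML peak-list export uses this package's own flat schema
  (`<peaklist><row><peak/></row></peaklist>`), documented by example in
  the writer's docstring; there is no community-standard schema for
  aligned peak lists.
- The EMG fit is numerically delicate for τ ≪ σ; non-convergence is
  reported, not silently ignored.
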