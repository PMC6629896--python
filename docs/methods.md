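# Methods

This note documents the models and estimators implemented in `cvcoupling`,
the choices made where the underlying methods literature leaves latitude,
and what the synthetic cohort generator does and does not emulate.

## Data model and preprocessing

A recording is a beat-aligned triple of series: the tachogram (BBI, the
beat-to-beat interval in ms), the systogram (SBP, per-beat end-systolic
pressure, mmHg) and the diastogram (DBP, per-beat end-diastolic pressure,
mmHg). Beat times are reconstructed from the cumulative tachogram with the
first beat anchored at t = 0; raw waveforms and fiducial-point detection are
out of scope.

**Artifact filter.** Ectopic beats and artifacts are flagged per channel
when a beat deviates from a centred rolling mean (window 20 beats) by more
than `lambda_sd` (default 3.0) rolling standard deviations plus a floor of
5% of the local mean magnitude; flagged beats are replaced by linear
interpolation between the nearest clean neighbours. The floor term keeps
clean low-noise recordings flag-free and makes flagging monotone in
`lambda_sd`. Because the rolling statistics include the beat itself, a
dense burst of artifacts can partially mask itself; at the ectopic rates
the generator produces (well under 5%) this is immaterial. Recordings with
more than 5% flagged beats are conventionally excluded (`exclusion_mask`).

**Resampling and normalization.** For spectral and directed-coherence
analysis each channel is linearly interpolated onto a 2 Hz grid
(`floor(duration * 2) + 1` samples) and, where required, z-normalized with
the population standard deviation so the variance is exactly one. Sample
(N−1) standard deviations are used for all descriptive indices (sdNN, SD1,
SD2).

## Joint symbolic dynamics

Increments of two simultaneous series are coded into symbols, overlapping
words of length 3 are formed, and the joint word distribution quantifies
the coupling. Binary coding flags increments (1) vs. everything else (0),
giving an 8 × 8 joint matrix. Ternary coding uses a threshold `l` (5 ms for
BBI, 1 mmHg for pressures): 0 for a decrement beyond −l, 1 for equilibrium
within ±l, 2 for an increment beyond +l, giving 27 word types and a
27 × 27 (729-cell) matrix. Accounts circulate that assign "1" to decrements
and "0" to equilibrium; the threshold-rule form above is the one
implemented, consistently with reading family E0 ("000") as three
successive decrements. Words overlap with stride 1.

The 27 ternary words partition into eight pattern families — E0/E1/E2 (no
variation), LU1/LD1 (slow rise/fall, 8 words each), LA1 (fast alternation,
2), P (peak-like, 3), V (valley-like, 3) — and the joint family matrix is
8 × 8. Per coupling the package emits the 64 family-pair probabilities, the
2 × 8 marginals and the Shannon entropy of the 64-cell joint distribution
(81 indices). Counting conventions in the surrounding literature are
ambiguous (a published total of 264 ternary indices does not decompose into
any obvious per-coupling count); the well-defined 81 per coupling are
emitted. Entropy on the joint family matrix was likewise a choice; marginal
entropies can be derived from the emitted marginals if needed.

## Poincaré plots, classical and segmented

SD1/SD2 are the sample standard deviations of the point cloud along the
minor/major axes of the lag plot: SD1 = sd((y−x)/√2), SD2 = sd((y+x)/√2).
Segmented analysis (SPPA) rotates the cloud 45° about its centroid so the
major axis is horizontal and overlays a 12 × 12 grid with rows of height
SD1/2 and columns of width SD2/2 (span ±3 SD per axis — the convention of
the originating segmented-Poincaré literature; the cell size is
configurable). Cells are half-open [low, high), so edge points fall in the
higher-index cell; row 1 is the bottom row and column 1 the leftmost.
Occupancy is reported in percent; mass outside the grid is reported
separately, so cells + out-of-grid = 100%. Cross-signal plots pair channel
one at beat n with channel two at beat n+1 (lag 1), mirroring the
univariate construction and the coupling orientation; lag 0 is available.
Because the grid is SD-adaptive, cell probabilities are invariant to
shifting and rescaling of both channels. Row/column labels such as
"Column 2-6" in parts of the literature are ambiguous between cells and
marginal sums; the package emits rows and columns (and optionally all 144
cells) under unambiguous names and asserts neither reading.

## Normalized short-time partial directed coherence

A multichannel AR model is fitted to the z-normalized 2 Hz channels by
stepwise least squares with Schwarz's Bayesian criterion selecting the
order in 1..p_max (default 20); the fit is delegated to statsmodels' VAR.
PDC uses the standard column-normalized form
π_{i←j}(f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²) with
Ā(f) = I − Σ_r A_r e^{−i2πfr/fs}, so the squared outflows of every source
sum to one per frequency. The time-variant field is computed in sliding
windows (default 600 samples = 5 min at 2 Hz, shift 300, i.e. 50% overlap
— the windows literature leaves the overlap open).

For an ordered channel pair, the forward and backward coupling strengths
are the window-averaged frequency means of the directed PDC (the "areas",
in [0, 1]; on a uniform grid the mean and the normalized integral
coincide, and the mean guarantees the [0, 1] range). Their ratio is
quantized into the normalized factor NF ∈ {−2, −1, 0, 1, 2}: |NF| = 2 for
dominant/weaker > 5, |NF| = 1 for a ratio in (2, 5], 0 otherwise, negative
when the second-listed channel drives; both means equal and positive is
flagged "equal influence", both zero "no coupling".

**Frequency band.** NF and the areas average π over 0–0.4 Hz by default
(VLF+LF+HF, where cardiovascular regulation operates), not over the full
0–1 Hz Nyquist range. The reason is empirical and structural: beat series
carry information at the beat rate (~1.1 Hz here), and linear interpolation
onto the 2 Hz grid uses the *next* beat, i.e. looks up to one beat into the
future. Above ~0.4 Hz the resulting PDC reflects interpolation artifacts
rather than physiology, to the point of inverting the apparent direction
(for a purely SBP→BBI-coupled system the 0.7–1.0 Hz band shows the reverse
direction dominating ~0.27 vs. 0.69). `band=None` restores the
full-Nyquist average.

## Dual sequence method

Spontaneous baroreflex sensitivity: maximal runs of ≥3 beats in which SBP
changes monotonically with every step > 1 mmHg are paired with the BBI
segment one beat later (delay configurable) whose steps all exceed 5 ms in
the same direction. Each paired run contributes the least-squares slope of
BBI on SBP (ms/mmHg); bradycardic sequences (both rising) average to
`bslope`, tachycardic (both falling) to `tslope`. The aggregation across
sequences defaults to the mean, matching the classical sequence method; a
`slope_agg="max"` switch keeps the steepest slope instead, since the
originating description ("the highest slope of every sequence") is
ambiguous. No minimum-correlation gate is applied by default (the
classical r ≥ 0.85 criterion is available as an option).

Note that when the tachogram is autocorrelated the sequence slope estimates
the total response over the run, which exceeds the one-beat gain by roughly
1/(1−ar); the parameter-recovery test therefore uses a generator profile
without BBI autoregression.

## Standard HRV/BPV indices

Per channel: meanNN, sdNN (N−1), rmssd, pNN50, and Welch band powers on
the 2 Hz series (256-sample segments, 50% overlap, per-segment mean
detrending — an estimator choice made for reproducibility) integrated over
VLF 0.0033–0.04 Hz (Task-Force convention for the lower edge), LF
0.04–0.15 Hz and HF 0.15–0.4 Hz, plus LF/HF and normalized LFn/HFn. The
7 × 3 = 21 core indices carry BBI/SYS/DIA prefixes; VLF/LFn/HFn are
supplementary. pNN50 applies the 50-unit rule in each channel's native
units — 50 mmHg on pressure series is a near-degenerate but literal
convention, and the threshold is configurable.

## Screening and classification

Indices are screened per group pair with the two-sided Mann–Whitney U test
(exact enumeration when both groups ≤ 8 and tie-free, otherwise the normal
approximation with tie correction) and tiered at alpha (0.01), alpha/10 and
the Bonferroni cut alpha/m computed from the actual number of indices m.
Redundancy among significant indices is pruned by absolute Spearman
correlation ≥ 0.7 (rank-based, consistent with the rank-based screen),
dropping the larger-p member of each pair, strongest correlations first,
name order on ties — the survivor set contains no pair at the threshold.

SVMs are trained on index pairs with Gaussian, Laplacian or ANOVA kernels;
a `laplace_printed` variant exp(−‖x−y‖²/2σ) is also provided because a
Gaussian-shaped kernel occasionally circulates under the Laplace name, but
the standard Laplacian exp(−‖x−y‖/σ) is the default. Features are
standardized with training-set statistics only; under leave-one-out
cross-validation the scaler is refit per fold, so the held-out subject
never informs the model. Grid search (defaults C ∈ {0.1, 0.3, 1, 3, 5.5,
7, 10}, σ ∈ {0.1, 0.3, 1, 1.5, 3}, d ∈ {1, 2, 3}) maximizes LOOCV
accuracy with ties broken by AUC then enumeration order. Sensitivity and
specificity take the patient (higher-risk) group as positive; AUC is the
rank statistic on pooled held-out decision values. The cascade stratifies
an unlabelled subject with a CON-vs-IDC stage whose CON verdict is
terminal, followed by an LR-vs-HR stage.

## Synthetic cohort generator

The generator is a linear stochastic difference-equation model, not a
physiologically detailed baroreflex model: it is the minimal structure
expressing the directed couplings the estimators target, with analytically
recoverable parameters. SBP follows an AR(1) plus a mechanical influence
of past BBI and a respiratory sinusoid (0.25 Hz default); BBI follows an
AR(1) plus the baroreflex influence of past SBP; DBP is linearly tied to
SBP plus noise. Cross-couplings act with a `coupling_delay` of 2 beats by
default — baroreflex and mechanical latencies are of the order of one to a
few seconds, and a delay beyond one beat is also what keeps direction
identifiable after 2 Hz interpolation (see the band discussion above).
Innovation variances are solved from the stationary covariance equations
so that the simulated marginal standard deviations match the profile's
targets; when the couplings alone already exceed a target the innovation is
clipped at a 5% variance floor and the marginal comes out slightly above
target. Ectopy is emulated by halving randomly chosen intervals.

Shipped profiles encode three groups whose means match the magnitudes
reported for healthy controls and low/high-risk dilated-cardiomyopathy
patients (BBI mean ≈ 884/907/828 ms, BBI sd targets ≈ 48/37/33 ms) and
whose couplings produce the qualitative structure the estimators should
resolve: heart-rate variability (sdNN, rmssd) falls CON → LR → HR,
short-term systolic variability (SD1) rises, the baroreflex gain falls
(8 → 5 → 0.5 ms/mmHg) and the cardiac → pressure gain rises (0.012 →
0.035 → 0.12 mmHg/ms), making the control group systolic-driven
(NF = −1 for the cardio-systolic pair) and the high-risk group
cardiac-driven (NF = +1). Gains are model defaults, not measured values.
Between-subject heterogeneity is drawn per subject (5% relative SD on
means, 15% log-normal on spreads and gains); without it all subjects of a
group would be statistically identical and any classifier would be
degenerate.

What passing tests on this generator do *not* show: robustness to
non-stationarity (drifting means, posture changes), nonlinear or
state-dependent coupling, realistic ectopy morphology, respiratory
frequency variability, or measurement noise of continuous-pressure
devices. Results on synthetic cohorts demonstrate estimator correctness
and pipeline behaviour, not clinical performance.

## Problem sizes used in the shipped tests

Parameter-recovery checks use 100 replicates of n = 4000 for MAR order
selection and coefficient coverage, 3000-beat recordings for baroreflex
gain recovery, 20 subjects × 1500 beats per direction for NF sign
recovery, and 10 gain levels × 20 subjects × 700 beats for the
area-vs-gain monotonicity. The pipeline-level check runs 20 subjects per
group at 1800 beats (≈ 26 min) through the standard/DSM/Poincaré feature
groups, Mann–Whitney screening with correlation pruning, a LOOCV grid
search over the top index pairs, and the two-stage cascade; these groups
were chosen because the check is about cohort separability and they carry
it at a fraction of the cost of the full symbolic/coherence extraction.

## Known limitations

- The filter's rolling statistics include the evaluated beat; extreme
  artifact bursts can self-mask (not reachable at generated rates).
- PDC assumes an adequate linear MAR description; strongly deterministic
  couplings (innovation clipped at the floor) reduce identifiability, and
  instantaneous (same-window) dependence is deliberately ignored.
- The sequence method's slope is an aggregate-response estimate, biased
  upward for autocorrelated tachograms (see above) and selection-biased at
  very low gains.
- NF integration above 0.4 Hz on 2 Hz-interpolated beat series reflects
  interpolation, not physiology; use beat-domain PDC if supra-0.4 Hz
  content matters.
- pNN50 on pressure channels with the literal 50-unit rule is nearly
  always zero; configure the threshold for meaningful pressure variants.
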