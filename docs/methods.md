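# Methods

`halospat` re-implements, as a reusable and tested pipeline, the analysis
used in spatial surveys of halite endolith microbiomes: microbial
communities living inside evaporitic salt nodules in hyperarid coastal
deserts. The survey design it targets is nested — two regions roughly
20 km apart, two hill sites within a region (~300 m), several nodules
within a site (~10 m), vertical slices within a nodule, and top/middle/
bottom positions within a slice (~3–10 cm). The scientific questions are
(i) how community similarity decays with spatial separation, (ii) which
taxa track humidity and light gradients inside a nodule, and (iii) how the
physical environment (dew/fog events, intra-nodule light, biomass) varies
across those scales.

## Environmental sensor statistics

Loggers record relative humidity (RH, %) and temperature (°C) every
30 minutes. Dew is scored when RH exceeds 95 %, fog when it exceeds 99 %;
both thresholds are strict inequalities, so a sample exactly at the
threshold does not trigger an event. An event is a maximal run of
consecutive above-threshold samples; its duration is run length × cadence.
Day counts are distinct calendar days touched by at least one event, and
an event spanning midnight counts toward both days — the convention is
documented because survey reports are usually silent on it. No minimum
duration and no gap-merging are applied (simplest rule; both are natural
extension points). Gaps (NaN samples) never count as above threshold and
therefore terminate events. Irregular cadence is refused with an
instruction to resample, rather than silently reinterpreted.

Smoothed daily profiles use local polynomial kernel regression with a
Gaussian kernel: at each query point a degree-q polynomial is fitted by
weighted least squares with weights exp(−((x−x₀)/h)²/2). Degree 6
reproduces the smoother conventionally used for year-long daily climate
profiles; degree 0 is the local ("spatial") average used for
abundance-versus-depth curves. By construction the smoother reproduces
polynomials up to its degree exactly on noiseless input; rank-deficient
local systems fall back to a lower degree, recorded per query point.

## Intra-nodule light and PAR

Measured spectra are divided pointwise by the source spectrum (linear
interpolation onto the measured grid) to give an effective transmission
fraction; analysis is restricted to 500–900 nm, where fiber-optic
measurements through salt are reliable. Profiles are standardized to the
mean of the top-position profiles, which absorbs inter-nodule variability
and makes the standardized reference mean identically 1.

PAR is estimated by integrating the transmitted solar spectrum over the
photosynthetic band (400–700 nm), dividing by the integrated incident
solar spectrum, and scaling by the maximum midday solar PAR
(default 2100 µmol photons/m²/s). The photosynthetic band extends below
the 500 nm data window; integration is therefore carried out over the
intersection actually covered by the data, and the effective band is
returned with the ratio — extrapolating transmission outside the measured
range is refused. Integration is trapezoidal on the union of the input
grids after linear interpolation; the choice is recorded because at these
smooth spectra the rule's error is negligible relative to measurement
noise.

Light scattered inside the salt matrix means a downward-facing probe still
records intensity; the isotropy correction is
1 + (band-integrated upwelling / band-integrated downwelling), giving 1.3
at the typical 30 % upwelling fraction. The correction defaults to OFF in
`estimate_par` because direct-transmission PAR values are conventionally
reported without it; pass the factor explicitly to apply it. Bottom
positions are not modeled: lab transmission measurements cannot reproduce
the field's lateral and under-nodule scattering there.

## Biomass

Cell densities are computed from DAPI-stained filter counts as
count × (filter area / eFOV) × (V_total / V_filtered) / mass, with
defaults eFOV = 0.203 mm², filter area = 226.98 mm², 2 ml filtered, and
0.5 g of halite. The total suspension volume is a prep-protocol choice,
not an instrument constant; the default of 10 ml is a documented
convention and absolute densities scale linearly with it — override it
with the value actually used. Outlier rejection is a single pass: per-image
density estimates (pooled across the sample's filters) farther than
k = 2 sample standard deviations from their mean are discarded, without
iteration; with a sample SD of zero nothing can be discarded, and a short
argument shows a single pass can never discard everything.

## Diversity

Count tables are samples × ASV DataFrames; phylogenies are rooted Newick
trees whose tips are ASV ids. Conventions follow the QIIME-era pipeline
this package mirrors: Shannon entropy in bits (log base 2), Pielou
evenness Shannon/log₂(richness) (undefined for one-taxon samples, reported
missing), Simpson 1 − Σp², Faith PD the total branch length of the minimal
subtree spanning the root and the tips present. Rarefaction subsamples
without replacement (multivariate hypergeometric) to a fixed depth,
dropping and logging shallower samples; "auto" depth is the minimum sample
total.

Bray–Curtis is Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ). Weighted UniFrac is
Σ_branches ℓ·|P_a−P_b| with P_x the fraction of sample x's reads
descending through the branch; the unnormalized variant is the default
(again the mirrored pipeline's convention) and the normalized variant
(divide by Σ ℓ·(P_a+P_b)) is a flag. Both are implemented from first
principles over a single postorder accumulation; the test suite checks
them against brute-force branch enumeration and against scikit-bio's
independent implementation.

PCoA is classical metric scaling: eigendecomposition of the
double-centered −½D² matrix. Axes with positive eigenvalues are retained
and variance proportions are computed over positive eigenvalues only;
negative eigenvalues (non-Euclidean dissimilarities) are reported
unmodified rather than clipped, so the user can judge distortion.

## Inferential statistics

**PERMANOVA.** Pseudo-F from among/within sums of squared
dissimilarities, p-value (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under free
permutation of sample labels (no strata, matching the mirrored pipeline's
reported use). Deterministic under an explicit seed.

**Group alpha tests** use Kruskal–Wallis with tie correction (SciPy's
implementation behind the module surface; an independent rank-arithmetic
oracle lives in the tests). The degenerate all-identical case returns
H = 0, p = 1.

**ANCOM.** For each ordered taxon pair the per-sample additive log-ratio
log((xᵢ+1)/(xⱼ+1)) is tested between groups; each taxon's family of
pairwise p-values is Benjamini–Hochberg corrected and W counts rejections
at α. A taxon is flagged when W ≥ 0.7·(n_taxa−1). The per-pair test
family, pseudocount, correction and cutoff are all configurable because
published ANCOM variants differ; the defaults are a two-sided pooled
t-test, pseudocount 1, BH, 0.7.

**Slice standardization** divides each taxon's relative abundance by its
mean within the sample's slice, making within-slice means exactly 1 and
removing inter-nodule and inter-slice composition differences before
positional contrasts. Taxa absent from a slice become missing, never
infinite.

**Positional tests** are two-sided paired Student t-tests per taxon,
pairing top/middle/bottom values on their slice (replicates within a
slice-position are averaged first); an unpaired pooled-variance variant
serves site comparisons, and a Welch-style choice was deliberately not
made the default because the classic Student test is what such surveys
report. Zero-variance nonzero differences are flagged degenerate with
p = 0. Raw p-values are always emitted; BH-adjusted values are added per
contrast across taxa.

**Depth trends** combine a Spearman correlation of standardized abundance
against distance-to-surface, an order-0 kernel-smoothed curve
(bandwidth 0.5 cm, half the width of a position depth band — narrow
enough to resolve a peak at 2–3 cm without tracking individual samples),
and a near-surface (<1.5 cm, configurable) versus interior contrast,
paired on slice means when a pairing is supplied.

**Scale decay** classifies every sample pair by the finest design level it
shares: same nodule and position → 3 cm (horizontal neighbours across
slices), same nodule → 10 cm, same site → 10 m, same region → 300 m,
otherwise 20 km. The classes partition all fully-labeled pairs; pairs with
incomplete labels are excluded and counted. Adjacent classes are compared
with two-sided t-tests on their dissimilarity distributions. The
replicate noise floor is the mean ± SD dissimilarity over designated
biological-replicate pairs.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with ground
truth, and its defaults are the survey conditions: 2 regions × 2 sites ×
6 nodules × 3 slices × 3 positions, 5000 reads per sample, 40 taxa.

Counts follow a logistic-normal (softmax-multinomial) model: per-sample
log-abundance is a taxon baseline plus β_RH·RH + β_light·L plus
independent Gaussian drift drawn per taxon at each nesting level (region,
site, nodule, position-within-nodule, slice, residual), then softmaxed and
sampled multinomially. This is the minimal generative model that yields
compositional count data with nested drift. The position-within-nodule
drift level exists because the field observation is that composition
changes predictably along the vertical axis but quasi-randomly between
slices; with position drift ≥ slice drift, horizontal neighbours (same
position, different slice) are more alike than vertical neighbours, which
is what the 3 cm < 10 cm decay ordering requires.

Covariates derive from depth below the nearest surface: top/bottom samples
sit at 0.5–1.5 cm, middle samples at 2–4 cm. The light index is −depth
(log-PAR under Beer–Lambert attenuation with unit coefficient); the
humidity index is a Gaussian bump peaking at 2.5 cm (SD 1.5 cm),
encoding a periphery that dries out and an interior that buffers
humidity, with optional per-region offsets for regional climate
differences.

Three effect presets set the study conditions. `null` (exchangeable
samples) backs the type-I-error calibration. `nested_drift` (SDs 0.8,
0.5, 0.3, 0.2, 0.12, 0.05 from region down to residual — decreasing
toward finer levels) produces distance decay. `intra_nodule_gradient`
contains one phototroph whose light slope is calibrated (0.24073) so that
its realized mean relative-abundance enrichment at tops versus middles is
+80 % after softmax normalization — the slope is below log(1.8)/2 because
the humidity-loving interior taxa inflate middle-sample denominators —
plus three interior heterotrophs with humidity slopes giving roughly
+310 %, +70 % and +50 % middle enrichment, over a dominant neutral
background community. Where survey papers do not state magnitudes
(inter-annual variation, drift SDs), defaults are order-of-magnitude
choices flagged in the source.

Sensor series are diel sinusoids (temperature peaking at 14:00, RH at
04:00) plus Gaussian noise, with defaults keeping baseline RH below the
dew threshold so injected events are recovered exactly: a dew event
forces RH into (95, 98], a fog event into (99, 99.8], over its stated
span. Overlapping injections of the same kind are rejected. Spectra are
Beer–Lambert: intensity(λ,d) = source(λ)·e^(−k(λ)·d). Field counts are
Poisson around the expectation implied by the true density, so the
density estimator applied to the noiseless expectation inverts exactly.

Every generator takes an explicit integer seed (NumPy `default_rng`); no
global state is used, and identical seeds give bit-identical outputs.

### What the generator does not emulate

Read-level artifacts (chimeras, primer bias, denoising errors), taxon
correlation structure beyond the shared environmental responses,
overdispersion beyond the logistic-normal's, rain events, seasonality in
the sensor series, and wavelength-dependent scattering anisotropy.
Passing tests on this generator therefore demonstrate the statistical
machinery is correct and calibrated under the assumed model — not that
the model captures every property of real halite data.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to the
survey's own scales: the full nested design (216 samples) for decay, the
intra-nodule design (54 samples) for gradient recovery, 500 null studies
at 16 samples (n_perm = 199) for PERMANOVA calibration, and ≥100 random
small instances per metric for oracle equivalence. Tolerances: exact
equality for integer outcomes (W, day counts, rarefied totals), 1e-8 for
metric/oracle agreement and PCoA round-trips, 1e-6 for attenuation
recovery. Ties in rank tests use midranks; PCoA eigenvalue positivity uses
a scale-relative threshold (n·ε·max|λ|); degenerate zero-variance t-tests
are reported as flagged limits (p = 0 or 1) rather than NaN.

## Known limitations

ANCOM is the classic W-statistic form, not later model-based variants;
PERMDISP-style dispersion tests are out of scope, so significant PERMANOVA
results can reflect dispersion as well as location differences; the
smoother offers no automatic bandwidth selection; absolute cell densities
depend on the user-supplied total suspension volume; and unweighted or
generalized UniFrac are not provided.
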