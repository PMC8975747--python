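# Methods

`cyanotransect` implements a computational chain for quantifying cyanophages
and virally infected picocyanobacteria along ocean transects: polony-assay
quantification, oceanic-regime classification, detection of the inter-gyre
virus hotspot, conversion of instantaneous infection into daily and
per-generation mortality, temperature x chlorophyll regression prediction of
cyanophage abundance, and a viral-shunt carbon budget. This note records the
models, the parameters that matter, and the numerical and design choices.

## Polony quantification

A polony reaction counts single virus genomes (free-phage mode) or infected,
flow-sorted cells (infected-cell mode). Concentration is
`mean(counts) / (volume x efficiency)`; infected fraction is
`max(0, mean(counts) - free-phage correction) / (cells x efficiency)`,
clipped to [0, 1]. Detection efficiencies are lineage-specific empirical
quantities; the default is 1.0 (no correction) and measured values are
supplied by configuration. Negative corrected counts clip to zero with a
flag rather than erroring, because low-infection samples legitimately hit
that boundary. Stage bounds use the early-infection (lowest) efficiency for
the upper bound and the late-infection (highest) efficiency for the lower
bound.

**Bootstrap.** Confidence intervals are percentile (2.5, 97.5) intervals
over resampled replicate means divided by efficiency draws. With the
two-replicate designs typical of these assays, nonparametric resampling of
replicates cannot reach nominal coverage (a resample of two values has three
outcomes), so the default resampler is parametric at the replicate level:
counts are redrawn from Poisson(mean count), which is the generating model
for single-molecule counting. Nonparametric replicate resampling and
efficiency-only resampling remain available (`resample_counts=` flag), and
efficiency uncertainty enters through a user-supplied set of efficiency
measurements (resampled) or a Beta jitter around a point value. Whether
counts, efficiencies, or both are resampled is an open choice in this kind
of assay; both are resampled by default when efficiency values are given.
Monte-Carlo checks show ~94-96% coverage for the default at Poisson rates of
a few hundred counts per reaction.

## Regimes, front, and mixed layer

Salinity thresholds partition the section: subtropical gyre > 34.6,
subpolar gyre < 33, transition zone between. Exact boundary values
(34.6, 33.0) are classified as transition ("intermediate waters"); the
choice is documented and tested. The chlorophyll front is the southernmost
south-to-north upward crossing of 0.2 mg m^-3, linearly interpolated between
the bracketing samples; multiple crossings warn and use the first. The mixed
layer is the linearly interpolated depth at which surface-referenced
potential density first exceeds the surface value by 0.1 kg m^-3; the
interpolation scheme is a numerical choice (profiles are discretely
sampled), and a profile with no exceedance is flagged rather than assigned
a depth.

## Hotspot detection

Cyanophage abundance is organized on the temperature axis, which anchors the
hotspot across cruises regardless of where the transition zone sits in
latitude. The steps:

1. **Scale and centre** per cruise: divide by the cruise-wide maximum, then
   subtract the mean scaled subtropical abundance. Out-and-back cruises
   contribute all samples to one cruise-wide scaling.
2. **Smooth**: pooled centred samples are reduced to per-0.1 °C bin means at
   the mean temperature of each bin (exact for affine profiles, and it
   averages replicate noise before interpolation), linearly interpolated to
   a regular 0.1 °C grid, then averaged over a 2.5 °C sliding window with
   truncated endpoints. Pooling across cruises before smoothing is the
   default; per-cruise smoothing is available via a flag.
3. **Curvature**: central second differences. The public `curvature`
   function uses the 1-bin stencil; the detector defaults to a wider stencil
   of half the smoothing window (1.25 °C) and additionally averages the
   curvature curve over one window width before peak-picking. Second
   differences at grid scale amplify noise quadratically, and the flank
   curvature peaks are broad and shallow; without these two choices the edge
   locations are noise-limited. Both widths are exposed as parameters.
4. **Edges**: the detected range is bounded by the largest positive-curvature
   peak on the cold flank and on the warm flank of the smoothed abundance
   maximum — the temperatures where the rate of change of abundance changes
   fastest on each side of the peak. This is the headline interpretive
   choice: a single "maximum of the second derivative" under-determines two
   edges, and flanking curvature maxima are the reading that yields a range
   containing the abundance peak. Ties break toward the peak. A profile
   whose smoothed maximum is not interior is flagged `no_interior_maximum`
   (monotone profiles have no hotspot).
5. **Latitude mapping**: per cruise, the temperature-latitude relation is
   median-filtered (kernel 3) to remove small inversions, forced monotone,
   and inverted by interpolation; edge temperatures outside a cruise's range
   clip to the transect ends with a flag.

Correlation diagnostics are Pearson correlations of log10-transformed
abundances (non-positive and missing pairs dropped, n reported).

## Mortality model

Instantaneous infection I (fraction of cells carrying virus at sampling) is
converted to a daily loss rate by the number of infection cycles per day:

    cycles = daylight_hours / (0.4 x latent_period(T))
    M_daily = min(1, I x cycles)

The latent period is referenced to culture measurements at 21 °C and
lengthens by 25% per 3 °C of cooling; warming shortens it by the symmetric
factor (division by 1.25 per 3 °C; an alternative x0.75-per-3-°C reading is
switchable). The 0.4 factor encodes the shorter latent periods at the high
irradiance of the surface mixed layer relative to dim culture conditions,
and lysis is assumed to stop at night (daylight hours are per-sample inputs;
no astronomical calculator is embedded; `nocturnal_lysis=True` removes the
day-length assumption). Cycles are continuous by default — flooring to whole
cycles is an option. The corrections are conservative: in the study domain
(T <= 21 °C, daylight < 24 h) removing the temperature or day-length
correction can only raise the estimate, a property that is tested. The cap
at M_daily = 1 is a package choice (a daily loss fraction cannot exceed the
population).

Per-generation mortality uses the cumulative distribution function

    M = 1 - exp(-M_daily x t_double)

with t_double = ln(2)/mu the doubling time in days of the natural
population. The mu convention (specific division rate, so the exponent is
M_daily x doubling time) is fixed as the default; the alternative reading
(mu as doublings per day, multiplying the exponent by ln 2) is switchable
because the symbolic definition admits both. With daily mortalities of
10-30% and doubling times of 2.8 d (Prochlorococcus) and 1.1 d
(Synechococcus), the default convention gives per-generation mortality of
roughly 24-57% and 10-28% respectively, matching the magnitudes expected
for these hosts.

Doubling times come from the faster-growing ecotype at each temperature:
high-light II Prochlorococcus above 14.7 °C (high-light I below), and
Synechococcus clade II above 23 °C (clade I below). Parametric
ecotype curves, when supplied, are combined by pointwise minimum; the
constant defaults (warm/cold 1.5/2.8 d for Prochlorococcus, 0.8/1.1 d for
Synechococcus) are configuration placeholders. Host mortality sums
per-lineage contributions, each lineage completing cycles at its own latent
period; abundance-weighted community averaging is implicit in that sum.

## Regression model

The deployment model is ordinary least squares of log10 abundance on
(1, T, Chl, T x Chl). The log10 response is a package choice: abundances
span orders of magnitude and the train/test screening itself uses
log-transformed candidates; a natural-scale switch exists. Chlorophyll
enters untransformed in the deployment model, with a log-Chl candidate in
the screening set. Candidate predictor sets (host abundances, total
picocyanobacteria, the Prochlorococcus:Synechococcus ratio, each interacted
with temperature) are ranked by RMSE on a held-out cruise; the
chlorophyll-interaction model is tagged as the deployment default regardless
of rank because gridded chlorophyll is far more widely available than host
abundances. Intervals are prediction intervals for new observations
(t-quantile, leverage + residual variance) computed on the log scale and
back-transformed, hence asymmetric on the natural scale; a mean-confidence
flavour is available. Gridded prediction is masked to T > 5 °C (thermal
bound on picocyanobacterial growth) and Chl < 0.4 mg m^-3 (the domain the
model was trained in); missing cells propagate as masked.

## Carbon budget

Lysate carbon per day is

    L_vir = P M_Pro (C_Pro - C_vir B) + S M_Syn (C_Syn - C_vir B)

computed per cyanophage lineage (each lineage's virion carbon x burst size
deducted from the lysed quota) and summed; lineage attribution of host
mortality is proportional to each lineage's infected-cell fraction, which is
how the per-lineage mortality columns are built. A virion payload at or
above the cell quota is rejected as unphysical (a single virion carries
well under 1% of cellular carbon). Burst sizes mix different measurement
types (infective units, particles, genome copies) in the literature; B is a
single configured number per lineage and this caveat is inherited. Carbon
quotas per cell are inputs with documented placeholder defaults (50 and
150 fg C for Prochlorococcus and Synechococcus).

Carbon converts to N and P through host elemental ratios (208 C:P and
6.4 N:P for Prochlorococcus; 130.7 C:P and 7.6 N:P for Synechococcus).
Regime totals multiply the mean volumetric flux by regime area x mean
mixed-layer depth (unit-tagged; km^2 x m -> litres exactly). Bacterial
production converts leucine incorporation using 131.2 g mol^-1 leucine,
7.3% leucine in protein, and 0.86 g C per g protein (all exposed);
bacterial carbon demand divides by a growth efficiency of 0.15, and the
lysate is assumed fully assimilable (an assimilation-efficiency knob
exists). Budget fractions above 1 warn rather than clip.

## Synthetic data

The generator emulates a spring North Pacific survey as static parametric
surfaces plus noise — no dynamical host-virus feedback. Defaults encode the
study conditions: three cruises of 40 samples between 22-46° N; temperature
strictly decreasing (24 to ~11.5 °C) so the temperature-latitude map is
invertible; a logistic salinity drop placing the 34.6/33.0 thresholds near
36/40° N; logistic chlorophyll with the 0.2 mg m^-3 front near 37.7° N;
Prochlorococcus at 2.2e5 ml^-1 declining logistically near 12 °C with a
virus-associated dip in the hotspot band (deep, 90%, on one cruise to mirror
the observed inter-annual contrast); Synechococcus peaking in the transition
zone; and cyanophages as a log-linear T x Chl surface (quadruple
4.0, 0.08, -2.0, 0.1, giving a subtropical mean near 6e5 ml^-1) plus a
Gaussian-in-temperature hotspot bump (15.5 °C, sigma 1.5 °C, amplitude
1.5e6 ml^-1, i.e. a 3-10x enrichment). The bump is Gaussian in temperature,
not latitude, because the hotspot is temperature-anchored across cruises.

Abundance noise is multiplicative lognormal (sd 0.15 in log10) with a shared
"biomass anomaly" component (sd 0.09) between hosts and phage that produces
the positive phage-host co-variation expected where viruses are
host-limited. The infected fraction follows a steep saturating (Hill) link
of true phage abundance (I_max 0.12, half-saturation 1.3e6 ml^-1, exponent
3.5): the steepness is a fixture choice, not an inference — it encodes the
positive feedback between infection and virus production needed for sub-1%
subtropical infection to coexist with ~9% hotspot infection at a 3-10x
abundance contrast. Polony counts are Poisson with efficiency thinning
absorbed into the rate; CTD profiles are mixed layers of constant density
with a linear pycnocline below.

What the generator does **not** emulate: advection and mixing, seasonal
migration of the front, lineage-specific infection kinetics, grazing, or
any feedback of mortality on abundances (the Prochlorococcus dip is imposed,
not emergent). Passing tests therefore demonstrate that the estimators
recover known structure under realistic noise — not that the ecological
story is correct in real data.

## Problem sizes and determinism

Statistical checks use: 500 simulated surveys (n = 87) for coefficient
recovery and 10^4 samples for RMSE convergence; 200 train/test splits for
model selection (held-out n = 500 so the ranking reflects expected, not
sampling, error); 2,000 new observations for interval coverage; 500
two-replicate Poisson assays (about 450 expected counts each) for bootstrap
coverage; 20 seeds of 2,000 samples for hotspot edge recovery, with the
analytic curvature-peak locations of the boxcar-smoothed Gaussian as oracle.
These sizes keep the full suite under a couple of minutes while leaving the
pass criteria statistically comfortable. All randomness flows through
`numpy.random.default_rng` with explicit seeds; identical seed and scenario
reproduce byte-identical CSV output.

## Known limitations

- Detection-efficiency defaults of 1.0 mean uncorrected output unless
  measured efficiencies are configured.
- The hotspot edge definition (flanking positive-curvature maxima) is one
  reading of an under-determined verbal definition; printed ranges from any
  particular field dataset depend on that dataset and cannot arbitrate the
  reading.
- The per-generation mortality formula ignores within-generation dynamics
  (constant hazard over the division interval).
- Regime budgets treat each regime as a single well-mixed box with one mean
  mixed-layer depth and area.
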