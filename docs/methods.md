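# Methods

`radsurvey` reconstructs terrestrial gamma-ray dose rates and radiological
hazard indices from three measurement channels — a shielded car-borne count
survey, fixed-point NaI(Tl) pulse-height spectra, and HPGe soil assays — and
compares the direct and soil-derived dose surfaces to quantify the
shielding/source effect of the built-up environment.  Because the field data
behind this class of national survey are rarely deposited, a synthetic
campaign generator with fully known truth stands in for the raw data; every
stage of the pipeline is tested as an inverse problem against that truth.

## Dose and hazard calculus

All closed-form quantities follow standard environmental-radiometry
conventions, with activities `A_U`, `A_Th`, `A_K` in Bq kg⁻¹ (²³⁸U series and
²³²Th series under secular equilibrium, measured through progeny photopeaks)
and absorbed dose rate in air `D` in nGy h⁻¹ at 1 m above ground:

* `D_soil = 0.43 A_U + 0.666 A_Th + 0.042 A_K`
* `OAED = D × 0.7 × 8760 × 0.2 × 10⁻⁶` mSv yr⁻¹ (outdoor), and the indoor
  counterpart with occupancy 0.8; the 0.7 Sv Gy⁻¹ conversion and the 0.2/0.8
  occupancy split are the UNSCEAR defaults.  By construction IAED/OAED = 4
  and IAED+OAED = D × 0.7 × 8760 × 10⁻⁶ exactly.
* `Ra_eq = A_U + 1.43 A_Th + 0.077 A_K` and
  `H_ex = A_U/370 + A_Th/259 + A_K/4810`, with `H_ex ≤ 1` the conventional
  acceptability limit.  Since (370, 259, 4810) ≈ 370/(1, 1.43, 0.077),
  `H_ex ≈ Ra_eq/370` to within 0.3% for any non-negative triplet.
* The ratio of difference `D_direct / D_soil` classifies a site's built-up
  environment: below 1 the artificial surfaces shield terrestrial gammas,
  above 1 the construction materials act as additional sources.

Internal arithmetic is never rounded; presentation rounding (doses to two
decimals, dose rates and Ra_eq to integers, ratios and H_ex to one decimal)
is applied only when printing report tables.

## Car-borne survey model

The reconstruction is multiplicative with no offset:
`D_air = C_in × SF_carbody × SF_asphalt × DCF`, with `C_in` the 30-s count
rate inside the car.  All three factors are fitted by through-origin least
squares on paired measurements (outside-vs-inside counts for the car body,
bare-vs-asphalt counts for the roadbed, unfolded dose-vs-outside counts for
the DCF); a through-origin form is forced by the multiplicative model — an
intercept fit is available as a diagnostic but is never used in the
reconstruction, and the DCF fit likewise defaults to through-origin.  The
slope uncertainty comes from the residual variance.  Factors are
campaign-keyed: the default truth assigns car-body factors 2.01 (northern
campaign) and 1.71 (southern), asphalt factors 0.96 (north; the roadbed can
itself be a source, so values below 1 are legal) and 1.37 (south), and a
DCF of 0.14 nGy h⁻¹ per cps.  No speed filtering or outlier rejection is
applied.

## Forward spectral model and response-matrix unfolding

The NaI(Tl) detector response is a *declared simplification* — the package's
self-consistent physics, not a calibrated detector Monte Carlo:

* Gaussian full-energy peak at each line energy with
  `FWHM(E) = r·√(0.662·E)`, `r` = 7.5% at 0.662 MeV by default;
* a flat per-line Compton continuum from zero to the line's Compton edge
  carrying 30% of the peak counts;
* full-energy-peak sensitivity `ε(E) = ε₀ (0.662/E)^0.4`;
* a flat cosmic floor across all channels (the measured cosmic secondary
  spectrum is soft but slowly varying over 0–3.2 MeV; an
  energy-independent per-channel floor is the simplest shape consistent
  with estimating it from a single high-energy window).

The line library covers the gammas a 3-in NaI(Tl) resolves on soil spectra
(six ²³⁸U-series lines, four ²³²Th-series lines, ⁴⁰K at 1.464 MeV) with
nominal emission probabilities.  Because the *same* forward model generates
synthetic spectra and builds the 22×22 response matrix, the unfolding
problem has an exact noise-free solution and round-trip correctness is
testable to solver precision.

Analysis chain per spectrum: two-point energy calibration on the ⁴⁰K
(1.464 MeV) and ²⁰⁸Tl (2.615 MeV) photopeaks — peaks searched within ±8% of
nominal after moving-average smoothing, centroids taken as the
floor-subtracted weighted mean over the contiguous run above half maximum
(a 5-point quadratic vertex was evaluated and rejected: for NaI peaks
10+ channels wide its curvature estimate is noise-dominated) — then cosmic
subtraction from the 3.0–3.2 MeV window mean (clamped at zero), rebinning
onto 22 unequal bins over 0–3.2 MeV, and non-negative least squares
(`scipy.optimize.nnls`) against the response matrix.  NNLS is the natural
solver for a non-negative incident flux; ill-conditioning beyond 10⁸ raises
a warning (the default matrix's condition number is ≈8).

Bin edges: the four flagged peak windows sit at 1.39–1.54 (⁴⁰K), 1.69–1.84
and 2.10–2.31 (²¹⁴Bi), 2.51–2.72 MeV (²⁰⁸Tl); the remaining edges are placed
so that every library line falls in a bin of its own (a log-uniform split
of the remainder was considered and rejected because it merges two U-series
lines into one bin and destroys line-level identifiability).  Bin
representative energies equal the contained line energy where one exists,
else the midpoint.

Coefficient tables are derived from the forward model rather than from a
transport calculation: flux-per-unit-activity of series *s* in bin *j* is
the summed emission probability of its lines there, and the per-bin
flux-to-dose coefficients are proportional to bin energy within each
series' support, normalised so that one Bq kg⁻¹ of each series carries
exactly its soil-dose coefficient (0.43 / 0.666 / 0.042 nGy h⁻¹).  This
makes `dose_from_flux` and `D_soil` consistent by construction — the
designed behaviour, since the soil-dose formula is the package's dose
ground truth.  Users may override both tables with published transport
coefficients.  ⁴⁰K activity is read from the 1.464 MeV window, the Th series
from the 2.615 MeV window, and the U series combines the 1.765 and
2.205 MeV windows by inverse-variance weights under Poisson flux statistics
(weights ∝ coefficient²/flux; an equal-weight option is retained).  Dose
can be integrated over all 22 bins (default) or the four peak windows only.

## HPGe soil assay

Absolute-method activities: `A = N_net / (ε(E)·p_γ·t·m)` with net peak area
`N_net` over a linear baseline through the mean of 3 flanking channels each
side of a ±3σ ROI, full-energy-peak efficiency `ε` interpolated log-log on a
nine-nuclide certified volume-source calibration (88–1836 keV; mild
extrapolation warned, queries far outside rejected), emission probability
`p_γ`, live time `t` (30 000 s default) and sample mass `m` (0.13 kg U-8
geometry default).  Peaks: ²¹⁴Pb 351.9 keV, ²¹⁴Bi 609.3 keV (combined into
the ²³⁸U series by inverse-variance weighting), ²²⁸Ac 911.2 keV (²³²Th
series alone, per the assay peak list), ⁴⁰K 1460.8 keV.  Uncertainties
propagate Poisson counting through the baseline subtraction plus the
efficiency-scale uncertainty in quadrature; negative net areas are clamped
at zero with a warning.  The shipped efficiency curve is a synthetic
stand-in (power law anchored at 5% at 661.7 keV, ±1.2% relative
uncertainty) labelled as such; no coincidence-summing or self-absorption
corrections are applied.

## Synthetic campaign generator

The generator's defaults are the study conditions, not tuning knobs:

* Two regions with soil-activity means ± SDs (Bq kg⁻¹) of 39±25 / 63±33 /
  551±259 (north) and 32±19 / 54±33 / 551±389 (south), split 178:284 over
  462 sites.  Activities are drawn from zero-truncated normals whose
  *truncated* mean and SD equal the configured values: the parent normal is
  solved by moment matching (`scipy.optimize.root` on the truncated-normal
  moments), feasible whenever SD/mean < ≈0.756 — true for every configured
  region.  Plain truncation would inflate the high-CV means by more than
  two standard errors and break mean-recovery guarantees.
* Site truth: `D_soil` from the soil-dose formula; an optional built-up
  multiplier (0.5–2.1, a shielding draw below 1 with configurable
  probability) perturbs the *direct-measurement* truth only, and scales the
  activities seen by the in-field NaI detector accordingly.
* Paired 30-s counts: outside = `D_direct/DCF`, inside = outside/SF_carbody,
  asphalt = outside (the outside measurement is made on asphalt),
  bare = asphalt × SF_asphalt; Poisson on counts, then divided by live time.
* Tracks: one record per 30-s interval along a route; the local truth is the
  nearest site's direct dose rate and the inside-car expectation is
  `D/(DCF·SF_carbody·SF_asphalt)`.
* HPGe spectra: the four assay peaks (2 keV FWHM, 1 keV/channel) on a flat
  0.002 cps/channel baseline, expected areas = activity × p_γ × ε × t × m.
* Everything is driven by `numpy.random.Generator`; a fixed seed gives
  bit-identical campaigns.

What the generator does **not** emulate — and hence what green tests do not
establish about real surveys: angular detector response, soil moisture and
radon-progeny washout, spectral drift and dead time, road-network geometry,
real spatial autocorrelation of geology (site activities are independent
draws), and any difference between the true detector response and the
package's simplified forward model.  Parameter-recovery results demonstrate
the *pipeline's* correctness as an inverse of the declared forward model,
not field accuracy.

## Gridding

Dose-rate maps use minimum-curvature interpolation: data are snapped to
their nearest cell (cell duplicates averaged) and clamped, and the free
cells minimise the discrete thin-plate bending energy
`Σ (z_xx² + 2 z_xy² + z_yy²)`, whose stationarity condition is the discrete
biharmonic equation away from the data.  The energy's null space is the
affine surfaces, so three non-collinear data determine the solution and any
plane through on-node data is reproduced exactly; fewer than three data
yield the degenerate constant surface (explicit opt-in).  The clamped
normal equations are solved by sparse direct factorisation by default, with
a conjugate-gradient option on the identical system (a damped-Jacobi
relaxation of the biharmonic stencil was evaluated and rejected: its
spectral radius approaches 1 as h⁴, making convergence impractical on
survey-scale grids).  Cells beyond a Chebyshev radius (default 3 cells) of
any datum are masked.  Default spacing 0.1° (0.25° in the pipeline report
stage, sized to track density); small survey extents are treated
equirectangularly, with no map projection.

## Pipeline, sizes and numerical choices

The orchestrated run is simulate → unfold → calibrate → carborne → soil →
assess → report, configured by one YAML file in which every survey constant
is inspectable; the manifest records a hash of the science-relevant config,
the seed and the package version, and identical config + seed reproduce all
outputs byte-for-byte.  Energy calibration is fitted once per campaign on a
long (1800 s) reference spectrum at the regional mean activity and reused
for every site spectrum — field practice, and robust to individual sites
whose Th content is too low to show a usable ²⁰⁸Tl calibration peak.

Default problem sizes — 462 fixed-point sites, 1000 track records, 10-min
NaI and 30 000 s HPGe live times — mirror the study design and complete in
a few seconds; they are the sizes at which the acceptance properties
(calibration factors within 5%, regional activity means within 2 SE,
noise-free round trips within 1%) are asserted.

Degenerate-input conventions: zero spectra unfold to zero flux; zero flux
maps to zero activities and dose; empty uncertainty lists combine to zero;
a single-record region reports an SD sentinel (NaN, printed as a dash);
`H_ex` flags strictly above 1 (the limit itself is acceptable); cosmic
subtraction clamps at zero per channel.

## Known limitations

The response matrix, flux coefficients and HPGe efficiency curve are all
self-consistent synthetic physics, so absolute accuracy against a real
detector is out of scope.  The ²⁰⁸Tl unfolding window is taken as
2.51–2.72 MeV and the ²²⁸Ac line as 911 keV (resolving internal
inconsistencies in the source conventions).  The Th series assay uses
²²⁸Ac alone.  Secular equilibrium is assumed throughout; no radon pathway,
no internal dosimetry, and no cartographic rendering.
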