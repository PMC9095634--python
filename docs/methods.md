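# Methods

## Physical model

The pipeline treats the dusty marine atmosphere as a two-component aerosol
(nonspherical dust, spherical everything-else) observed by a polarization
lidar, and closes a column mass budget over a lat/lon grid.

**Depolarization partition.** Backscatter mixes linearly in the co-polar
channel, so the composite particulate depolarization ratio (PDR) of a
mixture of dust (β_d, δ_d) and non-dust (β_nd, δ_nd) is

    δ = (β_d δ_d/(1+δ_d) + β_nd δ_nd/(1+δ_nd)) / (β_d/(1+δ_d) + β_nd/(1+δ_nd))

and its exact inverse gives the dust backscatter fraction

    f_d = (δ − δ_nd)(1 + δ_d) / ((δ_d − δ_nd)(1 + δ)),  clipped to [0, 1].

Values between the endmembers ("mixed dust") are covered continuously by the
same formula; beyond the endmembers the clip saturates at pure dust or pure
non-dust. The partition is monotone in δ and the clip preserves that.

**Mass chain.** DExt = S_d β_dust (S_d the dust lidar ratio), DMC =
DExt/DMEE, DMF = DMC·wind per layer; the column flux sums layers whose bin
midpoint lies below z_top. Every mass quantity is exactly linear in 1/DMEE;
dust loss frequency DLF = (DDF per area per day)/loading is the one quantity
from which DMEE cancels, and lifetime is its reciprocal.

**Flux-divergence deposition.** Assuming no loss through the column top and
no surface source over the ocean, deposition in a cell is the net
convergence of the column-integrated horizontal flux. Cell-face fluxes are
the arithmetic mean of the two adjacent cell-centre column fluxes times the
spherical face length (meridional faces Δφ·R·π/180; zonal faces
Δλ·R·π/180·cos φ, R = 6.371×10⁶ m); at the domain edge the face takes the
boundary cell's own value (one-sided). Because interior faces telescope, the
signed domain total equals boundary inflow − outflow to rounding — the
discrete scheme conserves mass by construction. Raw negative cells are
unphysical under the no-source assumption; they are flagged, excluded from
deposition totals (treated as zero), and retained in `raw_divergence` so the
signed bookkeeping stays available. Both totals are reported because the
right bookkeeping for climatological sums is genuinely ambiguous.

## Parameter defaults

| parameter | default | unit | meaning |
|---|---|---|---|
| δ_d | 0.25 | – | dust PDR endmember, mean of the typical 0.2–0.3 range |
| δ_nd | 0.045 | – | non-dust PDR endmember, mean of 0.02–0.07 |
| S_d | 44 | sr | characteristic 532 nm dust lidar ratio |
| S_nd | 25 | sr | marine-aerosol lidar ratio (synthetic generator only) |
| CAD window | [−100, −90] | – | confident-aerosol screening, applied per level |
| DMEE | 0.37 | m² g⁻¹ | dust mass extinction efficiency, altitude/humidity independent |
| z_top | 7000 | m | column top; dust above is negligible |
| grid | 2°×2°, 0–40°N, 30–76°E | – | study domain; 1 km altitude bins to 7 km |
| regions | 10–20°N; 50–58/58–66/66–74°E | – | WAS/CAS/EAS sectors |
| tiers | p < 0.10/0.05/0.01 | – | 90/95/99% significance from two-sided MK p |

The WAS/CAS/EAS longitude splits are a convention of this package (the band
and its three-way split are standard; exact boundaries are configurable and
carry no observational authority). Regional means are area-weighted with
cos(latitude); on a 2° grid in the 10–20°N band the weighting shifts means
by well under a percent but keeps sub-region recombination exact.

## Statistics

Trends are OLS slopes on the year index with the first year as base 0 (not
Theil–Sen, which is available as `sens_slope`); significance comes from the
classic non-seasonal Mann–Kendall test with tie-corrected variance,
±1 continuity correction and the normal approximation for the two-sided
p-value. For n = 14 annual values the normal approximation is accurate to
within about half a point of type-I error at the 5% level, which the test
suite measures directly (10⁴ white-noise series). No autocorrelation
correction and no cross-cell multiple-testing control are applied — per-cell
tiers are descriptive, as is conventional for trend maps. Pearson
correlations use pairwise-complete years and a t-based two-sided p; records
of different length (e.g. a nitrate series ending earlier) are handled by
per-variable year masks.

## Synthetic data: what it emulates and what it does not

* **Granules** reproduce the geometry (60 m levels to 10 km, profile
  lat/lon/time, CAD scores) and the two-component optics of nighttime
  level-2 aerosol profiles. Noise is mean-one multiplicative log-normal on
  backscatter and additive Gaussian on PDR clipped to [0, 0.8]; the −s²/2
  log-shift keeps noisy cell means unbiased so Monte-Carlo aggregation tests
  measure sampling error, not a noise-model artifact. Not emulated: clouds,
  daytime solar background, multiple scattering, attenuation, aerosol types
  beyond the two components. Passing retrieval tests therefore demonstrates
  correctness of the screening/partition/gridding algebra, not robustness to
  real retrieval error sources.
* **Plumes** prescribe concentration and winds on the grid and compute the
  deposition sink from exact face fluxes of the analytic fields — the
  finite-volume form of the analytic divergence — so mass closure holds to
  64-bit rounding and estimator error is attributable to the centred-face
  discretization alone. The Gaussian plume centres on the upwind domain edge
  so the in-domain flux decays monotonically and the sink is everywhere
  positive (a domain-centred Gaussian would have a signed divergence and
  trigger the negative-value exclusion, which the convergence oracle must
  avoid). Not emulated: time-varying winds, wind–concentration covariance
  (about 5% uncertainty in real monthly-mean products), vertical transport.
* **Series** are linear trends plus equicorrelated Gaussian noise via an
  eigen-factor construction, so any pair of variables attains the target
  correlation in expectation (the eigen route, unlike Cholesky, tolerates
  the ρ = 1 boundary). They emulate interannual regional anomalies only —
  no seasonality, no autocorrelation.

## Numerical choices

* Per-profile column optical depth uses the trapezoid rule on the native
  levels (≤ 0.5% error at 60 m spacing for kilometre-scale layers); gridded
  DOD uses the piecewise-constant sum over altitude bins, which makes the
  cell DOD exactly the mean of per-profile binned DODs (linearity).
* Missing data are NaN throughout; empty cells stay missing, never zero.
  For divergence, missing column fluxes are treated as zero flux — the
  conservative choice for a mass budget, at the cost of spurious divergence
  at the edge of sampled areas (visible when granules cover only part of the
  domain).
* Winds must be co-registered to the dust grid; profiles on other vertical
  coordinates are expected to be linearly interpolated in altitude first.
* Deposition convergence was verified on the analytic plume at 2°→1°→0.5°:
  total-deposition error 0.39% → 0.10% → 0.03% (second-order interior
  scheme, first-order one-sided boundary, boundary-dominated error).
* All generators take integer seeds; identical seeds give bit-identical
  outputs, and the pipeline run is deterministic end to end.

## Problem sizes

Tests and the acceptance script run on the full 2° study domain (20×23
cells, 7 altitude bins), granules of 30–200 profiles × 168 levels, 10⁴
Monte-Carlo replicates for the Mann–Kendall calibration and 2×10⁴-year
series for correlation recovery — sizes at which every statistical check
has comfortable resolution while the whole suite completes in seconds.

## Known limitations

* The flux-divergence method cannot separate wet from dry deposition and
  reports only the collective loss; negative-divergence cells are excluded
  rather than redistributed, so clipped totals are not strictly
  conservative (the signed total is also reported).
* The published basin-scale magnitudes (seasonal fluxes of tens of Tg yr⁻¹,
  multi-year trend maps) require the real multi-year satellite record;
  nothing at desk scale validates those magnitudes, only the estimators
  that produce them.
* DMEE is a scalar; real mass extinction efficiency varies regionally by
  tens of percent, which is why the sweep machinery treats it as the
  leading uncertainty.
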