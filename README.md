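# dustflux

Satellite-lidar quantification of mineral dust transport and deposition over
an oceanic domain, and of its association with marine productivity — built
around the Arabian Sea, where dust advected from the Middle East and Eastern
Africa fertilizes surface waters.

`dustflux` implements the full chain from depolarization-lidar profiles to
biogeochemical statistics:

1. **Dust separation.** Each particulate backscatter profile β_p(z) at 532 nm
   is screened with the cloud–aerosol discrimination score (confident aerosol
   only, CAD ∈ [−100, −90]) and split into dust and non-dust components from
   the particulate depolarization ratio δ using the two-component partition
   f_d = (δ − δ_nd)(1 + δ_d) / ((δ_d − δ_nd)(1 + δ)), with endmembers
   δ_d = 0.25 (dust) and δ_nd = 0.045 (spherical aerosol), clipped to [0, 1].
2. **Extinction and optical depth.** Dust extinction DExt = S_d · β_dust with
   the characteristic dust lidar ratio S_d = 44 sr; column dust optical depth
   DOD = ∫ DExt dz up to 7 km; profiles aggregated monthly to a 2° × 2° grid.
3. **Mass flux.** Dust mass concentration DMC = DExt / DMEE with mass
   extinction efficiency DMEE = 0.37 m² g⁻¹; zonal/meridional dust mass flux
   profiles DMF = DMC · (u, v) from monthly wind profiles, column-integrated
   below 7 km, with boundary-transect accounting in Tg yr⁻¹.
4. **Deposition.** Dust deposition flux DDF per cell as the convergence of the
   column-integrated horizontal fluxes (flux-divergence method, no loss
   through the column top); unphysical negative cells flagged and excluded.
   Dust loss frequency DLF = DDF / loading (day⁻¹, DMEE cancels) and lifetime
   DLT = 1/DLF (days).
5. **Statistics.** Gridded and regional OLS trends with Mann–Kendall
   significance tiers (90/95/99%), climatological anomalies, Pearson
   correlations of NPP against DDF and nitrate anomalies over the
   western/central/eastern sectors of the 10–20°N band, and DMEE /
   lidar-ratio sensitivity sweeps.

Every stage is testable offline: `dustflux.synthetic` generates lidar-like
granules that the partition inverts exactly, advected plumes whose deposition
sink is known in closed form (exact mass closure), and regional series with
prescribed trends and cross-correlations.

## Worked example

```python
import dustflux as dfx

# a synthetic nighttime granule: one dust layer (0.5-3.5 km, 0.1 km^-1)
# over marine background, 20% cloud-contaminated profiles
granule = dfx.make_granule(dfx.GranuleSpec(n_profiles=100,
                                           cad_outlier_fraction=0.2, seed=7))
screened, report = dfx.screen(granule)
print(report["profiles_retained"])          # 80

grid = dfx.GridDef()                        # 0-40N, 30-76E, 2 deg, 1 km bins
dust = dfx.grid_monthly(screened, grid)
flux = dfx.flux_profiles(dust, dfx.make_winds(grid, u0=5.0))
dep = dfx.divergence_deposition(flux, grid=grid)

print(round(dfx.dust_fraction(0.14), 4))    # 0.5081  (mixed-dust PDR)
print(dfx.symmetric_percent_diff(1/0.37, 1/0.5))  # 29.885...
```

`dust_fraction(0.14) = 0.5081` says a level with depolarization 0.14 carries
half dust, half spherical aerosol by backscatter; `29.885` is the symmetric
percent change of any deposition total when DMEE moves from 0.37 to
0.5 m² g⁻¹, since the whole mass pipeline is linear in 1/DMEE.

The same stages are available as a shell tool:

```bash
dustflux simulate --seed 1 --out granule.nc
dustflux retrieve --granules granule.nc --out grid.nc
dustflux flux --grid grid.nc --winds winds.nc --out flux.nc
dustflux deposit --flux flux.nc --out dep.nc
dustflux run --seed 1 --out-dir out/          # full pipeline
```

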