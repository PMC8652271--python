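"""Recover the basalward-return degree γ from nuclear trajectories.

Generates interkinetic nuclear tracks for 50 cells of a 50 µm-thick layer
(γ = 0.9, 2 µm position noise, 24 h of half-hourly observations) and
estimates γ from the maximal basal excursion of each nucleus.
"""

from epibend import TrackSpec, estimate_gamma, make_nuclear_tracks

spec = TrackSpec(gamma=0.9, n_cells=50, noise_sd=2.0, duration_h=24.0, interval_h=0.5)
observations, table, divisions = make_nuclear_tracks(spec, seed=7)

est = estimate_gamma(table, spec.thickness)
print(f"observations: {len(table)} rows, {table['id'].nunique()} cells, "
      f"{len(divisions)} divisions logged")
print(f"true gamma      = {spec.gamma}")
print(f"estimated gamma = {est:.3f}")
print("The estimate is the mean over cells of max(distance from the luminal "
      "edge)/thickness; the depth law peaks at d = gamma mid-cycle, so the "
      "two should agree within ~10% at this noise level.")
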