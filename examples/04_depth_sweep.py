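"""Peritumoral immune density as a function of stromal band depth.

Sweeps the band depth from 5 to 200 um and reports CD8 density in the
K17+ vs K17- band.  When exclusion acts near the tumor border, the
density contrast is strongest at shallow depths and washes out as the
band widens — the rationale for analyzing at 25 um.
"""

from immune_topo import Role, SyntheticConfig, depth_sweep, simulate_case

cfg = SyntheticConfig(
    image_hw_px=(900, 900), resolution_um_per_px=1.0,
    n_nests=5, nest_radius_um=(70.0, 12.0),
    base_intensity={Role.CD4: 0.0, Role.CD8: 600.0, Role.CD16: 0.0, Role.CD163: 0.0},
    zone_modulation={Role.CD4: 1.0, Role.CD8: 0.2, Role.CD16: 1.0, Role.CD163: 1.0},
    band_depth_um=200.0,  # generator places cells out to 200 um
    seed=11,
)
mask, _ = simulate_case(cfg)
profile = depth_sweep(mask, depths_um=(5.0, 10.0, 25.0, 50.0, 100.0, 150.0, 200.0))
cd8 = profile[profile["class"] == "CD8"].pivot(
    index="depth_um", columns="marker", values="density_per_mm2"
)
cd8["ratio K17-/K17+"] = cd8["K17-"] / cd8["K17+"]
print("CD8 peritumoral density (cells/mm^2) by band depth:")
print(cd8.round(1).to_string())
print("\nband areas grow with depth; the K17-/K17+ ratio stays near the"
      "\ngenerator's 5x contrast because exclusion here spans the whole band.")
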