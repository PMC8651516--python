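"""GP imaging of a phase-separated vesicle from 32-channel spectral data.

Renders the equatorial cross-section of a vesicle with an ordered (Lo)
and a disordered (Ld) phase, computes the per-pixel generalized
polarization GP = (Ib - Ir)/(Ib + Ir) at 575/640 nm, and reports the
packing contrast dGP = GP(Lo) - GP(Ld).
"""

import numpy as np

import gpfcs as g

cfg = g.VesicleImageConfig(
    phases=[
        g.VesiclePhase(0.0, np.pi, 300.0, gp_true=0.5),      # Lo half
        g.VesiclePhase(np.pi, 2 * np.pi, 300.0, gp_true=-0.1),  # Ld half
    ],
    background=0.0,
    seed=7,
)
stack = g.simulate_vesicle_stack(cfg)
img = g.gp_from_spectral(stack, threshold=500.0)
lo_mask, ld_mask = g.sector_masks(cfg)

for name, phase, mask in [("Lo", cfg.phases[0], lo_mask), ("Ld", cfg.phases[1], ld_mask)]:
    vals = img.gp[mask & img.mask]
    print(f"{name}: mean GP = {vals.mean():+.3f} "
          f"(analytic {g.analytic_sector_gp(phase, cfg):+.3f}, {vals.size} px)")
print(f"dGP (Lo - Ld) = {g.delta_gp(img, lo_mask, ld_mask):.3f}")

spec, peak = g.mean_spectrum(stack, ld_mask & (stack.total_intensity > 500))
print(f"Ld emission maximum: {peak:.0f} nm (red-shifted relative to Lo)")
# Sector means match the generator's analytic channel-integral GP within
# counting noise; the positive dGP is the dye's packing resolution.
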