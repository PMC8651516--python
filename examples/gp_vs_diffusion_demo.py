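"""Packing vs dynamics: the full pipeline on three membrane compositions.

Tightly packed (high-GP) membranes slow diffusion.  The demo simulates
FCS traces for three compositions with packing-dependent D, measures GP
and D from the same photon streams, and reports their rank correlation,
plus a spot-size calibration and a vesicle GP image.
"""

from pathlib import Path

from gpfcs.cli import run_demo

out = Path("scratch_demo_out")
df = run_demo(out, seed=1)
print(df[["composition", "gp", "d_um2_s", "tau_d_ms", "alpha"]].to_string(index=False))
print(f"\nSpearman rank correlation GP vs D: {df['spearman_gp_vs_d'].iloc[0]:.2f}")
print(f"outputs written under {out}/")
# The strictly negative rank correlation is the computational twin of the
# packing-dynamics anticorrelation seen in STED-FCS experiments.
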