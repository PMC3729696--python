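"""Generate a synthetic trajectory and measure its twist observables.

A 12-chain protofilament is perturbed with a cumulative 2 deg/monomer
sheet twist, the C-terminal hinge and thermal noise.  The script prints
the per-frame total twist (the V18/V24 dihedral between the second and
penultimate chains), the adjacent-monomer angle and the RMSD to the
starting structure -- the observables a fibril stability study tabulates
per system.
"""

from crossbeta import (
    PerturbationParams,
    build_protofilament,
    estimate_twist_rate,
    make_synthetic_ensemble,
    make_template_chain,
    rmsd_series,
    twist_series,
)
from crossbeta.geometry import adjacent_angle_series

asm = build_protofilament(make_template_chain(), n=12)
pert = PerturbationParams(seed=42, twist_per_monomer=2.0, hinge_bend=30.0,
                          noise_sigma=0.2, n_frames=11, frame_dt=5.0)
ens = make_synthetic_ensemble(asm, pert)

tw = twist_series(ens, window_ps=15.0)
adj = adjacent_angle_series(ens, window_ps=15.0)
rms = rmsd_series(ens)

print("frame  time/ps  twist/deg  adj-angle/deg  rmsd/A")
for k in range(ens.n_frames):
    print(f"{k:5d}  {ens.times[k]:7.1f}  {tw.per_frame[k]:9.2f}  "
          f"{adj.per_frame[k]:13.2f}  {rms.per_frame[k]:6.2f}")

print(f"\ntrailing-window means: twist {tw.mean_last_window:.2f} deg, "
      f"adjacent angle {adj.mean_last_window:.2f} deg")
print(f"recovered twist rate {estimate_twist_rate(ens):.2f} deg/monomer "
      f"(imposed {pert.twist_per_monomer})")
print("the total twist grows with stack size while the per-monomer angle "
      "stays near the imposed rate")
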