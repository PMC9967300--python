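"""Per-frame dimer geometry and coupling on a synthetic trajectory.

Generates a 2,000-frame fluctuating H-aggregate (mean separation 0.6 nm,
sd 0.1 nm, 10 degree orientation jitter), runs the full analysis
pipeline, and prints the time-series and GROMOS ensemble summaries.
"""

from sqdimer import analyze_trajectory
from sqdimer.synthetic import GeneratorConfig, generate_dimer_trajectory

cfg = GeneratorConfig(n_frames=2000, seed=42)
traj, rmap, sel, truth = generate_dimer_trajectory(cfg)
print(f"generated {traj.n_frames} frames, {traj.n_atoms} atoms "
      f"({cfg.packing} packing, mean R {cfg.mean_R} nm)")

result = analyze_trajectory(traj, rmap, sel)
print(f"analysed {result.n_frames_analyzed} frames after equilibration skip\n")
print(result.summaries.to_string(index=False, float_format=lambda x: f"{x:9.4f}"))
print()
print("R is the dye-dye centre distance (nm); kappa^2 near 1 and positive")
print("kappa' confirm a parallel-packed H-aggregate; J_mn is the exciton")
print("hopping parameter in cm^-1. The GROMOS row evaluates the metrics on")
print("cluster-average geometries, so its spread reflects distinct")
print("conformers rather than frame-to-frame noise.")
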