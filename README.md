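# sqdimer

Trajectory analysis of excitonically coupled squaraine (SQ) dye dimers
templated by DNA Holliday junctions.

DNA scaffolds can hold two dyes close enough for their optical
transitions to couple, forming H- (face-to-face) or J- (head-to-tail)
aggregates whose spectra shift relative to the monomer. Molecular
dynamics gives per-frame dye geometries; this package turns such
multi-frame coordinates into the quantities that characterise the
dimer:

* **Exciton hopping parameter** `J_mn` in the extended dipole
  approximation. Each transition dipole is replaced by charges
  ±q = μ/l at the π-conjugation-bridge termini r, s (the terminal
  benzene-ring centres, bridge length l), giving

  `J_mn = J_o (1/|r1−r2| − 1/|r1−s2| − 1/|s1−r2| + 1/|s1−s2|)`,
  `J_o = μ_m μ_n / (4π ε0 n² l_m l_n)`,

  with n the medium's refractive index. A point-dipole reference
  (the l → 0 limit) is provided alongside.
* **Orientation metrics** per frame: centre–centre distance R, oblique
  angle α = arccos(μ̂_m·μ̂_n), slip angles θ_i = arccos(R̂·μ̂_i), the
  orientation factor κ² = (μ̂_m·μ̂_n − 3(μ̂_m·R̂)(μ̂_n·R̂))² ∈ [0, 4]
  (≈1 H-aggregate, ≈4 J-aggregate), and the signed packing factor
  κ′ = μ̂_m·μ̂_n distinguishing parallel (AA) from antiparallel (AB)
  stacking.
* **Residue contact maps**: probability, over frames, that two residue
  centres of mass lie within 1.2 nm.
* **GROMOS clustering** of the dye atoms (greedy neighbour-count on the
  pairwise RMSD matrix, 0.05 nm cutoff, clusters >5 % of frames
  retained) and **ensemble summaries** — time-series mean ± sd next to
  per-cluster-geometry values.
* A **synthetic trajectory generator** (rigid template dyes, truncated
  normal separations, orientation jitter, planted conformers, mock
  four-arm junction scaffold) so the whole pipeline is testable with
  known ground truth.

Transition-dipole magnitudes for the packaged SQ variants (TDDFT
values): SQ-H2 12.99 D, SQ-Cl2 13.41 D, SQ-Me2 13.73 D.

## Worked example

```python
from sqdimer import analyze_trajectory
from sqdimer.synthetic import GeneratorConfig, generate_dimer_trajectory

cfg = GeneratorConfig(n_frames=2000, seed=42)   # AA H-aggregate, R ~ N(0.6, 0.1) nm
traj, rmap, sel, truth = generate_dimer_trajectory(cfg)
result = analyze_trajectory(traj, rmap, sel)
print(result.summaries.to_string(index=False))
```

prints (abridged):

```
     method      metric      mean        sd
time_series           R    0.6024    0.1003
time_series    kappa_sq    0.9577    0.0664
time_series kappa_prime    0.9792    0.0289
time_series        J_mn  526.9129  165.7949
     gromos           R    0.6005    0.0885
     gromos    kappa_sq    0.9929    0.0110
     gromos        J_mn  510.7360  112.6980
```

R recovers the planted 0.6 ± 0.1 nm separation; κ² near 1 with positive
κ′ confirms a parallel-packed H-aggregate; J_mn ≈ 500 cm⁻¹ is the
resulting hopping strength (refractive index 1.33). The GROMOS rows
evaluate the same metrics on cluster-average geometries, so their
spread reflects distinct conformers rather than frame noise.

The `examples/` directory has one short script per capability
(coupling formulas, trajectory metrics, contact maps, clustering);
each prints what it computes and what the numbers mean. A thin CLI
wraps the same pipeline:

```sh
sqdimer simulate --n-frames 500 --seed 1 --out run/
sqdimer analyze --traj run/trajectory.pdb --residue-map run/residue_map.yaml \
    --selections run/selections.yaml --out run/analysis/
sqdimer contact-map --traj run/trajectory.pdb --residue-map run/residue_map.yaml \
    --selections run/selections.yaml --out run/contacts/
```

Every figure the CLI renders has a CSV twin, and each run writes a
manifest (config echo, version, input checksums) for exact
reproduction.

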