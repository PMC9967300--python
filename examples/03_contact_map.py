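"""Residue contact maps: junction-core vs displaced dimer placement.

Builds the mock four-arm junction scaffold around the synthetic dimer in
both placements and compares how many scaffold residues each dye
contacts at a 1.2 nm centre-of-mass cutoff — the transverse-like
placement sits in the junction core and touches every arm, the
adjacent-like placement is pushed 1.5 nm out along one arm.
"""

from sqdimer import contact_probability, dye_contact_summary
from sqdimer.synthetic import GeneratorConfig, generate_dimer_trajectory, generate_mock_hj

for placement, nickname in (("junction_core", "transverse-like"),
                            ("displaced", "adjacent-like")):
    cfg = GeneratorConfig(n_frames=300, seed=7, placement=placement)
    traj, rmap, sel, _ = generate_dimer_trajectory(cfg)
    traj, rmap = generate_mock_hj(cfg, traj, rmap)
    cm = contact_probability(traj, rmap, cutoff=1.2)
    summary = dye_contact_summary(cm, rmap, threshold=0.5)
    print(f"{placement} ({nickname}):")
    print(f"  dye-dye contact probability: {cm.probability(1, 2):.2f}")
    for row in summary.itertuples():
        strands = sorted(set(row.contact_strands))
        print(f"  dye residue {row.dye_residue}: {row.n_contacts} scaffold "
              f"residues in contact >= 50% of frames (strands {strands})")
    print()

print("The dyes stay in permanent mutual contact in both placements; only")
print("their interaction with the scaffold differs — more surrounding")
print("residues within reach at the junction core, fewer when displaced.")
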