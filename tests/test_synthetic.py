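import numpy as np
import pytest
from scipy.stats import kstest, truncnorm

from sqdimer import DyeParameters, contact_probability, dimer_geometry_series
from sqdimer.synthetic import (
    ConformerSpec,
    GeneratorConfig,
    MIN_SEPARATION_NM,
    build_template_dye,
    generate_dimer_trajectory,
    generate_mock_hj,
    parameter_recovery_report,
)


class TestTemplateDye:
    def test_extraction_on_reference_pose(self, template, dye_params):
        from sqdimer import DyeSelection, Frame, SelectionConfig, extract_extended_dipole

        sel = SelectionConfig({
            "dye_m": DyeSelection(
                squarate_carbons=template.squarate,
                benzene_ring_far=template.ring_far,
                benzene_ring_near=template.ring_near,
                dye_residue_id=1,
            )
        })
        d = extract_extended_dipole(Frame(0, 0.0, template.coords), sel,
                                    DyeParameters({"dye_m": 12.99}), "dye_m")
        np.testing.assert_allclose(d.center, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(d.mu_hat, [1, 0, 0], atol=1e-12)
        assert d.length == pytest.approx(1.4)

    def test_ring_centres_equidistant_from_centre(self, template):
        far = template.coords[list(template.ring_far)].mean(axis=0)
        near = template.coords[list(template.ring_near)].mean(axis=0)
        assert np.linalg.norm(far) == pytest.approx(np.linalg.norm(near))

    def test_rigidity_under_generated_motion(self, template):
        cfg = GeneratorConfig(n_frames=5, seed=3, sd_R=0.1, orientation_jitter=15.0)
        traj, *_ = generate_dimer_trajectory(cfg)
        n = template.n_atoms
        ref = np.linalg.norm(
            template.coords[:, None, :] - template.coords[None, :, :], axis=-1
        )
        for frame in traj.frames:
            for sl in (slice(0, n), slice(n, 2 * n)):
                dye = frame.coords[sl]
                d = np.linalg.norm(dye[:, None, :] - dye[None, :, :], axis=-1)
                np.testing.assert_allclose(d, ref, atol=1e-9)


class TestGenerateDimerTrajectory:
    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(n_frames=20, seed=99)
        t1, *_ = generate_dimer_trajectory(cfg)
        t2, *_ = generate_dimer_trajectory(cfg)
        np.testing.assert_array_equal(t1.coords_array(), t2.coords_array())

    def test_different_seed_differs(self):
        a, *_ = generate_dimer_trajectory(GeneratorConfig(n_frames=5, seed=1))
        b, *_ = generate_dimer_trajectory(GeneratorConfig(n_frames=5, seed=2))
        assert not np.array_equal(a.coords_array(), b.coords_array())

    def test_noiseless_aa_exact_h_geometry(self, noiseless_aa, dye_params):
        traj, rmap, sel, truth = noiseless_aa
        series = dimer_geometry_series(traj, sel, dye_params, "dye_m", "dye_n")
        assert all(g.kappa_sq == pytest.approx(1.0, abs=1e-12) for g in series)
        assert all(g.kappa_prime == pytest.approx(1.0, abs=1e-12) for g in series)
        assert all(g.R == pytest.approx(0.6, abs=1e-12) for g in series)
        np.testing.assert_allclose(truth.R, 0.6)

    def test_sample_mean_within_clt_bound(self):
        cfg = GeneratorConfig(n_frames=10_000, seed=123, mean_R=0.6, sd_R=0.1)
        _, _, _, truth = generate_dimer_trajectory(cfg)
        assert abs(truth.R.mean() - 0.6) <= 3 * 0.1 / np.sqrt(10_000) + 5e-4
        # the extra 5e-4 covers the (tiny) truncation bias at 3 sigma

    def test_separation_distribution_matches_truncated_normal(self):
        cfg = GeneratorConfig(n_frames=10_000, seed=321, mean_R=0.6, sd_R=0.1)
        _, _, _, truth = generate_dimer_trajectory(cfg)
        a = (MIN_SEPARATION_NM - 0.6) / 0.1
        stat = kstest(truth.R, truncnorm(a, np.inf, loc=0.6, scale=0.1).cdf)
        assert stat.pvalue > 0.01

    def test_ab_negative_kappa_prime_under_moderate_jitter(self, dye_params):
        cfg = GeneratorConfig(n_frames=200, seed=55, packing="AB",
                              orientation_jitter=20.0)
        traj, rmap, sel, truth = generate_dimer_trajectory(cfg)
        series = dimer_geometry_series(traj, sel, dye_params, "dye_m", "dye_n")
        assert all(g.kappa_prime < 0 for g in series)
        np.testing.assert_allclose(truth.kappa_prime_base, -1.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_frames=0)
        with pytest.raises(ValueError):
            GeneratorConfig(mean_R=0.2)
        with pytest.raises(ValueError):
            GeneratorConfig(packing="BB")
        with pytest.raises(ValueError):
            ConformerSpec(fraction=1.5, mean_R=0.9)


@pytest.fixture(scope="module")
def core():
    cfg = GeneratorConfig(n_frames=25, seed=31, placement="junction_core",
                          sd_R=0.05, orientation_jitter=5.0)
    traj, rmap, sel, _ = generate_dimer_trajectory(cfg)
    return cfg, *generate_mock_hj(cfg, traj, rmap)


class TestMockJunction:
    def test_junction_core_dyes_near_multiple_arms(self, core):
        cfg, traj, rmap = core
        cm = contact_probability(traj, rmap, cutoff=1.2)
        for dye in rmap.dye_residues():
            strands = {
                rmap[rid].strand
                for rid in rmap.residue_ids
                if rmap[rid].label == "nucleotide" and cm.probability(dye, rid) == 1.0
            }
            assert len(strands) >= 2

    def test_displaced_contacts_fewer_than_core(self, core):
        cfg, core_traj, core_rmap = core
        disp_cfg = GeneratorConfig(n_frames=25, seed=31, placement="displaced",
                                   sd_R=0.05, orientation_jitter=5.0)
        traj, rmap, sel, _ = generate_dimer_trajectory(disp_cfg)
        traj, rmap = generate_mock_hj(disp_cfg, traj, rmap)

        def n_dye_arm_contacts(cm, rmap):
            return sum(
                1
                for dye in rmap.dye_residues()
                for rid in rmap.residue_ids
                if rmap[rid].label == "nucleotide" and cm.probability(dye, rid) >= 0.5
            )

        core_n = n_dye_arm_contacts(contact_probability(core_traj, core_rmap), core_rmap)
        disp_n = n_dye_arm_contacts(contact_probability(traj, rmap), rmap)
        assert disp_n < core_n

    def test_distal_arm_residues_never_contact_dyes(self, core):
        cfg, traj, rmap = core
        cm = contact_probability(traj, rmap, cutoff=1.2)
        by_strand = {}
        for rid in rmap.residue_ids:
            e = rmap[rid]
            if e.label == "nucleotide":
                by_strand.setdefault(e.strand, []).append(rid)
        for strand, rids in by_strand.items():
            for rid in sorted(rids)[3:]:  # beyond the 3 proximal residues
                for dye in rmap.dye_residues():
                    assert cm.probability(dye, rid) == 0.0

    def test_residue_bookkeeping_valid(self, core):
        cfg, traj, rmap = core
        assert traj.n_atoms == 34 + sum(n for n, _ in cfg.hj_arms)
        assert set(rmap.dye_residues()) == {1, 2}
        strands = {rmap[r].strand for r in rmap.residue_ids if rmap[r].label == "nucleotide"}
        assert strands == {"A", "B", "C", "D"}


class TestParameterRecovery:
    def test_noiseless_zero_error(self, noiseless_aa, dye_params):
        traj, rmap, sel, truth = noiseless_aa
        series = dimer_geometry_series(traj, sel, dye_params, "dye_m", "dye_n")
        report = parameter_recovery_report(truth, series)
        assert report["within_tolerance"].all()
        by_q = report.set_index("quantity")
        assert by_q.loc["mean_R", "abs_error"] == pytest.approx(0.0, abs=1e-12)
        assert by_q.loc["mean_kappa_sq", "abs_error"] == pytest.approx(0.0, abs=1e-12)

    def test_ab_sign_recovered(self, dye_params):
        cfg = GeneratorConfig(n_frames=100, seed=61, packing="AB",
                              orientation_jitter=10.0)
        traj, rmap, sel, truth = generate_dimer_trajectory(cfg)
        series = dimer_geometry_series(traj, sel, dye_params, "dye_m", "dye_n")
        report = parameter_recovery_report(truth, series).set_index("quantity")
        assert report.loc["kappa_prime_sign", "estimated"] == -1.0
        assert report.loc["kappa_prime_sign", "within_tolerance"]

    def test_planted_conformer_fractions_within_binomial_bound(self, dye_params):
        from sqdimer import filter_clusters, gromos_cluster, pairwise_rmsd

        cfg = GeneratorConfig(n_frames=400, seed=71, sd_R=0.01,
                              orientation_jitter=2.0,
                              conformer_switch=ConformerSpec(fraction=0.4, mean_R=0.9))
        traj, rmap, sel, truth = generate_dimer_trajectory(cfg)
        series = dimer_geometry_series(traj, sel, dye_params, "dye_m", "dye_n")
        cs = filter_clusters(gromos_cluster(
            pairwise_rmsd(traj, list(range(traj.n_atoms))), 0.05))
        report = parameter_recovery_report(truth, series, cs.fractions())
        frac_rows = report[report["quantity"].str.startswith("conformer_fraction")]
        assert len(frac_rows) == 2
        assert frac_rows["within_tolerance"].all()
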