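"""Synthetic cohort generator: couplings, spectra, reproducibility."""

import numpy as np
import pytest
from scipy import signal as sps

from emicconn import emic, pcc
from emicconn.preprocess import regress_motion
from emicconn import simulate as sim
from emicconn.simulate import CohortConfig, CouplingSpec


class TestCouplings:
    def test_full_strength_linear_coupling_is_perfectly_correlated(self):
        cfg = CohortConfig(n_regions=4, n_timepoints=175, noise_sd=0.0,
                           couplings=(CouplingSpec(0, 1, "linear", 1.0, 1.0),))
        sub = sim.generate_subject(cfg, 1, np.random.default_rng(0))
        assert pcc(sub.data[0], sub.data[1]) == pytest.approx(1.0, abs=1e-6)

    def test_null_cohort_has_no_systematic_correlation(self):
        vals = []
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            x, y = sim.coupled_pair("independent", 0.0, 0.0, 120, rng)
            vals.append(pcc(x, y))
        assert abs(np.mean(vals)) < 0.05

    def test_quadratic_coupling_detected_by_emic(self):
        cfg = CohortConfig(n_regions=3, n_timepoints=175, noise_sd=0.0,
                           couplings=(CouplingSpec(0, 1, "quadratic", 1.0, 1.0),))
        sub = sim.generate_subject(cfg, 1, np.random.default_rng(2))
        scores = emic(sub.data[0], sub.data[1])
        assert scores.emic > 0.5
        assert abs(scores.pcc) < 0.25  # centered square: near-zero linear part

    def test_group_strengths_selected_by_label(self):
        cfg = CohortConfig(n_regions=3, n_timepoints=150, noise_sd=0.0,
                           couplings=(CouplingSpec(0, 1, "linear", 0.9, 0.1),))
        ctrl = sim.generate_subject(cfg, 1, np.random.default_rng(5))
        pat = sim.generate_subject(cfg, -1, np.random.default_rng(5))
        assert pcc(ctrl.data[0], ctrl.data[1]) > pcc(pat.data[0], pat.data[1])

    def test_coupling_referencing_missing_region_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_regions=3,
                         couplings=(CouplingSpec(0, 5, "linear", 0.5, 0.5),))

    def test_invalid_coupling_specs_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(0, 0, "linear", 0.5, 0.5)
        with pytest.raises(ValueError):
            CouplingSpec(0, 1, "cubic", 0.5, 0.5)
        with pytest.raises(ValueError):
            CouplingSpec(0, 1, "linear", 1.5, 0.5)


class TestSpectrum:
    def test_power_concentrated_in_band(self):
        x = sim.band_limited_noise(8192, np.random.default_rng(0))
        f, p = sps.periodogram(x, fs=0.5)
        in_band = p[(f >= 0.01) & (f <= 0.08)].sum()
        assert in_band / p.sum() > 0.9


class TestCohortGeneration:
    def test_reproducible_byte_identical_files(self, tmp_path):
        cfg = sim.paper_like_config(n_regions=6, n_timepoints=60, n_controls=2,
                                    n_patients=2, n_linear=1, n_quadratic=1,
                                    seed=7)
        sim.generate_cohort(cfg, out_dir=tmp_path / "a")
        sim.generate_cohort(cfg, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_output_collision_is_an_error(self, tmp_path):
        cfg = sim.null_config(n_regions=3, n_timepoints=60, n_controls=1,
                              n_patients=1, seed=0)
        sim.generate_cohort(cfg, out_dir=tmp_path)
        with pytest.raises(FileExistsError):
            sim.generate_cohort(cfg, out_dir=tmp_path)

    def test_file_count_and_shapes(self, tmp_path):
        cfg = sim.null_config(n_regions=10, n_timepoints=175, n_controls=4,
                              n_patients=4, seed=3)
        coh = sim.generate_cohort(cfg, out_dir=tmp_path)
        tsvs = sorted(p for p in tmp_path.iterdir() if p.suffix == ".tsv"
                      and p.name != "manifest.tsv")
        assert len(tsvs) == 8
        assert all(s.data.shape == (10, 175) for s in coh.subjects)
        assert (tmp_path / "manifest.tsv").exists()
        assert (tmp_path / "ground_truth.json").exists()

    def test_existing_subjects_stable_when_cohort_grows(self):
        small = sim.null_config(n_regions=4, n_timepoints=50, n_controls=2,
                                n_patients=2, seed=11)
        big = sim.null_config(n_regions=4, n_timepoints=50, n_controls=3,
                              n_patients=2, seed=11)
        a = sim.generate_cohort(small)
        b = sim.generate_cohort(big)
        np.testing.assert_array_equal(a.subjects[0].data, b.subjects[0].data)
        np.testing.assert_array_equal(a.subjects[1].data, b.subjects[1].data)

    def test_effect_direction_matches_construction(self):
        """Group-mean PCC on planted linear edges is higher in controls;
        group-mean eMIC on planted quadratic edges higher in patients."""
        ok_lin = ok_quad = reps = 20
        lin_wins = quad_wins = 0
        for rep in range(reps):
            cfg = sim.paper_like_config(
                n_regions=12, n_timepoints=175, n_controls=8, n_patients=8,
                n_linear=2, n_quadratic=2, seed=900 + rep,
            )
            coh = sim.generate_cohort(cfg)
            lin = [c.edge for c in cfg.couplings if c.form == "linear"]
            quad = [c.edge for c in cfg.couplings if c.form == "quadratic"]
            vals = {"lin": {1: [], -1: []}, "quad": {1: [], -1: []}}
            for sub, grp in zip(coh.subjects, coh.labels):
                for i, j in lin:
                    vals["lin"][grp].append(pcc(sub.data[i], sub.data[j]))
                for i, j in quad:
                    vals["quad"][grp].append(emic(sub.data[i], sub.data[j]).emic)
            lin_wins += np.mean(vals["lin"][1]) > np.mean(vals["lin"][-1])
            quad_wins += np.mean(vals["quad"][-1]) > np.mean(vals["quad"][1])
        assert lin_wins >= 0.95 * reps
        assert quad_wins >= 0.95 * reps


class TestMotion:
    def test_zero_amplitude_motion_is_all_zero(self):
        cfg = sim.null_config(n_regions=3, n_timepoints=80)
        motion = sim.generate_motion(cfg, np.random.default_rng(0), amplitude=0.0)
        assert (motion.data == 0).all()

    def test_reproducible_from_seed(self):
        cfg = sim.null_config(n_regions=3, n_timepoints=80)
        a = sim.generate_motion(cfg, np.random.default_rng(4))
        b = sim.generate_motion(cfg, np.random.default_rng(4))
        np.testing.assert_array_equal(a.data, b.data)

    def test_injected_motion_component_removed_by_regression(self):
        cfg = sim.null_config(n_regions=3, n_timepoints=120)
        rng = np.random.default_rng(8)
        motion = sim.generate_motion(cfg, rng, amplitude=0.5)
        sub = sim.generate_subject(cfg, 1, rng)
        contaminated = sub.data.copy()
        contaminated[1] += 2.0 * motion.data[3]
        cleaned = regress_motion(sub.with_data(contaminated), motion)
        reg = motion.data[3] - motion.data[3].mean()
        corr = (cleaned.data[1] @ reg) / (
            np.linalg.norm(cleaned.data[1]) * np.linalg.norm(reg)
        )
        assert abs(corr) < 1e-6


class TestBattery:
    def test_deterministic_and_sized(self):
        a = [x[0][:3].tolist() for x in sim.association_battery(8, n=64, seed=1)]
        b = [x[0][:3].tolist() for x in sim.association_battery(8, n=64, seed=1)]
        assert a == b
        assert len(a) == 8
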