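"""Synthetic generator: severity mixture, structure-function link, floor,
noise schedule, locality, and determinism."""

import numpy as np
import pytest

from retinerve.records import qc_filter
from retinerve.synthetic import (
    GeneratorConfig,
    bundle_windows,
    generate_dataset,
    healthy_template,
    make_profile,
    sample_severity,
    td_from_truth,
    td_noise_sd,
    _damage_pattern,
    _apply_damage,
    _link_td,
)
from retinerve.vf_geometry import interval_of


class TestSeverityMixture:
    def test_degenerate_healthy_mixture_stays_in_interval_one(self, rng):
        cfg = GeneratorConfig(healthy_fraction=1.0, bulk_sd_db=0.5)
        sev = sample_severity(cfg, rng, size=2000)
        assert all(interval_of(s) == 1 for s in sev)

    def test_bulk_of_default_mixture_is_better_than_minus_six(self, rng):
        sev = sample_severity(GeneratorConfig(), rng, size=10_000)
        assert np.mean(sev > -6) > 0.5

    def test_long_tail_populates_all_intervals(self, rng):
        sev = sample_severity(GeneratorConfig(), rng, size=10_000)
        counts = {k: sum(interval_of(s) == k for s in sev) for k in (1, 2, 3, 4)}
        assert all(c > 0 for c in counts.values())
        # progressively diminishing occupancy through the tail
        assert counts[1] > counts[2] > counts[3] > counts[4]


class TestProfiles:
    def test_zero_severity_zero_noise_returns_template(self, rng):
        cfg = GeneratorConfig(rnfl_noise_sd_um=0.0)
        prof, gt = make_profile(0.0, cfg, rng)
        assert np.array_equal(prof, healthy_template(cfg))
        assert np.array_equal(gt.true_td, np.zeros(52))

    def test_extreme_severity_clamps_at_floor(self, rng):
        cfg = GeneratorConfig(rnfl_noise_sd_um=0.0)
        prof, gt = make_profile(-1e6, cfg, rng)
        assert prof.min() >= cfg.floor_thickness_um - 1e-9

    def test_profiles_never_negative(self, rng):
        cfg = GeneratorConfig(rnfl_noise_sd_um=30.0)
        for sev in (0.0, -5.0, -25.0):
            prof, _ = make_profile(sev, cfg, rng)
            assert prof.min() >= 0

    def test_early_group_mean_thickness_matches_config_target(self):
        cfg = GeneratorConfig(n_patients=250, seed=3)
        ds, truth = generate_dataset(cfg)
        early = ds.md > -6
        mean_thick = ds.rnfl[early].mean()
        assert abs(mean_thick - cfg.target_early_mean_um) < 4.0


class TestStructureFunctionLink:
    def test_windows_tile_each_half_disjointly(self, grid):
        win = bundle_windows(grid)
        for half, (lo, hi) in ((0, (0, 384)), (1, (384, 768))):
            rows = win[np.array([loc.hemifield == ("inferior_chart" if half == 0 else "superior_chart")
                                 for loc in grid])]
            covered = sorted((a, b) for a, b in rows)
            assert covered[0][0] == lo and covered[-1][1] == hi
            for (a1, b1), (a2, b2) in zip(covered, covered[1:]):
                assert b1 == a2  # contiguous, no gaps or overlaps

    def test_locality_of_window_perturbation(self, grid, rng):
        cfg = GeneratorConfig(rnfl_noise_sd_um=0.0)
        win = bundle_windows(grid)
        template = healthy_template(cfg)
        base = -cfg.slope_db_per_um * np.zeros(52)
        j = 17
        a, b = win[j]
        damaged = template.copy()
        damaged[a:b] -= 20.0
        realized = np.array([float(np.mean(template[s:e] - damaged[s:e])) for s, e in win])
        td = _link_td(realized, cfg)
        assert td[j] < 0
        others = np.delete(td, j)
        assert np.allclose(others, 0.0)

    def test_zero_loss_zero_noise_gives_zero_td(self, rng):
        cfg = GeneratorConfig(td_noise_sd0_db=0.0, td_noise_sd30_db=0.0,
                              rnfl_noise_sd_um=0.0)
        _, gt = make_profile(0.0, cfg, rng)
        td = td_from_truth(gt, cfg, rng)
        assert np.array_equal(td, np.zeros(52))

    def test_superior_half_damage_maps_to_inferior_chart(self, grid, rng):
        # damage confined to the superior hemiretina half (samples 0..383)
        cfg = GeneratorConfig(rnfl_noise_sd_um=0.0, td_noise_sd0_db=0.0,
                              td_noise_sd30_db=0.0)
        pattern = np.zeros(52)
        inf_chart = [j for j, l in enumerate(grid) if l.hemifield == "inferior_chart"]
        pattern[inf_chart[3:8]] = 1.0  # windows living in samples 0..383
        pattern = pattern / pattern.mean()
        _, gt = make_profile(-10.0, cfg, rng, pattern=pattern)
        td = gt.true_td
        sup_chart = [j for j, l in enumerate(grid) if l.hemifield == "superior_chart"]
        assert np.allclose(td[sup_chart], 0.0)
        assert td[inf_chart].min() < -1.0

    def test_monotonicity_in_severity_for_fixed_pattern(self, grid, rng):
        cfg = GeneratorConfig(rnfl_noise_sd_um=0.0)
        pattern = _damage_pattern(-8.0, cfg, np.random.default_rng(0))
        win = bundle_windows(grid)
        prev = None
        for sev in (0.0, -3.0, -8.0, -15.0, -25.0, -35.0):
            _, realized = _apply_damage(sev, pattern, cfg, win)
            td = _link_td(realized, cfg)
            if prev is not None:
                assert np.all(td <= prev + 1e-9)
            prev = td

    def test_floor_saturates_true_td(self, grid, rng):
        # beyond the floor, worsening severity no longer changes the profile
        cfg = GeneratorConfig(rnfl_noise_sd_um=0.0)
        pattern = np.ones(52)
        win = bundle_windows(grid)
        _, r1 = _apply_damage(-200.0, pattern, cfg, win)
        _, r2 = _apply_damage(-400.0, pattern, cfg, win)
        assert np.allclose(r1, r2)

    def test_noise_schedule_grows_with_damage(self):
        cfg = GeneratorConfig()
        sd0 = td_noise_sd(np.array([0.0]), cfg)[0]
        sd20 = td_noise_sd(np.array([-20.0]), cfg)[0]
        sd30 = td_noise_sd(np.array([-30.0]), cfg)[0]
        assert sd0 == pytest.approx(cfg.td_noise_sd0_db)
        assert sd0 < sd20 < sd30 == pytest.approx(cfg.td_noise_sd30_db)


class TestDatasetGeneration:
    def test_same_seed_identical_output(self):
        cfg = GeneratorConfig(n_patients=8, seed=21)
        a, ta = generate_dataset(cfg)
        b, tb = generate_dataset(cfg)
        assert a.frame.equals(b.frame)
        assert ta.equals(tb)

    def test_record_count_is_product_of_config(self):
        ds, truth = generate_dataset(GeneratorConfig(n_patients=5, eyes_per_patient=2,
                                                     tests_per_eye=3, seed=1))
        assert len(ds) == 30 and len(truth) == 30

    def test_generated_records_are_qc_clean(self, small_dataset):
        ds, _ = small_dataset
        _, dropped = qc_filter(ds)
        assert len(dropped) == 0

    def test_md_is_masked_true_td(self, small_dataset):
        ds, truth = small_dataset
        td_true = truth[[f"td_true_{j}" for j in range(52)]].to_numpy(float)
        assert np.allclose(ds.md, td_true.mean(axis=1), atol=1e-9)

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="floor_thickness_um"):
            GeneratorConfig(floor_thickness_um=0.0)
        with pytest.raises(ValueError, match="n_patients"):
            GeneratorConfig(n_patients=0)
        with pytest.raises(ValueError, match="link"):
            GeneratorConfig(link="cubic")

    def test_linear_link_dataset_supports_linear_recovery(self):
        """A linear regressor recovers the noise-free linear-link map.

        The fit uses more records than profile samples, so near-zero error
        reflects genuine representability rather than interpolation.
        """
        cfg = GeneratorConfig(n_patients=250, rnfl_noise_sd_um=0.0,
                              td_noise_sd0_db=0.0, td_noise_sd30_db=0.0,
                              floor_thickness_um=15.0, seed=4)
        ds, _ = generate_dataset(cfg)
        X, Y = ds.rnfl, ds.td
        assert len(ds) > X.shape[1]
        W, *_ = np.linalg.lstsq(X, Y, rcond=None)
        assert np.abs(X @ W - Y).mean() < 0.05
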