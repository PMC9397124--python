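"""The synthetic study generator: schedules, confounds, factor-model signals."""

import numpy as np
import pandas as pd
import pytest

from painflow import SimConfig, simulate_confounds, simulate_events, simulate_run
from painflow.simulate import (
    MOTION_COLUMNS,
    _motion_composite,
    framewise_displacement,
    make_partition,
    simulate_study,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestEvents:
    def test_default_schedule_counts(self):
        cfg = SimConfig()
        ev = simulate_events(cfg, _rng())
        assert len(ev) == 30
        assert (ev["trial_type"] == "painful").sum() == 15
        assert (ev["duration"] == 2.5).all()

    def test_intervals_uniform_on_range_and_increasing(self):
        cfg = SimConfig()
        gaps = []
        for seed in range(20):
            ev = simulate_events(cfg, _rng(seed))
            onsets = ev["onset"].to_numpy()
            assert (np.diff(onsets) > 0).all()
            gaps.extend(np.diff(onsets))
        gaps = np.array(gaps)
        assert gaps.min() >= 10 and gaps.max() <= 20
        assert abs(gaps.mean() - 15) < 0.5  # uniform(10, 20) has mean 15

    def test_degenerate_isi_gives_exact_spacing(self):
        cfg = SimConfig(isi_range_s=(15.0, 15.0))
        ev = simulate_events(cfg, _rng())
        assert np.allclose(np.diff(ev["onset"]), 15.0)

    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig()
        a = simulate_events(cfg, _rng(7))
        b = simulate_events(cfg, _rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_run_too_short_raises(self):
        cfg = SimConfig(n_trs=20)  # 60 s cannot hold 30 events at >= 10 s ISI
        with pytest.raises(ValueError, match="too short"):
            simulate_events(cfg, _rng())

    def test_schedule_leaves_post_onset_window(self):
        cfg = SimConfig()
        ev = simulate_events(cfg, _rng(3))
        assert ev["onset"].iloc[-1] + 3 * cfg.tr_seconds <= cfg.run_duration_s


class TestConfounds:
    def test_columns_follow_fmriprep_dialect(self):
        conf = simulate_confounds(SimConfig(), 50, _rng())
        for name in MOTION_COLUMNS:
            assert name in conf.columns
            assert f"{name}_derivative1" in conf.columns
        for k in range(6):
            assert f"a_comp_cor_{k:02d}" in conf.columns
        assert {"white_matter", "csf", "framewise_displacement"} <= set(conf.columns)
        assert len(conf) == 50

    def test_derivatives_are_backward_differences(self):
        conf = simulate_confounds(SimConfig(), 40, _rng())
        for name in MOTION_COLUMNS:
            x = conf[name].to_numpy()
            d = conf[f"{name}_derivative1"].to_numpy()
            assert d[0] == 0.0
            np.testing.assert_allclose(d[1:], np.diff(x), atol=1e-12)

    def test_fd_zero_for_constant_motion(self):
        motion = np.ones((6, 30))
        fd = framewise_displacement(motion)
        np.testing.assert_array_equal(fd, 0.0)

    def test_fd_rotations_scaled_to_50mm_arc(self):
        motion = np.zeros((6, 3))
        motion[3, 1] = 0.01  # 0.01 rad step in one rotation axis
        fd = framewise_displacement(motion)
        assert fd[1] == pytest.approx(0.5)  # 50 mm * 0.01 rad
        assert fd[2] == pytest.approx(0.5)  # rotation steps back

    def test_bad_run_flag_exceeds_exclusion_threshold(self):
        conf = simulate_confounds(SimConfig(), 160, _rng(), bad_run=True)
        assert conf["framewise_displacement"].mean() > 0.5


class TestRunSignals:
    def test_shape_matches_design(self):
        cfg = SimConfig()
        ev = simulate_events(cfg, _rng())
        run = simulate_run(cfg, "HC", ev, _rng())
        assert run.signals.shape == (400, 160)

    def test_between_community_correlation_without_boost(self):
        # pooled over many runs, off-community correlation ~ between_r
        cfg = SimConfig(
            n_nodes=20,
            community_sizes=[4, 4, 3, 3, 2, 2, 2],
            n_trs=120,
            n_events_per_run=12,
            n_painful=6,
            event_boost_patient=0.0,
            event_boost_control=0.0,
            confound_loading=0.0,
            within_r=0.3,
            between_r=0.1,
        )
        rng = _rng(5)
        part = make_partition(cfg)
        same = np.equal.outer(part.communities, part.communities)
        iu = np.triu_indices(cfg.n_nodes, 1)
        between, within = [], []
        for _ in range(60):
            ev = simulate_events(cfg, rng)
            run = simulate_run(cfg, "HC", ev, rng)
            c = np.corrcoef(run.signals)
            between.append(c[iu][~same[iu]].mean())
            within.append(c[iu][same[iu]].mean())
        assert np.mean(between) == pytest.approx(0.1, abs=0.02)
        assert np.mean(within) == pytest.approx(0.3, abs=0.03)

    def test_boost_raises_between_community_correlation_monotonically(self):
        # larger boost -> larger between-community correlation in boosted TRs
        means = []
        for boost in (0.0, 0.1, 0.2):
            cfg = SimConfig(
                n_nodes=20,
                community_sizes=[4, 4, 3, 3, 2, 2, 2],
                n_trs=120,
                n_events_per_run=12,
                n_painful=6,
                event_boost_patient=boost,
                confound_loading=0.0,
                within_r=0.35,
                between_r=0.05,
            )
            rng = _rng(99)
            part = make_partition(cfg)
            diff = ~np.equal.outer(part.communities, part.communities)
            iu = np.triu_indices(cfg.n_nodes, 1)
            vals = []
            for _ in range(80):
                ev = simulate_events(cfg, rng)
                run = simulate_run(cfg, "RA", ev, rng)
                onsets = (
                    ev.loc[ev.trial_type == "painful", "onset"] // cfg.tr_seconds
                ).astype(int)
                boosted = sorted(
                    {
                        t
                        for o in onsets
                        for t in range(o + 1, min(o + 4, cfg.n_trs))
                    }
                )
                c = np.corrcoef(run.signals[:, boosted])
                vals.append(c[iu][diff[iu]].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_boosted_correlation_matches_closed_form(self):
        # factor model: between-community corr in boosted TRs = between_r + boost
        cfg = SimConfig(
            n_nodes=30,
            community_sizes=[5, 5, 5, 5, 4, 3, 3],
            n_trs=150,
            n_events_per_run=15,
            n_painful=8,
            within_r=0.35,
            between_r=0.05,
            event_boost_patient=0.15,
            confound_loading=0.0,
        )
        rng = _rng(17)
        part = make_partition(cfg)
        diff = ~np.equal.outer(part.communities, part.communities)
        iu = np.triu_indices(cfg.n_nodes, 1)
        vals = []
        for _ in range(220):
            ev = simulate_events(cfg, rng)
            run = simulate_run(cfg, "RA", ev, rng)
            onsets = (
                ev.loc[ev.trial_type == "painful", "onset"] // cfg.tr_seconds
            ).astype(int)
            boosted = sorted(
                {t for o in onsets for t in range(o + 1, min(o + 4, cfg.n_trs))}
            )
            c = np.corrcoef(run.signals[:, boosted])
            vals.append(c[iu][diff[iu]].mean())
        assert np.mean(vals) == pytest.approx(0.20, abs=0.015)

    def test_boost_budget_violation_names_parameters(self):
        cfg = SimConfig(within_r=0.35, between_r=0.05, event_boost_patient=0.1,
                        confound_loading=0.0)
        ev = simulate_events(cfg, _rng())
        cfg.event_boost_patient = 0.4  # past construction-time validation
        with pytest.raises(ValueError, match="budget exceeded"):
            simulate_run(cfg, "RA", ev, _rng())
        with pytest.raises(ValueError, match="boost budget"):
            SimConfig(within_r=0.35, between_r=0.05, event_boost_patient=0.4)

    def test_invalid_config_rejected_upfront(self):
        with pytest.raises(ValueError, match="within_r"):
            SimConfig(within_r=0.1, between_r=0.2)
        with pytest.raises(ValueError, match="community_sizes"):
            SimConfig(n_nodes=10, community_sizes=[5, 4])


class TestStudyBundle:
    def test_fixed_seed_reproduces_bundle_bitwise(self, tiny_cfg):
        a = simulate_study(tiny_cfg)
        b = simulate_study(tiny_cfg)
        assert len(a.records) == len(b.records)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.run.signals, rb.run.signals)
            pd.testing.assert_frame_equal(ra.confounds, rb.confounds)
            pd.testing.assert_frame_equal(ra.events, rb.events)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)

    def test_four_runs_per_subject_two_per_site(self, tiny_bundle, tiny_cfg):
        counts = {}
        for rec in tiny_bundle.records:
            counts.setdefault(rec.run.subject, []).append(rec.run.site)
        n_subj = tiny_cfg.n_patients + tiny_cfg.n_controls
        assert len(counts) == n_subj
        for sites in counts.values():
            assert len(sites) == 4
            assert sites.count("joint") == 2 and sites.count("thumb") == 2

    def test_ages_within_configured_range(self, tiny_bundle, tiny_cfg):
        lo, hi = tiny_cfg.age_range
        assert tiny_bundle.manifest["age"].between(lo, hi).all()

    def test_zero_confound_loading_decouples_signals_from_motion(self):
        cfg = SimConfig(
            n_patients=1,
            n_controls=0,
            n_nodes=14,
            community_sizes=[2] * 7,
            n_trs=600,
            n_events_per_run=10,
            n_painful=5,
            confound_loading=0.0,
            seed=4,
        )
        bundle = simulate_study(cfg)
        rec = bundle.records[0]
        comp = _motion_composite(rec.confounds, np.random.default_rng(0))
        corr = [
            abs(np.corrcoef(sig, comp)[0, 1]) for sig in rec.run.signals
        ]
        assert max(corr) < 0.2  # ~N(0, 1/sqrt(600)) under independence
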