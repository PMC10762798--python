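"""Synthetic cohort generator: determinism, spectra and group structure."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from pdeeg.protocol import (ProtocolSchedule, RealizedBlock,
                            build_compact_protocol)
from pdeeg.synth import (BANDS, GeneratorConfig, SubjectSpec, generate_cohort,
                         generate_subject)


def _silent_config(**overrides):
    base = dict(
        band_amplitudes={b: 0.0 for b in BANDS},
        latent_load_gain={"PD": 0.0, "healthy": 0.0},
        latent_baseline={"PD": 0.0, "healthy": 0.0},
        global_mod_sd={"PD": 0.0, "healthy": 0.0},
        background_scale=0.0, noise_sd=0.0, seed=1,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def _mini_schedule(rest_s=30.0, task_s=30.0):
    return ProtocolSchedule(blocks=[
        RealizedBlock("rest", 0.0, rest_s, []),
        RealizedBlock("nback1", rest_s, task_s, []),
    ])


class TestGenerateSubject:
    def test_null_generator_gives_all_zero_signal(self, compact_schedule):
        rec = generate_subject(SubjectSpec("s", "healthy", 0),
                               compact_schedule, _silent_config())
        assert np.all(rec.samples == 0.0)

    def test_seeded_determinism(self, compact_schedule):
        cfg = GeneratorConfig(seed=5)
        a = generate_subject(SubjectSpec("s", "PD", 9), compact_schedule, cfg)
        b = generate_subject(SubjectSpec("s", "PD", 9), compact_schedule, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_recording_length_and_labels(self, compact_schedule):
        cfg = GeneratorConfig(seed=5)
        rec = generate_subject(SubjectSpec("s", "PD", 3), compact_schedule, cfg)
        assert len(rec.samples) == int(compact_schedule.total_duration_s) * 500
        assert len(rec.labels) == int(compact_schedule.total_duration_s)
        assert np.all(np.isfinite(rec.samples))

    def test_healthy_has_more_delta_power_than_pd(self, compact_schedule):
        """Welch-periodogram oracle: the configured Delta advantage shows up."""
        cfg = GeneratorConfig(seed=5)
        h = generate_subject(SubjectSpec("s", "healthy", 9),
                             compact_schedule, cfg)
        p = generate_subject(SubjectSpec("s", "PD", 9), compact_schedule, cfg)

        def delta_power(x):
            f, pxx = sp_signal.welch(x, fs=500, nperseg=2048)
            sel = (f >= 0.5) & (f <= 4.0)
            return pxx[sel].mean()

        assert delta_power(h.samples) > delta_power(p.samples)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            generate_subject(SubjectSpec("s", "PD", 0),
                             ProtocolSchedule(blocks=[]), GeneratorConfig())

    def test_background_spectral_slope_matches_config(self):
        """Periodogram regression over a rest-only segment recovers the
        1/f exponent within 10%."""
        sched = ProtocolSchedule(blocks=[RealizedBlock("rest", 0.0, 60.0, [])])
        cfg = _silent_config(background_scale=1.0, one_over_f_exponent=1.0)
        slopes = []
        for seed in range(5):
            cfg2 = _silent_config(background_scale=1.0,
                                  one_over_f_exponent=1.0, seed=seed)
            rec = generate_subject(SubjectSpec("s", "healthy", seed),
                                   sched, cfg2)
            f, pxx = sp_signal.welch(rec.samples, fs=500, nperseg=4096)
            sel = (f >= 0.5) & (f <= 40.0)
            slope = np.polyfit(np.log10(f[sel]), np.log10(pxx[sel]), 1)[0]
            slopes.append(-slope)
        assert abs(np.mean(slopes) - 1.0) < 0.1

    def test_latent_power_monotone_for_healthy_flat_for_pd(self):
        """Per-condition latent-band power tracks load only in the healthy
        group; the PD latent level is load-insensitive."""
        sched = ProtocolSchedule(blocks=[
            RealizedBlock("rest", 0.0, 60.0, []),
            RealizedBlock("nback0", 60.0, 60.0, []),
            RealizedBlock("nback1", 120.0, 60.0, []),
        ])

        def band_power_per_block(group, seed):
            cfg = _silent_config(
                latent_load_gain={"PD": 0.0, "healthy": 3.5},
                latent_baseline={"PD": 2.5, "healthy": 0.0},
                noise_sd=0.5, seed=seed)
            rec = generate_subject(SubjectSpec("s", group, seed), sched, cfg)
            out = []
            for lo, hi in ((5, 55), (65, 115), (125, 175)):  # avoid ramps
                seg = rec.samples[lo * 500:hi * 500]
                f, pxx = sp_signal.welch(seg, fs=500, nperseg=2048)
                sel = (f >= 1.5) & (f <= 4.0)
                out.append(pxx[sel].mean())
            return out

        healthy = np.mean([band_power_per_block("healthy", s)
                           for s in range(4)], axis=0)
        pd_ = np.mean([band_power_per_block("PD", s)
                       for s in range(4)], axis=0)
        assert healthy[0] < healthy[1] < healthy[2]
        # flat within noise: relative spread well below the healthy dynamic
        assert (pd_.max() - pd_.min()) / pd_.mean() < 0.25

    def test_invalid_fs_rejected(self, compact_schedule):
        with pytest.raises(ValueError):
            GeneratorConfig(fs=0)


class TestGenerateCohort:
    def test_cohort_size_and_groups(self, small_cohort):
        recs, meta = small_cohort
        assert len(recs) == 12
        assert (meta.group == "PD").sum() == 6
        assert (meta.group == "healthy").sum() == 6

    def test_minimal_cohort_has_distinct_seeds(self, compact_schedule):
        recs, meta = generate_cohort(1, compact_schedule,
                                     GeneratorConfig(seed=3))
        assert len(recs) == 2
        assert meta.seed.nunique() == 2

    def test_metadata_is_deterministic(self, compact_schedule):
        _, m1 = generate_cohort(2, compact_schedule, GeneratorConfig(seed=3))
        _, m2 = generate_cohort(2, compact_schedule, GeneratorConfig(seed=3))
        assert m1.equals(m2)

    def test_ages_within_truncation_bounds(self, small_cohort):
        _, meta = small_cohort
        assert meta.age.between(45, 90).all()

    def test_nonpositive_cohort_size_rejected(self, compact_schedule):
        with pytest.raises(ValueError):
            generate_cohort(0, compact_schedule, GeneratorConfig())

    def test_group_delta_effect_sign_recovered_across_cohorts(self):
        """Regressing extracted Delta power on group recovers the configured
        positive healthy-minus-PD sign in >= 90% of simulated cohorts."""
        sched = _mini_schedule(rest_s=90.0, task_s=90.0)
        hits = 0
        n_cohorts = 20
        for c in range(n_cohorts):
            recs, _ = generate_cohort(8, sched, GeneratorConfig(seed=100 + c))
            means = {}
            for g in ("PD", "healthy"):
                vals = []
                for r in recs:
                    if r.group != g:
                        continue
                    f, pxx = sp_signal.welch(r.samples, fs=500, nperseg=2048)
                    sel = (f >= 0.5) & (f <= 4.0)
                    vals.append(10 * np.log10(pxx[sel].mean()))
                means[g] = np.mean(vals)
            hits += means["healthy"] > means["PD"]
        assert hits >= 0.9 * n_cohorts
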