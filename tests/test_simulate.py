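"""Synthetic cohort generator: validation, determinism, structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from docentropy import ApEnParams, apen, capen
from docentropy.prognosis import MGOS_ORDER, classify_improvement
from docentropy.simulate import (CohortConfig, SubjectRecord,
                                 generate_channel_signal, generate_cohort,
                                 generate_outcome, generate_subject)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="fraction"):
            CohortConfig(irregularity_uws=1.2)
        with pytest.raises(ValueError, match="fraction"):
            CohortConfig(coupling_mcs=-0.1)

    def test_group_sizes(self):
        with pytest.raises(ValueError, match="subject"):
            CohortConfig(n_uws=0)

    def test_epoch_floor(self):
        with pytest.raises(ValueError, match="epoch_len"):
            CohortConfig(epoch_len=500)

    def test_diagnosis_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(diagnosis_mix={"TBI": 0.5, "stroke": 0.4, "other": 0.2})

    def test_scalar_gains_accepted(self):
        cfg = CohortConfig(pain_gain_unaffected=0.1)
        assert cfg.pain_gain_unaffected == {"UWS": 0.1, "MCS": 0.1}


class TestChannelSignal:
    def test_length_and_moments(self, rng):
        x = generate_channel_signal(0.5, 2048, 500, rng)
        assert len(x) == 2048
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, abs=1e-12)

    def test_irregularity_endpoints_ordered(self):
        p = ApEnParams(n_points=2048)
        lo = apen(generate_channel_signal(
            0.0, 2048, 500, np.random.default_rng(1)), p)
        hi = apen(generate_channel_signal(
            1.0, 2048, 500, np.random.default_rng(1)), p)
        assert lo < hi

    def test_rejects_bad_irregularity(self, rng):
        with pytest.raises(ValueError):
            generate_channel_signal(np.nan, 2048, 500, rng)
        with pytest.raises(ValueError):
            generate_channel_signal(1.5, 2048, 500, rng)


class TestCohortStructure:
    def test_cohort_size_and_schema(self, feature_cohort):
        meta = feature_cohort.meta
        assert len(meta) == 162
        assert (meta.group == "UWS").sum() == 98
        assert (meta.group == "MCS").sum() == 64
        assert set(meta.mgos_12m) <= set(MGOS_ORDER)
        assert meta.crs_r.between(0, 23).all()
        assert (meta.duration > 0).all()
        assert len(feature_cohort.apen_proxy) == 162 * 2 * 16
        assert len(feature_cohort.capen_proxy) == 162 * 2 * 10

    def test_reproducible_and_seed_sensitive(self):
        cfg = CohortConfig(n_uws=3, n_mcs=2, epoch_len=1024, seed=5)
        a = generate_cohort(cfg, signals=True)
        b = generate_cohort(cfg, signals=True)
        pd.testing.assert_frame_equal(a.meta, b.meta)
        np.testing.assert_array_equal(a.recordings[0].data, b.recordings[0].data)
        c = generate_cohort(CohortConfig(n_uws=3, n_mcs=2, epoch_len=1024,
                                         seed=6), signals=True)
        assert not np.array_equal(a.recordings[0].data, c.recordings[0].data)
        assert list(c.meta.columns) == list(a.meta.columns)

    def test_subject_stream_independent_of_cohort(self):
        """Subject i is a function of (config, i) alone."""
        cfg = CohortConfig(n_uws=3, n_mcs=2, epoch_len=1024, seed=5)
        cohort = generate_cohort(cfg, signals=True)
        rec, _, _, recs = generate_subject(cfg, "MCS", 4, signals=True)
        assert rec == SubjectRecord(**cohort.meta.iloc[4].to_dict())
        np.testing.assert_array_equal(recs[0].data, cohort.recordings[8].data)

    def test_crs_r_stochastic_dominance(self, feature_cohort):
        meta = feature_cohort.meta
        uws = np.sort(meta.loc[meta.group == "UWS", "crs_r"])
        mcs = np.sort(meta.loc[meta.group == "MCS", "crs_r"])
        qs = np.linspace(0.1, 0.9, 9)
        assert (np.quantile(mcs, qs) >= np.quantile(uws, qs)).all()


class TestPainResponse:
    def test_mcs_pain_response_exceeds_uws(self):
        """Unaffected-side pain-minus-rest responses larger in MCS, in
        expectation over 30 paired subjects per group (feature tier)."""
        cfg = CohortConfig(n_uws=30, n_mcs=30, seed=21)
        cohort = generate_cohort(cfg, signals=False)
        apen = cohort.apen_proxy
        wide = apen.pivot_table(index="subject_id",
                                columns=["condition", "channel"], values="apen")
        diff = wide["pain"] - wide["eyes_closed"]
        un = diff[[c for c in diff.columns if c.endswith("_U")]].mean(axis=1)
        groups = cohort.meta.set_index("subject_id")["group"]
        assert un[groups == "MCS"].mean() > un[groups == "UWS"].mean()

    def test_zero_gains_center_differences_on_zero(self):
        cfg = CohortConfig(n_uws=120, n_mcs=120, seed=8,
                           pain_gain_unaffected=0.0, pain_gain_affected=0.0)
        cohort = generate_cohort(cfg, signals=False)
        wide = cohort.apen_proxy.pivot_table(
            index="subject_id", columns=["condition", "channel"], values="apen")
        diff = (wide["pain"] - wide["eyes_closed"]).to_numpy()
        # mean of 240*16 i.i.d. zero-mean terms: SE ~ DIFF_NOISE_SD/62
        assert abs(diff.mean()) < 0.01

    def test_full_coupling_makes_channels_identical(self):
        cfg = CohortConfig(n_uws=1, n_mcs=1, epoch_len=1500, seed=9,
                           coupling_uws=1.0, coupling_mcs=1.0)
        _, _, _, recs = generate_subject(cfg, "UWS", 0, signals=True)
        rec = recs[0]
        c3, p3 = rec.channel("C3"), rec.channel("P3")
        np.testing.assert_array_equal(c3, p3)
        p = ApEnParams(n_points=1500)
        assert capen(c3, p3, p) == apen(c3, p)


class TestOutcomeModel:
    def _record(self, group="UWS", crs=10):
        return SubjectRecord(subject_id="S0", age=40, sex="male", duration=100,
                             diagnosis="TBI", group=group, crs_r=crs,
                             affected_side="left", true_affected_side="left")

    def test_intercept_half_gives_half_rate(self):
        rng = np.random.default_rng(0)
        hits = sum(generate_outcome(self._record(), {}, {"intercept": 0.5},
                                    rng)[1] for _ in range(1000))
        assert 450 <= hits <= 550  # Bernoulli(0.5), 1000 draws

    def test_crs_r_drives_improvement(self):
        rng = np.random.default_rng(1)
        crs, improved = [], []
        for _ in range(1000):
            c = int(rng.integers(0, 24))
            _, up = generate_outcome(self._record(crs=c), {},
                                     {"intercept": 0.0, "crs_r": 0.04}, rng)
            crs.append(c)
            improved.append(up)
        crs, improved = np.array(crs), np.array(improved, bool)
        assert crs[improved].mean() > crs[~improved].mean()

    def test_upgrade_rule_respected(self):
        rng = np.random.default_rng(2)
        for group, baseline in (("UWS", "VS"), ("MCS", "MCS")):
            for _ in range(200):
                mgos, up = generate_outcome(self._record(group=group), {},
                                            {"intercept": 0.5}, rng)
                assert up == classify_improvement(group, mgos)
                if group == "UWS" and up:
                    assert mgos in {"MCS", "severe_disability",
                                    "moderate_disability", "good_recovery"}

    def test_unknown_coefficient_name_rejected(self):
        with pytest.raises(KeyError, match="no matching"):
            generate_outcome(self._record(), {}, {"XX_A": 1.0},
                             np.random.default_rng(0))
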