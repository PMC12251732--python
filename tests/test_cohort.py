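"""Synthetic generators: risk-conditioned vitals and ADL bouts,
indirect pairing, the embedded comparison fixture, and the end-to-end
generate -> predict -> stack -> evaluate smoke property."""

import numpy as np
import pytest

from coopfall.cohort import (
    CohortEntry,
    MergedParticipant,
    default_profiles,
    generate_adl,
    generate_mfs_score,
    generate_vitals,
    indirect_pairing,
    simulate_cohort,
    table5_fixture,
)
from coopfall.errors import InvalidInputError
from coopfall.evaluation import mfs_to_level
from coopfall.levels import FiveLevelRisk as F
from coopfall.levels import ThreeLevelRisk as T


class TestVitalsGenerator:
    def test_zero_n_gives_empty_list(self, profiles):
        assert generate_vitals(profiles["low"], 0, seed=1) == []

    def test_same_seed_reproduces_samples(self, profiles):
        a = generate_vitals(profiles["high"], 5, seed=9)
        b = generate_vitals(profiles["high"], 5, seed=9)
        assert a == b

    def test_low_risk_spo2_mean_near_configured(self, profiles):
        samples = generate_vitals(profiles["low"], 500, seed=3)
        mean = np.mean([s.spo2 for s in samples])
        assert abs(mean - profiles["low"].vital_distributions["spo2"]["mean"]) < 0.5

    def test_generated_samples_always_satisfy_invariants(self, profiles):
        # 1000 seeded draws across all three profiles; VitalSignSample
        # construction enforces the invariants, so surviving is the test
        rng = np.random.default_rng(11)
        for label in ("low", "moderate", "high"):
            for s in generate_vitals(profiles[label], 334, seed=rng):
                assert s.systolic_bp > s.diastolic_bp > 0
                assert 0 < s.spo2 <= 100


class TestADLGenerator:
    def test_pure_sitting_mix_emits_only_sitting(self, profiles):
        prof = profiles["low"]
        pure = type(prof)(
            label="low",
            vital_distributions=prof.vital_distributions,
            adl_mix={"sitting": 1.0, "standing": 0.0, "walking": 0.0,
                     "running": 0.0, "jumping": 0.0},
            mfs_range=prof.mfs_range,
            fall_rate=prof.fall_rate,
        )
        bouts = generate_adl(pure, 3600.0, seed=2)
        assert {b.activity for b in bouts} == {"sitting"}

    def test_total_duration_is_conserved(self, profiles):
        bouts = generate_adl(profiles["moderate"], 7200.0, seed=5)
        assert sum(b.duration for b in bouts) == pytest.approx(7200.0)

    def test_long_horizon_walking_fraction_near_mix(self, profiles):
        prof = profiles["high"]
        bouts = generate_adl(prof, 500_000.0, seed=8)
        walk = sum(b.duration for b in bouts if b.activity == "walking")
        total = sum(b.duration for b in bouts)
        assert abs(walk / total - prof.adl_mix["walking"]) < 0.05

    def test_nonpositive_duration_rejected(self, profiles):
        with pytest.raises(InvalidInputError):
            generate_adl(profiles["low"], 0.0)


class TestMFSGenerator:
    def test_scores_stay_in_class_band_and_match_level(self, profiles):
        rng = np.random.default_rng(4)
        for label, level in [("low", T.LOW), ("moderate", T.MODERATE),
                             ("high", T.HIGH)]:
            for _ in range(50):
                score = generate_mfs_score(profiles[label], seed=rng)
                lo, hi = profiles[label].mfs_range
                assert lo <= score <= hi
                assert mfs_to_level(score) is level


class TestIndirectPairing:
    @staticmethod
    def _entry(pid, age, falls, mfs, level):
        return CohortEntry(id=pid, age=age, fall_history=falls,
                           mfs_level=mfs, level=level)

    def test_identical_single_row_cohorts_merge(self):
        a = [self._entry("A1", 70, 2, T.MODERATE, F.MODERATE)]
        b = [self._entry("B1", 70, 2, T.MODERATE, T.LOW)]
        res = indirect_pairing(a, b)
        assert len(res.merged) == 1
        m = res.merged[0]
        assert (m.ai1_level, m.ai2_level, m.mfs_level) == (
            F.MODERATE, T.LOW, T.MODERATE)

    def test_disjoint_ages_give_empty_result_with_warning(self, caplog):
        a = [self._entry("A1", 70, 2, T.MODERATE, F.MODERATE)]
        b = [self._entry("B1", 80, 2, T.MODERATE, T.LOW)]
        with caplog.at_level("WARNING", logger="coopfall.cohort"):
            res = indirect_pairing(a, b)
        assert res.merged == []
        assert res.unmatched_ai1 == ["A1"] and res.unmatched_ai2 == ["B1"]
        assert any("no matches" in r.message for r in caplog.records)

    def test_fall_history_tolerance_flag(self):
        a = [self._entry("A1", 70, 2, T.MODERATE, F.MODERATE)]
        b = [self._entry("B1", 70, 3, T.MODERATE, T.LOW)]
        assert indirect_pairing(a, b).merged == []
        assert len(indirect_pairing(a, b, fall_history_tolerance=1).merged) == 1

    def test_thirty_constructed_pairs_all_merge(self, rng):
        """Cohorts built pairwise-compatible merge into exactly 30."""
        a, b = [], []
        for i in range(30):
            age = int(rng.integers(60, 90))
            falls = int(rng.integers(0, 6))
            mfs = T(int(rng.integers(0, 3)))
            a.append(self._entry(f"A{i}", age, falls, mfs,
                                 F(int(rng.integers(0, 5)))))
            b.append(self._entry(f"B{i}", age, falls, mfs,
                                 T(int(rng.integers(0, 3)))))
        res = indirect_pairing(a, b)
        assert len(res.merged) == 30

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(InvalidInputError):
            indirect_pairing([], [])


class TestTable5Fixture:
    def test_length_is_ten(self, table5):
        assert len(table5.participants) == 10

    def test_row_p4(self, table5):
        p4 = next(p for p in table5.participants if p.id == "P4")
        assert p4.fall_history == 5
        assert p4.ai1_level is F.MODERATE
        assert p4.ai2_level is T.MODERATE
        assert table5.mfs["P4"] is T.HIGH

    def test_row_p9_all_low(self, table5):
        p9 = next(p for p in table5.participants if p.id == "P9")
        assert p9.fall_history == 0
        assert p9.ai1_level is F.LOW
        assert p9.ai2_level is T.LOW
        assert table5.meta_printed["P9"] is T.LOW
        assert table5.mfs["P9"] is T.LOW

    def test_merged_participant_age_floor(self):
        with pytest.raises(InvalidInputError):
            MergedParticipant(id="X", age=59, fall_history=0,
                              ai1_level=F.LOW, ai2_level=T.LOW,
                              mfs_level=T.LOW)


class TestSimulatedCohort:
    def test_round_trips_through_csv_losslessly(self, tmp_path):
        from coopfall import io as cio

        people = simulate_cohort(8, seed=13, adl_duration_s=3600.0)
        vit_p, adl_p = tmp_path / "v.csv", tmp_path / "a.csv"
        cio.vitals_frame(people).to_csv(vit_p, index=False)
        cio.adl_frame(people).to_csv(adl_p, index=False)
        back_v = dict(cio.read_vitals(vit_p))
        back_a = cio.read_adl(adl_p)
        for p in people:
            assert back_v[p.id] == p.vitals
            assert tuple(back_a[p.id]) == p.bouts

    def test_invalid_mix_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_cohort(5, mix=(0.5, 0.5, 0.5))

    def test_end_to_end_smoke_accuracy(self):
        """generate -> both base models -> meta -> evaluate runs clean and
        reaches >= 0.8 accuracy on noiseless profiles."""
        from coopfall.pipeline import run_synthetic_pipeline

        res = run_synthetic_pipeline(n_train=30, n_test=10, seed=0)
        assert res.report["exact_match"] >= 0.8
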