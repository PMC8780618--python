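"""Life-table construction and demographic parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohort_demog import (
    IndividualRecord,
    LifeTableSchedule,
    build_life_table,
    compute_parameters,
    doubling_time,
    finite_rate,
    generation_time,
    intrinsic_rate_birch,
    intrinsic_rate_lotka,
    jackknife_parameters,
    longevity_summary,
    net_reproductive_rate,
    reproduction_summary,
)
from cohort_demog.demography import bootstrap_parameters
from cohort_demog.exceptions import (
    EmptyCohortError,
    NumericError,
    SampleSizeError,
    ValidationError,
)


def schedule_of(rows, origin="adult_emergence"):
    arr = np.asarray(rows, dtype=float)
    return LifeTableSchedule(x=arr[:, 0], lx=arr[:, 1], mx=arr[:, 2],
                             age_origin=origin)


@st.composite
def random_schedules(draw):
    n = draw(st.integers(2, 25))
    x = np.cumsum(draw(st.lists(st.floats(0.5, 3.0), min_size=n, max_size=n)))
    lx = np.cumprod(draw(st.lists(st.floats(0.7, 1.0), min_size=n, max_size=n)))
    mx = np.array(draw(st.lists(st.floats(0.0, 5.0), min_size=n, max_size=n)))
    if (lx * mx).sum() <= 0.01:
        mx[0] += 1.0
    return schedule_of(np.column_stack([x, lx, mx]))


class TestRecordValidation:
    def test_eggs_longer_than_life(self):
        with pytest.raises(ValidationError):
            IndividualRecord("f1", "female", adult_longevity=2.0,
                             daily_eggs=[1, 1, 1])

    def test_durations_after_death_stage(self):
        with pytest.raises(ValidationError):
            IndividualRecord("x", "female", died_in_stage="L1",
                             stage_durations={"egg": 3.0, "L2": 2.0})

    def test_bad_sex(self):
        with pytest.raises(ValidationError):
            IndividualRecord("x", "hermaphrodite")


class TestBuildLifeTable:
    def test_single_female(self, single_female):
        sch = build_life_table([single_female], female_fraction=0.5)
        assert np.allclose(sch.x, [0.5, 1.5, 2.5])
        assert np.allclose(sch.lx, [1, 1, 1])
        assert np.allclose(sch.mx, [1, 1, 0])
        assert net_reproductive_rate(sch) == pytest.approx(2.0)

    def test_survivor_averaging(self, two_females):
        sch = build_life_table(two_females, female_fraction=1.0)
        assert np.allclose(sch.lx, [1.0, 0.5])
        # day 2: only f2 alive, laying 4 eggs
        assert np.allclose(sch.mx, [2.0, 4.0])

    def test_lxmx_identity(self, two_females):
        sch = build_life_table(two_females)
        assert np.allclose(sch.lxmx, sch.lx * sch.mx)

    def test_egg_viability_flag(self, single_female):
        sch = build_life_table([single_female], apply_egg_viability=True,
                               egg_viability=0.5)
        assert net_reproductive_rate(sch) == pytest.approx(1.0)

    def test_immature_survival_flag(self, single_female):
        dead = IndividualRecord("d1", "unknown", died_in_stage="egg",
                                stage_durations={"egg": 2.0})
        sch = build_life_table([single_female, dead],
                               apply_immature_survival=True)
        assert np.allclose(sch.lx, 0.5)

    def test_oviposition_origin_shifts_ages(self, single_female):
        sch = build_life_table([single_female], age_origin="oviposition",
                               immature_duration=15.0)
        assert np.allclose(sch.x, [15.5, 16.5, 17.5])

    def test_no_females_raises(self):
        male = IndividualRecord("m1", "male", adult_longevity=10.0)
        with pytest.raises(EmptyCohortError):
            build_life_table([male])

    def test_bad_female_fraction(self, single_female):
        with pytest.raises(ValidationError):
            build_life_table([single_female], female_fraction=1.5)


class TestParameters:
    def test_single_row_r0(self):
        sch = schedule_of([[1.0, 1.0, 1.0]])
        assert net_reproductive_rate(sch) == pytest.approx(1.0)

    def test_r0_linear_in_mx(self, two_females):
        sch = build_life_table(two_females)
        doubled = LifeTableSchedule(x=sch.x, lx=sch.lx, mx=2 * sch.mx)
        assert net_reproductive_rate(doubled) == pytest.approx(
            2 * net_reproductive_rate(sch))

    def test_generation_time_point_mass(self):
        sch = schedule_of([[10.0, 1.0, 3.0]])
        assert generation_time(sch) == pytest.approx(10.0)

    def test_generation_time_symmetric(self):
        sch = schedule_of([[1.0, 1.0, 1.0], [3.0, 1.0, 1.0]])
        assert generation_time(sch) == pytest.approx(2.0)

    def test_generation_time_requires_reproduction(self):
        sch = schedule_of([[1.0, 1.0, 0.0]])
        with pytest.raises(NumericError):
            generation_time(sch)

    def test_birch_published_diet_row(self):
        # printed R0 = 7.65 and T = 35.2 reproduce the printed r = 0.0578
        assert intrinsic_rate_birch(7.65, 35.2) == pytest.approx(0.0578,
                                                                 abs=5e-5)

    def test_birch_identities(self):
        assert intrinsic_rate_birch(1.0, 12.0) == 0.0
        assert intrinsic_rate_birch(math.e, 1.0) == pytest.approx(1.0)

    def test_doubling_time_published_rows(self):
        assert doubling_time(0.4547) == pytest.approx(1.52, abs=5e-3)
        assert doubling_time(0.0578) == pytest.approx(11.99, abs=5e-3)
        assert doubling_time(math.log(2.0)) == pytest.approx(1.0)

    def test_doubling_time_nonpositive_r(self):
        with pytest.warns(UserWarning):
            assert doubling_time(-0.1) == math.inf

    def test_finite_rate(self):
        assert finite_rate(0.0841) == pytest.approx(1.0877, abs=5e-5)
        assert finite_rate(0.0) == 1.0
        assert math.log(finite_rate(0.3333)) == pytest.approx(0.3333,
                                                              abs=1e-12)


class TestLotka:
    def test_point_mass_matches_birch(self):
        sch = schedule_of([[7.0, 1.0, 5.0]])
        r_l = intrinsic_rate_lotka(sch)
        assert r_l == pytest.approx(math.log(5.0) / 7.0, abs=1e-10)

    def test_two_row_grid_scan_oracle(self):
        sch = schedule_of([[1.0, 1.0, 2.0], [2.0, 1.0, 2.0]])
        r = intrinsic_rate_lotka(sch)
        grid = np.linspace(0.5, 1.5, 2_000_001)
        resid = np.abs(2 * np.exp(-grid) + 2 * np.exp(-2 * grid) - 1)
        assert r == pytest.approx(grid[resid.argmin()], abs=1e-6)
        assert abs(2 * math.exp(-r) + 2 * math.exp(-2 * r) - 1) <= 1e-10

    @given(random_schedules())
    @settings(max_examples=50, deadline=None)
    def test_residual_property(self, sch):
        r = intrinsic_rate_lotka(sch)
        assert abs(float(np.exp(-r * sch.x) @ sch.lxmx) - 1.0) <= 1e-8

    @given(random_schedules(), st.floats(1.1, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_scaling_mx_raises_r(self, sch, c):
        r1 = intrinsic_rate_lotka(sch)
        scaled = LifeTableSchedule(x=sch.x, lx=sch.lx, mx=c * sch.mx)
        assert net_reproductive_rate(scaled) == pytest.approx(
            c * net_reproductive_rate(sch), rel=1e-9)
        assert generation_time(scaled) == pytest.approx(generation_time(sch),
                                                        rel=1e-9)
        assert intrinsic_rate_lotka(scaled) > r1

    @given(random_schedules(), st.floats(0.5, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_shifting_ages_lowers_r(self, sch, delta):
        if net_reproductive_rate(sch) <= 1.0:
            return
        shifted = LifeTableSchedule(x=sch.x + delta, lx=sch.lx, mx=sch.mx)
        assert net_reproductive_rate(shifted) == pytest.approx(
            net_reproductive_rate(sch))
        assert intrinsic_rate_lotka(shifted) < intrinsic_rate_lotka(sch)

    @given(random_schedules())
    @settings(max_examples=30, deadline=None)
    def test_derived_identities(self, sch):
        p = compute_parameters(sch, r_method="lotka")
        if p.r_m > 0:
            assert p.dt * p.r_m == pytest.approx(math.log(2.0), abs=1e-12)
        assert math.log(p.lam) == pytest.approx(p.r_m, abs=1e-12)


class TestJackknife:
    def _records(self, n=5):
        return [IndividualRecord(f"f{i}", "female", adult_longevity=4.0,
                                 daily_eggs=[0, 3, 2, 1]) for i in range(n)]

    def test_identical_females_zero_width_ci(self):
        jk = jackknife_parameters(self._records(), r_method="birch")
        for lo, hi in jk.ci_95.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_point_estimate_is_all_female_estimate(self):
        recs = self._records()
        recs.append(IndividualRecord("f9", "female", adult_longevity=6.0,
                                     daily_eggs=[1, 1, 1, 1, 1, 1]))
        jk = jackknife_parameters(recs, r_method="birch")
        sch = build_life_table(recs)
        p = compute_parameters(sch, r_method="birch")
        assert jk.r0 == pytest.approx(p.r0)
        assert jk.r_m == pytest.approx(p.r_m)

    def test_requires_three_females(self):
        with pytest.raises(SampleSizeError):
            jackknife_parameters(self._records(2))

    def test_deterministic(self):
        recs = self._records()
        a = jackknife_parameters(recs, r_method="lotka")
        b = jackknife_parameters(recs, r_method="lotka")
        assert a.ci_95 == b.ci_95

    def test_bootstrap_alternative_seeded(self):
        recs = self._records()
        recs.append(IndividualRecord("f9", "female", adult_longevity=6.0,
                                     daily_eggs=[2, 1, 1, 1, 1, 1]))
        a = bootstrap_parameters(recs, n_boot=200, seed=4)
        b = bootstrap_parameters(recs, n_boot=200, seed=4)
        assert a.ci_95 == b.ci_95
        lo, hi = a.ci_95["R0"]
        assert lo <= a.r0 <= hi


class TestReproductionSummary:
    def test_worked_example(self):
        rec = IndividualRecord("f1", "female", adult_longevity=8.0,
                               daily_eggs=[0, 0, 3, 2, 0, 1, 0, 0])
        s = reproduction_summary([rec])
        assert s.pre_oviposition.mean == pytest.approx(2.0)
        assert s.oviposition.mean == pytest.approx(4.0)
        assert s.post_oviposition.mean == pytest.approx(2.0)
        assert s.fecundity.mean == pytest.approx(1.5)

    def test_zero_layer_flagged(self):
        layer = IndividualRecord("f1", "female", adult_longevity=4.0,
                                 daily_eggs=[1, 1, 0, 0])
        barren = IndividualRecord("f2", "female", adult_longevity=4.0,
                                  daily_eggs=[0, 0, 0, 0])
        s = reproduction_summary([layer, barren])
        assert s.zero_layers == ("f2",)
        assert s.fecundity.n == 1

    def test_fertility_percent(self):
        rec = IndividualRecord("f1", "female", adult_longevity=2.0,
                               daily_eggs=[5, 5], eggs_hatched=6)
        s = reproduction_summary([rec])
        assert s.fertility.mean == pytest.approx(60.0)

    def test_adult_days_denominator(self):
        rec = IndividualRecord("f1", "female", adult_longevity=8.0,
                               daily_eggs=[0, 0, 3, 2, 0, 1, 0, 0])
        s = reproduction_summary([rec], fecundity_denominator="adult_days")
        assert s.fecundity.mean == pytest.approx(6.0 / 8.0)


class TestLongevitySummary:
    def test_simple_group(self):
        recs = [IndividualRecord(f"m{i}", "male", adult_longevity=v)
                for i, v in enumerate([10.0, 20.0, 30.0])]
        out = longevity_summary(recs, by=["sex"])
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(20.0)
        assert row["se"] == pytest.approx(5.7735, abs=1e-3)
        assert (row["min"], row["max"]) == (10.0, 30.0)

    def test_single_record_missing_se(self):
        recs = [IndividualRecord("m1", "male", adult_longevity=12.0)]
        out = longevity_summary(recs, by=["sex"])
        assert math.isnan(out.iloc[0]["se"])

    def test_groups_by_sex_and_treatment(self):
        recs = [
            IndividualRecord("f1", "female", adult_longevity=10.0, treatment="a"),
            IndividualRecord("f2", "female", adult_longevity=20.0, treatment="b"),
            IndividualRecord("m1", "male", adult_longevity=5.0, treatment="a"),
        ]
        out = longevity_summary(recs)
        assert len(out) == 3
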