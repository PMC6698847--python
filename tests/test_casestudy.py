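import pytest

from memchrom.casestudy import (
    CaseStudySpec,
    PressureModel,
    batch_capacity,
    batch_report,
    batch_runtime,
    case_study_table,
    check_pressure,
    compare,
    cycle_time,
    eluent_consumption,
    pressure_drop,
    productivity_per_cycle,
    sequential_report,
    size_sequential,
)


def spec_for(fermenter: float, runs: int, module: float = 5.0) -> CaseStudySpec:
    return CaseStudySpec(fermenter_volume=fermenter, batch_runs=runs, module_volume=module)


class TestPressure:
    def test_module_train_backpressure(self):
        model = PressureModel(per_module_coefficient=0.2, instrument_offset=0.0)
        assert pressure_drop(3.0, 4, model) == pytest.approx(2.4)

    def test_total_with_instruments_within_limit(self):
        model = PressureModel()
        total = check_pressure(3.0, 4, model)
        assert total == pytest.approx(3.5)
        assert total <= model.limit

    def test_offset_only_at_vanishing_flow(self):
        model = PressureModel()
        assert pressure_drop(1e-12, 4, model) == pytest.approx(1.1)

    def test_violation_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            check_pressure(5.0, 4, PressureModel())


class TestCapacityArithmetic:
    def test_batch_capacity_small_scale(self):
        assert batch_capacity(spec_for(20, 3)) == pytest.approx(20 * 5 / 15)

    def test_batch_capacity_is_scale_invariant(self):
        assert batch_capacity(spec_for(2000, 300)) == pytest.approx(
            batch_capacity(spec_for(20, 3))
        )

    def test_zero_titer_gives_zero(self):
        spec = CaseStudySpec(fermenter_volume=20, batch_runs=3, titer=1e-12)
        assert batch_capacity(spec) == pytest.approx(0.0, abs=1e-10)

    def test_cycle_times(self):
        assert cycle_time(6.6667, 5, 5, 15, 5) == pytest.approx(3.2667, abs=2e-4)
        assert cycle_time(11.4, 5, 3, 15, 5) == pytest.approx(3.76, abs=1e-9)
        assert cycle_time(6.0, 5, 5, 0, 5) == pytest.approx(0.24)

    def test_productivities(self):
        assert productivity_per_cycle(20 / 3, 49 / 15) == pytest.approx(2938.8, abs=0.1)
        assert productivity_per_cycle(11.4, 3.76) == pytest.approx(4366.0, abs=0.1)
        assert productivity_per_cycle(0.0, 3.0) == 0.0

    def test_eluent_consumption(self):
        assert eluent_consumption(20 / 3, 5, 15) == pytest.approx(2.45, abs=1e-9)
        assert eluent_consumption(11.4, 5, 15) == pytest.approx(1.516, abs=1e-3)
        # elution-free limit: capacity = titer x 1 CV of feed
        assert eluent_consumption(5.0, 5.0, 0.0) == pytest.approx(1.0 / 5.0)

    def test_sequential_sizing(self):
        total, cycles = size_sequential(spec_for(2000, 300))
        assert total == 877 and cycles == 44
        total, _ = size_sequential(spec_for(200, 30))
        assert total == 88
        spec1 = CaseStudySpec(fermenter_volume=20, batch_runs=3, capacity_gain_factor=1.0)
        total, _ = size_sequential(spec1)
        assert total == 15

    def test_batch_runtimes(self):
        assert batch_runtime(spec_for(20, 3)) == pytest.approx(0.163, abs=5e-3)
        assert batch_runtime(spec_for(200, 30)) == pytest.approx(1.633, abs=5e-3)
        assert batch_runtime(spec_for(2000, 300)) == pytest.approx(16.33, abs=5e-3)


class TestCompare:
    def test_printed_deltas(self):
        b, s = batch_report(spec_for(2000, 300)), sequential_report(spec_for(2000, 300))
        deltas = compare(b, s)
        assert deltas["productivity_pct"] == pytest.approx(48.5, abs=0.1)
        assert deltas["eluent_pct"] == pytest.approx(-38.0, abs=0.2)
        assert deltas["capacity_pct"] == pytest.approx(71.0, abs=1e-9)

    def test_identical_reports_give_zero_deltas(self):
        b = batch_report(spec_for(20, 3))
        deltas = compare(b, b)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in deltas.values())

    def test_antisymmetry_on_relative_scale(self):
        b, s = batch_report(spec_for(20, 3)), sequential_report(spec_for(20, 3))
        fwd, back = compare(b, s), compare(s, b)
        for key in fwd:
            assert (1 + fwd[key] / 100) * (1 + back[key] / 100) == pytest.approx(1.0)


class TestInvariants:
    @pytest.mark.parametrize("module_volume", [0.15, 5.0, 50.0])
    def test_module_volume_cancels(self, module_volume):
        spec = spec_for(2000, 300, module=5.0)
        ref_b = batch_report(spec)
        scaled = CaseStudySpec(
            fermenter_volume=2000, batch_runs=int(300 * 5.0 / module_volume),
            module_volume=module_volume,
        )
        rep = batch_report(scaled)
        assert rep.productivity_per_cycle == pytest.approx(ref_b.productivity_per_cycle)
        assert rep.eluent_consumption == pytest.approx(ref_b.eluent_consumption)

    def test_eluent_decreases_with_capacity(self):
        values = [eluent_consumption(c, 5.0, 15.0) for c in (5.0, 8.0, 12.0, 20.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_table_has_batch_and_sequential_columns(self):
        table = case_study_table({"2000 L": spec_for(2000, 300)})
        assert "2000 L batch" in table.columns and "2000 L sequential" in table.columns
        assert table.loc["Eluent consumption (L/g)", "2000 L batch"] == pytest.approx(2.45)
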