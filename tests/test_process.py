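import numpy as np
import pytest

from memchrom.casestudy import PressureModel
from memchrom.fixtures import (
    FixtureSpec,
    default_elution_protocol,
    make_feed,
    make_module,
    make_symmetric_module,
)
from memchrom.process import (
    CycleResult,
    FractionPool,
    ICCCConfig,
    SequentialConfig,
    detect_cyclic_steady_state,
    run_batch_cycle,
    run_iccc,
    run_sequential,
)

RES = (6, 6, 6, 6, 6)  # coarse grid keeps the multi-module tests quick


@pytest.fixture(scope="module")
def protocol():
    return default_elution_protocol("IEX")


@pytest.fixture(scope="module")
def feed_cs():
    return make_feed(preset="case_study")


def iex(name="m"):
    return make_module(resin="IEX", name=name, resolution=RES)


class TestBatchCycle:
    def test_zero_load_gives_empty_pool(self, feed_cs, protocol):
        result = run_batch_cycle(iex(), feed_cs, 0.0, protocol)
        assert result.product_mass["product"] == pytest.approx(0.0, abs=1e-6)
        assert result.utilization == pytest.approx(0.0, abs=1e-9)

    def test_light_load_is_fully_recovered(self, feed_cs, protocol):
        result = run_batch_cycle(iex(), feed_cs, 1.0, protocol, load_flow=3.0)
        assert result.eluted_mass["product"] == pytest.approx(
            result.loaded_mass["product"], rel=0.01
        )

    def test_utilization_below_static_capacity(self, feed_cs, protocol):
        from memchrom.process import _saturation_capacity

        module = iex()
        result = run_batch_cycle(module, feed_cs, 3.0, protocol, load_flow=3.0)
        q_static = _saturation_capacity(module, feed_cs, 0.02)
        assert 0.0 < result.utilization < q_static

    def test_pressure_violation_blocks_simulation(self, feed_cs, protocol):
        tight = PressureModel(per_module_coefficient=1.0, instrument_offset=1.0, limit=2.0)
        with pytest.raises(ValueError, match="exceeds"):
            run_batch_cycle(iex(), feed_cs, 3.0, protocol, load_flow=3.0,
                            pressure_model=tight)


class TestSequential:
    def test_single_module_reduces_to_breakthrough_batch(self, feed_cs, protocol):
        config = SequentialConfig(
            modules=(iex("solo"),), elution_protocol=protocol, load_flow=3.0,
        )
        results = run_sequential(config, feed_cs, n_cycles=1)
        assert len(results) == 1
        r = results[0]
        assert r.loaded_mass["product"] > 0
        assert r.eluted_mass["product"] == pytest.approx(r.loaded_mass["product"], rel=0.05)

    def test_two_modules_raise_head_utilization(self, feed_cs, protocol):
        r1 = run_sequential(
            SequentialConfig(modules=(iex("a"),), elution_protocol=protocol),
            feed_cs, n_cycles=1,
        )[0]
        r2 = run_sequential(
            SequentialConfig(modules=(iex("b0"), iex("b1")), elution_protocol=protocol),
            feed_cs, n_cycles=1,
        )[0]
        assert r2.utilization > r1.utilization

    def test_results_do_not_depend_on_module_names(self, feed_cs, protocol):
        def run(names):
            config = SequentialConfig(
                modules=tuple(iex(n) for n in names), elution_protocol=protocol,
            )
            return run_sequential(config, feed_cs, n_cycles=1)[0]

        ra, rb = run(["x", "y"]), run(["y", "x"])
        assert ra.loaded_mass["product"] == pytest.approx(rb.loaded_mass["product"], rel=1e-9)
        assert ra.utilization == pytest.approx(rb.utilization, rel=1e-9)

    def test_pressure_checked_before_any_simulation(self, feed_cs, protocol):
        config = SequentialConfig(
            modules=tuple(iex(f"p{i}") for i in range(4)),
            elution_protocol=protocol,
            load_flow=5.0,
            pressure_model=PressureModel(),  # 4*0.2*5 + 1.1 = 5.1 > 4 bar
        )
        with pytest.raises(ValueError, match="exceeds"):
            run_sequential(config, feed_cs, n_cycles=1)


class TestSteadyStateDetection:
    @staticmethod
    def _cycle(i, product, recycle):
        return CycleResult(
            cycle=i, chromatograms={}, loaded_mass={}, eluted_mass={},
            recycled_mass={"iex": {"product": recycle}}, product_mass={"product": product},
            waste_mass={}, utilization=0.0,
        )

    def test_identical_cycles_reach_steady_state_immediately(self):
        results = [self._cycle(0, 10.0, 2.0), self._cycle(1, 10.0, 2.0)]
        reached, idx = detect_cyclic_steady_state(results, 0.01)
        assert reached and idx == 1

    def test_monotone_accumulation_is_not_steady(self):
        results = [self._cycle(i, 10.0 + 5 * i, 2.0 * (i + 1)) for i in range(4)]
        reached, _ = detect_cyclic_steady_state(results, 0.01)
        assert not reached

    def test_needs_two_cycles(self):
        assert detect_cyclic_steady_state([self._cycle(0, 1, 1)]) == (False, None)


class TestICCCConfigValidation:
    def _base(self):
        return dict(
            iex=make_module(resin="IEX", resolution=RES),
            hic=make_module(resin="HIC", resolution=RES),
            iex_protocol=default_elution_protocol("IEX", flow=1.0, gradient_cv=1.0),
            hic_protocol=default_elution_protocol("HIC", flow=1.0, gradient_cv=1.0),
            cut_points_iex=(3.0, 5.4, 6.5),
            cut_points_hic=(3.0, 4.2, 5.6),
        )

    def test_cut_points_must_increase(self):
        kwargs = self._base()
        kwargs["cut_points_iex"] = (5.0, 4.0, 6.0)
        with pytest.raises(ValueError, match="increasing"):
            ICCCConfig(**kwargs)

    def test_incomplete_routing_rejected(self):
        kwargs = self._base()
        kwargs["routing_iex"] = {"front": "iex", "middle": "hic"}
        with pytest.raises(ValueError, match="fractions"):
            ICCCConfig(**kwargs)

    def test_unknown_destination_rejected(self):
        kwargs = self._base()
        kwargs["routing_hic"] = {"front": "hic", "middle": "moon", "tail": "iex"}
        with pytest.raises(ValueError, match="destination"):
            ICCCConfig(**kwargs)


class TestICCC:
    def test_degenerate_routing_equals_batch_elution(self, feed_cs):
        # everything collected as product, nothing recycled: the IEX side of one
        # cycle is just a batch run
        protocol = default_elution_protocol("IEX", flow=1.0, gradient_cv=1.0)
        config = ICCCConfig(
            iex=make_module(resin="IEX", name="i", resolution=RES),
            hic=make_module(resin="HIC", name="h", resolution=RES),
            iex_protocol=protocol,
            hic_protocol=default_elution_protocol("HIC", flow=1.0, gradient_cv=1.0),
            cut_points_iex=(0.01, 0.02, 12.9),
            cut_points_hic=(0.01, 0.02, 12.9),
            routing_iex={"front": "waste", "middle": "product", "tail": "waste"},
            routing_hic={"front": "waste", "middle": "product", "tail": "waste"},
            load_cv=3.0,
            max_cycles=1,
        )
        results = run_iccc(config, feed_cs)
        batch = run_batch_cycle(
            make_module(resin="IEX", name="i2", resolution=RES), feed_cs, 3.0,
            protocol, load_flow=3.0,
        )
        assert results[0].product_mass["product"] == pytest.approx(
            batch.eluted_mass["product"], rel=0.02
        )

    def test_cycle_mass_conservation(self, feed_cs):
        config = ICCCConfig(
            iex=make_module(resin="IEX", name="i", resolution=RES),
            hic=make_module(resin="HIC", name="h", resolution=RES),
            iex_protocol=default_elution_protocol("IEX", flow=1.0, gradient_cv=1.0),
            hic_protocol=default_elution_protocol("HIC", flow=1.0, gradient_cv=1.0),
            cut_points_iex=(3.0, 5.4, 6.5),
            cut_points_hic=(3.0, 4.2, 5.6),
            load_cv=3.0,
            max_cycles=2,
        )
        results = run_iccc(config, feed_cs)
        for res in results:
            for name in ("product", "weak_binder"):
                eluted = res.eluted_mass[name]
                routed = (
                    res.product_mass.get(name, 0.0)
                    + res.waste_mass.get(name, 0.0)
                    + sum(d.get(name, 0.0) for d in res.recycled_mass.values())
                )
                assert routed == pytest.approx(eluted, rel=0.01, abs=1e-3)


class TestFractionPool:
    def test_volume_weighted_concentrations(self):
        pool = FractionPool()
        pool.add(2.0, {"p": 4.0})
        pool.add(2.0, {"p": 0.0, "w": 2.0})
        conc = pool.concentrations()
        assert conc["p"] == pytest.approx(1.0)
        assert conc["w"] == pytest.approx(0.5)

    def test_empty_pool_has_zero_concentration(self):
        pool = FractionPool()
        pool.add(0.0, {"p": 0.0})
        assert pool.concentrations()["p"] == 0.0
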