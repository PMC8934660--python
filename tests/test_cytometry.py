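"""Flow-cytometry derived metrics against constructed and generated tables."""

import numpy as np
import pandas as pd
import pytest

from gliastat.cytometry import (
    apoptosis_gating,
    coculture_uptake_percent,
    default_gate,
    highly_phagocytic_fraction,
    phagocytic_activity,
    phagocytosis_percent,
    relative_growth,
    relative_mfi,
)
from gliastat.simulate import Population, simulate_flow_events


def _table(values, channel="FL1_green"):
    return pd.DataFrame({channel: values})


class TestPhagocytosis:
    def test_control_subtraction(self):
        sample = _table([10.0] * 10 + [0.0] * 90)
        control = _table([10.0] * 2 + [0.0] * 98)
        assert phagocytosis_percent(sample, control, "FL1_green", 5.0) == pytest.approx(8.0)

    def test_floor_at_zero(self):
        sample = _table([0.0] * 100)
        control = _table([10.0] * 5 + [0.0] * 95)
        assert phagocytosis_percent(sample, control, "FL1_green", 5.0) == 0.0

    def test_generator_mixture_recovered(self):
        pops = [
            Population("neg", {"FL1_green": 100.0}, {"FL1_green": 20.0}, 0.85),
            Population("pos", {"FL1_green": 1000.0}, {"FL1_green": 50.0}, 0.15),
        ]
        sample = simulate_flow_events(10_000, pops, seed=1)
        ctrl = simulate_flow_events(
            10_000,
            [
                Population("neg", {"FL1_green": 100.0}, {"FL1_green": 20.0}, 0.98),
                Population("pos", {"FL1_green": 1000.0}, {"FL1_green": 50.0}, 0.02),
            ],
            seed=2,
        )
        pct = phagocytosis_percent(sample, ctrl, "FL1_green", 500.0)
        se = 100 * np.sqrt(0.15 * 0.85 / 10_000 + 0.02 * 0.98 / 10_000)
        assert abs(pct - 13.0) < 3 * se

    def test_beads_per_cell_and_high_fraction(self):
        assert phagocytic_activity(3000.0, 1000.0) == pytest.approx(3.0)
        assert highly_phagocytic_fraction([1, 2, 3, 5]) == pytest.approx(50.0)
        assert highly_phagocytic_fraction([2, 2, 2]) == 0.0  # strict > 2
        with pytest.raises(ValueError):
            phagocytic_activity(100.0, 0.0)


class TestGrowth:
    def test_anchor_is_one(self):
        g = relative_growth({24.0: 800.0, 48.0: 400.0})
        assert g[24.0] == pytest.approx(1.0)

    def test_halving_mfi_doubles_growth(self):
        g = relative_growth({24.0: 800.0, 48.0: 400.0})
        assert g[48.0] == pytest.approx(2.0)

    def test_exponential_dilution_series(self):
        mfi = {t: 1000.0 * 2 ** (-(t - 24.0) / 24.0) for t in (24.0, 48.0, 72.0)}
        g = relative_growth(mfi)
        assert list(np.round(g.values, 6)) == [1.0, 2.0, 4.0]

    def test_missing_anchor_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            relative_growth({48.0: 1.0})

    def test_scale_invariance(self):
        a = relative_growth({24.0: 800.0, 48.0: 300.0})
        b = relative_growth({24.0: 8.0, 48.0: 3.0})
        assert np.allclose(a, b)


class TestRelativeMfi:
    def test_identical_is_one(self):
        t = _table([5.0, 7.0, 9.0], "violet")
        assert relative_mfi(t, t.copy(), "violet") == pytest.approx(1.0)

    def test_scaling(self):
        ctrl = _table([4.0, 6.0], "violet")
        assert relative_mfi(_table([10.0, 15.0], "violet"), ctrl, "violet") == pytest.approx(2.5)

    def test_generator_ratio(self):
        ctrl = simulate_flow_events(
            10_000, [Population("c", {"FL1_green": 500.0}, {"FL1_green": 50.0}, 1.0)], seed=3
        )
        sample = simulate_flow_events(
            10_000, [Population("s", {"FL1_green": 900.0}, {"FL1_green": 50.0}, 1.0)], seed=4
        )
        assert relative_mfi(sample, ctrl, "FL1_green") == pytest.approx(1.8, abs=0.02)


class TestApoptosis:
    def test_all_double_negative_viable(self):
        ev = pd.DataFrame({"annexin": [1.0] * 5, "pi": [1.0] * 5})
        out = apoptosis_gating(ev, "annexin", "pi", 10.0, 10.0)
        assert out["viable"] == 1.0
        assert sum(out.values()) == pytest.approx(1.0)

    def test_constructed_quadrants(self):
        ev = pd.DataFrame(
            {
                "annexin": [100.0] * 10 + [100.0] * 20 + [0.0] * 30 + [0.0] * 40,
                "pi": [0.0] * 10 + [100.0] * 20 + [100.0] * 30 + [0.0] * 40,
            }
        )
        out = apoptosis_gating(ev, "annexin", "pi", 50.0, 50.0)
        assert out == {
            "apoptotic": pytest.approx(0.1),
            "late_apoptotic": pytest.approx(0.2),
            "necrotic": pytest.approx(0.3),
            "viable": pytest.approx(0.4),
        }

    def test_generator_mixture_recovered(self):
        pops = [
            Population("apo", {"annexin": 1000.0, "pi": 0.0}, {"annexin": 50.0, "pi": 10.0}, 0.05),
            Population("late", {"annexin": 1000.0, "pi": 1000.0}, {"annexin": 50.0, "pi": 50.0}, 0.10),
            Population("nec", {"annexin": 0.0, "pi": 1000.0}, {"annexin": 10.0, "pi": 50.0}, 0.05),
            Population("ok", {"annexin": 0.0, "pi": 0.0}, {"annexin": 10.0, "pi": 10.0}, 0.80),
        ]
        ev = simulate_flow_events(10_000, pops, seed=5)
        out = apoptosis_gating(ev, "annexin", "pi", 500.0, 500.0)
        for key, w in [("apoptotic", 0.05), ("late_apoptotic", 0.10), ("necrotic", 0.05), ("viable", 0.80)]:
            assert abs(out[key] - w) < 3 * np.sqrt(w * (1 - w) / 10_000)


class TestUptakeAndGates:
    def test_no_ctv_positive_is_zero(self):
        ev = pd.DataFrame({"cfse": [100.0] * 10, "violet": [0.0] * 10})
        assert coculture_uptake_percent(ev, "cfse", "violet", 50.0, 50.0) == 0.0

    def test_twelve_of_hundred(self):
        ev = pd.DataFrame({"cfse": [100.0] * 100, "violet": [100.0] * 12 + [0.0] * 88})
        assert coculture_uptake_percent(ev, "cfse", "violet", 50.0, 50.0) == pytest.approx(12.0)

    def test_generator_uptake_fraction(self):
        pops = [
            Population("uptake", {"cfse": 500.0, "violet": 800.0}, {"cfse": 30.0, "violet": 40.0}, 0.2),
            Population("plain", {"cfse": 500.0, "violet": 0.0}, {"cfse": 30.0, "violet": 10.0}, 0.8),
        ]
        ev = simulate_flow_events(10_000, pops, seed=6)
        pct = coculture_uptake_percent(ev, "cfse", "violet", 100.0, 400.0)
        assert abs(pct - 20.0) < 3 * 100 * np.sqrt(0.2 * 0.8 / 10_000)

    def test_default_gate_is_control_quantile(self):
        ctrl = _table(np.linspace(0, 100, 1001))
        assert default_gate(ctrl, "FL1_green", 0.99) == pytest.approx(99.0)

    def test_no_gated_events_raises(self):
        ev = pd.DataFrame({"cfse": [0.0], "violet": [0.0]})
        with pytest.raises(ValueError, match="CFSE"):
            coculture_uptake_percent(ev, "cfse", "violet", 50.0, 50.0)


class TestFlowSimulator:
    def test_single_population_uniform_labels(self):
        ev = simulate_flow_events(100, [Population("only", {"x": 10.0}, {"x": 1.0}, 1.0)], seed=0)
        assert (ev["truth_label"] == "only").all()

    def test_weight_recovery_and_determinism(self):
        pops = [
            Population("a", {"x": 0.0}, {"x": 1.0}, 0.2),
            Population("b", {"x": 100.0}, {"x": 1.0}, 0.8),
        ]
        ev1 = simulate_flow_events(10_000, pops, seed=7)
        ev2 = simulate_flow_events(10_000, pops, seed=7)
        assert ev1.equals(ev2)
        frac = (ev1["truth_label"] == "a").mean()
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 10_000)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_flow_events(10, [Population("a", {"x": 0.0}, {"x": 1.0}, 0.5)], seed=0)
        with pytest.raises(ValueError, match="negative"):
            simulate_flow_events(
                10, [Population("a", {"x": 0.0}, {"x": -1.0}, 1.0)], seed=0
            )
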