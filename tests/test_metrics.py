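"""Trace analyses, exercised on synthetic traces with known structure."""

import numpy as np
import pytest

from neurofp import BinaryPattern, SimulationTrace, make_series_protocol
from neurofp.metrics import (LONG_TERM, NC, SHORT_TERM, UNDETERMINED, WLC,
                             WTA, classify_competition, classify_memory,
                             closed_form_spontaneous, coexistence_count,
                             detect_propagation, propagation_velocity,
                             steady_level, survival_time,
                             total_activity_mode)

N = 2500


def make_trace(series: dict, T: int, n=5) -> SimulationTrace:
    labels = ["spontaneous"] + [k for k in series if k != "spontaneous"]
    counts = np.zeros((T, len(labels)), dtype=np.int32)
    for k, lab in enumerate(labels):
        if lab in series:
            counts[:, k] = series[lab]
    return SimulationTrace(counts, labels, N,
                           meta={"fingerprint_length": n})


def plateau(T, start, level, rise=0, end=None, noise=0.0, seed=0):
    """0 until start, linear rise, plateau at `level` until `end`."""
    rng = np.random.default_rng(seed)
    x = np.zeros(T)
    r = max(rise, 1)
    x[start:start + r] = np.linspace(0, level, r)
    stop = end if end is not None else T
    x[start + r:stop] = level
    if noise:
        x += rng.normal(0, noise, T) * (x > 0)
    return np.clip(x, 0, N).astype(np.int32)


class TestSteadyLevel:
    def test_time_mean(self):
        tr = make_trace({"A": plateau(1000, 100, 300)}, 1000)
        est = steady_level(tr, "A", (500, 1000))
        assert est.mean == pytest.approx(300)
        assert est.se is None

    def test_across_run_se(self):
        trs = [make_trace({"A": plateau(1000, 100, lvl)}, 1000)
               for lvl in (290, 300, 310)]
        est = steady_level(trs, "A", (500, 1000))
        assert est.mean == pytest.approx(300)
        assert est.se == pytest.approx(10 / np.sqrt(3))

    def test_absent_label_is_zero(self):
        tr = make_trace({"A": plateau(1000, 100, 300)}, 1000)
        assert steady_level(tr, "nope", (0, 1000)).mean == 0

    def test_empty_window_rejected(self):
        tr = make_trace({}, 10)
        with pytest.raises(ValueError):
            steady_level(tr, "A", (5, 5))


class TestDetection:
    def test_threshold_split(self):
        hi = make_trace({"A": plateau(2000, 500, 300)}, 2000)
        lo = make_trace({"A": plateau(2000, 500, 10)}, 2000)
        assert detect_propagation(hi, "A", (500, 2000)) == "detected"
        assert detect_propagation(lo, "A", (500, 2000)) == "not-detected"


class TestVelocity:
    def test_ramp(self):
        """Steady 400 reached after a linear 100-step rise from onset: the
        centred-smoothed count crosses 75% of steady ~75 steps in, so the
        implied rise time lands near that mark."""
        tr = make_trace({"A": plateau(3000, 500, 400, rise=100)}, 3000)
        v = propagation_velocity(tr, "A", (500, 3000))
        t_rise = 400 / v
        assert 55 <= t_rise <= 120

    def test_undetected_is_error(self):
        tr = make_trace({"A": plateau(3000, 500, 5)}, 3000)
        with pytest.raises(ValueError):
            propagation_velocity(tr, "A", (500, 3000))


class TestMemory:
    def test_persistent_is_long_term(self):
        tr = make_trace({"A": plateau(30_000, 5000, 400)}, 30_000)
        assert classify_memory(tr, "A", 15_000) == LONG_TERM

    def test_decay_to_zero_is_short_term(self):
        tr = make_trace({"A": plateau(30_000, 5000, 400, end=18_000)},
                        30_000)
        assert classify_memory(tr, "A", 15_000) == SHORT_TERM

    def test_still_decaying_is_undetermined(self):
        """A trace that has fallen below the detection level on average but
        is still clearly nonzero at the end has not resolved."""
        sig = plateau(30_000, 5000, 400, end=None).astype(float)
        sig[15_000:] = np.maximum(400 - 0.04 * np.arange(15_000), 45)
        tr = make_trace({"A": sig.astype(np.int32)}, 30_000)
        assert classify_memory(tr, "A", 15_000) == UNDETERMINED

    def test_short_trace_rejected(self):
        tr = make_trace({"A": plateau(6000, 100, 100)}, 6000)
        with pytest.raises(ValueError):
            classify_memory(tr, "A", 5000)


class TestSurvival:
    def test_disappearance_time(self):
        tr = make_trace({"A": plateau(20_000, 1000, 300, end=12_000)},
                        20_000)
        assert survival_time(tr, "A", 10_000) == 2000

    def test_already_absent_is_zero(self):
        tr = make_trace({"A": plateau(20_000, 1000, 300, end=5000)}, 20_000)
        assert survival_time(tr, "A", 10_000) == 0

    def test_censored_is_none(self):
        tr = make_trace({"A": plateau(20_000, 1000, 300)}, 20_000)
        assert survival_time(tr, "A", 10_000) is None


class TestCompetition:
    A = BinaryPattern((1, 0, 1, 0, 1), "A")
    B = BinaryPattern((1, 1, 0, 1, 1), "B")

    def proto(self):
        return make_series_protocol(self.A, self.B, (1,), t0=5000,
                                    on=10_000, off=5000, repeats=4)

    def test_single_label_is_nc(self):
        tr = make_trace({"A": plateau(10_000, 100, 300)}, 10_000)
        assert classify_competition(tr, ["A"]) == NC

    def test_no_concurrency_is_nc(self):
        T = 65_000
        a = plateau(T, 5000, 300, end=15_500)
        b = plateau(T, 20_000, 300, end=30_500)
        tr = make_trace({"A": a, "B": b}, T)
        assert classify_competition(tr, ["A", "B"], self.proto()) == NC

    def test_each_handoff_resolves_to_wta(self):
        T = 65_000
        a = plateau(T, 5000, 300, end=21_000)      # dies 1000 into ep 2
        a += plateau(T, 35_000, 300, end=51_000)   # returns, dies again
        b = plateau(T, 20_000, 300, end=36_000)
        b += plateau(T, 50_000, 300)
        tr = make_trace({"A": a, "B": b}, T)
        assert classify_competition(tr, ["A", "B"], self.proto()) == WTA

    def test_sustained_coexistence_is_wlc(self):
        T = 65_000
        a = plateau(T, 5000, 300)                  # never dies
        b = plateau(T, 20_000, 300)
        tr = make_trace({"A": a, "B": b}, T)
        assert classify_competition(tr, ["A", "B"], self.proto()) == WLC

    def test_parallel_concurrency_is_wlc(self):
        T = 20_000
        tr = make_trace({"A": plateau(T, 1000, 200),
                         "B": plateau(T, 1000, 200)}, T)
        assert classify_competition(tr, ["A", "B"]) == WLC


class TestCoexistence:
    def test_counts_labels_above_threshold(self):
        T = 1000
        tr = make_trace({"A": np.full(T, 100, np.int32),
                         "B": np.full(T, 19, np.int32),
                         "C": np.full(T, 3, np.int32)}, T)
        assert coexistence_count(tr, ["A", "B", "C"], (0, T)) == 2.0
        assert coexistence_count(tr, ["A", "B", "C"], (0, T), theta=1) == 3.0

    def test_single_stimulus_at_most_one(self):
        tr = make_trace({"A": plateau(1000, 0, 50)}, 1000)
        assert coexistence_count(tr, ["A"], (500, 1000)) <= 1.0


class TestTotalActivity:
    def test_conserved_total_is_constant(self):
        T = 20_000
        spont = np.full(T, 400, np.int32)
        spont[10_000:] = 200
        stim = np.zeros(T, np.int32)
        stim[10_000:] = 200                      # stimulus replaces spont
        tr = make_trace({"spontaneous": spont, "A": stim}, T)
        assert total_activity_mode(tr, (2000, 10_000), (10_000, T)) == \
            "constant"

    def test_growth_is_increased(self):
        T = 20_000
        spont = np.full(T, 400, np.int32)
        stim = np.zeros(T, np.int32)
        stim[10_000:] = 300
        tr = make_trace({"spontaneous": spont, "A": stim}, T)
        assert total_activity_mode(tr, (2000, 10_000), (10_000, T)) == \
            "increased"

    def test_autonomous_is_constant(self):
        tr = make_trace({"spontaneous": np.full(9000, 417, np.int32)}, 9000)
        assert total_activity_mode(tr, (0, 4000), (4000, 9000)) == "constant"


class TestClosedForm:
    @pytest.mark.parametrize("p_e,expected", [
        (0.50, 1 / 3),
        (0.80, 6 / 17.25),
        (1.00, 6 / 17),
        (0.05, 1 / 6),
    ])
    def test_values(self, p_e, expected):
        assert closed_form_spontaneous(5, p_e) == pytest.approx(expected)

    def test_vanishes_as_pe_to_zero(self):
        assert closed_form_spontaneous(5, 1e-6) < 1e-5

    def test_requires_positive_pe(self):
        with pytest.raises(ValueError):
            closed_form_spontaneous(5, 0.0)
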