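"""Parameter sampling, oscillation criteria and the screen contract."""

import numpy as np
import pytest
from scipy import stats

from lwdclock.network import MODEL_II, Trace
from lwdclock.screen import (
    EmptyScreenError,
    OscillationCriteria,
    ParameterRanges,
    ScreenResult,
    assess_oscillation,
    mutant_period_table,
    sample_parameters,
    screen_variant,
    simulate_set,
)
from lwdclock.synthetic import gen_screen_fixture


def _sine_trace(period=24.0, t_end=480.0, offset=10.0, damp_tau=None):
    t = np.arange(0.0, t_end, 0.5)
    env = np.exp(-t / damp_tau) if damp_tau else 1.0
    y = offset + env * np.sin(2 * np.pi * t / period)
    vals = np.tile(y[:, None], (1, 4))
    return Trace(t, vals, ("CCA1", "PRR9", "TOC1", "LWD1"))


class TestSampling:
    def test_degenerate_interval_yields_constant(self):
        r = ParameterRanges({"v_CCA1": (3.0, 3.0), "d_CCA1": (0.5, 0.5)})
        draws = list(sample_parameters(r, 5, seed=1))
        assert all(d == {"v_CCA1": 3.0, "d_CCA1": 0.5} for d in draws)

    def test_log_uniform_law(self):
        r = ParameterRanges({"K": (1e-2, 1e2)})
        vals = np.array([d["K"] for d in sample_parameters(r, 10000, seed=2)])
        u = (np.log(vals) - np.log(1e-2)) / (np.log(1e2) - np.log(1e-2))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_seeding_contract(self):
        r = ParameterRanges.default(MODEL_II)
        a = list(sample_parameters(r, 100, seed=7))
        b = list(sample_parameters(r, 100, seed=7))
        c = list(sample_parameters(r, 100, seed=8))
        assert a == b
        assert a != c

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterRanges({"v": (0.0, 1.0)})
        with pytest.raises(ValueError):
            ParameterRanges({"v": (2.0, 1.0)})


class TestAssessOscillation:
    def test_sustained_sinusoid(self):
        v = assess_oscillation(_sine_trace())
        assert v.is_oscillatory
        assert v.period == pytest.approx(24.0, abs=0.1)

    def test_damped_signal_rejected(self):
        v = assess_oscillation(_sine_trace(damp_tau=30.0))
        assert not v.is_oscillatory
        assert v.reason == "DAMPED_OR_GROWING"

    def test_constant_trace_has_no_peaks(self):
        t = np.arange(0.0, 480.0, 0.5)
        tr = Trace(t, np.full((t.size, 4), 5.0), ("CCA1", "PRR9", "TOC1", "LWD1"))
        v = assess_oscillation(tr)
        assert not v.is_oscillatory
        assert v.reason == "NO_PEAKS"

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            OscillationCriteria(min_cycles=2)
        with pytest.raises(ValueError):
            OscillationCriteria(peak_ratio_band=(0.5, 2.5))
        with pytest.raises(ValueError):
            OscillationCriteria(min_relative_amplitude=0.0)


class TestScreen:
    def test_empty_screen(self):
        r = screen_variant(MODEL_II, n=0, seed=0)
        assert r.n_accepted == 0
        assert r.accepted_params.shape == (0, len(r.param_names))

    def test_unsatisfiable_amplitude_criterion(self):
        ranges, _, _ = gen_screen_fixture()
        crit = OscillationCriteria(min_relative_amplitude=np.inf)
        r = screen_variant(MODEL_II, ranges, n=50, seed=0, criteria=crit)
        assert r.n_accepted == 0

    def test_collapsed_ranges_accept_every_draw(self):
        ranges, criteria, _ = gen_screen_fixture(half_width_decades=0.0)
        r = screen_variant(MODEL_II, ranges, n=10, seed=3, criteria=criteria)
        assert r.n_accepted == 10

    def test_seed_determinism_and_chunk_invariance(self):
        ranges, criteria, _ = gen_screen_fixture()
        a = screen_variant(MODEL_II, ranges, n=200, seed=5, criteria=criteria)
        b = screen_variant(MODEL_II, ranges, n=200, seed=5, criteria=criteria,
                           chunk=37)
        assert a.n_accepted == b.n_accepted
        assert np.array_equal(a.accepted_params, b.accepted_params)

    def test_tightening_criteria_never_accepts_more(self, tiny_screen):
        ranges, criteria, _ = gen_screen_fixture()
        tighter = [
            OscillationCriteria(min_cycles=criteria.min_cycles + 1),
            OscillationCriteria(peak_ratio_band=(0.98, 1.02)),
            OscillationCriteria(min_relative_amplitude=0.5),
        ]
        for crit in tighter:
            r = screen_variant(MODEL_II, ranges, n=400, seed=0, criteria=crit)
            assert r.n_accepted <= tiny_screen.n_accepted

    def test_archived_set_passes_both_genotypes(self, archived_set):
        for genotype in ("WT", "lwd1lwd2"):
            tr = simulate_set(archived_set, MODEL_II, genotype)
            v = assess_oscillation(tr)
            assert v.is_oscillatory, (genotype, v)

    def test_screen_result_json_roundtrip(self, tiny_screen):
        back = ScreenResult.from_json(tiny_screen.to_json())
        assert back.n_accepted == tiny_screen.n_accepted
        assert np.allclose(back.accepted_params, tiny_screen.accepted_params)

    def test_accepted_sets_csv_export(self, tiny_screen, tmp_path):
        import pandas as pd

        path = tmp_path / "accepted.csv"
        tiny_screen.accepted_to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == tiny_screen.n_accepted
        assert set(tiny_screen.param_names) <= set(df.columns)


class TestMutantPeriods:
    def test_empty_screen_rejected(self):
        empty = screen_variant(MODEL_II, n=0, seed=0)
        with pytest.raises(EmptyScreenError):
            mutant_period_table(empty)

    def test_wild_type_normalised_to_24(self, tiny_screen):
        tab = mutant_period_table(tiny_screen, genotypes=("WT", "prr9"))
        s = tab.stats["WT"]
        assert s["median"] == s["min"] == s["max"] == 24.0

    def test_box_stats_ordered(self, tiny_screen):
        tab = mutant_period_table(tiny_screen)
        for g, s in tab.stats.items():
            if s["n"]:
                assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]

    def test_unknown_genotype_rejected(self, tiny_screen):
        with pytest.raises(ValueError):
            mutant_period_table(tiny_screen, genotypes=("elf3",))
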