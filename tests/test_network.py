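"""Structure and simulation of the simplified clock models."""

import numpy as np
import pytest

from lwdclock.network import (
    ACTIVATION,
    LWD1LWD2,
    MODEL_I,
    MODEL_II,
    WT,
    Genotype,
    Perturbation,
    Trace,
    UnknownGeneError,
    UnknownVariantError,
    apply_genotype,
    build_model,
    simulate,
)


class TestStructure:
    def test_model_ii_adds_exactly_the_lwd_cca1_activation(self):
        e1 = set(build_model(MODEL_I).edges)
        e2 = set(build_model(MODEL_II).edges)
        extra = e2 - e1
        assert len(extra) == 1
        (edge,) = extra
        assert (edge.source, edge.target, edge.sign) == ("LWD1", "CCA1", ACTIVATION)

    def test_model_i_has_no_lwd_input_on_cca1(self):
        assert not any(
            e.source == "LWD1" and e.target == "CCA1"
            for e in build_model(MODEL_I).edges
        )

    def test_parameter_count_difference_is_two(self):
        assert (
            build_model(MODEL_II).parameter_count()
            - build_model(MODEL_I).parameter_count()
        ) == 2

    def test_unknown_variant_rejected(self):
        with pytest.raises(UnknownVariantError):
            build_model("MODEL_III")

    def test_json_roundtrip(self, archived_set):
        m = build_model(MODEL_II).with_parameters(archived_set)
        m2 = type(m).from_json(m.to_json())
        assert m2 == m


class TestGenotype:
    def test_wild_type_is_identity(self, archived_set):
        m = build_model(MODEL_II).with_parameters(archived_set)
        assert apply_genotype(m, WT) == m

    def test_input_model_unchanged(self, archived_set):
        m = build_model(MODEL_II).with_parameters(archived_set)
        apply_genotype(m, LWD1LWD2)
        assert m.dose == {}

    def test_null_gene_decays_below_exponential_bound(self, archived_set):
        m = apply_genotype(
            build_model(MODEL_II).with_parameters(archived_set),
            Genotype("cca1-null", (Perturbation("CCA1", "null"),)),
        )
        x0 = np.array([2.0, 0.5, 0.5, 0.5])
        tr = simulate(m, 60.0, initial_state=x0)
        d = archived_set["d_CCA1"]
        bound = 2.0 * np.exp(-d * tr.time) + 1e-8
        assert np.all(tr.channel("CCA1") <= bound)

    def test_overexpression_adds_constitutive_production(self, archived_set):
        m = build_model(MODEL_II).with_parameters(archived_set)
        ox = apply_genotype(
            m, Genotype("TOC1ox", (Perturbation("TOC1", "overexpress", 3.0),))
        )
        # production at a state where normal TOC1 transcription is fully repressed
        x = np.array([1e6, 0.0, 0.0, 0.0])
        prod = ox._production(x)
        assert prod[m.species.index("TOC1")] >= 3.0 * archived_set["v_TOC1"]

    def test_unknown_gene_and_bad_strength_rejected(self, archived_set):
        m = build_model(MODEL_II).with_parameters(archived_set)
        with pytest.raises(UnknownGeneError):
            apply_genotype(m, Genotype("x", (Perturbation("ELF3", "null"),)))
        with pytest.raises(ValueError):
            apply_genotype(
                m, Genotype("x", (Perturbation("TOC1", "overexpress", -1.0),))
            )


class TestSimulate:
    def test_zero_production_zero_state_stays_at_origin(self, archived_set):
        # all production switched off: the origin is a fixed point
        m = apply_genotype(
            build_model(MODEL_II).with_parameters(archived_set),
            Genotype("dead", tuple(
                Perturbation(g, "null") for g in ("CCA1", "PRR9", "TOC1", "LWD1")
            )),
        )
        tr = simulate(m, 50.0, initial_state=np.zeros(4))
        assert np.allclose(tr.values, 0.0, atol=1e-12)

    def test_linear_limit_matches_closed_form(self, archived_set):
        # Huge half-saturations switch all regulation off: each gene
        # becomes dx/dt = v - d*x with x(t) = v/d * (1 - exp(-d t)).
        params = dict(archived_set)
        for k in params:
            if k.startswith("K_"):
                params[k] = 1e12
            if k.startswith("a_"):
                params[k] = 1e-300
        m = build_model(MODEL_II).with_parameters(params)
        tr = simulate(m, 25.0, initial_state=np.zeros(4))
        for g in m.species:
            v, d = params[f"v_{g}"], params[f"d_{g}"]
            expected = v / d * (1.0 - np.exp(-d * tr.time))
            err = np.abs(tr.channel(g) - expected) / (v / d)
            assert err.max() < 1e-5

    def test_value_near_equilibrium_single_gene(self, archived_set):
        params = dict(archived_set)
        for k in params:
            if k.startswith("K_"):
                params[k] = 1e12
            if k.startswith("a_"):
                params[k] = 1e-300
        m = build_model(MODEL_II).with_parameters(params)
        d = params["d_CCA1"]
        tr = simulate(m, 5.0 / d, dt_out=5.0 / d / 50)
        v = params["v_CCA1"]
        target = v / d * (1 - np.exp(-5.0))
        assert abs(tr.channel("CCA1")[-1] - target) / target < 0.01

    def test_determinism(self, archived_set):
        m = build_model(MODEL_II).with_parameters(archived_set)
        t1 = simulate(m, 120.0)
        t2 = simulate(m, 120.0)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(t1.time, t2.time)

    def test_nonnegativity_and_uniform_grid(self, archived_set):
        m = build_model(MODEL_II).with_parameters(archived_set)
        tr = simulate(m, 240.0)
        assert np.all(tr.values >= 0.0)
        assert np.allclose(np.diff(tr.time), 0.1)

    def test_trace_csv_roundtrip(self, archived_set, tmp_path):
        m = build_model(MODEL_II).with_parameters(archived_set)
        tr = simulate(m, 24.0)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = Trace.from_csv(path)
        assert back.species == tr.species
        assert np.allclose(back.values, tr.values)
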