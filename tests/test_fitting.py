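"""Global chi-square machinery: dispatch, sharing rules, fitting, bootstrap."""

import numpy as np
import pytest

import loopex.synth as sy
from loopex import (Dataset, DatasetCollection, Parameter, ParameterGraph,
                    chi2, assemble_global_model, fit_global,
                    monte_carlo_uncertainty)
from loopex.fitting import _predict, _resolve


def lite_slow_preset():
    """EXSY + IR only slow-exchange study (cheap refits for bootstrap tests)."""
    preset = sy.preset_exo10_apo()
    keep = ("pE_exo10", "kex_exo10", "R1_exo10", "S_exsy", "S_ir")
    preset.experiments = [e for e in preset.experiments
                          if e[1] in ("EXSY", "IR")]
    preset.parameters = [p for p in preset.parameters if p.name in keep]
    preset.truth = {k: v for k, v in preset.truth.items() if k in keep}
    return preset


# ---------------------------------------------------------------------------
# chi2
# ---------------------------------------------------------------------------

def test_chi2_perfect_agreement_is_zero():
    assert chi2([1.0, 2.0], [1.0, 2.0], [0.1, 0.2]) == 0.0


def test_chi2_two_sigma_point():
    assert chi2([1.0], [1.4], [0.2]) == pytest.approx(4.0)


def test_chi2_additive_over_datasets():
    o1, c1, s1 = [1.0, 2.0], [1.1, 1.8], [0.1, 0.1]
    o2, c2, s2 = [5.0], [4.0], [0.5]
    total = chi2(o1 + o2, c1 + c2, s1 + s2)
    assert total == pytest.approx(chi2(o1, c1, s1) + chi2(o2, c2, s2))


# ---------------------------------------------------------------------------
# assembly and sharing rules
# ---------------------------------------------------------------------------

def test_assemble_rejects_unlinked_free_parameter():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=0)
    graph = preset.graph()
    graph.add(Parameter(name="orphan", value=1.0, vary=True))
    with pytest.raises(ValueError, match="orphan"):
        assemble_global_model(data, graph)


def test_assemble_rejects_missing_parameter():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=0)
    data[0].param_map["p_E"] = "no_such_parameter"
    with pytest.raises(KeyError, match="no_such_parameter"):
        assemble_global_model(data, preset.graph())


def test_rna_bound_dataset_forces_open_conformation():
    """A plusRNA-tagged dataset is evaluated at p_E = 0 regardless of the
    population parameter's current value."""
    preset = sy.preset_plus_rna()
    data = sy.generate_dataset(preset, seed=0, noiseless=True)
    ds = data["spectrum_rna_dia"]
    values = dict(preset.truth)
    values["pE_rna"] = 0.35          # would shift intensity if honoured
    assert _resolve(ds, values)["p_E"] == 0.0
    np.testing.assert_allclose(_predict(ds, _resolve(ds, values)), ds.y)


def test_fixed_parameters_are_immutable():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=1)
    graph = preset.graph()
    graph["kex_exo10"].vary = False
    fit = fit_global(data, graph, maxfev=4000)
    assert fit.params["kex_exo10"] == preset.truth["kex_exo10"]
    assert "kex_exo10" not in graph.free_names


def test_all_fixed_graph_gives_deterministic_chi2():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=2)
    graph = preset.graph()
    for name in graph.names:
        graph[name].vary = False
    gm = assemble_global_model(data, graph)
    a = gm.chi2(graph.values())
    b = gm.chi2(graph.values())
    assert a == b and a > 0 and graph.n_free == 0


def test_chi2_decomposes_over_datasets():
    data, graph, truth = sy.merge_presets(sy.replica_study(), seed=3)
    gm = assemble_global_model(data, graph)
    per = gm.chi2_by_dataset(truth)
    assert gm.chi2(truth) == pytest.approx(sum(per.values()), rel=1e-15)
    assert len(per) == len(data)


def test_replica_free_parameter_enumeration():
    """The combined study exposes exactly the documented free-parameter set:
    per-complex populations and rates; shared probe shifts; per-condition
    relaxation rates; per-dataset scales; PRE rates of the open state."""
    _, graph, _ = sy.merge_presets(sy.replica_study(), seed=0)
    expected = {
        "pE_exo9", "kex_exo9", "pE_exo10", "kex_exo10",      # dynamics
        "omega_G", "omega_E",                                # shared shifts
        "R1_exo9", "R2_exo9", "R2inf_471", "R2inf_565",      # Exo9 rates
        "R1_exo10", "R2_exo10",                              # Exo10 rates
        "R1_rna", "R2_rna",                                  # +RNA rates
        "S_exsy", "S_ir", "S_spec", "S_ir_rna", "S_spec_rna",  # scales
        "Gamma1_open", "Gamma2_open",                        # PREs
    }
    assert set(graph.free_names) == expected
    # RNA-bound population/rate are fixed, not fitted
    assert not graph["pE_rna"].vary and not graph["kex_rna"].vary


def test_removing_rna_datasets_leaves_apo_chi2_unchanged():
    data, graph, truth = sy.merge_presets(sy.replica_study(), seed=5)
    gm_all = assemble_global_model(data, graph)
    apo = DatasetCollection([ds for ds in data if ds.tags["rna"] == "apo"])
    graph_apo = graph.copy()
    for name in ("Gamma1_open", "Gamma2_open", "R1_rna", "R2_rna",
                 "S_ir_rna", "S_spec_rna"):
        graph_apo[name].vary = False
    gm_apo = assemble_global_model(apo, graph_apo)
    full = gm_all.chi2_by_dataset(truth)
    sub = gm_apo.chi2_by_dataset(truth)
    for name, val in sub.items():
        assert val == pytest.approx(full[name], rel=1e-14)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_noise_free_self_consistency():
    """Noise-free data, start 5% off: generating values recovered to 0.1%."""
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=0, noiseless=True)
    rng = np.random.default_rng(17)
    start = {k: v * (1 + rng.uniform(-0.05, 0.05))
             for k, v in preset.truth.items()}
    fit = fit_global(data, preset.graph(), start=start)
    assert fit.chi2 <= 1e-6
    for name, true in preset.truth.items():
        assert fit.params[name] == pytest.approx(true, rel=1e-3)


def test_fit_is_deterministic():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=4)
    start = {"pE_exo10": 0.22, "kex_exo10": 50.0}
    a = fit_global(data, preset.graph(), start=start)
    b = fit_global(data, preset.graph(), start=start)
    assert a.params == b.params and a.chi2 == b.chi2


def test_fit_improves_on_start():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=6)
    start = {k: v * 1.15 if v else v for k, v in preset.truth.items()}
    gm = assemble_global_model(data, preset.graph())
    start_vals = {**preset.truth, **start}
    fit = fit_global(data, preset.graph(), start=start)
    assert fit.chi2 <= gm.chi2(start_vals)


def test_fit_rejects_unknown_start_key():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=0)
    with pytest.raises(KeyError):
        fit_global(data, preset.graph(), start={"bogus": 1.0})


# ---------------------------------------------------------------------------
# Monte-Carlo bootstrap
# ---------------------------------------------------------------------------

def test_monte_carlo_fixed_seed_reproducible():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=8)
    fit = fit_global(data, preset.graph())
    a = monte_carlo_uncertainty(fit, data, preset.graph(), n=6, seed=3)
    b = monte_carlo_uncertainty(fit, data, preset.graph(), n=6, seed=3)
    assert a.mc_samples.equals(b.mc_samples)          # bitwise identical
    assert a.mc_samples.shape == (6, preset.graph().n_free)
    assert set(a.mc_sd) == set(preset.graph().free_names)


def test_monte_carlo_different_seeds_differ():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=8)
    fit = fit_global(data, preset.graph())
    a = monte_carlo_uncertainty(fit, data, preset.graph(), n=4, seed=1)
    b = monte_carlo_uncertainty(fit, data, preset.graph(), n=4, seed=2)
    assert not a.mc_samples.equals(b.mc_samples)


def test_monte_carlo_reports_quantiles():
    preset = lite_slow_preset()
    data = sy.generate_dataset(preset, seed=9)
    fit = fit_global(data, preset.graph())
    out = monte_carlo_uncertainty(fit, data, preset.graph(), n=8, seed=0)
    q = out.mc_quantiles
    assert list(q.index) == [0.025, 0.16, 0.5, 0.84, 0.975]
    assert np.all(q.loc[0.025] <= q.loc[0.975])
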