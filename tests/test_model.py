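"""Structure, simulation and sensitivity tests for the network model."""

import numpy as np
import pytest

import fimdesign as fd
from fimdesign.model import (
    ParameterSet,
    Perturbation,
    SolverFailure,
    forward_sensitivities,
)


class TestStructure:
    def test_model1_counts(self, model):
        assert model.n_genes == 6
        assert len(model.edges) == 8
        assert model.n_states == 12
        assert model.n_parameters == 29

    def test_parameter_classes(self, model):
        names = model.parameter_names
        assert sum(n.startswith("pro") for n in names) == 6
        assert sum(n.startswith("rbs") for n in names) == 6
        assert sum(n.startswith("K") for n in names) == 8
        assert sum(n.startswith("h") for n in names) == 8
        assert "p_deg_rate" in names
        assert "mRNA_deg_rate" not in names  # fixed constant, not free
        assert model.fixed_constants["mRNA_deg_rate"] == 1.0

    def test_edge_parameters_unique(self, model):
        ks = [e.k_name for e in model.edges]
        hs = [e.h_name for e in model.edges]
        assert len(set(ks)) == 8 and len(set(hs)) == 8
        for n in ks + hs:
            assert model.parameter_names.count(n) == 1

    def test_regulation_wiring(self, model):
        wiring = {(e.regulator, e.target): (e.sign, e.k_name, e.h_name)
                  for e in model.edges}
        assert wiring[(1, 2)] == ("activating", "K2", "h2")
        assert wiring[(6, 2)] == ("inhibiting", "K5", "h5")
        assert wiring[(1, 3)] == ("activating", "K3", "h3")
        assert wiring[(2, 3)] == ("inhibiting", "K4", "h4")
        assert wiring[(1, 4)] == ("activating", "K1", "h1")
        assert wiring[(5, 4)] == ("inhibiting", "K8", "h8")
        assert wiring[(4, 5)] == ("inhibiting", "K6", "h6")
        assert wiring[(4, 6)] == ("inhibiting", "K7", "h7")

    def test_report_lists_parameters_and_edges(self, model):
        rep = model.report()
        assert "p_deg_rate" in rep and "K8" in rep and "-|" in rep


class TestParameterSet:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            ParameterSet({"a": -1.0})
        with pytest.raises(ValueError):
            ParameterSet({"a": 0.0})

    def test_log_roundtrip(self, truth, model):
        names = model.parameter_names
        back = ParameterSet.from_log_array(names, truth.log_array(names))
        assert np.allclose(back.as_array(names), truth.as_array(names),
                           rtol=1e-15)


class TestPerturbation:
    def test_unknown_gene_rejected(self, model):
        with pytest.raises(ValueError, match="9"):
            fd.apply_perturbation(model, Perturbation("delete", 9))

    def test_delete_zeroes_production(self, model):
        pm = fd.apply_perturbation(model, Perturbation("delete", 3))
        assert pm.pro_factors[2] == 0.0 and pm.rbs_factors[2] == 0.0
        assert model.pro_factors[2] == 1.0  # original untouched

    def test_knockdown_scales_one_mrna_degradation(self, model):
        pm = fd.apply_perturbation(model, Perturbation("knockdown", 5))
        assert pm.mrna_deg_rates[4] == 5.0
        assert all(r == 1.0 for i, r in enumerate(pm.mrna_deg_rates) if i != 4)

    def test_overexpress_doubles_translation(self, model, truth):
        pm = fd.apply_perturbation(model, Perturbation("overexpress", 4))
        _, rbs, *_ = pm.effective_arrays(truth)
        assert rbs[3] == pytest.approx(2 * truth["rbs4_strength"])

    def test_free_parameter_list_unchanged(self, model):
        pm = fd.apply_perturbation(model, Perturbation("delete", 1))
        assert pm.parameter_names == model.parameter_names


class TestSimulate:
    def test_initial_condition(self, model, truth):
        traj = fd.simulate(model, truth, np.linspace(0, 20, 5))
        y0 = traj.states[0]
        assert np.all(y0[0::2] == 0.0)  # mRNA
        assert np.all(y0[1::2] == 1.0)  # protein

    def test_mrna1_closed_form(self, model, random_params):
        # gene 1 is unregulated: mRNA1(t) = pro1 * (1 - e^-t)
        t = np.linspace(0, 20, 41)
        for p in random_params[:3]:
            traj = fd.simulate(model, p, t)
            expect = p["pro1_strength"] * (1 - np.exp(-t))
            assert np.allclose(traj.series("mRNA1"), expect, rtol=1e-6,
                               atol=1e-8)

    def test_deleted_gene_protein_decays(self, model, truth):
        pm = fd.apply_perturbation(model, Perturbation("delete", 1))
        t = np.linspace(0, 20, 21)
        traj = fd.simulate(pm, truth, t)
        assert np.allclose(traj.series("p1"),
                           np.exp(-truth["p_deg_rate"] * t), rtol=1e-6)
        assert np.allclose(traj.series("mRNA1"), 0.0, atol=1e-9)

    def test_non_negative_under_all_perturbations(self, model, random_params):
        perts = [Perturbation("wild")] + [
            Perturbation(k, g)
            for k in ("delete", "overexpress", "knockdown")
            for g in (1, 4, 6)
        ]
        t = np.linspace(0, 20, 11)
        for p in random_params[:3]:
            for pert in perts:
                traj = fd.simulate(fd.apply_perturbation(model, pert), p, t)
                assert np.all(traj.states >= 0.0)

    def test_steady_state_by_t20(self, model, truth):
        from fimdesign._kinetics import rhs

        traj = fd.simulate(model, truth, np.array([0.0, 40.0]))
        pro, rbs, K, h, pdeg, mdeg = model.effective_arrays(truth)
        et, er, es = model._edge_arrays()
        dy = rhs(40.0, traj.states[-1], pro, rbs, K, h, pdeg, mdeg, et, er, es)
        assert np.all(np.abs(dy) < 1e-3)

    def test_solver_failure_is_signalled(self, model):
        # production rates near the floating-point ceiling overflow the
        # state vector; the integrator must signal, not return garbage
        extreme = {n: 1.0 for n in model.parameter_names}
        extreme["pro1_strength"] = 1e200
        extreme["rbs1_strength"] = 1e200
        with pytest.raises(SolverFailure):
            fd.simulate(model, ParameterSet(extreme), np.linspace(0, 20, 41))

    def test_unsorted_times_rejected(self, model, truth):
        with pytest.raises(ValueError):
            fd.simulate(model, truth, np.array([1.0, 0.5]))


class TestObservationJacobian:
    def test_uninfluential_parameter_is_zero(self, model, truth):
        # protein 3 regulates nothing, so rbs3 cannot influence any mRNA
        J = fd.observation_jacobian(model, truth, [("mRNA1", 5.0),
                                                   ("mRNA4", 10.0)])
        j = model.parameter_index("rbs3_strength")
        assert np.allclose(J[:, j], 0.0, atol=1e-12)

    def test_log_derivative_of_mrna1(self, model, truth):
        # d mRNA1/d log pro1 = pro1 (1 - e^-t) -> pro1 for large t
        J = fd.observation_jacobian(model, truth, [("mRNA1", 20.0)])
        j = model.parameter_index("pro1_strength")
        assert J[0, j] == pytest.approx(truth["pro1_strength"], rel=1e-5)

    def test_forward_matches_finite_differences_wild(self, model,
                                                     random_params):
        p = random_params[0]
        obs = [("mRNA2", 4.0), ("p4", 12.0), ("p6", 20.0), ("mRNA5", 8.0)]
        Jf = fd.observation_jacobian(model, p, obs, method="forward")
        Jd = fd.observation_jacobian(model, p, obs, method="fd")
        assert np.allclose(Jf, Jd, rtol=1e-4, atol=1e-6)

    def test_forward_matches_finite_differences_perturbed(self, model,
                                                          random_params):
        # larger FD step: the knockdown trajectory changes the integrator's
        # step sequence between +/- evaluations, so a tiny step amplifies
        # solver noise instead of improving truncation error
        pm = fd.apply_perturbation(model, Perturbation("knockdown", 5))
        p = random_params[0]
        obs = [("mRNA2", 4.0), ("p4", 12.0), ("p6", 20.0), ("mRNA5", 8.0)]
        Jf = fd.observation_jacobian(pm, p, obs, method="forward")
        Jd = fd.observation_jacobian(pm, p, obs, method="fd", fd_step=1e-3)
        assert np.allclose(Jf, Jd, rtol=1e-3, atol=1e-5)

    def test_deleted_production_columns_vanish(self, model, truth):
        pm = fd.apply_perturbation(model, Perturbation("delete", 1))
        _, sens = forward_sensitivities(pm, truth, np.linspace(0, 20, 5))
        for name in ("pro1_strength", "rbs1_strength"):
            assert np.allclose(sens[..., model.parameter_index(name)], 0.0)
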