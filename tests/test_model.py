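import numpy as np
import pandas as pd
import pytest

import feedeff as fe
from feedeff.model import (
    FixedTerm,
    ModelError,
    ModelSpec,
    RandomTerm,
    assemble_mme,
    build_spec,
    solve_mme,
)


class TestLegendreBasis:
    def test_midpoint_even_polynomials_only(self):
        # t = 0 at the midpoint of the standardised range
        mid = (1 + 44) / 2
        vals = fe.legendre_basis(mid)
        assert np.allclose(vals, [1.0, 0.0, -0.5, 0.0, 0.375])

    def test_left_endpoint_alternating_signs(self):
        vals = fe.legendre_basis(1)
        assert np.allclose(vals, [1, -1, 1, -1, 1])

    def test_t_half_recurrence_values(self):
        week = 1 + 0.75 * 43  # maps to t = 0.5
        vals = fe.legendre_basis(week)
        assert np.allclose(vals, [1.0, 0.5, -0.125, -0.4375, -0.2890625])

    def test_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            fe.legendre_basis(45)


class TestBuildSpec:
    def test_refi_regresses_every_term_on_edmi(self):
        spec = build_spec("refi_rdc")
        assert spec.edmi_column == "edmi_rdc"
        assert spec.fixed[0].kind == "nested_covariate"
        assert spec.fixed[0].columns == ("edmi_rdc",)
        assert all(t.slope_column == "edmi_rdc" for t in spec.random)
        # deliberately no intercept or lactation-curve fixed effect
        assert all(t.kind != "intercept" for t in spec.fixed)

    def test_ece_replaces_sinks_with_lactation_week(self):
        spec = build_spec("ece")
        kinds = [(t.name, t.kind) for t in spec.fixed]
        assert ("lwk", "class") in kinds
        assert all(t.kind != "covariates" for t in spec.fixed)

    def test_rfi_has_four_sink_covariates_and_hpy(self):
        spec = build_spec("rfi")
        sinks = [t for t in spec.fixed if t.kind == "covariates"][0]
        assert sinks.columns == ("ecm", "mbw", "bwl", "bwg")
        assert any(t.class_column == "hpy" for t in spec.fixed if t.kind == "class")

    def test_multitrait_five_traits_legendre_by_herd(self):
        spec = build_spec("multitrait")
        assert spec.traits == ("dmi", "ecm", "mbw", "bwl", "bwg")
        leg = [t for t in spec.fixed if t.kind == "legendre"][0]
        assert leg.order == 4 and leg.class_column == "herd"

    def test_unknown_metric(self):
        with pytest.raises(ModelError):
            build_spec("nope")


class TestAssembleSolve:
    def test_single_mean_reduces_to_ols(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 6.0], "period": 1})
        spec = ModelSpec("mean", ("y",), fixed=[FixedTerm("mu", "intercept")], random=[])
        fit = solve_mme(assemble_mme(spec, df, fe.VarianceComponents(random={}, residual=[1.0])))
        assert fit.solution("mu").iloc[0] == pytest.approx(3.0)

    def test_near_zero_genetic_variance_shrinks_solutions(self, reduced_study, reduced_ainv):
        vc = fe.VarianceComponents(
            random={"htm": 4e-4, "pe": 0.003, "animal": 1e-9},
            residual=reduced_study.true_parameters.residual,
        )
        fit = fe.fit_metric("refi_rdc", reduced_study.records, vc, kernel_inverse=reduced_ainv)
        assert np.abs(fit.breeding_values()).max() < 1e-4

    def test_gls_blup_oracle_heterogeneous_residuals(self):
        rng = np.random.default_rng(8)
        n = 12
        df = pd.DataFrame(
            {
                "y": rng.normal(10, 2, n),
                "x": rng.normal(0, 1, n),
                "grp": list("aabbccddeeff"),
                "period": [1, 2] * 6,
            }
        )
        spec = ModelSpec(
            "fix",
            ("y",),
            fixed=[FixedTerm("mu", "intercept"), FixedTerm("beta", "covariates", ("x",))],
            random=[RandomTerm("grp", "grp")],
        )
        vc = fe.VarianceComponents(random={"grp": 0.7}, residual=[1.3, 2.1])
        fit = solve_mme(assemble_mme(spec, df, vc))
        X = np.column_stack([np.ones(n), df.x])
        grp = pd.Categorical(df.grp)
        Z = np.zeros((n, 6))
        Z[np.arange(n), grp.codes] = 1
        R = np.diag(np.where(df.period == 1, 1.3, 2.1))
        V = Z @ (0.7 * np.eye(6)) @ Z.T + R
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df.y)
        u = 0.7 * Z.T @ Vi @ (df.y - X @ b)
        got_fixed = np.concatenate([fit.solution("mu").values, fit.solution("beta").values])
        assert np.abs(got_fixed - b).max() < 1e-8
        assert np.abs(fit.solution("grp").values - u).max() < 1e-8

    def test_record_permutation_invariance(self, reduced_study, reduced_ainv):
        vc = reduced_study.true_parameters
        data = reduced_study.records
        fit1 = fe.fit_metric("refi_rdc", data, vc, kernel_inverse=reduced_ainv)
        rng = np.random.default_rng(4)
        shuffled = data.iloc[rng.permutation(len(data))].reset_index(drop=True)
        fit2 = fe.fit_metric("refi_rdc", shuffled, vc, kernel_inverse=reduced_ainv)
        assert np.abs(fit1.breeding_values() - fit2.breeding_values()).max() < 1e-10

    def test_residual_rescaling_leaves_fixed_effects_unchanged(self, reduced_study, reduced_ainv):
        data = reduced_study.records
        vc1 = reduced_study.true_parameters
        vc2 = fe.VarianceComponents(
            random={k: 3.0 * float(v) for k, v in vc1.random.items()},
            residual=3.0 * vc1.residual,
        )
        f1 = fe.fit_metric("rfi", data, vc1, kernel_inverse=reduced_ainv)
        f2 = fe.fit_metric("rfi", data, vc2, kernel_inverse=reduced_ainv)
        assert np.abs(f1.solution("sinks") - f2.solution("sinks")).max() < 1e-8
        assert np.abs(f1.solution("hpy") - f2.solution("hpy")).max() < 1e-8

    def test_direct_and_cg_agree(self, reduced_study, reduced_ainv):
        vc = reduced_study.true_parameters
        spec = build_spec("refi_rdc")
        system = assemble_mme(spec, reduced_study.records, vc, kernel_inverse=reduced_ainv)
        direct = solve_mme(system, method="direct")
        cg = solve_mme(system, method="cg", tol=1e-12)
        assert np.abs(direct.solutions_vector - cg.solutions_vector).max() < 1e-6

    def test_solver_residual_check(self, reduced_study, reduced_ainv):
        vc = reduced_study.true_parameters
        spec = build_spec("refi_rdc")
        system = assemble_mme(spec, reduced_study.records, vc, kernel_inverse=reduced_ainv)
        fit = solve_mme(system)
        assert fit.diagnostics["rel_residual"] < 1e-8


class TestMetricFits:
    def test_alpha_is_one_when_dmi_equals_edmi(self):
        # noise-free study: DMI = eDMI exactly, so every HPY regression is 1
        cfg = fe.SimConfig.reduced(
            seed=5,
            alpha_sd=0.0,
            variance_components={
                "htm": 0.0,
                "pe": 0.0,
                "animal": 0.0,
                "residual_weighted": 0.0,
                "residual_pattern": (1, 1, 1, 1, 1),
            },
        )
        study = fe.simulate_study(cfg)
        vc = fe.VarianceComponents(
            random={"htm": 1e-6, "pe": 1e-6, "animal": 1e-6},
            residual=np.full(5, 1e-4),
        )
        fit = fe.fit_metric(
            "refi_rdc", study.records, vc, kernel_inverse=fe.a_inverse(study.pedigree)
        )
        alpha = fit.solution("alpha")
        assert np.abs(alpha - 1.0).max() < 1e-3

    def test_ssgblup_equals_blup_when_G_is_A22(self, reduced_study, reduced_ainv):
        ped = reduced_study.pedigree
        a22 = fe.a22_from_pedigree(ped, reduced_study.genotypes.ids)
        hinv = fe.h_inverse(reduced_ainv, a22, a22)
        vc = reduced_study.true_parameters
        f_a = fe.fit_metric("refi_rdc", reduced_study.records, vc, kernel_inverse=reduced_ainv)
        f_h = fe.fit_metric("refi_rdc", reduced_study.records, vc, kernel_inverse=hinv)
        assert np.abs(f_a.breeding_values() - f_h.breeding_values()).max() < 1e-6

    def test_rfi_recovers_generating_sink_coefficients(self):
        study = fe.simulate_study(fe.SimConfig.reduced(seed=13))
        vc = fe.VarianceComponents(
            random={"htm": 0.15, "pe": 1.2, "animal": 1.1},
            residual=study.true_parameters.residual,
        )
        fit = fe.fit_metric(
            "rfi", study.records, vc, kernel_inverse=fe.a_inverse(study.pedigree)
        )
        c = fit.solution("sinks")
        # generating coefficients scaled by slopes near 1; loose empirical bands
        assert c["ecm"] == pytest.approx(0.456, abs=0.05)
        assert c["mbw"] == pytest.approx(0.0508, abs=0.03)
        assert c["bwl"] == pytest.approx(-3.25, abs=0.45)
        assert c["bwg"] == pytest.approx(3.25, abs=0.45)

    def test_edmi_fit_mean_tracks_dmi_mean(self, reduced_study, reduced_ainv):
        vc = fe.VarianceComponents(
            random={"htm": 0.15, "pe": 1.2, "animal": 1.1},
            residual=reduced_study.true_parameters.residual,
        )
        fit = fe.fit_metric("rfi", reduced_study.records, vc, kernel_inverse=reduced_ainv)
        mean_dmi = reduced_study.records["dmi"].mean()
        assert abs(fit.edmi_fit().mean() - mean_dmi) / mean_dmi < 0.01

    def test_multitrait_fit_produces_five_trait_ebvs(self, reduced_study, reduced_ainv):
        from feedeff.validation import multitrait_varcomp

        vc = multitrait_varcomp(
            reduced_study.config, float(reduced_study.records["edmi_rdc"].mean())
        )
        fit = fe.fit_metric("multitrait", reduced_study.records, vc, kernel_inverse=reduced_ainv)
        bvs = fit.breeding_values()
        assert list(bvs.columns) == ["dmi", "ecm", "mbw", "bwl", "bwg"]
        assert len(bvs) == len(reduced_study.pedigree)
        # breeding values of each trait center near zero
        assert np.abs(bvs.mean()).max() < 0.5

    def test_model_facade_matches_functional_path(self, reduced_study):
        model = fe.FeedEfficiencyModel(
            reduced_study.records, "refi_rdc", reduced_study.pedigree
        )
        res = model.fit(reduced_study.true_parameters)
        direct = fe.fit_metric(
            "refi_rdc",
            reduced_study.records,
            reduced_study.true_parameters,
            kernel_inverse=model.kernel_inverse,
        )
        assert np.abs(res.breeding_values() - direct.breeding_values()).max() == 0.0
        assert "refi_rdc" in res.summary()
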