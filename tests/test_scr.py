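"""SCR likelihood against exhaustive enumeration, AICc arithmetic,
model ranking, and derived-estimate algebra."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fragpop import scr as S
from fragpop import synthetic as syn
from fragpop.core_data import DetectionData, HabitatMask, build_mask


# ---------------------------------------------------------------------------
# Brute-force oracle: explicit loops over mask points, occasions, traps,
# mixture classes, with the bk state reconstructed from the history.
# ---------------------------------------------------------------------------


def oracle_loglik(beta, spec, mask, data, covariate=None):
    p = S._unpack(np.asarray(beta, float), spec, len(data.sessions))
    sigma = math.exp(p["log_sigma"])
    a = mask.cell_area
    if spec.has_h2:
        pi2 = expit(p["pmix_logit"])
        phis = [1 - pi2, pi2]
        offs = [0.0, p["h2"]]
    else:
        phis = [1.0]
        offs = [0.0]
    total = 0.0
    for s_idx, s in enumerate(data.sessions):
        y = data.y[s]
        n_i, J, K = y.shape
        xy = data.traps[s][["x", "y"]].to_numpy(float)
        D = []
        for xi, x in enumerate(mask.points):
            v = p["d0"]
            if spec.density_kind == "session":
                v += p["d_sess"][s_idx]
            elif spec.density_kind == "covariate":
                v += p["d_cov"] * covariate[xi]
            D.append(math.exp(v))
        lam = 0.0
        for xi, x in enumerate(mask.points):
            pdot_classes = 0.0
            for phi, off in zip(phis, offs):
                surv = 1.0
                for j in range(J):
                    d = math.hypot(x[0] - xy[j, 0], x[1] - xy[j, 1])
                    p0 = expit(p["g0"] + off) * math.exp(-d * d / (2 * sigma**2))
                    surv *= (1 - p0) ** K
                pdot_classes += phi * (1 - surv)
            lam += D[xi] * a * pdot_classes
        total -= lam + math.lgamma(n_i + 1)
        for i in range(n_i):
            L_i = 0.0
            for xi, x in enumerate(mask.points):
                mix = 0.0
                for phi, off in zip(phis, offs):
                    P = 1.0
                    for j in range(J):
                        d = math.hypot(x[0] - xy[j, 0], x[1] - xy[j, 1])
                        hn = math.exp(-d * d / (2 * sigma**2))
                        seen = False
                        for k in range(K):
                            g0 = expit(
                                p["g0"] + off + (p["bk"] if seen else 0.0)
                            )
                            pr = g0 * hn
                            P *= pr if y[i, j, k] else (1 - pr)
                            if y[i, j, k]:
                                seen = True
                    mix += phi * P
                L_i += D[xi] * a * mix
            total += math.log(L_i)
    return total


def _toy_dataset():
    traps = pd.DataFrame({"trap_id": ["T1"], "x": [0.3], "y": [0.1]})
    y = np.array([[[1, 0]], [[1, 1]]])  # 2 individuals, 1 trap, 2 occasions
    data = DetectionData(
        ["S1"], {"S1": traps}, {"S1": 2}, {"S1": y},
        {"S1": ["a", "b"]}, {"a": "F", "b": "F"},
    )
    mask = HabitatMask(
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]), spacing=1.0,
        covariates={"pnat": np.array([0.1, 0.6, 0.9])},
    )
    return data, mask


class TestLikelihoodOracle:
    @pytest.mark.parametrize(
        "density,g0",
        [
            ("~1", "~1"),
            ("~1", "~bk"),
            ("~1", "~h2"),
            ("~1", "~bk+h2"),
            ("~pnat", "~bk"),
            ("~session", "~1"),
        ],
    )
    def test_matches_enumeration(self, density, g0):
        data, mask = _toy_dataset()
        spec = S.SCRModelSpec(density, g0)
        design = S.build_design(data, spec, mask)
        rng = np.random.default_rng(1)
        for _ in range(3):
            k = spec.n_parameters(1)
            beta = rng.normal(scale=0.8, size=k)
            beta[-1] = rng.normal(0.2, 0.3)  # keep sigma moderate
            got = -S.neg_log_likelihood(beta, design)
            want = oracle_loglik(
                beta, spec, mask, data, covariate=mask.covariates["pnat"]
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_two_session_oracle_with_bk(self):
        traps = pd.DataFrame({"trap_id": ["T1", "T2"], "x": [0.0, 1.2],
                              "y": [0.0, 0.0]})
        y1 = np.array([[[1, 0], [0, 1]]])  # spatial recapture
        y2 = np.array([[[0, 1], [0, 0]], [[1, 1], [1, 0]]])
        data = DetectionData(
            ["S1", "S2"], {"S1": traps, "S2": traps}, {"S1": 2, "S2": 2},
            {"S1": y1, "S2": y2}, {"S1": ["a"], "S2": ["b", "c"]},
            {"a": "F", "b": "F", "c": "F"},
        )
        mask = HabitatMask(np.array([[0.0, 0.5], [1.0, 0.5]]), spacing=1.0)
        spec = S.SCRModelSpec("~1", "~bk")
        design = S.build_design(data, spec, mask)
        beta = np.array([-0.5, -1.0, 0.8, 0.1])
        got = -S.neg_log_likelihood(beta, design)
        want = oracle_loglik(beta, spec, mask, data)
        assert got == pytest.approx(want, abs=1e-10)

    def test_covariate_model_nests_homogeneous(self):
        data, mask = _toy_dataset()
        hom = S.build_design(data, S.SCRModelSpec("~1", "~1"), mask)
        cov = S.build_design(data, S.SCRModelSpec("~pnat", "~1"), mask)
        b_hom = np.array([-0.3, -1.2, 0.4])
        b_cov = np.array([-0.3, 0.0, -1.2, 0.4])  # slope = 0
        assert S.neg_log_likelihood(b_cov, cov) == pytest.approx(
            S.neg_log_likelihood(b_hom, hom), abs=1e-12
        )

    def test_discretization_stability(self):
        traps = pd.DataFrame(
            {"trap_id": [f"T{i}" for i in range(4)],
             "x": [0.0, 2.0, 0.0, 2.0], "y": [0.0, 0.0, 2.0, 2.0]}
        )
        mask1 = build_mask(traps, buffer=6, spacing=0.5)
        mask2 = build_mask(traps, buffer=6, spacing=0.25)
        truth = syn.SCRTruth(density=0.5, g0=0.3, sigma=1.5, n_sessions=1,
                             n_occasions=4)
        data = syn.simulate_scr(truth, traps, mask1, seed=3)
        spec = S.SCRModelSpec("~1", "~1")
        beta = np.array([math.log(0.5), math.log(0.3 / 0.7), math.log(1.5)])
        l1 = -S.neg_log_likelihood(beta, S.build_design(data, spec, mask1))
        l2 = -S.neg_log_likelihood(beta, S.build_design(data, spec, mask2))
        assert abs(l1 - l2) < 0.01


class TestDetectionBasics:
    def test_detect_prob_closed_forms(self):
        assert S.detect_prob(0.2, 2.0, 0.0) == pytest.approx(0.2)
        assert S.detect_prob(0.2, 2.0, 2.0) == pytest.approx(
            0.2 * math.exp(-0.5)
        )
        d = np.linspace(0, 20, 50)
        p = S.detect_prob(0.2, 2.0, d)
        assert (np.diff(p) < 0).all()
        assert p[-1] < 1e-8

    def test_bk_indicator_persists_and_is_trap_specific(self):
        y = np.zeros((1, 2, 5), dtype=int)
        y[0, 0, 2] = 1  # detection at trap 0, occasion 3
        b = S.bk_indicator(y)
        assert b[0, 0, :3].tolist() == [0, 0, 0]
        assert b[0, 0, 3:].tolist() == [1, 1]
        assert b[0, 1].sum() == 0

    def test_no_detections_no_bk(self):
        b = S.bk_indicator(np.zeros((2, 3, 4), dtype=int))
        assert b.sum() == 0


class TestAicc:
    def test_printed_triplets_reconstructed(self):
        # males: logLik -444.64, K=4, n = 10+14+22 = 46
        assert S.aicc(-444.64, 4, 46) == pytest.approx(898.26, abs=0.01)
        # females: logLik -539.78, K=4, n = 23+19+26 = 68
        assert S.aicc(-539.78, 4, 68) == pytest.approx(1088.20, abs=0.01)

    def test_large_n_limit_is_aic(self):
        assert S.aicc(-100.0, 3, 10**7) == pytest.approx(206.0, abs=1e-4)

    def test_small_n_undefined(self):
        with pytest.raises(ValueError):
            S.aicc(-10.0, 4, 5)


class TestModelTable:
    def _fake_fit(self, label_density, aicc_val, k=4):
        spec = S.SCRModelSpec(label_density, "~bk")
        return S.SCRFit(
            spec=spec, beta=np.zeros(k), param_names=[""] * k,
            vcov=np.eye(k), logLik=-aicc_val / 2, K=k, n_histories=50,
            AICc=aicc_val, converged=True,
        )

    def test_single_model_normalization(self):
        df = S.model_table([self._fake_fit("~1", 900.0)])
        assert df["dAICc"].iloc[0] == 0.0
        assert df["weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_sorted(self):
        fits = [self._fake_fit(d, v) for d, v in
                [("~1", 898.26), ("~session", 898.65), ("~pnat", 899.93)]]
        df = S.model_table(fits[::-1])
        assert df["AICc"].is_monotonic_increasing
        assert df["weight"].sum() == pytest.approx(1.0)
        assert df["competitive"].tolist() == [True, True, True]


class TestRealizedAndCombined:
    def test_combined_sex_reconstruction_from_printed_values(self):
        # sex-specific D and asymmetric CIs as printed; SEs recovered from
        # the CI half-widths
        def est(d, lo, hi, area=1827.09):
            se = (hi - lo) / (2 * 1.96)
            return S.RealizedEstimates(
                D=(d, lo, hi), D_se=se, g0=(np.nan,) * 3,
                sigma=(np.nan,) * 3, N=(d * area,) * 3, habitat_area=area,
            )

        f = est(0.039, 0.028, 0.052)
        m = est(0.015, 0.010, 0.022)
        comb, female_biased = S.combine_sexes(f, m)
        assert comb.D[0] == pytest.approx(0.054)
        assert comb.D[1] == pytest.approx(0.041, abs=0.001)
        assert comb.D[2] == pytest.approx(0.067, abs=0.001)
        assert female_biased
        # derived abundance from the printed habitat area
        assert round(m.D[0] * 1827.09) == 27
        assert round(f.D[0] * 1827.09) == 71
        assert abs(comb.N[0] - 98) <= 1

    def test_symmetric_inputs_give_symmetric_ci(self):
        e = S.RealizedEstimates(
            D=(0.02, 0.015, 0.025), D_se=0.0025, g0=(np.nan,) * 3,
            sigma=(np.nan,) * 3, N=(20.0,) * 3, habitat_area=1000.0,
        )
        comb, biased = S.combine_sexes(e, e)
        assert comb.D[0] - comb.D[1] == pytest.approx(comb.D[2] - comb.D[0])
        assert not biased

    def test_mismatched_areas_rejected(self):
        e1 = S.RealizedEstimates((0.1,) * 3, 0.01, (np.nan,) * 3,
                                 (np.nan,) * 3, (1.0,) * 3, 10.0)
        e2 = S.RealizedEstimates((0.1,) * 3, 0.01, (np.nan,) * 3,
                                 (np.nan,) * 3, (1.0,) * 3, 20.0)
        with pytest.raises(ValueError):
            S.combine_sexes(e1, e2)


class TestFitEndToEnd:
    def test_fit_recovers_generating_parameters_roughly(self):
        traps, _ = syn.place_traps(
            syn.simulate_landscape(syn.LandscapeConfig(seed=7))
        )
        mask = build_mask(traps, buffer=8, spacing=2)
        truth = syn.SCRTruth(density=0.06, g0=0.15, sigma=2.5, n_sessions=2,
                             n_occasions=6)
        data = syn.simulate_scr(truth, traps, mask, seed=5)
        fit = S.fit(S.SCRModelSpec("~1", "~1"), data, mask)
        assert fit.converged
        est = S.realized_estimates(fit, mask, habitat_only=False)
        assert est.D[0] == pytest.approx(0.06, rel=0.35)
        assert est.sigma[0] == pytest.approx(2.5, rel=0.25)
        assert est.D[1] < est.D[0] < est.D[2]

    def test_aicc_identity_on_fit(self):
        traps = pd.DataFrame(
            {"trap_id": ["T1", "T2", "T3"], "x": [0.0, 2.0, 4.0],
             "y": [0.0, 0.0, 0.0]}
        )
        mask = build_mask(traps, buffer=5, spacing=1)
        truth = syn.SCRTruth(density=1.0, g0=0.3, sigma=1.2, n_sessions=1,
                             n_occasions=5)
        data = syn.simulate_scr(truth, traps, mask, seed=9)
        fit = S.fit(S.SCRModelSpec("~1", "~1"), data, mask,
                    compute_vcov=False)
        assert fit.AICc == pytest.approx(
            S.aicc(fit.logLik, fit.K, fit.n_histories)
        )


class TestPosteriors:
    def test_posterior_normalized_and_mode_near_single_detection(self):
        traps = pd.DataFrame(
            {"trap_id": ["T1", "T2"], "x": [0.0, 4.0], "y": [0.0, 0.0]}
        )
        mask = build_mask(traps, buffer=4, spacing=1)
        y = np.zeros((1, 2, 3), dtype=int)
        y[0, 1, 0] = 1  # single detection at T2
        data = DetectionData(["S1"], {"S1": traps}, {"S1": 3}, {"S1": y},
                             {"S1": ["a"]}, {"a": "F"})
        spec = S.SCRModelSpec("~1", "~1")
        design = S.build_design(data, spec, mask)
        fit = S.SCRFit(
            spec=spec, beta=np.array([0.0, math.log(0.2 / 0.8), 0.0]),
            param_names=S._param_names(spec, ["S1"]), vcov=np.eye(3),
            logLik=0.0, K=3, n_histories=1, AICc=10.0, converged=True,
            design=design,
        )
        post, modes = S.posterior_activity_centers(fit)
        assert post.shape[0] == 1
        assert post.sum() == pytest.approx(1.0)
        mode_pt = mask.points[modes[0][1]]
        assert np.hypot(mode_pt[0] - 4.0, mode_pt[1]) <= 1.0 + 1e-9
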