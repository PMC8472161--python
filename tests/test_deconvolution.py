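import numpy as np
import pandas as pd
import pytest

from pepfinger.deconvolution import (
    DeconvolutionError,
    build_specificity_matrix,
    class_constrained_inference,
    infer_activities,
)

NM = 1e-9


@pytest.fixture(scope="module")
def matrix():
    return build_specificity_matrix()


def grid_oracle(kobs, eff, lo=0.0, hi=2e-9, coarse=31, refine=14):
    """Independent nonnegative least-squares oracle: coarse grid search over
    (lo..hi)^n_enzymes, refined by re-gridding around the incumbent with a
    window of three old grid steps (wide enough to escape the near-collinear
    valley of the specificity matrix). Entirely independent of scipy's nnls."""
    n = eff.shape[1]
    centers = np.full(n, (lo + hi) / 2)
    half = (hi - lo) / 2
    best = None
    for _ in range(refine):
        axes = [
            np.linspace(max(0.0, c - half), c + half, coarse) for c in centers
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([m.ravel() for m in mesh], axis=1)
        resid = np.linalg.norm(cand @ eff.T - kobs, axis=1)
        i = int(np.argmin(resid))
        best, centers = float(resid[i]), cand[i]
        half = 3 * (2 * half / (coarse - 1))
    return centers, best


class TestBuildMatrix:
    def test_published_entries(self, matrix):
        """Spot checks against the published specificity table."""
        assert matrix.eff[matrix.substrates.index("PepA"), matrix.enzymes.index("MMP2")] == 3.2e5
        assert matrix.eff[matrix.substrates.index("PepB"), matrix.enzymes.index("MMP9")] == 8.5e5
        # "no activity" entries are exactly zero
        for sub, enz in [("PepD", "MMP8"), ("PepD", "MMP9"), ("PepE", "MMP9")]:
            assert matrix.eff[matrix.substrates.index(sub), matrix.enzymes.index(enz)] == 0.0
        assert all(matrix.class_of[e] == "metallo" for e in matrix.enzymes)

    def test_custom_table_and_errors(self, matrix):
        frame = matrix.to_frame()
        rebuilt = build_specificity_matrix(frame)
        np.testing.assert_array_equal(rebuilt.eff, matrix.eff)
        with pytest.raises(DeconvolutionError, match="empty"):
            build_specificity_matrix(frame.iloc[0:0])
        dup = pd.concat([frame, frame.iloc[[0]]])
        with pytest.raises(DeconvolutionError, match="duplicate"):
            build_specificity_matrix(dup)
        neg = frame.copy()
        neg.loc[0, "efficiency_M_per_s"] = -1.0
        with pytest.raises(DeconvolutionError, match="negative"):
            build_specificity_matrix(neg)


class TestInferActivities:
    def test_zero_rates_give_zero_concentrations(self, matrix):
        est = infer_activities(np.zeros(5), matrix)
        np.testing.assert_array_equal(est.conc_nM, 0.0)
        assert est.residual_norm == 0.0
        assert est.identifiable

    def test_single_enzyme_generative_recovery(self, matrix):
        """k_obs = 1 nM x MMP2 column recovers (1, 0, 0) nM and agrees with
        the grid-search oracle."""
        kobs = NM * matrix.column("MMP2")
        est = infer_activities(kobs, matrix)
        np.testing.assert_allclose(est.conc_nM, [1.0, 0.0, 0.0], atol=1e-6)
        assert est.residual_norm == pytest.approx(0.0, abs=1e-9)
        oracle_conc, _ = grid_oracle(kobs, matrix.eff)
        np.testing.assert_allclose(est.conc_nM, oracle_conc / NM, atol=5e-3)

    def test_mixture_recovery_noise_free(self, matrix):
        truth = np.array([0.5, 0.25, 0.25])  # nM
        kobs = matrix.eff @ (truth * NM)
        est = infer_activities(kobs, matrix)
        np.testing.assert_allclose(est.conc_nM, truth, rtol=1e-6)

    def test_random_instances_match_grid_oracle(self, rng, matrix):
        for _ in range(5):
            truth = rng.uniform(0, 1.5, 3) * NM
            kobs = matrix.eff @ truth
            est = infer_activities(kobs, matrix)
            oracle_conc, oracle_resid = grid_oracle(kobs, matrix.eff)
            assert est.residual_norm <= oracle_resid + 1e-9
            np.testing.assert_allclose(est.conc_nM * NM, oracle_conc, atol=1e-15)

    def test_noisy_recovery_median_error(self, matrix):
        """1% multiplicative noise: median single-enzyme recovery error over
        100 seeded replicates stays below 10%."""
        errors = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            kobs = NM * matrix.column("MMP9") * r.normal(1.0, 0.01, 5)
            est = infer_activities(kobs, matrix)
            errors.append(abs(est.conc_nM[matrix.enzymes.index("MMP9")] - 1.0))
        assert np.median(errors) < 0.10

    def test_scaling_equivariance(self, rng, matrix):
        kobs = matrix.eff @ (rng.uniform(0, 1, 3) * NM)
        base = infer_activities(kobs, matrix)
        scaled = infer_activities(3.5 * kobs, matrix)
        np.testing.assert_allclose(scaled.conc_nM, 3.5 * base.conc_nM, rtol=1e-9)

    def test_nonnegativity_under_inconsistent_input(self, rng, matrix):
        for _ in range(10):
            est = infer_activities(rng.uniform(0, 1e-3, 5), matrix)
            assert np.all(est.conc_nM >= 0)

    def test_dimension_mismatch(self, matrix):
        with pytest.raises(DeconvolutionError):
            infer_activities(np.zeros(4), matrix)

    def test_ridge_shrinks_toward_zero(self, matrix):
        kobs = NM * matrix.column("MMP2")
        plain = infer_activities(kobs, matrix)
        ridged = infer_activities(kobs, matrix, ridge=1e8)
        # the penalty trades residual for a smaller-norm solution
        assert np.linalg.norm(ridged.conc_nM) < np.linalg.norm(plain.conc_nM)
        assert ridged.residual_norm >= plain.residual_norm


class TestClassConstrained:
    def test_ideal_mmpi_attributes_everything_to_metallo(self, matrix):
        """Only MMP2 active, ideal MMPi: the (NONE - MMPi) differential carries
        the whole signal, nothing survives BOTHi."""
        none = NM * matrix.column("MMP2")
        groups = {
            "NONE": none,
            "MMPi": np.zeros(5),
            "COMi": none.copy(),
            "BOTHi": np.zeros(5),
        }
        res = class_constrained_inference(groups, matrix)
        met = res.by_class["metallo"]
        assert met.as_dict()["MMP2"] == pytest.approx(1.0, rel=1e-6)
        csc = res.by_class["csc"]
        assert csc.enzymes == ()  # no CSC enzymes in the default matrix
        assert csc.residual_norm == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.unattributed_kobs_per_s, 0.0)
        assert res.disinhibition == {}

    def test_nothing_inhibitable(self, matrix):
        none = np.full(5, 1e-4)
        groups = {g: none.copy() for g in ("NONE", "MMPi", "COMi", "BOTHi")}
        res = class_constrained_inference(groups, matrix)
        np.testing.assert_array_equal(res.by_class["metallo"].conc_nM, 0.0)
        np.testing.assert_allclose(res.unattributed_kobs_per_s, none)

    def test_disinhibition_floored_and_recorded(self, matrix):
        none = np.full(5, 1e-4)
        mmpi = none.copy()
        mmpi[0] = 2e-4  # inhibited well faster than its control on PepA
        res = class_constrained_inference({"NONE": none, "MMPi": mmpi}, matrix)
        assert res.disinhibition == {"MMPi": ["PepA"]}
        assert np.all(res.by_class["metallo"].conc_nM >= 0)

    def test_missing_none_is_hard_error(self, matrix):
        with pytest.raises(DeconvolutionError, match="NONE"):
            class_constrained_inference({"MMPi": np.zeros(5)}, matrix)
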