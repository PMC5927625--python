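"""RUV and bivariate-LOESS normalization against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh

import memascreen as ms
from memascreen.errors import LayoutError, NumericalError
from memascreen.normalize import (SignalMatrix, apply_transform, build_signal_matrix,
                                  invert_transform, loess_spatial_normalize,
                                  normalize_pipeline, replicate_median_residuals,
                                  ruv_normalize)
from memascreen.simulate import SimulationParams, spatial_field
from tests_support_matrix import grid_matrix


class TestTransforms:
    def test_count_zero_maps_to_zero(self):
        assert apply_transform(np.array([0.0]), "log2p1")[0] == 0.0

    def test_logit_half_maps_to_zero(self):
        assert apply_transform(np.array([0.5]), "logit", eps=0.01)[0] == 0.0

    @pytest.mark.parametrize("tf", ["identity", "log2p1", "log2", "logit"])
    def test_round_trip(self, tf):
        x = np.array([0.25, 0.5, 0.75]) if tf == "logit" else np.array([1.0, 2.0, 7.5])
        y = invert_transform(apply_transform(x, tf, eps=1e-3), tf, eps=1e-3)
        np.testing.assert_allclose(y, x, atol=1e-12)


class TestBuildSignalMatrix:
    def test_shape_and_alignment(self, small_design, small_spots):
        m = build_signal_matrix(small_spots, "cell_count")
        assert m.values.shape == (small_design.n_arrays, len(small_design.layout))
        assert list(m.row_meta.columns) == ["array_id", "cell_line", "treatment", "ligand"]
        assert m.col_meta.ecm.notna().all()

    def test_inconsistent_layout_rejected(self, small_spots):
        broken = small_spots.copy()
        idx = broken[broken.array_id == broken.array_id.iloc[0]].index[0]
        broken.loc[idx, "ecm"] = "OTHER"
        with pytest.raises(LayoutError):
            build_signal_matrix(broken, "cell_count")


class TestReplicateMedianResiduals:
    def test_arithmetic(self):
        m = grid_matrix([[1.0, 2.0, 4.0]], ["E1"] * 3, n_cols=3)
        np.testing.assert_allclose(replicate_median_residuals(m), [[-1.0, 0.0, 2.0]])

    def test_equal_replicates_give_zero(self):
        m = grid_matrix([[5.0, 5.0, 3.0, 3.0]], ["E1", "E1", "E2", "E2"], n_cols=4)
        np.testing.assert_allclose(replicate_median_residuals(m), np.zeros((1, 4)))

    def test_matches_double_loop_oracle(self, small_spots):
        m = build_signal_matrix(small_spots, "cell_count")
        res = replicate_median_residuals(m)
        for i in range(0, m.values.shape[0], 7):  # sample of arrays
            for ecm in m.col_meta.ecm.unique():
                cols = [j for j in range(m.values.shape[1]) if m.col_meta.ecm[j] == ecm]
                vals = m.values[i, cols]
                med = np.nanmedian(vals)
                for j, v in zip(cols, vals):
                    expect = v - med if np.isfinite(v) else np.nan
                    assert res[i, j] == pytest.approx(expect, nan_ok=True)


class TestRUV:
    def test_k0_is_identity(self, small_spots):
        m = build_signal_matrix(small_spots, "cell_count")
        out, model = ruv_normalize(m, 0)
        np.testing.assert_array_equal(out.values, m.values)
        assert model.singular_values is not None  # scree still reported

    def test_rank1_artifact_removed_exactly(self):
        """Noiseless 20x60: MEP means + u v^T (v median-free per ECM group)."""
        rng = np.random.default_rng(42)
        n_arr, n_ecm, reps = 20, 6, 10
        ecm = np.repeat([f"E{i}" for i in range(n_ecm)], reps)
        truth = np.repeat(rng.normal(5, 1, (n_arr, n_ecm)), reps, axis=1)
        u, v = rng.normal(size=n_arr), rng.normal(size=60)
        for i in range(n_ecm):  # artifact visible to the replicate controls
            v[i * reps:(i + 1) * reps] -= np.median(v[i * reps:(i + 1) * reps])
        m = grid_matrix(truth + np.outer(u, v), ecm)
        out, _ = ruv_normalize(m, 1)
        assert np.abs(out.values - truth).max() < 1e-8

    def test_idempotent_in_noiseless_case(self):
        rng = np.random.default_rng(3)
        truth = np.repeat(rng.normal(5, 1, (10, 4)), 5, axis=1)
        u, v = rng.normal(size=10), rng.normal(size=20)
        for i in range(4):
            v[i * 5:(i + 1) * 5] -= np.median(v[i * 5:(i + 1) * 5])
        m = grid_matrix(truth + np.outer(u, v), np.repeat([f"E{i}" for i in range(4)], 5))
        once, _ = ruv_normalize(m, 1)
        twice, _ = ruv_normalize(once, 1)
        assert np.abs(twice.values - once.values).max() < 1e-8

    @pytest.mark.parametrize("shape,k", [((6, 12), 2), ((10, 12), 3), ((5, 8), 1)])
    def test_matches_projection_oracle(self, shape, k):
        """Truncated-SVD removal equals least-squares projection onto the top-k
        right singular subspace computed independently via the R^T R eigenproblem."""
        rng = np.random.default_rng(shape[0] * 100 + k)
        vals = rng.normal(5, 1, shape)
        ecm = np.repeat([f"E{i}" for i in range(shape[1] // 4)], 4)
        m = grid_matrix(vals, ecm, n_cols=4)
        R = replicate_median_residuals(m)
        _, V = eigh(R.T @ R)  # ascending eigenvalues
        Q = V[:, ::-1][:, :k]  # top-k right singular subspace
        proj = R @ Q @ Q.T  # least-squares projection of each row onto span(Q)
        out, _ = ruv_normalize(m, k)
        np.testing.assert_allclose(out.values, vals - proj, atol=1e-8)

    def test_k_exceeding_rank_errors(self):
        m = grid_matrix(np.ones((3, 4)), ["E1", "E1", "E2", "E2"], n_cols=4)
        with pytest.raises(NumericalError, match="rank"):
            ruv_normalize(m, 2)
        with pytest.raises(NumericalError, match="min"):
            ruv_normalize(m, 5)

    def test_replicate_cv_shrinks_on_simulated_batch(self, small_spots):
        """RUV(3) reduces the replicate CV for >= 90% of MEPs."""
        m = build_signal_matrix(small_spots, "cell_count")
        out, _ = ruv_normalize(m, 3)

        def mep_cvs(mat):
            raw = invert_transform(mat.values, mat.transform, mat.transform_eps)
            df = pd.DataFrame({
                "v": raw.ravel(),
                "ecm": np.tile(mat.col_meta.ecm, mat.values.shape[0]),
                "lig": np.repeat(mat.row_meta.ligand, mat.values.shape[1]),
                "tr": np.repeat(mat.row_meta.treatment, mat.values.shape[1])})
            g = df.groupby(["tr", "lig", "ecm"])["v"]
            return (g.std() / g.mean()).dropna()

        before, after = mep_cvs(m), mep_cvs(out)
        assert (after < before).mean() >= 0.90


class TestLoess:
    def test_constant_array_unchanged(self):
        m = grid_matrix(np.full((1, 100), 2.5), ["E"] * 100)
        out, _ = loess_spatial_normalize(m, span=0.5)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-9)

    def test_additive_constant_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (1, 100))
        m1 = grid_matrix(vals, ["E"] * 100)
        m2 = grid_matrix(vals + 7.5, ["E"] * 100)
        o1, _ = loess_spatial_normalize(m1, 0.5)
        o2, _ = loess_spatial_normalize(m2, 0.5)
        np.testing.assert_allclose(o2.values - o1.values, 7.5, atol=1e-9)

    def test_flat_plus_noise_barely_changes(self):
        """No spatial structure: the corrected values stay near the input."""
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            vals = 5.0 + rng.normal(0, 1.0, (1, 700))
            m = grid_matrix(vals, ["E"] * 700, n_cols=35)
            out, _ = loess_spatial_normalize(m, span=0.5)
            assert np.abs(out.values - vals).mean() < 1.0 / 3

    def test_planted_surface_decorrelated(self):
        """Counts with a planted smooth surface: after RUV + LOESS the corrected
        values are uncorrelated with the surface (|r| < 0.05 per array)."""
        d = ms.build_design(46, 7, 15, 8, seed=2, cell_lines=("AU565",),
                            treatments=("DMSO",))
        p = SimulationParams(spatial_amplitude=1.0, batch_sd=0.0, seed=2)
        cells = ms.simulate_experiment(d, p)
        gated, _ = ms.gate_edu(cells)
        spots = ms.summarize_spots(gated, d)
        m = build_signal_matrix(spots, "cell_count")
        mm, _ = ruv_normalize(m, 3)
        mm, _ = loess_spatial_normalize(mm, span=0.5)
        for i, aid in enumerate(mm.row_meta.array_id):
            surf = spatial_field(aid, d.n_rows, d.n_cols, p)
            s = surf[mm.col_meta.spot_row, mm.col_meta.spot_col]
            assert abs(np.corrcoef(mm.values[i], s)[0, 1]) < 0.05
            assert abs(np.corrcoef(m.values[i], s)[0, 1]) > 0.5  # raw was contaminated

    def test_span_too_small_errors_with_feasible_span(self):
        m = grid_matrix(np.random.default_rng(0).normal(size=(1, 100)), ["E"] * 100)
        with pytest.raises(NumericalError, match="feasible span"):
            loess_spatial_normalize(m, span=0.01)


class TestPipeline:
    def test_identity_composition_on_constant_input(self, small_spots):
        spots = small_spots.copy()
        spots["cell_count"] = 32
        out, _ = normalize_pipeline(spots, signals=["cell_count"], k=0, span=0.9)
        np.testing.assert_allclose(out["cell_count"], 32, atol=1e-6)
        np.testing.assert_array_equal(out["cell_count_raw"], 32)

    def test_outputs_finite_where_inputs_finite(self, small_spots):
        out, models = normalize_pipeline(
            small_spots, signals=["cell_count", "edu_fraction"], k=3, span=0.5)
        for sig in ("cell_count", "edu_fraction"):
            fin = np.isfinite(small_spots[sig].astype(float))
            assert np.isfinite(out.loc[fin, sig]).all()
        assert set(models) == {"cell_count", "edu_fraction"}

    def test_errors_annotated_with_signal(self, small_spots):
        with pytest.raises(NumericalError, match="cell_count"):
            normalize_pipeline(small_spots, signals=["cell_count"], k=10_000)
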