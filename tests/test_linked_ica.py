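"""Linked ICA contracts: VB ascent, recovery, ARD, prediction, perturbation."""

import dataclasses

import numpy as np
import pytest

import voxlica.linked_ica as li
from voxlica.components import matched_recovery_score
from voxlica.linked_ica import (
    LinkedModelConfig,
    fit,
    free_energy_terms,
    perturb_genes,
    predict_unseen_features,
)
from voxlica.synthetic import SyntheticSpec, generate_linked_dataset
from voxlica.types import ModalityMatrix


def test_free_energy_trace_non_decreasing(ref_decomp):
    tr = ref_decomp.free_energy_trace
    diffs = np.diff(tr)
    assert np.all(diffs >= -1e-8 * np.abs(tr[:-1]))


def test_convergence_by_relative_change(ref_decomp):
    tr = ref_decomp.free_energy_trace
    assert ref_decomp.converged
    rel = abs(tr[-1] - tr[-2]) / abs(tr[-2])
    assert rel < ref_decomp.config.rel_tol
    assert tr.size <= ref_decomp.config.max_iter


def test_max_iter_exhaustion_flags_unconverged(ref_matrices):
    dec = fit(ref_matrices, LinkedModelConfig(L=5, seed=1, max_iter=5))
    assert not dec.converged
    assert dec.free_energy_trace.size == 5


def test_decomposition_invariants(ref_decomp):
    np.testing.assert_allclose(np.linalg.norm(ref_decomp.H, axis=1), 1.0,
                               atol=1e-10)
    for Wk in ref_decomp.W:
        assert np.all(Wk >= 0.0)
    from scipy.stats import skew
    assert np.all(skew(ref_decomp.H, axis=1) >= 0.0)
    totals = ref_decomp.explained_variance.sum(axis=1)
    assert np.all(np.diff(totals) <= 1e-12)  # sorted descending


def test_noiseless_rank_one_recovered_exactly():
    spec = SyntheticSpec(grid_dims=(8, 8, 8), mask_fill=1.0, L=1, R=(20,),
                         snr=np.inf, missing_fraction=0.0,
                         unique_components=(), seed=3)
    _, mask, _, truth = generate_linked_dataset(spec)
    mat = ModalityMatrix(truth.noisy[0], [f"g{r}" for r in range(20)],
                         "gene", mask)
    dec = fit([mat], LinkedModelConfig(L=1, seed=0))
    rho = np.corrcoef(dec.H[0], truth.H_true[0])[0, 1]
    assert abs(rho) == pytest.approx(1.0, abs=1e-6)
    recon = dec.reconstruct(0, original_units=True)
    np.testing.assert_allclose(recon, truth.noisy[0],
                               rtol=1e-6, atol=1e-6 * np.abs(truth.noisy[0]).max())


def test_planted_source_recovery(ref_decomp, ref_truth):
    _, rhos, _ = matched_recovery_score(ref_decomp.H, ref_truth.H_true)
    assert np.all(rhos >= 0.95)


def test_modality_weight_rank_order_recovered(ref_decomp, ref_truth):
    """After matching, the ordering of the canonical per-modality weights
    ||X^k_:,i|| W^k_i (on the z-scored scale the model sees) is recovered."""
    pairs, _, _ = matched_recovery_score(ref_decomp.H, ref_truth.H_true)
    order = sorted(pairs, key=lambda p: p[1])
    for k in range(2):
        sd = ref_truth.noisy[k].std(axis=1)
        w_true = np.linalg.norm(ref_truth.X_true[k] / sd[:, None], axis=0) \
            * ref_truth.W_true[k]
        est = np.array([ref_decomp.W[k][e] for e, _ in order])
        tru = np.array([w_true[t] for _, t in order])
        np.testing.assert_array_equal(np.argsort(-est), np.argsort(-tru))


def test_ard_shuts_down_surplus_components(overfit_decomp):
    share = overfit_decomp.explained_variance.sum(axis=1)
    share = share / share.sum()
    assert int((share < 0.01).sum()) >= 5


def test_voxel_permutation_equivariance(ref_matrices, ref_decomp):
    rng = np.random.default_rng(0)
    perm = rng.permutation(ref_matrices[0].n_voxels)
    permuted = [
        ModalityMatrix(m.values[:, perm], m.feature_ids, m.modality_name,
                       m.mask)
        for m in ref_matrices
    ]
    dec_p = fit(permuted, LinkedModelConfig(L=5, seed=1))
    np.testing.assert_allclose(dec_p.H, ref_decomp.H[:, perm], atol=1e-6)
    for k in range(2):
        np.testing.assert_allclose(dec_p.W[k], ref_decomp.W[k], rtol=1e-6)


def test_shape_and_validation_errors(ref_matrices, ref_mask):
    short = ModalityMatrix(ref_matrices[1].values[:, :-1],
                           ref_matrices[1].feature_ids, "proj",
                           _shrunk_mask(ref_mask))
    with pytest.raises(ValueError, match="voxel count"):
        fit([ref_matrices[0], short], LinkedModelConfig(L=2))
    with pytest.raises(ValueError, match="rank bound"):
        fit([ref_matrices[1]], LinkedModelConfig(L=31))
    bad = ref_matrices[0].values.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit([bad], LinkedModelConfig(L=2))


def _shrunk_mask(mask):
    from voxlica.types import VoxelMask
    grid = mask.grid.copy()
    grid[tuple(mask.coords[-1])] = False
    return VoxelMask(grid)


class TestReconstruct:
    def test_empty_component_set_is_zero(self, ref_decomp):
        recon = ref_decomp.reconstruct(0, components=[])
        assert not recon.any()

    def test_single_component_equals_outer_product(self, ref_decomp):
        """Manual rank-1 computation for one component."""
        i = 1
        manual = ref_decomp.W[0][i] * np.outer(ref_decomp.X[0][:, i],
                                               ref_decomp.H[i])
        np.testing.assert_allclose(ref_decomp.reconstruct(0, components=[i]),
                                   manual, atol=1e-12)

    def test_all_components_close_to_data(self, ref_decomp, ref_matrices):
        recon = ref_decomp.reconstruct(0, original_units=True)
        y = ref_matrices[0].values
        r2 = 1 - np.sum((y - recon) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.85                   # SNR 10 => ~91% signal variance

    def test_bad_indices_rejected(self, ref_decomp):
        with pytest.raises(IndexError):
            ref_decomp.reconstruct(5)
        with pytest.raises(IndexError):
            ref_decomp.reconstruct(0, components=[99])


class TestExplainedVariance:
    def test_zero_weight_modality_has_zero_contribution(self, ref_decomp,
                                                        ref_truth):
        """The planted gene-only source contributes nothing to projections."""
        pairs, _, _ = matched_recovery_score(ref_decomp.H, ref_truth.H_true)
        unique_est = [e for e, t in pairs if t == 4][0]
        rel = ref_decomp.relative_contribution()
        assert rel[unique_est, 1] < 1e-3
        assert rel[unique_est, 0] > 0.999

    def test_single_component_noiseless_conserves_variance(self):
        spec = SyntheticSpec(grid_dims=(8, 8, 8), mask_fill=1.0, L=1,
                             R=(15, 10), snr=np.inf, missing_fraction=0.0,
                             unique_components=(), seed=5)
        _, mask, _, truth = generate_linked_dataset(spec)
        mats = [ModalityMatrix(truth.noisy[k], [f"f{r}" for r in
                               range(truth.noisy[k].shape[0])], f"m{k}", mask)
                for k in range(2)]
        dec = fit(mats, LinkedModelConfig(L=1, seed=0))
        np.testing.assert_allclose(dec.explained_variance[0], 1.0, atol=1e-3)


class TestFreeEnergyTerms:
    def test_dof_scale_halving_halves_likelihood_term(self, ref_matrices):
        """Term-wise recomputation: the likelihood term is linear in the
        per-modality degrees-of-freedom tempering factor."""
        state = _capture_state(ref_matrices, L=3)
        full = free_energy_terms(state)
        halved = dataclasses.replace(state, lam=state.lam * 0.5)
        half = free_energy_terms(halved)
        for k in range(2):
            assert half[f"likelihood_{k}"] == pytest.approx(
                0.5 * full[f"likelihood_{k}"])
        # prior/entropy terms do not depend on the tempering
        assert half["x_terms"] == pytest.approx(full["x_terms"])
        assert half["h_terms"] == pytest.approx(full["h_terms"])

    def test_invalid_precision_state_rejected(self, ref_matrices):
        state = _capture_state(ref_matrices, L=2)
        state.beta_rate[0] = -1.0
        with pytest.raises(FloatingPointError):
            free_energy_terms(state)


def _capture_state(mats, L, iters=5):
    arrays, _, _, _ = li._coerce_modalities(mats)
    Yz = []
    for Y in arrays:
        mu = Y.mean(axis=1, keepdims=True)
        sd = Y.std(axis=1, keepdims=True)
        Yz.append((Y - mu) / np.where(sd == 0, 1.0, sd))
    cfg = LinkedModelConfig(L=L, seed=1)
    state = li._init_state(Yz, cfg, cfg.dof_scales(len(Yz)))
    for _ in range(iters):
        for k in range(len(Yz)):
            li._update_x(state, k)
            li._update_alpha(state, k)
            li._update_w(state, k)
        li._update_h(state)
        li._update_z(state)
        li._update_mog(state)
        for k in range(len(Yz)):
            li._update_beta(state, k)
    return state


class TestPredictUnseen:
    def test_row_in_span_has_zero_mse(self, ref_decomp):
        basis = ref_decomp.W[0][:, None] * ref_decomp.H
        row = np.array([1.5, -2.0, 0.5, 1.0, -0.5]) @ basis
        _, _, mses = predict_unseen_features(ref_decomp, row, k=0)
        assert mses[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_row_gets_zero_coefficients(self, ref_decomp):
        rng = np.random.default_rng(2)
        row = rng.standard_normal(ref_decomp.n_voxels)
        basis = ref_decomp.W[0][:, None] * ref_decomp.H
        basis = basis - basis.mean(axis=1, keepdims=True)
        P = basis.T @ np.linalg.solve(basis @ basis.T, basis)
        row = row - row @ P
        row -= row.mean()                  # orthogonal to basis and intercept
        row = row / row.std()
        coef, _, mses = predict_unseen_features(ref_decomp, row, k=0)
        assert np.abs(coef).max() < 1e-8
        assert mses[0] == pytest.approx(1.0, abs=1e-6)  # z-scored row variance

    def test_held_out_rows_reach_noise_floor(self):
        spec = SyntheticSpec(seed=7, R=(80, 30), missing_fraction=0.0)
        _, mask, _, truth = generate_linked_dataset(spec)
        train = ModalityMatrix(truth.noisy[0][:60],
                               [f"g{r}" for r in range(60)], "gene", mask)
        proj = ModalityMatrix(truth.noisy[1],
                              [f"i{r}" for r in range(30)], "proj", mask)
        dec = fit([train, proj], LinkedModelConfig(L=5, seed=1))
        held = truth.noisy[0][60:]
        _, _, mses = predict_unseen_features(dec, held, k=0)
        noise_floor = np.mean(truth.noise_sd[0] ** 2 / held.var(axis=1))
        assert mses.mean() <= 1.2 * noise_floor


class TestPerturbGenes:
    def test_scale_one_is_identity(self, ref_decomp):
        delta = perturb_genes(ref_decomp, [ref_decomp.feature_ids[0][0]], 1.0)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_unknown_gene_rejected(self, ref_decomp):
        with pytest.raises(KeyError, match="nope"):
            perturb_genes(ref_decomp, ["nope"], 0.5)

    def test_zero_loading_gene_gives_zero_delta(self, ref_decomp):
        dec = dataclasses.replace(
            ref_decomp, X=[x.copy() for x in ref_decomp.X])
        dec.X[0][7, :] = 0.0
        delta = perturb_genes(dec, [dec.feature_ids[0][7]], 0.0)
        np.testing.assert_allclose(delta, 0.0, atol=1e-10)

    def test_knockout_closed_form_on_rank_one_model(self):
        """L=1 with a single loading gene: silencing it removes exactly the
        baseline component reconstruction from the projections."""
        rng = np.random.default_rng(8)
        N = 200
        H = rng.standard_normal((1, N))
        H /= np.linalg.norm(H)
        X1 = np.zeros((4, 1))
        X1[2, 0] = 1.0
        X2 = rng.standard_normal((3, 1))
        X2 /= np.linalg.norm(X2)
        dec = _manual_decomp(H, [X1, X2], [np.array([2.0]), np.array([1.5])])
        delta = perturb_genes(dec, ["g2"], 0.0)
        np.testing.assert_allclose(delta, -dec.reconstruct(1, components=[0]),
                                   atol=1e-10)


def _manual_decomp(H, X, W):
    from voxlica.linked_ica import LinkedDecomposition
    return LinkedDecomposition(
        H=H, X=X, W=W, noise_precision=[1.0] * len(X),
        free_energy_trace=np.array([0.0]),
        component_order=np.arange(H.shape[0]), converged=True,
        explained_variance=np.ones((H.shape[0], len(X))),
        modality_names=[f"m{k}" for k in range(len(X))],
        feature_ids=[[f"g{r}" for r in range(Xk.shape[0])] for Xk in X],
        row_means=[np.zeros(Xk.shape[0]) for Xk in X],
        row_stds=[np.ones(Xk.shape[0]) for Xk in X],
        config=LinkedModelConfig(L=H.shape[0]),
    )


def test_local_fit_reproduces_global_components(ref_matrices, ref_decomp):
    """Fitting on half the projection features preserves the shared
    spatial maps (the local-vs-global robustness property)."""
    from voxlica.preprocess import subset_features

    half = subset_features(ref_matrices[1], ref_matrices[1].feature_ids[::2])
    dec_half = fit([ref_matrices[0], half], LinkedModelConfig(L=5, seed=1))
    _, rhos, _ = matched_recovery_score(dec_half.H, ref_decomp.H)
    assert np.all(rhos >= 0.7)
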