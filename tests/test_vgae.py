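import numpy as np
import pytest
import scipy.sparse as sp

from stmosaic._autograd import Tensor
from stmosaic._nn import Adam
from stmosaic.spatial_graph import normalize_adjacency
from stmosaic.vgae import (
    LatentEmbedding,
    MaskedVGAE,
    decode_adjacency,
    loss_graph,
    loss_kl,
    loss_sce,
    loss_vgae,
    reparameterize,
)


@pytest.fixture()
def toy_model():
    return MaskedVGAE(in_dim=5, fc_hidden=6, latent_dim=3, gcn_hidden=4, seed=0)


@pytest.fixture()
def toy_graph():
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]:
        A[i, j] = A[j, i] = 1
    return sp.csr_matrix(A)


class TestEncode:
    def test_shapes_and_sum_identity(self, toy_model, toy_graph, rng):
        X = rng.normal(size=(6, 5))
        emb = toy_model.encode_numpy(X, normalize_adjacency(toy_graph))
        assert isinstance(emb, LatentEmbedding)
        for m in (emb.Z_f, emb.mu, emb.logvar, emb.Z_g, emb.Z):
            assert m.shape == (6, 3)
        np.testing.assert_allclose(emb.Z, emb.Z_f + emb.Z_g, atol=1e-12)

    def test_dimension_mismatch_reports_shapes(self, toy_model, toy_graph, rng):
        with pytest.raises(ValueError, match="features"):
            toy_model.encode(rng.normal(size=(6, 9)), normalize_adjacency(toy_graph))

    def test_permutation_equivariance(self, toy_model, toy_graph, rng):
        toy_model.eval()  # running-stat BN so outputs are row-independent
        # push a training batch through first to set plausible running stats
        toy_model.train()
        X = rng.normal(size=(6, 5))
        Ahat = normalize_adjacency(toy_graph)
        toy_model.encode_numpy(X, Ahat)
        toy_model.eval()
        emb = toy_model.encode_numpy(X, Ahat)
        perm = rng.permutation(6)
        P = np.eye(6)[perm]
        Ahat_p = sp.csr_matrix(P @ Ahat.toarray() @ P.T)
        emb_p = toy_model.encode_numpy(X[perm], Ahat_p)
        np.testing.assert_allclose(emb_p.Z, emb.Z[perm], atol=1e-10)

    def test_identity_graph_is_dense_layer(self, toy_model, rng):
        # edgeless graph + self-loops normalizes to the identity; graph conv
        # then acts per-spot, so each row depends only on its own input
        toy_model.eval()
        X = rng.normal(size=(4, 5))
        I = sp.eye(4, format="csr")
        emb = toy_model.encode_numpy(X, I)
        X2 = X.copy()
        X2[3] = rng.normal(size=5)
        emb2 = toy_model.encode_numpy(X2, I)
        np.testing.assert_array_equal(emb.Z[:3], emb2.Z[:3])
        assert np.any(emb.Z[3] != emb2.Z[3])


class TestReparameterize:
    def test_eps_zero_gives_mu(self, rng):
        mu = rng.normal(size=(4, 3))
        logvar = rng.normal(size=(4, 3))
        for mode in ("standard", "literal"):
            np.testing.assert_array_equal(
                reparameterize(mu, logvar, np.zeros_like(mu), mode=mode), mu
            )

    def test_logvar_zero_branches(self, rng):
        mu = rng.normal(size=(2, 2))
        e = rng.normal(size=(2, 2))
        zeros = np.zeros_like(mu)
        np.testing.assert_allclose(
            reparameterize(mu, zeros, e, mode="standard"), mu + e
        )
        np.testing.assert_allclose(reparameterize(mu, zeros, e, mode="literal"), mu)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)), mode="x")


class TestDecodeAdjacency:
    def test_zero_latent_gives_half(self):
        A = decode_adjacency(np.zeros((3, 2)))
        np.testing.assert_allclose(A, np.full((3, 3), 0.5))

    def test_orthonormal_rows_closed_form(self):
        Z = np.eye(2)
        A = decode_adjacency(Z)
        sig1 = 1 / (1 + np.exp(-1))
        np.testing.assert_allclose(np.diag(A), [sig1, sig1])
        np.testing.assert_allclose(A[0, 1], 0.5)

    def test_scaling_asymptote(self):
        Z = np.ones((2, 2)) * 50.0
        A = decode_adjacency(Z)
        assert np.all(A > 1 - 1e-9)

    def test_symmetric_in_unit_interval(self, rng):
        A = decode_adjacency(rng.normal(size=(5, 3)))
        np.testing.assert_allclose(A, A.T, atol=1e-14)
        assert np.all((A > 0) & (A < 1))


class TestDecodeExpression:
    def test_zero_latent_gives_bias(self, toy_model):
        I = sp.eye(4, format="csr")
        out = toy_model.decode_expression(Tensor(np.zeros((4, 3))), I).data
        np.testing.assert_allclose(out, np.tile(toy_model.decoder_b.data, (4, 1)))

    def test_permutation_equivariance(self, toy_model, toy_graph, rng):
        Z = rng.normal(size=(6, 3))
        Ahat = normalize_adjacency(toy_graph)
        out = toy_model.decode_expression(Tensor(Z), Ahat).data
        perm = rng.permutation(6)
        P = np.eye(6)[perm]
        Ahat_p = sp.csr_matrix(P @ Ahat.toarray() @ P.T)
        out_p = toy_model.decode_expression(Tensor(Z[perm]), Ahat_p).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


class TestLosses:
    def test_graph_zero_when_equal(self, rng):
        A = rng.random((4, 4))
        assert loss_graph(A, A) == 0.0

    def test_graph_hand_case(self):
        A = np.zeros((2, 2))
        At = np.zeros((2, 2))
        At[0, 1] = 0.5
        assert loss_graph(A, At) == pytest.approx(0.0625)

    def test_graph_nonnegative(self, rng):
        assert loss_graph(rng.random((3, 3)), rng.random((3, 3))) >= 0

    def test_kl_standard_normal_zero(self):
        assert loss_kl(np.zeros((5, 4)), np.zeros((5, 4))) == 0.0

    def test_kl_single_unit_half(self):
        assert loss_kl(np.ones((1, 1)), np.zeros((1, 1))) == pytest.approx(0.5)

    def test_kl_nonnegative(self, rng):
        for _ in range(20):
            mu = rng.normal(size=(3, 4))
            lv = rng.normal(size=(3, 4))
            assert loss_kl(mu, lv) >= -1e-12

    def test_sce_proportional_zero(self):
        X = np.array([[1.0, 2, 3], [2, 0, 1]])
        assert loss_sce(X, 3.0 * X, np.array([0, 1]), gamma=2) == pytest.approx(0, abs=1e-10)

    def test_sce_orthogonal_gamma2(self):
        X = np.array([[1.0, 0]])
        Xt = np.array([[0.0, 1]])
        assert loss_sce(X, Xt, np.array([0]), gamma=2) == pytest.approx(1.0, abs=1e-9)

    def test_sce_antiparallel_gamma1(self):
        X = np.array([[1.0, 0]])
        assert loss_sce(X, -X, np.array([0]), gamma=1) == pytest.approx(2.0, abs=1e-9)

    def test_sce_bounds(self, rng):
        gamma = 3.0
        for _ in range(20):
            val = loss_sce(
                rng.normal(size=(6, 4)), rng.normal(size=(6, 4)), np.arange(3), gamma
            )
            assert 0 <= val <= 2**gamma + 1e-9

    def test_sce_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            loss_sce(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)), np.array([]))

    def test_sce_gamma_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            loss_sce(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)), [0], gamma=0.5)

    def test_vgae_additivity(self):
        assert loss_vgae(0, 0, 0) == 0
        assert loss_vgae(1, 2, 3) == 6
        assert loss_vgae(0.1, 0.2, 0.3) == pytest.approx(0.6)


class TestTrainingBehavior:
    def test_graph_loss_decreases_over_50_steps(self, rng):
        # edgeless toy graph: training L_graph alone must monotonically improve
        n, d = 12, 3
        model = MaskedVGAE(in_dim=4, fc_hidden=5, latent_dim=d, gcn_hidden=4, seed=1)
        A = np.zeros((n, n))
        Ahat = sp.eye(n, format="csr")
        X = rng.normal(size=(n, 4))
        opt = Adam(model.parameters(), lr=1e-2)
        losses = []
        for _ in range(50):
            emb = model.encode(X, Ahat, eps=np.zeros((n, d)))
            lg = loss_graph(Tensor(A), decode_adjacency(emb["Z"]))
            opt.zero_grad()
            lg.backward()
            opt.step()
            losses.append(float(lg.data))
        assert losses[-1] < losses[0]

    def test_eval_mode_deterministic(self, toy_model, toy_graph, rng):
        X = rng.normal(size=(6, 5))
        Ahat = normalize_adjacency(toy_graph)
        toy_model.eval()
        e1 = toy_model.encode_numpy(X, Ahat)
        e2 = toy_model.encode_numpy(X, Ahat)
        np.testing.assert_array_equal(e1.Z, e2.Z)
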