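"""Loss suite vs independently coded, literal-formula brute-force oracles."""

import numpy as np
import pytest

from medi2i.losses import (
    FixedProjectionExtractor, LossWeights, adversarial_losses,
    cosine_semantic_loss, downsample_mask, l1_loss, mse_loss,
    perceptual_loss, pixel_contrastive_loss, reconstruction_loss,
    structure_consistency_loss, total_loss, triangular_loss,
)
from medi2i.nn.tensor import Tensor

RNG = np.random.default_rng(21)
W = LossWeights()


def stub_zero_extractor(x):
    return [Tensor(np.zeros((1,)))]


def identity_extractor(x):
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    return [t]


# ---------------------------------------------------------------------------
# reconstruction / perceptual / triangular
# ---------------------------------------------------------------------------

class TestReconstruction:
    def test_perfect_reconstruction_zero(self):
        x = RNG.random((2, 1, 8, 8))
        val = reconstruction_loss(x, x, x, x, identity_extractor, W)
        assert val.item() == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_arithmetic(self):
        x = RNG.random((1, 1, 6, 6))
        y = RNG.random((1, 1, 6, 6))
        val = reconstruction_loss(x, y, x + 0.1, y + 0.1, stub_zero_extractor, W)
        assert val.item() == pytest.approx(2.0, rel=1e-9)

    def test_matches_formula_oracle(self):
        extractor = FixedProjectionExtractor(seed=3)
        for _ in range(25):
            xs, xt, rs, rt = (RNG.random((1, 1, 8, 8)) for _ in range(4))
            val = reconstruction_loss(xs, xt, rs, rt, extractor, W).item()
            # independent evaluation: lambda_L1*(L1+L1) + lambda_p*(Lp+Lp)
            def lp(a, b):
                return sum(float(np.mean((fa.data - fb.data) ** 2))
                           for fa, fb in zip(extractor(a), extractor(b)))
            oracle = 10.0 * (np.abs(rs - xs).mean() + np.abs(rt - xt).mean()) \
                + 0.1 * (lp(rs, xs) + lp(rt, xt))
            assert val == pytest.approx(oracle, abs=1e-6)


class TestPerceptual:
    def test_identical_zero_and_symmetric(self):
        extractor = FixedProjectionExtractor(seed=1)
        a, b = RNG.random((1, 1, 8, 8)), RNG.random((1, 1, 8, 8))
        assert perceptual_loss(a, a, extractor).item() == pytest.approx(0.0, abs=1e-12)
        assert perceptual_loss(a, b, extractor).item() == \
            pytest.approx(perceptual_loss(b, a, extractor).item(), rel=1e-9)

    def test_identity_extractor_reduces_to_mse(self):
        a, b = RNG.random((4, 4)), RNG.random((4, 4))
        val = perceptual_loss(a, b, identity_extractor).item()
        assert val == pytest.approx(float(np.mean((a - b) ** 2)), rel=1e-9)


class TestTriangular:
    def test_perfect_roundtrip_zero(self):
        x = RNG.random((1, 1, 8, 8))
        assert triangular_loss(x, x, identity_extractor, W).item() == \
            pytest.approx(0.0, abs=1e-12)

    def test_offset_arithmetic(self):
        x = RNG.random((1, 1, 8, 8))
        val = triangular_loss(x + 0.05, x, stub_zero_extractor, W)
        assert val.item() == pytest.approx(0.5, rel=1e-9)

    def test_matches_oracle(self):
        extractor = FixedProjectionExtractor(seed=5)
        a, b = RNG.random((1, 1, 8, 8)), RNG.random((1, 1, 8, 8))
        def lp(u, v):
            return sum(float(np.mean((fu.data - fv.data) ** 2))
                       for fu, fv in zip(extractor(u), extractor(v)))
        oracle = 10.0 * np.abs(a - b).mean() + 0.1 * lp(a, b)
        assert triangular_loss(a, b, extractor, W).item() == pytest.approx(oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# pixel contrastive + structure consistency
# ---------------------------------------------------------------------------

def pcl_oracle(p: np.ndarray, q: np.ndarray, mask: np.ndarray, tau: float) -> float:
    """Literal double-loop evaluation of the symmetric per-pixel InfoNCE."""
    idx = [(y, x) for y, x in zip(*np.nonzero(mask))]
    total = 0.0
    for (yi, xi) in idx:
        pi, qi = p[:, yi, xi], q[:, yi, xi]
        den_pq = sum(np.exp(pi @ q[:, yj, xj] / tau) for yj, xj in idx)
        den_qp = sum(np.exp(qi @ p[:, yj, xj] / tau) for yj, xj in idx)
        total -= np.log(np.exp(pi @ qi / tau) / den_pq * np.exp(qi @ pi / tau) / den_qp)
    return total


def _unit_features(shape, rng):
    f = rng.normal(size=shape)
    return f / np.linalg.norm(f, axis=0, keepdims=True)


class TestPixelContrastive:
    def test_single_pixel_identical_zero(self):
        p = _unit_features((3, 4, 4), RNG)
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        assert pixel_contrastive_loss(p, p, mask).item() == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_p_q(self):
        p = _unit_features((3, 6, 6), RNG)
        q = _unit_features((3, 6, 6), RNG)
        mask = RNG.random((6, 6)) > 0.5
        a = pixel_contrastive_loss(p, q, mask).item()
        b = pixel_contrastive_loss(q, p, mask).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_empty_mask_zero(self):
        p = _unit_features((3, 4, 4), RNG)
        assert pixel_contrastive_loss(p, p, np.zeros((4, 4), bool)).item() == 0.0

    def test_rejects_unnormalized(self):
        p = RNG.normal(size=(3, 4, 4)) * 5
        mask = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            pixel_contrastive_loss(p, p, mask)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = _unit_features((4, 6, 6), rng)
        q = _unit_features((4, 6, 6), rng)
        mask = rng.random((6, 6)) > 0.6
        if not mask.any():
            mask[0, 0] = True
        val = pixel_contrastive_loss(p, q, mask, tau=0.07).item()
        assert val == pytest.approx(pcl_oracle(p, q, mask, 0.07), abs=1e-6)

    def test_invariant_under_joint_pixel_permutation(self):
        rng = np.random.default_rng(3)
        p = _unit_features((4, 4, 4), rng)
        q = _unit_features((4, 4, 4), rng)
        mask = np.ones((4, 4), bool)
        base = pixel_contrastive_loss(p, q, mask).item()
        perm = rng.permutation(16)
        pp = p.reshape(4, 16)[:, perm].reshape(4, 4, 4)
        qp = q.reshape(4, 16)[:, perm].reshape(4, 4, 4)
        assert pixel_contrastive_loss(pp, qp, mask).item() == pytest.approx(base, rel=1e-9)


class TestStructureConsistency:
    def test_identical_features_single_pixel_zero(self):
        phi = RNG.normal(size=(8, 4, 4))
        mask0 = np.zeros((16, 16), bool)
        mask0[0, 0] = True
        assert structure_consistency_loss(phi, phi, mask0).item() == \
            pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_mse_term(self):
        rng = np.random.default_rng(1)
        phi = rng.normal(size=(8, 4, 4))
        c = 0.3
        mask0 = np.zeros((16, 16), bool)   # empty foreground -> MSE only
        val = structure_consistency_loss(phi, phi + c, mask0).item()
        assert val == pytest.approx(c * c, rel=1e-9)

    def test_mask_downsampling_any_rule(self):
        mask0 = np.zeros((16, 16), bool)
        mask0[5, 9] = True                 # one pixel lights up its 4x4 block
        down = downsample_mask(mask0, 4)
        assert down.sum() == 1 and down[1, 2]

    def test_matches_component_sum(self):
        from medi2i.losses import _normalize_channelwise
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 4, 4))
        b = rng.normal(size=(8, 4, 4))
        mask0 = np.ones((16, 16), bool)
        val = structure_consistency_loss(a, b, mask0).item()
        na = _normalize_channelwise(Tensor(a)).data
        nb = _normalize_channelwise(Tensor(b)).data
        oracle = np.mean((a - b) ** 2) + pcl_oracle(na, nb, np.ones((4, 4), bool), 0.07)
        assert val == pytest.approx(oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# adversarial + cosine + totals
# ---------------------------------------------------------------------------

class _ConstD:
    def __init__(self, value):
        self.value = value

    def __call__(self, x, T):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        return x * 0.0 + self.value


class TestAdversarial:
    def test_perfect_discriminator_zero_d_loss(self):
        x = RNG.random((1, 1, 8, 8))
        class D:
            def __call__(self, img, T):
                img = img if isinstance(img, Tensor) else Tensor(img)
                target = 1.0 if img.data is not None and np.allclose(img.data, x) else 0.0
                return img * 0.0 + target
        d_loss, _ = adversarial_losses(D(), x, x + 1.0, None)
        assert d_loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_half_everywhere(self):
        x = RNG.random((1, 1, 8, 8))
        d_loss, g_loss = adversarial_losses(_ConstD(0.5), x, x, None)
        assert d_loss.item() == pytest.approx(0.5, rel=1e-9)
        assert g_loss.item() == pytest.approx(0.25, rel=1e-9)

    def test_fooled_discriminator_zero_g_loss(self):
        x = RNG.random((1, 1, 8, 8))
        _, g_loss = adversarial_losses(_ConstD(1.0), x, x, None)
        assert g_loss.item() == pytest.approx(0.0, abs=1e-12)


class TestCosine:
    def test_identical_minus_one(self):
        v = RNG.normal(size=8)
        v /= np.linalg.norm(v)
        assert cosine_semantic_loss(v, v).item() == pytest.approx(-1.0, rel=1e-9)

    def test_orthogonal_zero(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        assert cosine_semantic_loss(a, b).item() == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_plus_one(self):
        v = RNG.normal(size=8)
        assert cosine_semantic_loss(v, -v).item() == pytest.approx(1.0, rel=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            cosine_semantic_loss(np.zeros(4), np.ones(4))


class TestTotalLoss:
    def test_all_zero(self):
        comps = dict(rec=0.0, con=0.0, tri=0.0, adv=0.0, cos=0.0)
        assert total_loss(comps, "init", W) == 0.0
        assert total_loss(comps, "fine", W) == 0.0

    def test_init_arithmetic(self):
        assert total_loss(dict(rec=1.0, con=2.0), "init", W) == pytest.approx(3.0)

    def test_fine_arithmetic(self):
        comps = dict(rec=1.0, con=2.0, tri=3.0, adv=0.4, cos=-0.5)
        assert total_loss(comps, "fine", W) == pytest.approx(7.95)

    def test_missing_component_errors(self):
        with pytest.raises(KeyError):
            total_loss(dict(rec=1.0), "init", W)
        with pytest.raises(KeyError):
            total_loss(dict(rec=1.0, con=1.0), "fine", W)

    def test_linear_in_each_component(self):
        rng = np.random.default_rng(0)
        base = dict(rec=rng.random(), con=rng.random(), tri=rng.random(),
                    adv=rng.random(), cos=rng.random())
        coeffs = dict(rec=1.0, con=1.0, tri=1.0, adv=5.0, cos=0.1)
        t0 = total_loss(base, "fine", W)
        for name, lam in coeffs.items():
            bumped = dict(base)
            bumped[name] += 0.25
            assert total_loss(bumped, "fine", W) - t0 == pytest.approx(0.25 * lam)


def test_make_report_populates_stage_totals():
    from medi2i.losses import make_report
    comps = dict(rec=1.0, con=2.0, tri=3.0, adv=0.4, cos=-0.5)
    report = make_report(comps, "fine", W)
    assert report.total_init == pytest.approx(3.0)
    assert report.total_fine == pytest.approx(7.95)
    row = report.as_row()
    assert row["total_fine"] == report.total_fine and row["rec"] == 1.0


def test_weights_must_be_positive():
    with pytest.raises(ValueError):
        LossWeights(lambda_l1=-1.0)


def test_one_adamw_step_decreases_init_total():
    """Smoke property: a single optimizer step on a fixed toy batch lowers
    the initial-stage objective."""
    from medi2i import nn
    from medi2i.translation import Translator, TranslatorConfig
    rng = np.random.default_rng(0)
    cfg = TranslatorConfig(stem_channels=4, stage_channels=(6, 8),
                           stage_blocks=(1, 1), cond_dim=8,
                           disc_channels=(4, 6, 8), disc_blocks=1, hyper_rank=2)
    model = Translator(cfg, rng)
    x_src = rng.random((2, 1, 16, 16)).astype(np.float32)
    x_tgt = rng.random((2, 1, 16, 16)).astype(np.float32)
    T = Tensor(rng.normal(size=(2, 8)).astype(np.float32))

    def objective():
        phi_s = model.encoder(Tensor(x_src))
        phi_t = model.encoder(Tensor(x_tgt))
        rec = reconstruction_loss(x_src, x_tgt,
                                  model.decoder(phi_t, T), model.decoder(phi_s, T),
                                  stub_zero_extractor, W)
        con = mse_loss(phi_s, phi_t)
        return total_loss({"rec": rec, "con": con}, "init", W)

    opt = nn.AdamW(model.parameters(), lr=1e-4)
    first = objective()
    opt.zero_grad()
    first.backward()
    opt.step()
    second = objective()
    assert second.item() < first.item()
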