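"""Dual-encoder contracts and the supervised contrastive objective."""

import numpy as np
import pytest

from medi2i.dclip import (DCLIPModel, ImageEncoderConfig, TextEncoderConfig,
                          dclip_loss, pretrain_dclip, zero_shot_classify)
from medi2i.prompts import KeywordSet, render_prompt
from medi2i.tokenizer import load_default_tokenizer, train_bpe, template_lexicon
from medi2i.nn.tensor import Tensor

TOK = load_default_tokenizer()


def micro_model(seed=0, proj=16):
    tcfg = TextEncoderConfig(layers=1, width=32, heads=2, vocab_size=TOK.vocab_size,
                             max_context=96, projection_dim=proj)
    icfg = ImageEncoderConfig(stage_channels=(8, 8, 16, 16), stage_blocks=(1, 1, 1, 1),
                              pool_heads=2, projection_dim=proj)
    return DCLIPModel(tcfg, icfg, np.random.default_rng(seed), TOK)


def prompt_for(sequence):
    return render_prompt(KeywordSet(organ="brain", plane="axial",
                                    modality="magnetic resonance imaging",
                                    sequence=sequence))


class TestTokenizer:
    def test_roundtrip_lowercased(self):
        s = "A T2-weighted magnetic resonance imaging of the brain for the subject."
        assert TOK.decode(TOK.encode(s)) == \
            "a t2 - weighted magnetic resonance imaging of the brain for the subject ."

    def test_special_tokens_wrap(self):
        ids = TOK.encode("brain")
        assert ids[0] == TOK.sos_id and ids[-1] == TOK.eos_id

    def test_training_deterministic(self):
        a = train_bpe(template_lexicon(), n_merges=50)
        b = train_bpe(template_lexicon(), n_merges=50)
        assert a.vocab == b.vocab and a.merges == b.merges
        assert a.vocab_hash() == b.vocab_hash()


class TestEncoders:
    def test_text_embedding_unit_norm_and_deterministic(self):
        model = micro_model()
        z1 = model.encode_text(prompt_for("T1-weighted"))
        z2 = model.encode_text(prompt_for("T1-weighted"))
        assert z1.shape == (16,)
        assert np.linalg.norm(z1.data) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_array_equal(z1.data, z2.data)

    def test_text_differs_across_sequences(self):
        model = micro_model()
        z1 = model.encode_text(prompt_for("T1-weighted"))
        z2 = model.encode_text(prompt_for("T2-weighted"))
        assert not np.allclose(z1.data, z2.data)

    def test_overlong_prompt_errors_or_truncates(self):
        model = micro_model()
        long_prompt = render_prompt(KeywordSet(
            organ="brain", plane="axial",
            modality="magnetic resonance imaging " * 30))
        with pytest.raises(ValueError):
            model.encode_text(long_prompt)
        model.text_cfg.truncate_overlong = True
        z = model.encode_text(long_prompt)
        assert z.shape == (16,)

    def test_image_embedding_contract(self):
        model = micro_model()
        img = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        z = model.encode_image(img)
        assert z.shape == (16,)
        assert np.linalg.norm(z.data) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_array_equal(z.data, model.encode_image(img).data)

    def test_image_size_divisibility(self):
        model = micro_model()
        # strides (4,2,2,2) x stem 1 -> /32: 64 -> 16 -> 8 -> 4 -> 2
        z = model.encode_image(np.zeros((2, 64, 64), dtype=np.float32))
        assert z.shape == (2, 16)
        with pytest.raises(ValueError):
            model.encode_image(np.zeros((50, 50), dtype=np.float32))

    def test_nonfinite_pixels_rejected(self):
        model = micro_model()
        img = np.full((64, 64), np.nan, dtype=np.float32)
        with pytest.raises(ValueError):
            model.encode_image(img)

    def test_full_size_configs_describe_printed_structure(self):
        # configuration objects carry the full-scale architecture
        tcfg = TextEncoderConfig()
        assert (tcfg.layers, tcfg.width, tcfg.heads) == (12, 768, 12)
        assert tcfg.vocab_size == 49152 and tcfg.max_context == 256
        icfg = ImageEncoderConfig()
        assert icfg.stage_channels == (96, 192, 384, 768)
        assert icfg.stage_blocks == (3, 3, 9, 3)
        assert icfg.stage_strides == (4, 2, 2, 2)


def dclip_oracle(zT, zI, M, tau):
    """Literal nested-loop evaluation of the double-sum objective."""
    zT, zI, M = np.asarray(zT), np.asarray(zI), np.asarray(M)
    total = 0.0
    for i in range(M.shape[0]):           # text -> images
        matches = np.nonzero(M[i])[0]
        if matches.size == 0:
            continue
        den = sum(np.exp(zT[i] @ zI[j] / tau) for j in range(zI.shape[0]))
        total -= sum(np.log(np.exp(zT[i] @ zI[m] / tau) / den)
                     for m in matches) / matches.size
    for i in range(M.shape[1]):           # image -> texts
        matches = np.nonzero(M[:, i])[0]
        if matches.size == 0:
            continue
        den = sum(np.exp(zI[i] @ zT[j] / tau) for j in range(zT.shape[0]))
        total -= sum(np.log(np.exp(zI[i] @ zT[m] / tau) / den)
                     for m in matches) / matches.size
    return total


def infonce_reference(zT, zI, tau):
    """Standard symmetric CLIP loss (independent routine, identity labels)."""
    zT, zI = np.asarray(zT), np.asarray(zI)
    logits = zT @ zI.T / tau
    def ce(lg):
        lse = np.log(np.exp(lg - lg.max(1, keepdims=True)).sum(1)) + lg.max(1)
        return -(np.diag(lg) - lse).sum()
    return ce(logits) + ce(logits.T)


def _unit_rows(rng, n, d):
    z = rng.normal(size=(n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


class TestDCLIPLoss:
    def test_single_pair_zero(self):
        z = np.array([[1.0, 0.0]])
        assert dclip_loss(z, z, [[1]], 0.07).item() == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_identity_hand_value(self):
        zT = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = 4 * np.log(1 + np.exp(-1 / 0.07))
        assert dclip_loss(zT, zT, np.eye(2), 0.07).item() == \
            pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        zT = _unit_rows(rng, 8, 6)
        zI = _unit_rows(rng, 8, 6)
        M = (rng.random((8, 8)) > 0.6).astype(int)
        np.fill_diagonal(M, 1)
        val = dclip_loss(zT, zI, M, 0.07).item()
        assert val == pytest.approx(dclip_oracle(zT, zI, M, 0.07), abs=1e-6)

    def test_zero_match_rows_contribute_zero(self):
        rng = np.random.default_rng(0)
        zT = _unit_rows(rng, 3, 4)
        zI = _unit_rows(rng, 3, 4)
        M = np.eye(3, dtype=int)
        M[2] = 0                          # text 2 matches nothing
        M[:, 2] = 0                       # image 2 matched by nothing
        val = dclip_loss(zT, zI, M, 0.07).item()
        assert val == pytest.approx(dclip_oracle(zT, zI, M, 0.07), abs=1e-9)
        assert np.isfinite(val)

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_identity_matrix_equals_infonce(self, n):
        rng = np.random.default_rng(n)
        zT = _unit_rows(rng, n, 8)
        zI = _unit_rows(rng, n, 8)
        val = dclip_loss(zT, zI, np.eye(n), 0.07).item()
        assert val == pytest.approx(infonce_reference(zT, zI, 0.07), abs=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        zT = _unit_rows(rng, 6, 8)
        zI = _unit_rows(rng, 6, 8)
        M = (rng.random((6, 6)) > 0.5).astype(int)
        np.fill_diagonal(M, 1)
        base = dclip_loss(zT, zI, M, 0.07).item()
        perm = rng.permutation(6)
        permuted = dclip_loss(zT, zI[perm], M[:, perm], 0.07).item()
        assert permuted == pytest.approx(base, rel=1e-9)

    def test_nonnegative_and_perfect_concentration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            zT = _unit_rows(rng, 5, 8)
            zI = _unit_rows(rng, 5, 8)
            M = (rng.random((5, 5)) > 0.5).astype(int)
            assert dclip_loss(zT, zI, M, 0.07).item() >= 0.0

    def test_invalid_temperature(self):
        z = np.eye(2)
        with pytest.raises(ValueError):
            dclip_loss(z, z, np.eye(2), 0.0)


class TestZeroShot:
    def test_exact_candidate_wins(self):
        cands = np.eye(4)
        assert zero_shot_classify(cands[2], list(cands)) == 2

    def test_tie_resolves_to_lower_index(self):
        v = np.array([1.0, 0.0])
        cands = [np.array([0.0, 1.0]), v.copy(), v.copy()]
        assert zero_shot_classify(v, cands) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=8)
        cands = [rng.normal(size=8) for _ in range(6)]
        sims = [c @ v / np.linalg.norm(c) / np.linalg.norm(v) for c in cands]
        assert zero_shot_classify(v, cands) == int(np.argmax(sims))


class TestPretraining:
    def _toy_corpus(self, n=16):
        rng = np.random.default_rng(0)
        corpus = []
        for i in range(n):
            seq = ["T1-weighted", "T2-weighted"][i % 2]
            base = 0.2 if i % 2 == 0 else 0.7
            img = np.clip(base + 0.05 * rng.normal(size=(32, 32)), 0, 1).astype(np.float32)
            corpus.append((img, prompt_for(seq)))
        return corpus

    def micro_cfgs(self):
        tcfg = TextEncoderConfig(layers=1, width=32, heads=2,
                                 vocab_size=TOK.vocab_size, max_context=96,
                                 projection_dim=16)
        icfg = ImageEncoderConfig(stage_channels=(8, 8, 16, 16),
                                  stage_blocks=(1, 1, 1, 1), pool_heads=2,
                                  projection_dim=16)
        return tcfg, icfg

    def test_loss_decreases_on_heldout_batch(self):
        corpus = self._toy_corpus()
        tcfg, icfg = self.micro_cfgs()
        held_imgs = np.stack([c[0] for c in corpus[:8]])[:, None]
        held_prompts = [c[1] for c in corpus[:8]]
        M = np.zeros((8, 8), int)
        for i in range(8):
            for j in range(8):
                M[i, j] = held_prompts[i].texts() == held_prompts[j].texts()

        def held_loss(model):
            zT = model.encode_text(held_prompts)
            zI = model.encode_image(Tensor(held_imgs))
            return dclip_loss(zT, zI, M, 0.07).item()

        model0 = DCLIPModel(tcfg, icfg, np.random.default_rng(5), TOK)
        before = held_loss(model0)
        model, _ = pretrain_dclip(corpus, tcfg, icfg, epochs=3, batch_size=8,
                                  rng=np.random.default_rng(5), lr=3e-4)
        assert held_loss(model) < before

    def test_same_seed_identical_loss_sequence(self):
        corpus = self._toy_corpus(8)
        tcfg, icfg = self.micro_cfgs()
        _, h1 = pretrain_dclip(corpus, tcfg, icfg, epochs=2, batch_size=4,
                               rng=np.random.default_rng(9), lr=1e-4)
        _, h2 = pretrain_dclip(corpus, tcfg, icfg, epochs=2, batch_size=4,
                               rng=np.random.default_rng(9), lr=1e-4)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_empty_corpus_errors(self):
        tcfg, icfg = self.micro_cfgs()
        with pytest.raises(ValueError):
            pretrain_dclip([], tcfg, icfg, epochs=1, batch_size=4,
                           rng=np.random.default_rng(0))

    def test_log_csv_written(self, tmp_path):
        corpus = self._toy_corpus(8)
        tcfg, icfg = self.micro_cfgs()
        log = tmp_path / "dclip.csv"
        pretrain_dclip(corpus, tcfg, icfg, epochs=1, batch_size=4,
                       rng=np.random.default_rng(0), log_path=log)
        assert log.read_text().startswith("epoch,loss")


def test_checkpoint_roundtrip(tmp_path):
    model = micro_model(seed=3)
    path = tmp_path / "dclip.npz"
    model.save(path)
    back = DCLIPModel.load_from(path)
    img = np.random.default_rng(1).random((64, 64)).astype(np.float32)
    np.testing.assert_array_equal(model.encode_image(img).data,
                                  back.encode_image(img).data)
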