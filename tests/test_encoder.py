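"""Architecture contracts: position encoding, masked attention, the
convolution unit's shortcut, block composition, and padding invariance."""

import math
from dataclasses import replace

import numpy as np
import pytest

import cropformer as cf
from cropformer.data import ValidationError
from cropformer.encoder import (
    ConvModule,
    CropformerBlock,
    CropformerEncoder,
    CropResidual,
    FeedForward,
    MultiHeadAttention,
)
from cropformer.nn import Tensor

CFG = replace(cf.SMALL_PROFILE, dropout=0.0)


def small_encoder(seed=0, cfg=CFG):
    enc = CropformerEncoder(cfg, np.random.default_rng(seed))
    enc.eval()
    return enc


class TestPositionEncode:
    def test_doy_zero_gives_sin0_cos0_pattern(self):
        out = cf.position_encode(np.array([0]), d_time=8)
        assert np.allclose(out[0, 0::2], 0.0)
        assert np.allclose(out[0, 1::2], 1.0)

    def test_matches_scalar_evaluation(self):
        # independent closed-form check at d_time=128, base 10000
        out = cf.position_encode(np.array([91]), d_time=128, pe_base=10000.0)
        assert out[0, 0] == pytest.approx(math.sin(91.0), abs=1e-9)
        assert out[0, 1] == pytest.approx(math.cos(91.0), abs=1e-9)
        for k in (3, 17, 63):
            arg = 91.0 / 10000.0 ** (2 * k / 128)
            assert out[0, 2 * k] == pytest.approx(math.sin(arg), abs=1e-9)
            assert out[0, 2 * k + 1] == pytest.approx(math.cos(arg), abs=1e-9)

    def test_unit_circle_identity_and_range(self):
        rng = np.random.default_rng(0)
        doy = rng.integers(1, 366, size=50)
        out = cf.position_encode(doy, d_time=64)
        assert np.all(np.abs(out) <= 1.0 + 1e-12)
        sq = out[:, 0::2] ** 2 + out[:, 1::2] ** 2
        assert np.allclose(sq, 1.0, atol=1e-6)

    def test_odd_width_rejected(self):
        with pytest.raises(ValidationError):
            cf.position_encode(np.array([5]), d_time=7)

    def test_configurable_base_changes_frequencies(self):
        a = cf.position_encode(np.array([140]), 16, pe_base=1000.0)
        b = cf.position_encode(np.array([140]), 16, pe_base=10000.0)
        assert not np.allclose(a, b)


class TestEmbedding:
    def test_concat_order_temporal_first(self, make_seq):
        enc = small_encoder()
        s = make_seq(doy=[15, 60, 200])
        batch = cf.pad_batch([s])
        x = enc.embed(batch).data
        pe = cf.position_encode(batch.doy, CFG.d_time, CFG.pe_base)
        assert x.shape[-1] == CFG.d_time + CFG.d_spec
        assert np.allclose(x[..., : CFG.d_time], pe, atol=1e-6)

    def test_token_embedding_is_rowwise_affine(self, make_seq):
        enc = small_encoder()
        s = make_seq(doy=list(range(10, 80, 10)))
        assert s.t == 7
        batch = cf.pad_batch([s])
        tok = enc.token(Tensor(batch.spectra)).data
        assert tok.shape == (1, 7, CFG.d_spec)
        # linearity with zero bias
        enc.token.bias.data[:] = 0.0
        t1 = enc.token(Tensor(batch.spectra)).data
        t2 = enc.token(Tensor(2.0 * batch.spectra)).data
        assert np.allclose(t2, 2.0 * t1, atol=1e-5)

    def test_shifted_doy_changes_embedding(self, make_seq):
        enc = small_encoder()
        a = make_seq(doy=[20, 40, 60], seed=3)
        b = cf.SpectralSequence("b", a.doy + 30, a.spectra)
        xa = enc.embed(cf.pad_batch([a])).data
        xb = enc.embed(cf.pad_batch([b])).data
        # spectral halves agree, temporal halves differ per the closed form
        assert np.allclose(xa[..., CFG.d_time:], xb[..., CFG.d_time:], atol=1e-6)
        assert not np.allclose(xa[..., : CFG.d_time], xb[..., : CFG.d_time])


def loop_attention_oracle(x, mha, valid_mask):
    """Straight-line transcription of single-head scaled dot-product
    attention with key masking, including the output projection."""
    n, T, d = x.shape
    out = np.zeros_like(x)
    W1, b1 = mha.l1.weight.data, mha.l1.bias.data
    W2, b2 = mha.l2.weight.data, mha.l2.bias.data
    W3, b3 = mha.l3.weight.data, mha.l3.bias.data
    Wo, bo = mha.out.weight.data, mha.out.bias.data
    for i in range(n):
        q = x[i] @ W1 + b1
        k = x[i] @ W2 + b2
        v = x[i] @ W3 + b3
        ctx = np.zeros((T, d))
        for t in range(T):
            logits = np.array([
                q[t] @ k[u] / mha.scale if valid_mask[i, u] else -np.inf
                for u in range(T)
            ])
            w = np.exp(logits - logits[np.isfinite(logits)].max())
            w[~np.isfinite(logits)] = 0.0
            w = w / w.sum()
            ctx[t] = sum(w[u] * v[u] for u in range(T))
        out[i] = ctx @ Wo + bo
    return out


class TestAttention:
    def make(self, n_heads=1, d=8, seed=0):
        cfg = replace(CFG, d_spec=d // 2, d_time=d // 2, n_heads=n_heads)
        return MultiHeadAttention(cfg, np.random.default_rng(seed))

    def test_single_head_matches_loop_oracle(self, f64):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 4, 8))
        mask = np.ones((3, 4), bool)
        mask[1, 2:] = False
        mha = self.make()
        got = mha(Tensor(x), mask).data
        want = loop_attention_oracle(x, mha, mask)
        assert np.abs(got - want).max() < 1e-5

    def test_masked_keys_get_exactly_zero_weight(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 6, 8))
        mask = np.ones((2, 6), bool)
        mask[0, 4:] = False
        mha = self.make(n_heads=2)
        w = mha.attention_weights(Tensor(x), mask)
        assert np.all(w[0, :, :, 4:] == 0.0)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)

    def test_singleton_sequence_ignores_query_and_key_maps(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 1, 8))
        mask = np.ones((1, 1), bool)
        mha = self.make()
        base = mha(Tensor(x), mask).data
        mha.l1.weight.data[:] = rng.normal(size=mha.l1.weight.shape)
        mha.l2.weight.data[:] = rng.normal(size=mha.l2.weight.shape)
        again = mha(Tensor(x), mask).data
        assert np.allclose(base, again, atol=1e-6)

    def test_padded_spectra_cannot_influence_valid_outputs(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 5, 8)).astype(np.float32)
        mask = np.ones((1, 5), bool)
        mask[0, 3:] = False
        mha = self.make(n_heads=2)
        a = mha(Tensor(x), mask).data[:, :3]
        x2 = x.copy()
        x2[0, 3:] = 99.0
        b = mha(Tensor(x2), mask).data[:, :3]
        assert np.array_equal(a, b)

    def test_all_keys_masked_is_an_error(self):
        mha = self.make()
        x = np.zeros((1, 3, 8))
        with pytest.raises(ValidationError):
            mha(Tensor(x), np.zeros((1, 3), bool))


class TestConvModule:
    def test_eval_mode_deterministic(self, make_seq):
        cm = ConvModule(CFG, np.random.default_rng(1))
        cm.eval()
        x = np.random.default_rng(2).normal(size=(2, 6, CFG.d_model))
        mask = np.ones((2, 6), bool)
        a = cm(Tensor(x), mask).data
        b = cm(Tensor(x), mask).data
        assert np.array_equal(a, b)

    def test_crop_residual_inner_shortcut_identity(self):
        cr = CropResidual(CFG, np.random.default_rng(3))
        cr.eval()
        cr.pw2.weight.data[:] = 0.0
        cr.pw2.bias.data[:] = 0.0
        x = np.random.default_rng(4).normal(size=(2, 5, CFG.d_model))
        out = cr(Tensor(x), np.ones((2, 5), bool)).data
        assert np.allclose(out, x, atol=1e-6)

    def test_padding_extension_leaves_valid_positions_unchanged(self, f64):
        cm = ConvModule(CFG, np.random.default_rng(5))
        cm.eval()
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 4, CFG.d_model))
        mask = np.ones((1, 4), bool)
        out_plain = cm(Tensor(x), mask).data
        xp = np.concatenate([x, np.zeros((1, 5, CFG.d_model))], axis=1)
        mp = np.concatenate([mask, np.zeros((1, 5), bool)], axis=1)
        out_padded = cm(Tensor(xp), mp).data
        assert np.abs(out_padded[:, :4] - out_plain).max() < 1e-10


class TestFeedForward:
    def test_position_wise_permutation_equivariance(self):
        ffn = FeedForward(CFG, np.random.default_rng(7))
        ffn.eval()
        x = np.random.default_rng(8).normal(size=(1, 6, CFG.d_model)).astype(np.float32)
        perm = np.array([3, 1, 5, 0, 4, 2])
        a = ffn(Tensor(x)).data[:, perm]
        b = ffn(Tensor(x[:, perm])).data
        assert np.array_equal(a, b)

    def test_zero_weights_give_bias_broadcast(self):
        ffn = FeedForward(CFG, np.random.default_rng(9))
        ffn.eval()
        ffn.lin1.weight.data[:] = 0.0
        ffn.lin2.weight.data[:] = 0.0
        x = np.random.default_rng(10).normal(size=(2, 3, CFG.d_model))
        out = ffn(Tensor(x)).data
        assert np.allclose(out, ffn.lin2.bias.data, atol=1e-7)

    def test_full_profile_ffn_width_default(self):
        assert cf.ModelConfig().d_ffn == 1024


class TestBlock:
    def test_three_residual_stages_match_composition(self, f64):
        blk = CropformerBlock(CFG, np.random.default_rng(11))
        blk.eval()
        rng = np.random.default_rng(12)
        x = rng.normal(size=(2, 5, CFG.d_model))
        mask = np.ones((2, 5), bool)
        got = blk(Tensor(x), mask).data

        xt = Tensor(x)
        x1 = xt + blk.ln_attn(blk.mha(xt, mask))
        x2 = x1 + blk.cm(x1, mask)
        want = (x2 + blk.ln_ffn(blk.ffn(x2))).data
        assert np.abs(got - want).max() < 1e-10

    def test_shape_preserved_and_values_changed_by_stack(self, tiny_world):
        cfg = replace(CFG, n_blocks=3)
        enc = small_encoder(cfg=cfg)
        batch = cf.pad_batch(tiny_world["train"].samples[:3])
        x0 = enc.embed(batch)
        out = enc(batch)
        assert out.shape == x0.shape
        assert not np.allclose(out.data, x0.data)


class TestEncoder:
    def test_padding_invariance_at_valid_positions(self, f64, tiny_world):
        enc = small_encoder(seed=13)
        samples = sorted(tiny_world["train"].samples[:6], key=lambda s: s.t)
        short = samples[0]
        alone = enc(cf.pad_batch([short])).data[0, : short.t]
        batched = enc(cf.pad_batch(samples)).data[0, : short.t]
        assert np.abs(alone - batched).max() < 1e-5

    def test_deterministic_weight_initialization(self):
        a = small_encoder(seed=21)
        b = small_encoder(seed=21)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)

    def test_parameter_count_independent_of_sequence_length(self, make_seq):
        enc = small_encoder()
        n0 = enc.n_parameters()
        enc(cf.pad_batch([make_seq(doy=list(range(1, 6)))]))
        enc(cf.pad_batch([make_seq(doy=list(range(1, 101, 2)))]))
        assert enc.n_parameters() == n0

    def test_band_mismatch_rejected(self, make_seq):
        enc = small_encoder()
        with pytest.raises(ValidationError):
            enc(cf.pad_batch([make_seq(n_bands=3)]))

    def test_checkpoint_round_trip_bit_exact(self, tmp_path, tiny_world):
        enc = small_encoder(seed=31)
        w = cf.EncoderWeights.from_encoder(enc)
        cf.save_checkpoint(w, tmp_path / "enc.npz")
        back, extra, meta = cf.load_checkpoint(tmp_path / "enc.npz")
        assert back.config == enc.config
        for k, v in w.state.items():
            assert np.array_equal(back.state[k], v)
        batch = cf.pad_batch(tiny_world["train"].samples[:2])
        rebuilt = back.build()
        rebuilt.eval()
        assert np.array_equal(rebuilt(batch).data, enc(batch).data)


class TestModelConfig:
    def test_full_size_defaults(self):
        c = cf.ModelConfig()
        assert (c.n_blocks, c.n_crop_residual, c.n_heads) == (3, 2, 8)
        assert c.d_model == 256 and c.d_ffn == 1024
        assert (c.kernel_size, c.conv_padding, c.conv_stride) == (7, 3, 1)
        assert c.dropout == 0.1

    @pytest.mark.parametrize("bad", [
        dict(d_spec=100, d_time=100, n_heads=3),     # not divisible
        dict(kernel_size=6, conv_padding=2),         # even kernel
        dict(conv_padding=2),                        # not length-preserving
        dict(d_time=15),                             # odd temporal width
        dict(dropout=1.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValidationError):
            replace(cf.ModelConfig(), **bad)
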