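"""Architecture contracts: patch arithmetic, text encoding, masked fusion,
AFT head, baselines."""
import numpy as np
import pytest

from mmsurv.nn.autodiff import Tensor
from mmsurv.nn.model import (
    FusionConfig,
    PatchEmbed,
    SurvivalTransformer,
    build_baseline,
    count_parameters,
    encode_text,
    load_checkpoint,
    nll_loss,
    save_checkpoint,
)
from mmsurv.tabular import PromptSet


def toy_prompts(n=1, missing=()):
    entries = [
        ("age_bin", "The patient is between 48 and 63 years old",
         "clinical_genetic"),
        ("sex", "The patient is male", "clinical_genetic"),
        ("idh", "The IDH gene is wildtype", "clinical_genetic"),
        ("eor", "The patient underwent gross total resection", "treatment"),
        ("radiotherapy", "The patient received radiotherapy", "treatment"),
    ]
    entries = [
        (v, None if v in missing else p, m) for v, p, m in entries
    ]
    return [PromptSet(tuple(entries)) for _ in range(n)]


@pytest.fixture(scope="module")
def small_config():
    return FusionConfig(embed_dim=32, n_heads=4, n_encoder_layers=1,
                        n_fusion_layers=1, volume_shape=(16, 16, 8),
                        patch_size=(8, 8, 4), adaptor_hidden=32, seed=0)


@pytest.fixture(scope="module")
def small_volumes():
    rng = np.random.default_rng(5)
    return rng.normal(size=(3, 4, 16, 16, 8))


class TestPatchEmbed:
    def test_full_scale_token_count(self):
        cfg = FusionConfig(embed_dim=64, volume_shape=(160, 192, 40),
                           patch_size=(16, 16, 8))
        pe = PatchEmbed(np.random.default_rng(0), cfg)
        assert pe.n_tokens == 600

    def test_toy_token_count(self):
        cfg = FusionConfig(volume_shape=(24, 24, 8), patch_size=(8, 8, 4))
        pe = PatchEmbed(np.random.default_rng(0), cfg)
        assert pe.n_tokens == 18

    def test_indivisible_shape_names_axis(self):
        with pytest.raises(ValueError, match="axis 1"):
            FusionConfig(volume_shape=(24, 25, 8), patch_size=(8, 8, 4))

    def test_zero_volume_gives_positional_encodings_plus_bias(self):
        cfg = FusionConfig(embed_dim=16, volume_shape=(16, 16, 8),
                           patch_size=(8, 8, 4))
        pe = PatchEmbed(np.random.default_rng(1), cfg)
        out = pe(np.zeros((2, 4, 16, 16, 8)))
        expected = pe.pos.data + pe.proj.bias.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)
        np.testing.assert_allclose(out.data[1], expected, atol=1e-12)


class TestEncodeText:
    def test_identical_prompt_identical_vector(self):
        t1 = encode_text(toy_prompts(), dim=32, seed=0)
        t2 = encode_text(toy_prompts(), dim=32, seed=0)
        np.testing.assert_array_equal(t1.embeddings, t2.embeddings)

    def test_missing_variable_masked(self):
        t = encode_text(toy_prompts(missing=("idh",)), dim=32, seed=0)
        idx = 2
        assert not t.presence_mask[0, idx]
        np.testing.assert_array_equal(t.embeddings[0, idx], 0.0)
        assert t.presence_mask[0, 0]

    def test_distinct_prompts_nearly_orthogonal_at_d64(self):
        from mmsurv.tabular import _templates

        vecs = encode_text(
            [PromptSet(tuple((f"v{i}", p, "clinical_genetic")
                             for i, (p, _) in enumerate(_templates().values())))],
            dim=64, seed=0,
        ).embeddings[0]
        sims = vecs @ vecs.T
        off = sims[~np.eye(len(vecs), dtype=bool)]
        assert np.quantile(np.abs(off), 0.99) < 0.5

    def test_modality_filtering(self):
        t = encode_text(toy_prompts(), dim=16, seed=0, modality="treatment")
        assert t.embeddings.shape[1] == 2

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            encode_text(toy_prompts(), backend="word2vec")

    def test_pretrained_backend_unavailable_is_informative(self):
        with pytest.raises(RuntimeError, match="hashed_stub"):
            encode_text(toy_prompts(), backend="pretrained_lm")


class TestFusion:
    def test_attention_sums_to_one_over_unmasked(self, small_config,
                                                 small_volumes):
        model = SurvivalTransformer(small_config)
        out = model.forward(small_volumes, toy_prompts(3, missing=("sex",)))
        for w in out.attention_records:
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_masked_positions_bitwise_irrelevant(self, small_config,
                                                 small_volumes):
        model = SurvivalTransformer(small_config)
        prompts = toy_prompts(3, missing=("idh", "radiotherapy"))
        o1 = model.forward(small_volumes, prompts)
        # second pass: perturb the (zero) embeddings at masked positions by
        # overriding the mask on random data via the override hook
        n_tab = 5
        mask = np.ones((3, n_tab), dtype=bool)
        mask[:, [2, 4]] = False
        o_zero = model.forward(small_volumes, toy_prompts(3),
                               tabular_mask_override=mask)
        o_masked_values = model.forward(
            small_volumes, toy_prompts(3, missing=("idh", "radiotherapy")),
            tabular_mask_override=mask,
        )
        np.testing.assert_array_equal(o_zero.params.log_lambda,
                                      o_masked_values.params.log_lambda)
        np.testing.assert_array_equal(o1.params.log_lambda,
                                      o_zero.params.log_lambda)

    def test_all_masked_raises(self, small_config):
        model = SurvivalTransformer(small_config, use_image=False)
        prompts = toy_prompts(1, missing=("age_bin", "sex", "idh", "eor",
                                          "radiotherapy"))
        with pytest.raises(ValueError, match="no observed modality"):
            model.forward(None, prompts)

    def test_image_fully_masked_equals_nimt_with_shared_weights(
            self, small_config, small_volumes):
        full = SurvivalTransformer(small_config, use_image=True)
        nimt = SurvivalTransformer(small_config, use_image=False)
        shared = nimt.state_dict().keys()
        full_state = full.state_dict()
        nimt.load_state_dict({k: full_state[k] for k in shared})
        prompts = toy_prompts(3, missing=("sex",))
        out_full = full.forward(None, prompts)  # image stream absent
        out_nimt = nimt.forward(small_volumes, prompts)
        np.testing.assert_allclose(out_full.params.log_lambda,
                                   out_nimt.params.log_lambda, atol=1e-12)
        np.testing.assert_allclose(out_full.params.log_rho,
                                   out_nimt.params.log_rho, atol=1e-12)

    def test_prompt_token_permutation_invariance(self, small_config,
                                                 small_volumes):
        model = SurvivalTransformer(small_config)
        base = toy_prompts(2, missing=("idh",))[0]
        clin = [e for e in base.entries if e[2] == "clinical_genetic"]
        trt = [e for e in base.entries if e[2] == "treatment"]
        permuted = PromptSet(tuple(clin[::-1] + trt[::-1]))
        o1 = model.forward(small_volumes[:1], [base])
        o2 = model.forward(small_volumes[:1], [permuted])
        np.testing.assert_allclose(o1.params.log_lambda, o2.params.log_lambda,
                                   atol=1e-10)


class TestAFTHead:
    def test_initialization_contract(self, small_config, small_volumes):
        model = SurvivalTransformer(small_config)
        out = model.forward(small_volumes, toy_prompts(3))
        np.testing.assert_allclose(np.exp(out.params.log_lambda), 24.0,
                                   rtol=1e-9)
        np.testing.assert_allclose(np.exp(out.params.log_rho), 1.0, rtol=1e-9)

    def test_outputs_inside_clamp_ranges_for_extreme_inputs(self, small_config):
        from mmsurv.nn.model import AFTHead
        from mmsurv.weibull import LOG_LAMBDA_RANGE, LOG_RHO_RANGE

        rng = np.random.default_rng(2)
        head = AFTHead(rng, 8, small_config)
        head.head_lambda.weight.data[:] = rng.normal(size=(8, 1)) * 100
        head.head_rho.weight.data[:] = rng.normal(size=(8, 1)) * 100
        x = Tensor(rng.normal(size=(20, 8)) * 50)
        ll, lr = head(x, x)
        assert np.all(ll.data <= LOG_LAMBDA_RANGE[1] + 1e-9)
        assert np.all(ll.data >= LOG_LAMBDA_RANGE[0] - 1e-9)
        assert np.all(lr.data <= LOG_RHO_RANGE[1] + 1e-9)
        assert np.all(lr.data >= LOG_RHO_RANGE[0] - 1e-9)

    def test_gradient_flows_to_both_queries(self, small_config, small_volumes):
        model = SurvivalTransformer(small_config)
        # break the symmetric zero-init so gradients reach both heads
        rng = np.random.default_rng(3)
        model.aft_head.head_lambda.weight.data[:] = rng.normal(size=(32, 1)) * 0.1
        model.aft_head.head_rho.weight.data[:] = rng.normal(size=(32, 1)) * 0.1
        out = model.forward(small_volumes, toy_prompts(3))
        loss = nll_loss(out.log_lambda_t, out.log_rho_t, [5.0, 10.0, 20.0],
                        [1, 0, 1])
        loss.backward()
        assert model.queries.grad is not None
        assert np.abs(model.queries.grad[0]).max() > 0
        assert np.abs(model.queries.grad[1]).max() > 0


class TestBaselines:
    def test_nimt_never_reads_volume(self, small_config, small_volumes):
        nimt = build_baseline("nimt", small_config)
        prompts = toy_prompts(3)
        o1 = nimt.forward(small_volumes, prompts)
        o2 = nimt.forward(small_volumes * 100 + 7, prompts)
        np.testing.assert_array_equal(o1.params.log_lambda,
                                      o2.params.log_lambda)

    def test_all_models_output_params_per_subject(self, small_config):
        rng = np.random.default_rng(6)
        vols = rng.normal(size=(8, 4, 16, 16, 8))
        prompts = toy_prompts(8)
        for kind in ("cnn", "vit_image_only", "nimt"):
            model = build_baseline(kind, small_config)
            out = model.forward(vols, prompts)
            assert out.params.log_lambda.shape == (8,)
            assert out.params.log_rho.shape == (8,)

    def test_parameter_counts(self, small_config):
        counts = {k: count_parameters(build_baseline(k, small_config))
                  for k in ("cnn", "vit_image_only", "nimt")}
        assert all(c > 0 for c in counts.values())
        assert counts["cnn"] != counts["vit_image_only"]

    def test_unknown_kind_rejected(self, small_config):
        with pytest.raises(ValueError):
            build_baseline("mlp", small_config)


class TestConfigValidation:
    def test_embed_dim_head_divisibility(self):
        with pytest.raises(ValueError):
            FusionConfig(embed_dim=30, n_heads=4)

    def test_unknown_text_backend(self):
        with pytest.raises(ValueError):
            FusionConfig(text_backend="gpt")


class TestEndToEndGradient:
    def test_total_nll_gradient_matches_finite_differences(self, small_config):
        rng = np.random.default_rng(7)
        vols = rng.normal(size=(4, 4, 16, 16, 8))
        prompts = toy_prompts(4, missing=("sex",))
        times = [4.0, 9.0, 15.0, 30.0]
        events = [1, 0, 1, 1]
        model = SurvivalTransformer(small_config)
        model.aft_head.head_lambda.weight.data[:] = rng.normal(size=(32, 1)) * 0.1
        model.aft_head.head_rho.weight.data[:] = rng.normal(size=(32, 1)) * 0.1

        def loss_fn():
            out = model.forward(vols, prompts)
            return nll_loss(out.log_lambda_t, out.log_rho_t, times, events)

        loss = loss_fn()
        loss.backward()
        eps = 1e-6
        checked = 0
        for p in model.parameters():
            if p.grad is None:
                continue
            flat = p.data.reshape(-1)
            idx = rng.integers(0, flat.size, size=min(3, flat.size))
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = float(loss_fn().data)
                flat[i] = orig - eps
                dn = float(loss_fn().data)
                flat[i] = orig
                num = (up - dn) / (2 * eps)
                assert num == pytest.approx(p.grad.reshape(-1)[i], abs=2e-5)
                checked += 1
        assert checked > 30


def test_checkpoint_roundtrip_and_template_guard(tmp_path, small_config,
                                                 small_volumes, monkeypatch):
    model = SurvivalTransformer(small_config)
    prompts = toy_prompts(2)
    before = model.forward(small_volumes[:2], prompts[:2]).params.log_lambda
    path = tmp_path / "model.npz"
    save_checkpoint(model, path, extra={"note": "test"})
    loaded, extra = load_checkpoint(path)
    assert extra["note"] == "test"
    after = loaded.forward(small_volumes[:2], prompts[:2]).params.log_lambda
    np.testing.assert_array_equal(before, after)

    import mmsurv.nn.model as model_mod

    monkeypatch.setattr(model_mod, "template_table_hash", lambda: "tampered")
    with pytest.raises(RuntimeError, match="template"):
        load_checkpoint(path)
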