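"""Architecture fidelity, width derivation, builders, and scale accounting."""

import numpy as np
import pytest

from dpae.model import (
    ArchitectureSpec,
    Model,
    SpecError,
    build_backbone_variant,
    build_model,
    canonical_mlp_table1,
    count_flops,
    count_params,
    derive_path_widths,
    model_report,
)

# the published reference widths of the 512-input fully connected variant
TABLE1_WIDTHS = {
    "dense_1": 230, "dense_2": 103, "dense_3": 46,
    "dense_4": 680, "dense_5": 511, "dense_6": 383,
    "concat_1": 429, "bn_1": 429,
    "dense_7": 193, "dense_8": 86, "dense_9": 39, "dense_10": 86, "dense_11": 193,
    "dense_12": 46, "add_1": 46, "dense_13": 20,
    "dense_14": 383, "add_2": 383, "dense_15": 287,
    "concat_2": 307, "bn_2": 307,
    "dense_16": 256, "output": 512,
}


class TestCanonicalSpec:
    @pytest.mark.parametrize("name,width", sorted(TABLE1_WIDTHS.items()))
    def test_every_published_width(self, name, width):
        assert canonical_mlp_table1().layer(name).width == width

    def test_sixteen_trainable_hidden_layers(self):
        assert canonical_mlp_table1().n_hidden_trainable == 16

    def test_second_concat_wiring(self):
        # 307 = 20 + 287: the second concatenation joins the two path outputs
        spec = canonical_mlp_table1()
        assert set(spec.layer("concat_2").inputs) == {"dense_13", "dense_15"}

    def test_roundtrip_serialization(self, tmp_path):
        spec = canonical_mlp_table1()
        spec.save(tmp_path / "arch.yaml")
        loaded = ArchitectureSpec.load(tmp_path / "arch.yaml")
        assert loaded.widths() == spec.widths()


class TestDerivePathWidths:
    def test_low_path_first_width(self):
        assert derive_path_widths(512, 0.45, 1, "shrink") == [230]

    def test_high_path_first_width(self):
        assert derive_path_widths(512, 0.75, 1, "expand_first") == [682]

    def test_floor_chain(self):
        assert derive_path_widths(300, 0.45, 2, "shrink") == [135, 60]

    def test_full_chains(self):
        assert derive_path_widths(512, 0.45, 3, "shrink") == [230, 103, 46]
        assert derive_path_widths(512, 0.75, 3, "expand_first") == [682, 511, 383]

    @pytest.mark.parametrize("ratio", [0.0, 1.0, 1.5, -0.3])
    def test_invalid_ratio(self, ratio):
        with pytest.raises(ValueError):
            derive_path_widths(512, ratio, 1, "shrink")


class TestBackboneVariants:
    def test_cnn_pathway_geometry(self):
        spec = build_backbone_variant(512, "cnn")
        for stage in (1, 2, 3):
            assert spec.layer(f"conv_p1_{stage}").options["kernel"] == 3
            assert spec.layer(f"conv_p1_{stage}").options["stride"] == 2
            assert spec.layer(f"conv_p2_{stage}").options["kernel"] == 5
            assert spec.layer(f"conv_p2_{stage}").options["stride"] == 4

    def test_rnn_units_follow_floor_chains(self):
        spec = build_backbone_variant(512, "rnn")
        assert [spec.layer(f"gru_p1_{i}").options["hidden"] for i in (1, 2, 3)] == [230, 103, 46]
        assert [spec.layer(f"gru_p2_{i}").options["hidden"] for i in (1, 2, 3)] == [682, 511, 383]

    @pytest.mark.parametrize("backbone", ["mlp", "cnn", "rnn"])
    def test_output_width_is_input_len(self, backbone):
        spec = build_backbone_variant(512, backbone)
        assert spec.layers[-1].width == 512

    def test_unknown_backbone(self):
        with pytest.raises(ValueError):
            build_backbone_variant(512, "transformer")


class TestBuildModel:
    @pytest.mark.parametrize("input_len", [256, 512, 1024])
    def test_mlp_autoencoder_contract(self, input_len):
        spec = build_backbone_variant(input_len, "mlp")
        model = build_model(spec, seed=0)
        out = model.predict(np.zeros((2, input_len)))
        assert out.shape == (2, input_len)
        assert np.all(np.isfinite(out))

    @pytest.mark.parametrize("backbone", ["cnn", "rnn"])
    def test_other_backbones_forward(self, backbone):
        model = build_model(build_backbone_variant(512, backbone), seed=0)
        out = model.predict(np.random.default_rng(1).standard_normal((2, 512)))
        assert out.shape == (2, 512) and np.all(np.isfinite(out))

    @pytest.mark.parametrize("use_fusion,use_residual", [(False, True), (True, False)])
    def test_ablation_variants_forward(self, use_fusion, use_residual):
        spec = canonical_mlp_table1(use_fusion=use_fusion, use_residual=use_residual)
        out = build_model(spec, seed=0).predict(np.zeros((2, 512)))
        assert out.shape == (2, 512) and np.all(np.isfinite(out))

    def test_no_residual_removes_add_nodes_only(self):
        full = canonical_mlp_table1()
        bare = canonical_mlp_table1(use_residual=False)
        assert any(s.kind == "add" for s in full.layers)
        assert not any(s.kind == "add" for s in bare.layers)
        dense_widths = lambda spec: {s.name: s.width for s in spec.layers if s.kind != "add"}
        assert dense_widths(full) == dense_widths(bare)

    def test_seeded_initialization_is_deterministic(self):
        spec = canonical_mlp_table1()
        x = np.random.default_rng(3).standard_normal((4, 512))
        a = build_model(spec, seed=11).predict(x)
        b = build_model(spec, seed=11).predict(x)
        np.testing.assert_array_equal(a, b)
        c = build_model(spec, seed=12).predict(x)
        assert not np.array_equal(a, c)

    def test_inconsistent_spec_rejected(self):
        from dpae.model import LayerSpec

        layers = [
            LayerSpec("input", "input", 8),
            LayerSpec("dense_a", "dense", 4, ("input",)),
            LayerSpec("dense_b", "dense", 5, ("input",)),
            LayerSpec("bad_add", "add", 4, ("dense_a", "dense_b")),
            LayerSpec("output", "output", 8, ("bad_add",)),
        ]
        with pytest.raises(SpecError, match="bad_add"):
            ArchitectureSpec(input_len=8, layers=layers)


def table1_oracle_counts():
    """Independent spreadsheet-style sum over the published layer shapes."""
    dense_shapes = [
        (512, 230), (230, 103), (103, 46),
        (512, 680), (680, 511), (511, 383),
        (429, 193), (193, 86), (86, 39), (39, 86), (86, 193),
        (193, 46), (46, 20), (193, 383), (383, 287),
        (307, 256), (256, 512),
    ]
    params = sum(i * o + o for i, o in dense_shapes) + 2 * 429 + 2 * 307
    flops = sum(2 * i * o for i, o in dense_shapes) + 2 * 429 + 2 * 307 + 46 + 383
    return params, flops


class TestScaleAccounting:
    def test_single_dense_examples(self):
        from dpae.model import LayerSpec

        spec = ArchitectureSpec(
            input_len=10,
            layers=[
                LayerSpec("input", "input", 10),
                LayerSpec("dense_1", "dense", 5, ("input",)),
                LayerSpec("output", "output", 10, ("dense_1",)),
            ],
        )
        # dense 10->5 contributes 55 params and 100 flops
        assert count_params(spec) == 55 + (5 * 10 + 10)
        assert count_flops(spec) == 100 + 2 * 5 * 10

    def test_canonical_counts_match_independent_sum(self):
        params, flops = table1_oracle_counts()
        spec = canonical_mlp_table1()
        assert count_params(spec) == params
        assert count_flops(spec) == flops

    def test_removing_fusion_block_reduces_params(self):
        assert count_params(canonical_mlp_table1(use_fusion=False)) < count_params(
            canonical_mlp_table1()
        )

    def test_flops_dominate_params_for_dense_specs(self):
        spec = canonical_mlp_table1()
        report = model_report(spec)
        assert report.flops >= report.trainable_params
        assert report.trainable_params > 0 and report.flops > 0
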