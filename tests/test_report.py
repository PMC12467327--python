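import numpy as np
import pandas as pd
import pytest

from ascseg.phantom import PhantomSpec, generate_phantom
from ascseg.pipeline import TrainConfig
from ascseg.report import (asc_cost_fraction, asc_overhead_flops,
                           flops_per_target_slice, improvement_table,
                           avt_benchmark_tables, ablation_harness)
from ascseg.segmenter import ReferenceUNetConfig, analytic_flops_per_slice


class TestCostModel:
    @pytest.mark.parametrize("B,expected", [(64, 1 / 4096), (1, 1.0), (8, 1 / 64)])
    def test_cost_fraction(self, B, expected):
        assert asc_cost_fraction(B) == expected

    def test_cost_fraction_rejects_bad_width(self):
        with pytest.raises(ValueError):
            asc_cost_fraction(0)

    def test_flops_per_target_slice_examples(self):
        assert flops_per_target_slice(73.50, 4) == pytest.approx(294.00)
        assert flops_per_target_slice(524.53, 4) == pytest.approx(2098.12)
        assert flops_per_target_slice(5.0, 1) == 5.0

    def test_flops_linear_in_block_size(self):
        base = 17.3
        vals = [flops_per_target_slice(base, m) for m in (1, 2, 3, 4, 8)]
        for m, v in zip((1, 2, 3, 4, 8), vals):
            assert v == pytest.approx(m * base)

    def test_enhancement_overhead_is_linear_in_pixels(self):
        a = asc_overhead_flops(64 * 64, 16)
        b = asc_overhead_flops(4 * 64 * 64, 16)
        assert b == pytest.approx(4 * a, rel=0.01)

    def test_overhead_tiny_next_to_segmenter(self):
        cfg = ReferenceUNetConfig(channel_width=64, depth=4)
        seg = analytic_flops_per_slice(cfg, 512, 512)
        assert asc_overhead_flops(512 * 512, 16) / seg < 1e-4

    def test_analytic_flops_scale_with_width_squared(self):
        f8 = analytic_flops_per_slice(ReferenceUNetConfig(channel_width=8, depth=4), 64, 64)
        f16 = analytic_flops_per_slice(ReferenceUNetConfig(channel_width=16, depth=4), 64, 64)
        assert 3.5 < f16 / f8 < 4.1  # ~B^2 up to the input-layer term


class TestImprovementTable:
    def test_published_benchmark_deltas(self):
        tables = avt_benchmark_tables()
        out, max_ddsc, max_diou = improvement_table(tables["baseline"],
                                                    tables["augmented"])
        assert max_ddsc == pytest.approx(24.84)
        assert max_diou == pytest.approx(28.13)
        assert len(out) == 8

    def test_heldout_case_deltas(self):
        h = avt_benchmark_tables()["heldout"].set_index("case")
        assert (h.loc["R9", "DSC_aug"] - h.loc["R9", "DSC_base"]) == pytest.approx(16.64)
        assert (h.loc["R9", "IoU_aug"] - h.loc["R9", "IoU_base"]) == pytest.approx(22.51)

    def test_identical_tables_give_zero_deltas(self):
        t = avt_benchmark_tables()["baseline"]
        out, mx_d, mx_i = improvement_table(t, t)
        assert (out["dDSC"] == 0).all() and mx_d == 0.0 and mx_i == 0.0

    def test_maxima_invariant_to_row_order(self):
        tables = avt_benchmark_tables()
        shuffled = tables["augmented"].sample(frac=1.0, random_state=0)
        _, mx_d, mx_i = improvement_table(tables["baseline"], shuffled)
        assert (mx_d, mx_i) == (pytest.approx(24.84), pytest.approx(28.13))

    def test_label_mismatch_rejected(self):
        t = avt_benchmark_tables()["baseline"]
        other = t.copy()
        other.loc[0, "model"] = "FancyNet"
        with pytest.raises(ValueError, match="labels"):
            improvement_table(t, other)

    def test_unequal_parameter_counts_rejected(self):
        t = avt_benchmark_tables()["baseline"]
        other = t.copy()
        other.loc[0, "params"] = 1.0
        with pytest.raises(ValueError, match="parameter"):
            improvement_table(t, other)


class TestAblationHarness:
    def test_grid_smoke_run(self, tmp_path):
        cases = [generate_phantom(PhantomSpec(level=2, seed=60 + i, n_slices=8,
                                              height=32, width=32, vessel_radius=4.0))
                 for i in range(3)]
        table = ablation_harness(
            cases[:2], cases[2:], block_sizes=(2, 3), kernel_sizes=(8,),
            strides=(1, 2),
            segmenter_config=ReferenceUNetConfig(channel_width=2, depth=2),
            train_config=TrainConfig(epochs=1, learning_rate=1e-3, seed=0),
            out_csv=tmp_path / "ablation.csv")
        assert len(table) == 4  # 2 block sizes x 1 kernel x 2 strides
        # stride cells re-derive voxel depth (0.625 -> 1.25)
        assert set(table["voxel_depth_mm"].round(4)) == {0.625, 1.25}
        # every cell shares the segmenter, hence the parameter count
        assert table["params"].nunique() == 1
        # block-mode FLOPs figures scale with block size
        f2 = table[table.block_size == 2].iloc[0]["flops_per_target_slice"]
        f3 = table[table.block_size == 3].iloc[0]["flops_per_target_slice"]
        assert f3 / f2 == pytest.approx(1.5)
        assert (tmp_path / "ablation.csv").exists()

    def test_infeasible_kernel_rejected(self):
        cases = [generate_phantom(PhantomSpec(level=2, seed=1, n_slices=6,
                                              height=32, width=32, vessel_radius=4.0))]
        with pytest.raises(ValueError, match="infeasible"):
            ablation_harness(cases, cases, block_sizes=(2,), kernel_sizes=(64,),
                             segmenter_config=ReferenceUNetConfig(channel_width=2, depth=2),
                             train_config=TrainConfig(epochs=1, seed=0))
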