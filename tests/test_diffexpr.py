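import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icdmir.errors import ContrastError, NormalizationError, ParameterError
from icdmir.io import SampleInfo
from icdmir.diffexpr import (
    bh_adjust,
    ddct_relative_quantity,
    filter_expressed,
    nb_contrast_test,
    signed_fc,
    signed_fc_to_log2,
    size_factors,
)


def _two_group_samples(n=3):
    return [
        SampleInfo(f"t{i}", "L", "DXR", i + 1) for i in range(n)
    ] + [
        SampleInfo(f"c{i}", "L", "untreated", i + 1) for i in range(n)
    ]


def _nb(rng, mu, dispersion, size):
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mu), size)


class TestFilterExpressed:
    def test_mirna_floor_drops_low_rows(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [2, 0], "c": [2, 0]},
                              index=["low", "high"])
        kept = filter_expressed(counts, feature_kind="miRNA")
        assert list(kept.index) == ["high"]

    def test_mrna_floor_uses_max_over_samples(self):
        counts = pd.DataFrame({"a": [10], "b": [0], "c": [0]}, index=["f"])
        assert len(filter_expressed(counts, feature_kind="mRNA")) == 1

    def test_floor_zero_is_identity(self):
        counts = pd.DataFrame({"a": [0, 1], "b": [0, 2]})
        assert filter_expressed(counts, floor=0).equals(counts)

    def test_negative_floor_rejected(self):
        with pytest.raises(ParameterError):
            filter_expressed(pd.DataFrame({"a": [1]}), floor=-1)


class TestSizeFactors:
    def test_hand_computed_two_sample_case(self):
        sf = size_factors(pd.DataFrame([[2, 4], [2, 4]]))
        assert sf.to_numpy() == pytest.approx([2 ** -0.5, 2 ** 0.5])

    def test_identical_columns_give_unit_factors(self):
        sf = size_factors(pd.DataFrame([[5, 5, 5], [9, 9, 9]]))
        assert sf.to_numpy() == pytest.approx([1, 1, 1])

    def test_single_sample(self):
        assert size_factors(pd.DataFrame([[7]])).to_numpy() == pytest.approx([1])

    def test_all_zero_feature_everywhere_raises(self):
        with pytest.raises(NormalizationError):
            size_factors(pd.DataFrame([[0, 1], [2, 0]]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_geomean_one_and_scaling_covariance(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.integers(1, 500, size=(30, 4)))
        sf = size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)
        scaled = counts.copy()
        scaled[0] = counts[0] * 3
        sf2 = size_factors(scaled)
        # scaling one sample by c multiplies its factor by c (up to the
        # global geometric-mean rescale, identical across samples)
        ratio = sf2 / sf
        assert ratio[0] / ratio[1] == pytest.approx(3.0)
        assert ratio[1] == pytest.approx(ratio[2])


class TestSignedFc:
    @pytest.mark.parametrize("log2, expected", [(1, 2.0), (-1, -2.0), (0, 1.0)])
    def test_definition(self, log2, expected):
        assert signed_fc(log2) == pytest.approx(expected)

    def test_round_trip_most_extreme_table_value(self):
        assert signed_fc(signed_fc_to_log2(-22.34)) == pytest.approx(-22.34)

    def test_inverse_rejects_sub_unit_values(self):
        with pytest.raises(ParameterError):
            signed_fc_to_log2(0.5)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    def test_missing_passthrough_excluded_from_m(self):
        out = bh_adjust([0.01, None, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels_and_dominates_raw(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert ours == pytest.approx(ref)
        assert (ours >= np.asarray(ps) - 1e-12).all()


class TestDdct:
    def test_two_cycle_gain_is_fourfold(self):
        assert ddct_relative_quantity(24, 20, 26, 20) == pytest.approx(4.0)

    def test_no_change_is_unity(self):
        assert ddct_relative_quantity(20, 20, 20, 20) == pytest.approx(1.0)

    def test_one_cycle_loss_halves(self):
        assert ddct_relative_quantity(25, 20, 24, 20) == pytest.approx(0.5)


class TestNbContrast:
    def test_identical_groups_give_null_result(self):
        samples = _two_group_samples()
        counts = pd.DataFrame(
            {s.sample_id: [50, 7] for s in samples}, index=["f1", "f2"]
        )
        res = nb_contrast_test(counts, samples, "L", "DXR")
        assert res.loc["f1", "log2_fc"] == 0
        assert res.loc["f1", "p"] == pytest.approx(1.0)

    def test_planted_fourfold_feature_detected(self):
        rng = np.random.default_rng(0)
        samples = _two_group_samples()
        data = {}
        for s in samples:
            mu = 400 if s.condition == "DXR" else 100
            col = np.concatenate(
                [_nb(rng, mu, 0.05, 1), _nb(rng, 150, 0.05, 60)]
            )
            data[s.sample_id] = col
        counts = pd.DataFrame(data, index=[f"f{i}" for i in range(61)])
        res = nb_contrast_test(counts, samples, "L", "DXR")
        assert res.loc["f0", "log2_fc"] > 0
        assert res.loc["f0", "p"] < 0.05

    def test_swapped_labels_negate_fc_and_preserve_p(self):
        rng = np.random.default_rng(1)
        samples = _two_group_samples()
        counts = pd.DataFrame(
            {s.sample_id: _nb(rng, 200, 0.1, 50) for s in samples}
        )
        res = nb_contrast_test(counts, samples, "L", "DXR")
        flip = {"DXR": "untreated", "untreated": "DXR"}
        swapped = [
            SampleInfo(s.sample_id, s.cell_line, flip[s.condition], s.replicate)
            for s in samples
        ]
        res_sw = nb_contrast_test(counts, swapped, "L", "DXR")
        assert res_sw["log2_fc"].to_numpy() == pytest.approx(
            -res["log2_fc"].to_numpy()
        )
        assert res_sw["p"].to_numpy() == pytest.approx(res["p"].to_numpy())

    def test_zero_in_both_groups_reported_missing(self):
        samples = _two_group_samples()
        counts = pd.DataFrame(
            {s.sample_id: [0, 20] for s in samples}, index=["dead", "alive"]
        )
        res = nb_contrast_test(counts, samples, "L", "DXR")
        assert res.loc["dead", "log2_fc"] == 0
        assert np.isnan(res.loc["dead", "p"])

    def test_missing_group_raises_named_error(self):
        samples = [SampleInfo("a", "L", "DXR", 1), SampleInfo("b", "L", "DXR", 2)]
        counts = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ContrastError, match="untreated"):
            nb_contrast_test(counts, samples, "L", "DXR")

    def test_type_one_error_calibration(self):
        """Null simulation: rejection rate at alpha 0.05 stays near nominal."""
        rng = np.random.default_rng(0)
        mu = rng.lognormal(np.log(200), 1.0, 2000)
        samples = _two_group_samples()
        counts = pd.DataFrame(
            {s.sample_id: _nb(rng, mu, 0.1, 2000) for s in samples}
        )
        res = nb_contrast_test(counts, samples, "L", "DXR")
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07


class TestAgainstDeseq2:
    def test_log2fc_and_calls_agree_on_planted_fixture(self):
        """Cross-check the simplified NB test against an independent DESeq2 fit."""
        anndata = pytest.importorskip("anndata")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        samples = _two_group_samples(4)
        n_feat = 60
        mu = rng.lognormal(np.log(300), 0.5, n_feat)
        effect = np.ones(n_feat)
        effect[:6] = 4.0
        effect[6:12] = 0.25
        data = {
            s.sample_id: _nb(
                rng, mu * (effect if s.condition == "DXR" else 1.0), 0.05, n_feat
            )
            for s in samples
        }
        counts = pd.DataFrame(data, index=[f"f{i}" for i in range(n_feat)])
        ours = nb_contrast_test(counts, samples, "L", "DXR")

        adata = anndata.AnnData(
            X=counts.T.to_numpy(),
            obs=pd.DataFrame(
                {"condition": [s.condition for s in samples]},
                index=[s.sample_id for s in samples],
            ),
            var=pd.DataFrame(index=counts.index),
        )
        dds = DeseqDataSet(adata=adata, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "DXR", "untreated"], quiet=True
        )
        stats.summary()
        theirs = stats.results_df

        planted = [f"f{i}" for i in range(12)]
        diff = (ours.loc[planted, "log2_fc"]
                - theirs.loc[planted, "log2FoldChange"])
        assert np.abs(diff).max() < 0.35
        assert (
            np.sign(ours.loc[planted, "log2_fc"])
            == np.sign(theirs.loc[planted, "log2FoldChange"])
        ).all()
        assert (ours.loc[planted, "p_adj"] < 0.05).all()
        assert (theirs.loc[planted, "padj"] < 0.05).all()
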