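import numpy as np
import pandas as pd
import pytest

from isofit.errors import AggregationError, ContractError, NormalizationError
from isofit.expression import (
    ExpressionSet,
    aggregate_expression,
    compute_usage,
    filter_low_expression,
    filter_minor_isoforms,
    gene_map_from_models,
    normalize,
    tmm_factors,
)
from isofit.models import GeneModel, TranscriptModel

from conftest import make_gene


def _xset(values, design):
    return ExpressionSet(values=values, design=design)


@pytest.fixture
def counts_2x3(design_2x3):
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.poisson(100, size=(40, 6)).astype(float),
        index=[f"T{i}" for i in range(40)],
        columns=design_2x3.index,
    )
    return _xset(values, design_2x3)


class TestTMM:
    def test_scalar_multiple_columns_give_unit_factors(self, design_2x3):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=100).astype(float) + 1
        values = pd.DataFrame(
            {s: base * m for s, m in zip(design_2x3.index, [1, 2, 3, 0.5, 1.5, 4])},
            index=[f"T{i}" for i in range(100)],
        )
        x = _xset(values, design_2x3)
        f = tmm_factors(x.values)
        assert np.allclose(f, 1.0, atol=1e-9)
        norm = normalize(x)
        cols = norm.values.to_numpy()
        assert np.allclose(cols, cols[:, [0]] , atol=1e-6)

    def test_duplicated_sample_doubles_effective_lib(self, design_2x3):
        rng = np.random.default_rng(2)
        base = rng.poisson(80, size=60).astype(float) + 1
        values = pd.DataFrame(
            {s: base.copy() for s in design_2x3.index},
            index=[f"T{i}" for i in range(60)],
        )
        values["B_3"] = base * 2
        x = _xset(values, design_2x3)
        norm = normalize(x)
        # closed-form oracle: CPM of proportional columns is identical
        assert np.isclose(
            norm.effective_lib_size["B_3"] / norm.effective_lib_size["A_1"], 2.0
        )
        assert np.allclose(norm.values["B_3"], norm.values["A_1"])

    def test_single_sample_factor_one(self):
        values = pd.DataFrame({"S1": [10.0, 20.0, 30.0]}, index=["a", "b", "c"])
        design = pd.Series({"S1": "A"})
        norm = normalize(_xset(values, design))
        assert np.isclose(norm.norm_factors["S1"], 1.0)
        assert np.allclose(norm.values["S1"], values["S1"] / 60.0 * 1e6)

    def test_all_zero_sample_raises(self, design_2x3):
        values = pd.DataFrame(
            np.ones((5, 6)), index=list("abcde"), columns=design_2x3.index
        )
        values["A_2"] = 0.0
        with pytest.raises(NormalizationError, match="A_2"):
            normalize(_xset(values, design_2x3))

    def test_factors_geometric_mean_one(self, counts_2x3):
        f = tmm_factors(counts_2x3.values)
        assert np.isclose(np.exp(np.log(f).mean()), 1.0)

    def test_normalize_twice_rejected(self, counts_2x3):
        norm = normalize(counts_2x3)
        with pytest.raises(ContractError):
            normalize(norm)


class TestLowExpressionFilter:
    def test_zero_transcript_removed(self, counts_2x3):
        x = counts_2x3
        x.values.loc["T0"] = 0.0
        norm = normalize(x)
        out = filter_low_expression(norm, min_cpm=1.0)
        assert "T0" not in out.values.index

    def test_one_sided_expression_retained(self, design_2x3):
        values = pd.DataFrame(
            np.full((10, 6), 100.0),
            index=[f"T{i}" for i in range(10)],
            columns=design_2x3.index,
        )
        values.loc["T0", ["B_1", "B_2", "B_3"]] = 0.0
        norm = normalize(_xset(values, design_2x3))
        out = filter_low_expression(norm, min_cpm=1.0)
        assert "T0" in out.values.index

    def test_min_cpm_zero_is_identity(self, counts_2x3):
        norm = normalize(counts_2x3)
        out = filter_low_expression(norm, min_cpm=0.0)
        assert list(out.values.index) == list(norm.values.index)

    def test_dropped_genes_listed(self, design_2x3):
        values = pd.DataFrame(
            [[0.0] * 6, [100.0] * 6],
            index=["T0", "T1"],
            columns=design_2x3.index,
        )
        gene_map = pd.Series({"T0": "G0", "T1": "G1"})
        norm = normalize(_xset(values, design_2x3))
        out = filter_low_expression(norm, min_cpm=1.0, gene_map=gene_map)
        assert out.dropped_genes == ["G0"]


def _two_tx_models(cds_b=(1030, 1209)):
    t1 = TranscriptModel("T1", "G1", "chr1", "+", [(1000, 1400)], cds_genomic=(1030, 1209))
    t2 = TranscriptModel("T2", "G1", "chr1", "+", [(1000, 1500)], cds_genomic=cds_b)
    t3 = TranscriptModel("T3", "G2", "chr1", "+", [(5000, 5400)])
    return {"G1": make_gene("G1", [t1, t2]), "G2": make_gene("G2", [t3])}


class TestAggregation:
    def test_gene_sum(self, design_2x3):
        values = pd.DataFrame(
            [[10.0] * 6, [30.0] * 6, [7.0] * 6],
            index=["T1", "T2", "T3"],
            columns=design_2x3.index,
        )
        x = _xset(values, design_2x3)
        out = aggregate_expression(x, _two_tx_models(), level="gene")
        assert np.allclose(out.values.loc["G1"], 40.0)
        # mass conservation
        assert np.allclose(out.values.sum(axis=0), values.sum(axis=0))

    def test_identical_cds_grouped(self, design_2x3):
        values = pd.DataFrame(
            [[10.0] * 6, [30.0] * 6, [7.0] * 6],
            index=["T1", "T2", "T3"],
            columns=design_2x3.index,
        )
        x = _xset(values, design_2x3)
        out = aggregate_expression(x, _two_tx_models(), level="cds")
        # same ORF despite different 3' UTR lengths -> one summed row
        assert out.values.shape[0] == 1
        assert np.allclose(out.values.iloc[0], 40.0)

    def test_distinct_cds_not_grouped(self, design_2x3):
        values = pd.DataFrame(
            [[10.0] * 6, [30.0] * 6, [7.0] * 6],
            index=["T1", "T2", "T3"],
            columns=design_2x3.index,
        )
        x = _xset(values, design_2x3)
        out = aggregate_expression(
            x, _two_tx_models(cds_b=(1060, 1209)), level="cds"
        )
        assert out.values.shape[0] == 2

    def test_noncoding_gene_absent_from_cds(self, design_2x3):
        values = pd.DataFrame(
            [[10.0] * 6, [30.0] * 6, [7.0] * 6],
            index=["T1", "T2", "T3"],
            columns=design_2x3.index,
        )
        out = aggregate_expression(
            _xset(values, design_2x3), _two_tx_models(), level="cds"
        )
        assert not any(r.startswith("G2") for r in out.values.index)

    def test_unknown_transcript_raises(self, design_2x3):
        values = pd.DataFrame(
            [[1.0] * 6], index=["TX"], columns=design_2x3.index
        )
        with pytest.raises(AggregationError):
            aggregate_expression(_xset(values, design_2x3), _two_tx_models(), "gene")


class TestUsage:
    def test_single_isoform_usage_one(self, design_2x3):
        values = pd.DataFrame([[50.0] * 6], index=["T1"], columns=design_2x3.index)
        norm = normalize(_xset(values, design_2x3))
        u = compute_usage(norm, pd.Series({"T1": "G1"}))
        assert np.allclose(u.usage.loc["T1"], 1.0)

    def test_usage_ratio(self, design_2x3):
        values = pd.DataFrame(
            [[8.0] * 6, [2.0] * 6], index=["T1", "T2"], columns=design_2x3.index
        )
        x = ExpressionSet(values=values, design=design_2x3, normalized=True)
        u = compute_usage(x, pd.Series({"T1": "G1", "T2": "G1"}))
        assert np.allclose(u.usage.loc["T1"], 0.8)
        assert np.allclose(u.usage.loc["T2"], 0.2)

    def test_zero_condition_flagged(self, design_2x3):
        values = pd.DataFrame(
            [[8.0, 8.0, 8.0, 0.0, 0.0, 0.0], [2.0, 2.0, 2.0, 0.0, 0.0, 0.0]],
            index=["T1", "T2"],
            columns=design_2x3.index,
        )
        x = ExpressionSet(values=values, design=design_2x3, normalized=True)
        u = compute_usage(x, pd.Series({"T1": "G1", "T2": "G1"}))
        assert not u.evaluable.loc["G1", "B"]
        assert u.usage["B"].isna().all()

    def test_rows_sum_to_one(self, design_2x3):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(
            rng.uniform(1, 100, size=(30, 6)),
            index=[f"T{i}" for i in range(30)],
            columns=design_2x3.index,
        )
        gene_map = pd.Series(
            {f"T{i}": f"G{i // 3}" for i in range(30)}
        )
        x = ExpressionSet(values=values, design=design_2x3, normalized=True)
        u = compute_usage(x, gene_map)
        sums = u.usage.groupby(gene_map).sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_usage_invariant_under_library_rescaling(self, design_2x3):
        rng = np.random.default_rng(6)
        values = pd.DataFrame(
            rng.uniform(1, 100, size=(12, 6)),
            index=[f"T{i}" for i in range(12)],
            columns=design_2x3.index,
        )
        gene_map = pd.Series({f"T{i}": f"G{i // 2}" for i in range(12)})
        x1 = ExpressionSet(values=values, design=design_2x3, normalized=True)
        scaled = values * pd.Series(
            [3.0, 1.0, 0.5, 2.0, 1.0, 7.0], index=design_2x3.index
        )
        # per-sample global rescaling changes replicate means, so compare
        # usage computed per sample group after renormalizing columns back
        x2 = ExpressionSet(
            values=scaled / [3.0, 1.0, 0.5, 2.0, 1.0, 7.0],
            design=design_2x3, normalized=True,
        )
        u1 = compute_usage(x1, gene_map).usage
        u2 = compute_usage(x2, gene_map).usage
        assert np.allclose(u1, u2)


class TestMinorIsoformFilter:
    def _set(self, rows, design):
        values = pd.DataFrame(
            rows, index=[f"T{i}" for i in range(len(rows))], columns=design.index
        )
        return ExpressionSet(values=values, design=design, normalized=True)

    def test_five_percent_isoform_removed(self, design_2x3):
        x = self._set([[95.0] * 6, [5.0] * 6], design_2x3)
        gm = pd.Series({"T0": "G", "T1": "G"})
        out = filter_minor_isoforms(x, gm, mode="proportion", threshold=0.10)
        assert list(out.values.index) == ["T0"]

    def test_condition_specific_usage_retained(self, design_2x3):
        x = self._set(
            [[95.0, 95.0, 95.0, 60.0, 60.0, 60.0], [5.0, 5.0, 5.0, 40.0, 40.0, 40.0]],
            design_2x3,
        )
        gm = pd.Series({"T0": "G", "T1": "G"})
        out = filter_minor_isoforms(x, gm, mode="proportion", threshold=0.10)
        assert set(out.values.index) == {"T0", "T1"}

    def test_single_isoform_gene_unchanged(self, design_2x3):
        x = self._set([[5.0] * 6], design_2x3)
        gm = pd.Series({"T0": "G"})
        out = filter_minor_isoforms(x, gm, mode="proportion", threshold=0.10)
        assert list(out.values.index) == ["T0"]

    def test_foldchange_mode(self, design_2x3):
        x = self._set([[80.0] * 6, [10.0] * 6, [30.0] * 6], design_2x3)
        gm = pd.Series({"T0": "G", "T1": "G", "T2": "G"})
        out = filter_minor_isoforms(x, gm, mode="foldchange", threshold=2.0)
        # 80/10 = 8 >= 2 in both conditions -> T1 removed; 80/30 < 2 x... 2.67 >= 2 -> removed
        assert list(out.values.index) == ["T0"]

    def test_major_never_removed(self, design_2x3):
        x = self._set([[5.0] * 6], design_2x3)
        gm = pd.Series({"T0": "G"})
        out = filter_minor_isoforms(x, gm, mode="proportion", threshold=0.9999999)
        assert "T0" in out.values.index

    def test_threshold_contract(self, design_2x3):
        x = self._set([[1.0] * 6], design_2x3)
        gm = pd.Series({"T0": "G"})
        with pytest.raises(ContractError):
            filter_minor_isoforms(x, gm, mode="proportion", threshold=1.5)
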