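import numpy as np
import pandas as pd
import pytest

from isofit.expression import ExpressionSet, UsageTable, compute_usage
from isofit.models import TranscriptModel
from isofit.polya import (
    build_polya_library,
    dpau,
    run_dpa,
    run_utrl,
    utr_weighted_length,
)
from isofit.synthetic import SimulationSpec, simulate_dataset

from conftest import make_gene


def _tx(tx_id, end, gene="G", start=1, cds_end=400, nmd=False, coding=True):
    t = TranscriptModel(
        tx_id, gene, "chr1", "+", [(start, end)],
        cds_genomic=(101, cds_end) if coding else None,
    )
    t.is_nmd = nmd
    return t


def _expr(rows, design, normalized=True):
    values = pd.DataFrame(rows, columns=design.index).astype(float)
    values.index = [f"T{i + 1}" for i in range(len(rows))]
    return ExpressionSet(values=values, design=design, normalized=normalized)


class TestLibrary:
    def test_worked_example(self, design_2x3):
        # 3' ends at 1000, 1050, 2000; all well expressed
        models = {"G": make_gene("G", [_tx("T1", 1000), _tx("T2", 1050),
                                       _tx("T3", 2000)])}
        x = _expr([[30] * 6, [30] * 6, [40] * 6], design_2x3)
        lib = build_polya_library(models, x)
        rec = lib.genes["G"]
        assert len(rec.clusters) == 2
        assert sorted(len(c.members) for c in rec.clusters) == [1, 2]
        assert rec.proximal.members == ["T1", "T2"]
        assert rec.distal.members == ["T3"]
        assert rec.eligible  # |2000 - rep(proximal)| >= 60

    def test_minor_site_dropped(self, design_2x3):
        models = {"G": make_gene("G", [_tx("T1", 1000), _tx("T2", 2000)])}
        x = _expr([[95] * 6, [5] * 6], design_2x3)
        lib = build_polya_library(models, x, min_frac=0.10)
        rec = lib.genes["G"]
        assert len(rec.clusters) == 1
        assert not rec.eligible

    def test_minor_site_kept_if_10pct_in_one_condition(self, design_2x3):
        models = {"G": make_gene("G", [_tx("T1", 1000), _tx("T2", 2000)])}
        x = _expr([[95, 95, 95, 60, 60, 60], [5, 5, 5, 40, 40, 40]], design_2x3)
        lib = build_polya_library(models, x)
        assert len(lib.genes["G"].clusters) == 2

    def test_single_polya_not_eligible(self, design_2x3):
        models = {"G": make_gene("G", [_tx("T1", 1000), _tx("T2", 1010)])}
        x = _expr([[50] * 6, [50] * 6], design_2x3)
        rec = build_polya_library(models, x).genes["G"]
        assert len(rec.clusters) == 1
        assert rec.eligible is False

    def test_noncoding_and_nmd_discarded(self, design_2x3):
        models = {"G": make_gene("G", [
            _tx("T1", 1000),
            _tx("T2", 2000, nmd=True),
            _tx("T3", 3000, coding=False),
        ])}
        x = _expr([[50] * 6, [50] * 6, [50] * 6], design_2x3)
        rec = build_polya_library(models, x).genes["G"]
        members = [tx for c in rec.clusters for tx in c.members]
        assert members == ["T1"]

    def test_gene_without_usable_isoforms_absent(self, design_2x3):
        models = {"G": make_gene("G", [_tx("T1", 1000, coding=False)])}
        x = _expr([[50] * 6], design_2x3)
        lib = build_polya_library(models, x)
        assert "G" not in lib.genes

    def test_middle_cluster_assigned_to_nearest(self, design_2x3):
        models = {"G": make_gene("G", [_tx("T1", 1000), _tx("T2", 1200),
                                       _tx("T3", 2000)])}
        x = _expr([[40] * 6, [20] * 6, [40] * 6], design_2x3)
        rec = build_polya_library(models, x).genes["G"]
        by_label = {tuple(c.members): c.label for c in rec.clusters}
        assert by_label[("T2",)] == "proximal"  # 200 bp vs 800 bp

    def test_clustering_idempotent(self, design_2x3):
        rng = np.random.default_rng(5)
        ends = sorted(int(e) for e in rng.integers(1000, 5000, size=8))
        models = {"G": make_gene("G", [
            _tx(f"T{i + 1}", e) for i, e in enumerate(ends)
        ])}
        x = _expr([[50] * 6 for _ in ends], design_2x3)
        lib = build_polya_library(models, x, min_frac=0.0)
        reps = {f"T{i + 1}": None for i in range(len(ends))}
        # re-cluster the representatives: they must stay apart
        cluster_reps = sorted(c.representative for c in lib.genes["G"].clusters)
        assert all(b - a > 75 for a, b in zip(cluster_reps, cluster_reps[1:]))

    def test_monotonicity_merge_window_and_min_frac(self, design_2x3):
        rng = np.random.default_rng(6)
        ends = sorted(int(e) for e in rng.integers(1000, 3000, size=10))
        models = {"G": make_gene("G", [
            _tx(f"T{i + 1}", e) for i, e in enumerate(ends)
        ])}
        weights = rng.uniform(1, 20, size=10)
        x = _expr([[w] * 6 for w in weights], design_2x3)
        n_prev = None
        for window in (10, 40, 75, 150, 400):
            lib = build_polya_library(models, x, merge_window=window, min_frac=0.0)
            n = len(lib.genes["G"].clusters)
            if n_prev is not None:
                assert n <= n_prev  # wider window never yields more clusters
            n_prev = n
        n_prev = None
        for frac in (0.0, 0.05, 0.10, 0.2, 0.5):
            lib = build_polya_library(models, x, min_frac=frac)
            n = len(lib.genes["G"].clusters)
            if n_prev is not None:
                assert n <= n_prev  # higher floor never keeps more clusters
            n_prev = n


class TestDpau:
    def test_formula(self):
        assert dpau(30.0, 10.0) == pytest.approx(0.75)

    def test_all_distal(self):
        assert dpau(42.0, 0.0) == pytest.approx(1.0)

    def test_complement(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d, p = rng.uniform(0.1, 10, size=2)
            assert dpau(d, p) + dpau(p, d) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def dpa_ds():
    spec = SimulationSpec(n_genes=60, frac_dpa=0.2, seed=13,
                          mean_range=(150.0, 400.0))
    return simulate_dataset(spec)


class TestRunDpa:
    def test_planted_flip_detected(self, dpa_ds):
        from isofit.expression import normalize

        x = dpa_ds.expression_set()
        lib = build_polya_library(dpa_ds.annotation.genes, normalize(x))
        out = run_dpa(lib, x)
        joined = out.join(dpa_ds.truth)
        planted = joined[joined.is_dpa.fillna(False)]
        assert planted["significant"].mean() >= 0.9
        assert planted["polya_switching"].all()
        nulls = joined[~joined.is_dpa.fillna(True)]
        assert nulls["significant"].mean() <= 0.1

    def test_delta_dpau_matches_usage_change(self, dpa_ds):
        # 2-isoform genes with one polyA cluster per isoform: delta-DPAU
        # equals total usage change
        from isofit.differential import run_diu
        from isofit.expression import normalize

        x = dpa_ds.expression_set()
        lib = build_polya_library(dpa_ds.annotation.genes, normalize(x))
        dpa = run_dpa(lib, x)
        diu = run_diu(x, dpa_ds.annotation.genes)
        joined = dpa.join(diu[["total_usage_change"]])
        ok = joined.dropna(subset=["delta_dpau", "total_usage_change"])
        assert np.allclose(ok["delta_dpau"], ok["total_usage_change"], atol=1e-6)


class TestUtrw:
    def test_formula(self):
        assert utr_weighted_length([0.25, 0.75], [100, 500]) == pytest.approx(400.0)

    def test_single_isoform(self):
        assert utr_weighted_length([1.0], [300]) == pytest.approx(300.0)

    def test_convex_combination(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            k = int(rng.integers(1, 6))
            u = rng.dirichlet(np.ones(k))
            lens = rng.uniform(50, 800, size=k)
            w = utr_weighted_length(u, lens)
            assert lens.min() - 1e-9 <= w <= lens.max() + 1e-9


class TestRunUtrl:
    def _usage(self, u_by_cond, index):
        usage = pd.DataFrame(u_by_cond, index=index)
        gene_of = pd.Series("G", index=index)
        evaluable = pd.DataFrame(
            {c: [True] for c in u_by_cond}, index=["G"]
        )
        return UsageTable(usage=usage, gene_of=gene_of, evaluable=evaluable)

    def test_single_isoform_constant(self):
        models = {"G": make_gene("G", [_tx("T1", 1000, cds_end=700)])}
        usage = self._usage({"A": [1.0], "B": [1.0]}, ["T1"])
        table, gt = run_utrl(models, usage, end="utr3")
        assert table.loc["G", "utrw_A"] == pytest.approx(300.0)
        assert table.loc["G", "delta"] == pytest.approx(0.0)
        assert gt["p"] == pytest.approx(1.0)

    def test_weighted_example(self):
        # UTR3 lengths 100 and 500; usages 0.25/0.75
        models = {"G": make_gene("G", [_tx("T1", 500, cds_end=400),
                                       _tx("T2", 900, cds_end=400)])}
        usage = self._usage({"A": [0.25, 0.25], "B": [0.25, 0.25]}, ["T1", "T2"])
        # renormalized over coding isoforms -> 0.5/0.5 here; use raw usages
        usage.usage.loc["T2", "A"] = 0.75
        usage.usage.loc["T2", "B"] = 0.75
        table, _ = run_utrl(models, usage, end="utr3")
        assert table.loc["G", "utrw_A"] == pytest.approx(400.0)

    def test_identical_usage_global_p_one(self, dpa_ds=None):
        spec = SimulationSpec(n_genes=20, seed=21)
        ds = simulate_dataset(spec)
        usage = UsageTable(
            usage=ds.usage, gene_of=pd.Series(
                {tx: tx.split(".")[0] for tx in ds.usage.index}
            ),
            evaluable=pd.DataFrame(True, index=sorted({
                tx.split(".")[0] for tx in ds.usage.index
            }), columns=["A", "B"]),
        )
        table, gt = run_utrl(ds.annotation.genes, usage, end="utr3")
        assert np.allclose(table["delta"], 0.0)
        assert gt["p"] == pytest.approx(1.0)

    def test_planted_shift_significant(self):
        from isofit.expression import gene_map_from_models, normalize

        spec = SimulationSpec(n_genes=40, frac_utr=0.5, seed=23,
                              mean_range=(200.0, 400.0))
        ds = simulate_dataset(spec)
        x = normalize(ds.expression_set())
        usage = compute_usage(x, gene_map_from_models(ds.annotation.genes))
        table, gt = run_utrl(ds.annotation.genes, usage, end="utr3")
        assert gt["p"] < 0.01
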