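"""Pseudobulk chunking rules, conservation, dispersion recovery, LRT properties."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsc.config import CONTROL, POP, PipelineConfig
from popsc.pseudobulk import (
    NbFit,
    PseudobulkTable,
    _chunk_sizes,
    bulk_table_de,
    de_per_cell_type,
    de_summary,
    fit_nb_dispersion,
    make_pseudobulks,
    nb_lrt,
    run_de,
)
from popsc.simulate import PlantedDeg, SimulationSpec, simulate, simulate_bulk

from conftest import tiny_umi


class TestChunking:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (40, [20, 20]),
            (45, [20, 25]),  # remainder 5 < 10 merged into the last chunk
            (30, [20, 10]),  # remainder >= 10 kept as its own replicate
            (20, [20]),
            (15, [15]),  # below one full group but above the stratum minimum
        ],
    )
    def test_stated_remainder_rule(self, n, expected):
        assert _chunk_sizes(n, 20, 10) == expected

    @given(st.integers(min_value=10, max_value=500))
    @settings(max_examples=100, deadline=None)
    def test_sizes_partition_and_respect_minimum(self, n):
        sizes = _chunk_sizes(n, 20, 10)
        assert sum(sizes) == n
        assert all(s >= 10 for s in sizes)
        assert sum(1 for s in sizes if s != 20) <= 1  # at most one irregular chunk


def _stratified_matrix(rng, n_genes=60, layout=((CONTROL, "s1", 40), (POP, "s2", 45))):
    cols, conds, samps = [], [], []
    for cond, samp, n in layout:
        cols.append(rng.poisson(2, size=(n_genes, n)))
        conds += [cond] * n
        samps += [samp] * n
    counts = np.concatenate(cols, axis=1)
    return tiny_umi(counts, conditions=conds, samples=samps,
                    types=["t1"] * counts.shape[1])


class TestMakePseudobulks:
    def test_counts_conserved_per_stratum(self):
        rng = np.random.default_rng(0)
        m = _stratified_matrix(rng)
        pb = make_pseudobulks(m, seed=1)
        for (cond, samp), meta in pb.replicate_meta.groupby(["condition", "sample"]):
            cell_mask = ((m.cell_meta["condition"] == cond)
                         & (m.cell_meta["sample"] == samp)).to_numpy()
            stratum_total = np.asarray(m.counts[:, cell_mask].sum(axis=1)).ravel()
            pb_total = pb.counts[:, meta.index.to_numpy()].sum(axis=1)
            np.testing.assert_array_equal(pb_total, stratum_total)

    def test_replicate_sizes_follow_rule(self):
        rng = np.random.default_rng(0)
        m = _stratified_matrix(rng)
        pb = make_pseudobulks(m, seed=1)
        sizes = pb.replicate_meta.groupby("sample")["n_cells_summed"].apply(list)
        assert sorted(sizes["s1"]) == [20, 20]
        assert sorted(sizes["s2"]) == [20, 25]

    def test_small_stratum_dropped(self):
        rng = np.random.default_rng(0)
        m = _stratified_matrix(rng, layout=((CONTROL, "s1", 40), (POP, "s2", 8)))
        pb = make_pseudobulks(m, seed=1)
        assert set(pb.replicate_meta["sample"]) == {"s1"}

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(0)
        m = _stratified_matrix(rng)
        a = make_pseudobulks(m, seed=5)
        b = make_pseudobulks(m, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)


def _nb_table(rng, n_genes, reps_per_cond, mu, phi, fc=None):
    """Direct NB pseudobulk table: equal libraries, optional planted FC."""
    mu_vec = np.full(n_genes, float(mu))
    cols = []
    conds = []
    for cond in (CONTROL, POP):
        m = mu_vec.copy()
        if fc is not None and cond == POP:
            m = m * fc
        for _ in range(reps_per_cond):
            lam = rng.gamma(1 / phi, m * phi) if phi > 0 else m
            cols.append(rng.poisson(lam))
            conds.append(cond)
    meta = pd.DataFrame({
        "cell_type": "t", "condition": conds,
        "sample": [f"r{i}" for i in range(len(conds))],
        "chunk_index": 0, "n_cells_summed": 1,
    })
    return PseudobulkTable(counts=np.column_stack(cols),
                          gene_ids=[f"g{i}" for i in range(n_genes)],
                          replicate_meta=meta)


class TestDispersion:
    def test_poisson_data_gives_small_common(self):
        rng = np.random.default_rng(1)
        pb = _nb_table(rng, 2000, 3, mu=50, phi=0.0)
        fit = fit_nb_dispersion(pb)
        assert fit.common_dispersion < 0.05

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(2)
        pb = _nb_table(rng, 2000, 3, mu=100, phi=0.4)
        fit = fit_nb_dispersion(pb)
        assert 0.3 < fit.common_dispersion < 0.5

    def test_duplicated_columns_leave_means_unchanged(self):
        rng = np.random.default_rng(3)
        pb = _nb_table(rng, 50, 3, mu=20, phi=0.2)
        doubled = PseudobulkTable(
            counts=np.concatenate([pb.counts, pb.counts], axis=1),
            gene_ids=pb.gene_ids,
            replicate_meta=pd.concat([pb.replicate_meta] * 2, ignore_index=True),
        )
        f1 = fit_nb_dispersion(pb)
        f2 = fit_nb_dispersion(doubled)
        pd.testing.assert_frame_equal(f1.group_means, f2.group_means)

    def test_single_replicate_condition_rejected(self):
        rng = np.random.default_rng(4)
        pb = _nb_table(rng, 10, 2, mu=10, phi=0.1)
        with pytest.raises(ValueError, match="2 replicates"):
            fit_nb_dispersion(pb, design=np.array([0, 0, 0, 1.0]))


class TestLrt:
    def test_constant_gene_null(self):
        counts = np.full((3, 6), 7)
        meta = pd.DataFrame({"cell_type": "t",
                             "condition": [CONTROL] * 3 + [POP] * 3,
                             "sample": list("abcdef"), "chunk_index": 0,
                             "n_cells_summed": 1})
        pb = PseudobulkTable(counts=counts, gene_ids=["a", "b", "c"], replicate_meta=meta)
        res = run_de(pb)
        assert np.allclose(res.log2fc, 0.0, atol=1e-6)
        assert (res.p_value > 0.99).all()

    def test_condition_swap_negates_log2fc(self):
        rng = np.random.default_rng(5)
        pb = _nb_table(rng, 200, 3, mu=40, phi=0.2, fc=2.0)
        res = run_de(pb)
        flipped_meta = pb.replicate_meta.copy()
        flipped_meta["condition"] = flipped_meta["condition"].map(
            {CONTROL: POP, POP: CONTROL})
        pb2 = PseudobulkTable(counts=pb.counts, gene_ids=pb.gene_ids,
                              replicate_meta=flipped_meta)
        res2 = run_de(pb2)
        np.testing.assert_allclose(res.log2fc, -res2.log2fc, atol=1e-5)
        np.testing.assert_allclose(res.p_value, res2.p_value, rtol=1e-6, atol=1e-9)

    def test_poisson_limit_matches_poisson_glm_deviance(self):
        """With phi fixed at 0 the NB LRT equals a Poisson GLM deviance test."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        pb = _nb_table(rng, 50, 3, mu=30, phi=0.0, fc=1.6)
        cond = pb.condition_indicator()
        fit = NbFit(common_dispersion=0.0, dispersion=np.zeros(50),
                    offsets=np.log(pb.counts.sum(axis=0).astype(float)),
                    design=np.column_stack([np.ones(6), cond]),
                    gene_ids=pb.gene_ids)
        res = nb_lrt(pb, fit)
        from scipy import stats as sps
        for g in range(50):
            y = pb.counts[g]
            full = sm.GLM(y, fit.design, family=sm.families.Poisson(),
                          offset=fit.offsets).fit()
            red = sm.GLM(y, fit.design[:, :1], family=sm.families.Poisson(),
                         offset=fit.offsets).fit()
            p_oracle = sps.chi2.sf(red.deviance - full.deviance, 1)
            assert res.p_value[g] == pytest.approx(p_oracle, abs=1e-6)

    def test_matches_edger_at_fixed_dispersion(self, tmp_path):
        """Independent cross-check: edgeR glmLRT with the same fixed dispersion
        and library offsets reproduces our p-values."""
        rng = np.random.default_rng(7)
        pb = _nb_table(rng, 80, 3, mu=40, phi=0.2, fc=1.7)
        table = pd.DataFrame(pb.counts, index=pb.gene_ids,
                             columns=[f"{c}_{i}" for i, c in
                                      enumerate(pb.replicate_meta.condition)])
        table.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            x <- read.delim(commandArgs(TRUE)[1], row.names=1)
            group <- factor(sub("_.*", "", colnames(x)), levels=c("control","POP"))
            y <- DGEList(counts=x, group=group)
            fit <- glmFit(y, model.matrix(~group), dispersion=0.2)
            tab <- topTags(glmLRT(fit), n=Inf, sort.by="none")$table
            write.table(data.frame(gene=rownames(tab), p=tab$PValue),
                        commandArgs(TRUE)[2], sep="\\t", row.names=FALSE, quote=FALSE)
        """)
        (tmp_path / "edger.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "edger.R"),
                        str(tmp_path / "counts.tsv"), str(tmp_path / "edger.tsv")],
                       check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "edger.tsv", sep="\t").set_index("gene")["p"]
        fit = NbFit(common_dispersion=0.2, dispersion=np.full(80, 0.2),
                    offsets=np.log(pb.counts.sum(axis=0).astype(float)),
                    design=np.column_stack([np.ones(6), pb.condition_indicator()]),
                    gene_ids=pb.gene_ids)
        mine = nb_lrt(pb, fit).set_index("gene")["p_value"]
        assert np.abs(mine - oracle.reindex(mine.index)).max() < 1e-6


@pytest.fixture(scope="module")
def planted_sim():
    plants = tuple(
        PlantedDeg(f"G{100 + i:04d}", "a", 1.5 if i < 8 else -1.5) for i in range(16)
    )
    spec = SimulationSpec(
        n_genes=500, cell_types=("a", "b"),
        proportions={CONTROL: (0.6, 0.4), POP: (0.6, 0.4)},
        n_samples={CONTROL: 3, POP: 3}, cells_per_sample=120,
        planted_degs=plants, planted_lr=(), markers_per_type=0,
        qc_outliers={}, plant_baseline=2.5, n_mito_genes=5, rng_seed=21,
    )
    return simulate(spec), plants


class TestPerCellType:
    def test_both_directions_recovered(self, planted_sim):
        (m, truth), plants = planted_sim
        res = de_per_cell_type(m, seed=21)
        de_a = res["a"].set_index("gene")
        up = [p.gene for p in plants if p.log2fc > 0]
        down = [p.gene for p in plants if p.log2fc < 0]
        assert de_a.loc[up, "significant"].mean() >= 0.75
        assert de_a.loc[down, "significant"].mean() >= 0.75
        assert (de_a.loc[up, "log2fc"] > 0).all()
        assert (de_a.loc[down, "log2fc"] < 0).all()
        summary = de_summary(res)
        row = summary[summary.cell_type == "a"].iloc[0]
        assert row.n_up >= 6 and row.n_down >= 6

    def test_type_absent_in_one_condition_skipped(self, planted_sim):
        (m, truth), _ = planted_sim
        labels = m.labels().copy()
        pop_mask = (m.cell_meta["condition"] == POP).to_numpy()
        labels[pop_mask & (labels == "b").to_numpy()] = "a"
        res = de_per_cell_type(m, labels, seed=21)
        assert "b" not in res

    def test_same_seed_identical(self, planted_sim):
        (m, _), _ = planted_sim
        r1 = de_per_cell_type(m, seed=3)["a"]
        r2 = de_per_cell_type(m, seed=3)["a"]
        pd.testing.assert_frame_equal(r1, r2)


def test_bulk_table_de_null_and_recovery():
    spec = SimulationSpec(n_genes=600, n_mito_genes=0, planted_degs=(), planted_lr=(),
                          markers_per_type=0, bulk_dispersion=0.2,
                          bulk_planted_degs=tuple((f"G{10 + i:04d}", 2.0) for i in range(15)),
                          rng_seed=31)
    table, truth = simulate_bulk(spec, 3)
    res = bulk_table_de(table).set_index("gene")
    planted = truth["gene"].tolist()
    assert res.loc[planted, "significant"].mean() >= 0.9  # log2FC=2 at mean ~50: high power
    null_p = res.drop(planted)["p_value"]
    assert 0.02 < (null_p < 0.05).mean() < 0.09
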