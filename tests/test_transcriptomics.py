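"""Moderated-t differential expression, BH adjustment, hypergeometric enrichment."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhabdosignal.errors import ConfigError, RhabdosignalError
from rhabdosignal.synthetic_data import ExpressionConfig, generate_expression
from rhabdosignal.transcriptomics import (
    ExpressionMatrix,
    benjamini_hochberg,
    count_de_genes,
    differential_expression,
    enrich,
    read_expression,
    read_gmt,
    write_expression,
)


@pytest.fixture(scope="module")
def de_run():
    matrix, truth = generate_expression(ExpressionConfig(seed=0))
    return differential_expression(matrix), truth


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged_and_single_p_unchanged(self):
        assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
        assert benjamini_hochberg([0.42]) == pytest.approx([0.42])

    def test_out_of_range_rejected(self):
        with pytest.raises(RhabdosignalError):
            benjamini_hochberg([0.5, 1.5])

    def test_monotone_in_sorted_order_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = rng.permutation(200)
        assert benjamini_hochberg(p[perm]) == pytest.approx(adj[perm])


class TestDifferentialExpression:
    def test_planted_genes_recovered_with_low_false_discovery(self, de_run):
        results, truth = de_run
        called = results[results["call"] != "not_significant"]
        called_genes = set(called["gene"])
        sensitivity = len(called_genes & set(truth)) / len(truth)
        fdr = len(called_genes - set(truth)) / max(len(called_genes), 1)
        assert sensitivity >= 0.8
        assert fdr <= 0.1
        for _, row in called.iterrows():
            if row["gene"] in truth:
                assert row["call"] == truth[row["gene"]]

    def test_call_thresholds_applied_exactly(self, de_run):
        results, _ = de_run
        up = (results["adj_p"] < 0.05) & (results["log_fc"] >= 1.5)
        down = (results["adj_p"] < 0.05) & (results["log_fc"] <= -1.5)
        assert ((results["call"] == "up") == up).all()
        assert ((results["call"] == "down") == down).all()

    def test_identical_group_means_not_significant(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            np.tile(rng.normal(5, 1, size=(50, 1)), (1, 8))
            + rng.normal(0, 0.3, size=(50, 8)),
            index=[f"G{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = {f"s{i}": "treatment" if i < 4 else "control" for i in range(8)}
        results = differential_expression(ExpressionMatrix(data, groups))
        gene0 = results.iloc[0]
        assert abs(gene0["log_fc"]) < 1.5 or gene0["adj_p"] >= 0.05

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        matrix, _ = generate_expression(ExpressionConfig(n_genes=200, seed=5))
        results = differential_expression(matrix, prior_df=0)
        treat = matrix.data[matrix.samples_in("treatment")].to_numpy()
        ctrl = matrix.data[matrix.samples_in("control")].to_numpy()
        t_ref, p_ref = stats.ttest_ind(treat, ctrl, axis=1, equal_var=True)
        assert results["moderated_t"].to_numpy() == pytest.approx(t_ref)
        assert results["p_value"].to_numpy() == pytest.approx(p_ref)

    def test_infinite_prior_df_gives_z_statistic_with_prior_variance(self):
        matrix, _ = generate_expression(ExpressionConfig(n_genes=200, seed=6))
        results = differential_expression(matrix, prior_df=math.inf)
        from rhabdosignal.transcriptomics import fit_variance_prior

        treat = matrix.data[matrix.samples_in("treatment")].to_numpy()
        ctrl = matrix.data[matrix.samples_in("control")].to_numpy()
        n1, n2 = treat.shape[1], ctrl.shape[1]
        s_sq = (treat.var(axis=1, ddof=1) * (n1 - 1)
                + ctrl.var(axis=1, ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
        _, s0_sq = fit_variance_prior(s_sq, n1 + n2 - 2)
        log_fc = treat.mean(axis=1) - ctrl.mean(axis=1)
        z = log_fc / np.sqrt(s0_sq * (1 / n1 + 1 / n2))
        assert results["moderated_t"].to_numpy() == pytest.approx(z)
        assert results["p_value"].to_numpy() == pytest.approx(
            2 * stats.norm.sf(np.abs(z)))

    def test_permuted_label_null_p_values_are_uniform(self):
        matrix, _ = generate_expression(
            ExpressionConfig(n_genes=5000, n_de=0, seed=9))
        results = differential_expression(matrix)
        ks = stats.kstest(results["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_single_replicate_group_rejected(self):
        data = pd.DataFrame(np.ones((5, 3)), index=list("ABCDE"),
                            columns=["t1", "t2", "c1"])
        groups = {"t1": "treatment", "t2": "treatment", "c1": "control"}
        with pytest.raises(ConfigError):
            ExpressionMatrix(data, groups)

    def test_matrix_file_round_trip(self, tmp_path):
        matrix, _ = generate_expression(ExpressionConfig(n_genes=30, n_de=5, seed=1))
        write_expression(matrix, tmp_path / "m.tsv", tmp_path / "g.tsv")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "g.tsv")
        assert np.allclose(back.data.to_numpy(), matrix.data.to_numpy())
        assert dict(back.groups) == dict(matrix.groups)


class TestAgainstLimma:
    def test_moderated_statistics_match_bioconductor_limma(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma cross-check cannot run")
        matrix, _ = generate_expression(
            ExpressionConfig(n_genes=80, n_de=8, seed=21))
        write_expression(matrix, tmp_path / "m.tsv", tmp_path / "g.tsv")
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            groups <- read.delim(args[2], header=FALSE)
            design <- model.matrix(~0 + factor(groups$V2,
                                   levels=c("control", "treatment")))
            colnames(design) <- c("control", "treatment")
            fit <- lmFit(x, design)
            fit <- contrasts.fit(fit,
                makeContrasts(treatment - control, levels=design))
            fit <- eBayes(fit)
            tt <- topTable(fit, number=Inf, sort.by="none")
            write.csv(data.frame(gene=rownames(tt), logFC=tt$logFC,
                                 t=tt$t, P=tt$P.Value),
                      args[3], row.names=FALSE)
        """))
        out = tmp_path / "limma.csv"
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "m.tsv"),
             str(tmp_path / "g.tsv"), str(out)],
            check=True, capture_output=True,
        )
        ours = differential_expression(matrix)
        theirs = pd.read_csv(out)
        merged = ours.merge(theirs, on="gene")
        assert merged["log_fc"].to_numpy() == pytest.approx(
            merged["logFC"].to_numpy())
        assert merged["moderated_t"].to_numpy() == pytest.approx(
            merged["t"].to_numpy(), rel=1e-6)
        assert merged["p_value"].to_numpy() == pytest.approx(
            merged["P"].to_numpy(), rel=1e-6)


class TestCountDeGenes:
    def test_empty_and_all_null_results(self):
        assert count_de_genes(pd.DataFrame()) == (0, 0, 0)
        frame = pd.DataFrame({"call": ["not_significant"] * 5})
        assert count_de_genes(frame) == (0, 0, 0)

    def test_counts_equal_truth_tally(self, de_run):
        results, _ = de_run
        n, up, down = count_de_genes(results)
        assert n == up + down
        assert up == int((results["call"] == "up").sum())
        assert down == int((results["call"] == "down").sum())


class TestEnrichment:
    def test_list_equal_to_pathway_gives_closed_form_fold(self):
        background = [f"g{i}" for i in range(100)]
        sets = {"path": set(background[:10]), "other": set(background[50:80])}
        result = enrich(background[:10], sets, background)
        row = result[result["set_name"] == "path"].iloc[0]
        assert row["fold_enrichment"] == pytest.approx(100 / 10)
        assert row["p_value"] == result["p_value"].min()

    def test_fold_enrichment_formula_example(self):
        # k/n over K/N with (9, 36, 200, 8000) gives exactly 10.0
        background = [f"g{i}" for i in range(8000)]
        pathway = set(background[:36])
        gene_list = background[:9] + background[100:291]  # 200 genes, 9 hits
        result = enrich(gene_list, {"set": pathway}, background)
        row = result.iloc[0]
        assert (row["k"], row["K"], row["n"], row["N"]) == (9, 36, 200, 8000)
        assert row["fold_enrichment"] == pytest.approx(10.0)

    def test_hypergeometric_tail_equals_enumeration_small_universe(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            big_n = int(rng.integers(10, 61))
            big_k = int(rng.integers(1, big_n + 1))
            n = int(rng.integers(1, big_n + 1))
            k = int(rng.integers(0, min(n, big_k) + 1))
            p_pkg = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
            p_enum = sum(
                math.comb(big_k, j) * math.comb(big_n - big_k, n - j)
                / math.comb(big_n, n)
                for j in range(k, min(n, big_k) + 1)
            )
            assert p_pkg == pytest.approx(p_enum, rel=1e-9, abs=1e-12)

    def test_fold_invariant_to_common_scaling(self):
        background = [f"g{i}" for i in range(200)]
        sets = {"s": set(background[:20])}
        base = enrich(background[:40], sets, background).iloc[0]
        scaled_bg = [f"g{i}" for i in range(400)]
        scaled_sets = {"s": set(scaled_bg[:40])}
        scaled = enrich(scaled_bg[:80], scaled_sets, scaled_bg).iloc[0]
        assert scaled["fold_enrichment"] == pytest.approx(base["fold_enrichment"])

    def test_random_lists_show_no_enrichment(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(2000)]
        sets = {f"s{j}": set(rng.choice(background, 50, replace=False))
                for j in range(20)}
        significant = 0
        for seed in range(20):
            draw = np.random.default_rng(seed).choice(background, 100,
                                                      replace=False)
            result = enrich(list(draw), sets, background)
            significant += int((result["fdr"] < 0.05).any())
        assert significant <= 1

    def test_empty_inputs_are_errors(self):
        with pytest.raises(ConfigError):
            enrich(["a"], {"s": {"a"}}, [])
        with pytest.raises(ConfigError):
            enrich([], {"s": {"a"}}, ["a"])

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "myopathy\tdisease\tDES\tTNNT1\tMYH7\n"
            "short\tx\tA\n"  # fewer than 3 fields of genes still parses
            "\n"
        )
        sets = read_gmt(path)
        assert sets["myopathy"] == {"DES", "TNNT1", "MYH7"}
        assert sets["short"] == {"A"}
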