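"""Subtype rules, differential-expression filtering and target assembly."""

import numpy as np
import pandas as pd
import pytest

from adcscreen.io import load_fixture_table
from adcscreen.synthetic import generate_target_universe
from adcscreen.targets import (FilterThresholds, assign_subtype, balanced_top_n,
                               batch_effect_assessment, de_filter, emt_markers,
                               intersect_targets_emt, localization_classify,
                               localization_flags, mean_rank_order)

TISSUE_COLS = ["Blood", "BM", "Breast", "Colon", "Heart", "Kidney", "Liver",
               "Lung", "Pancreas", "Skin", "Stomach"]


class TestAssignSubtype:
    @pytest.mark.parametrize("er,pr,her2,expected", [
        ("POS", "NEG", "POS", "luminal"),     # ER+ takes precedence over HER2
        ("NEG", "POS", "NEG", "luminal"),
        ("NEG", "NEG", "POS", "HER2+"),
        ("NEG", "NEG", "NEG", "triple-negative"),
        ("MISSING", "NEG", "NEG", "UNASSIGNED"),
        ("NEG", "MISSING", "POS", "UNASSIGNED"),
        ("NEG", "NEG", "MISSING", "UNASSIGNED"),
        ("POS", "MISSING", "MISSING", "luminal"),  # one positive suffices
    ])
    def test_receptor_rules(self, er, pr, her2, expected):
        assert assign_subtype(er, pr, her2) == expected

    def test_annotated_normal_overrides(self):
        assert assign_subtype("POS", "POS", "POS", annotated_normal=True) == "normal"


def two_group_matrix(gene_means):
    """Build a matrix whose group means equal the requested values exactly.

    ``gene_means``: dict gene -> (cancer_mean, {tissue: normal_mean}).
    Two samples per group at mean +/- 0.1 keep every group non-degenerate.
    """
    genes = list(gene_means)
    tissues = sorted({t for _, (_, norms) in gene_means.items() for t in norms})
    cols, data = [], {g: [] for g in genes}
    for s, d in (("C_1", 0.1), ("C_2", -0.1)):
        cols.append(s)
        for g in genes:
            data[g].append(gene_means[g][0] + d)
    for t in tissues:
        for s, d in ((f"N_{t}_1", 0.1), (f"N_{t}_2", -0.1)):
            cols.append(s)
            for g in genes:
                data[g].append(gene_means[g][1][t] + d)
    matrix = pd.DataFrame.from_dict(data, orient="index", dtype=float)
    matrix.columns = cols
    cancer = ["C_1", "C_2"]
    normals = {t: [f"N_{t}_1", f"N_{t}_2"] for t in tissues}
    return matrix, cancer, normals


class TestDeFilter:
    def test_no_differential_expression_fails(self):
        m, cancer, normals = two_group_matrix(
            {"flat": (8.0, {"Liver": 8.0, "Lung": 8.0})})
        rec = de_filter(m, cancer, normals)
        assert rec.loc["flat", "mean_ratio"] == pytest.approx(1.0)
        assert not rec.loc["flat", "passed_filter"]

    def test_spiked_gene_ratio_arithmetic(self):
        # cancer 3 log2 units above every normal tissue
        m, cancer, normals = two_group_matrix(
            {"spike": (9.0, {"Liver": 6.0, "Lung": 6.0, "Skin": 6.0})})
        rec = de_filter(m, cancer, normals)
        assert rec.loc["spike", "mean_ratio"] == pytest.approx(8.0)
        assert rec.loc["spike", "max_normal_over_cancer"] == pytest.approx(0.125)
        assert rec.loc["spike", "mean_ovl"] < 0.6
        assert bool(rec.loc["spike", "passed_filter"])

    def test_high_normal_tissue_fails_max_ratio(self):
        # overexpressed on average but 2 log2 higher in one normal tissue
        m, cancer, normals = two_group_matrix(
            {"toxic": (9.0, {"Liver": 4.0, "Lung": 4.0, "Skin": 11.0})})
        rec = de_filter(m, cancer, normals)
        assert rec.loc["toxic", "max_normal_over_cancer"] == pytest.approx(4.0)
        assert not rec.loc["toxic", "passed_filter"]

    def test_erbb2_fixture_row_passes_ratio_clauses(self):
        """The HER2-amplified receptor satisfies both ratio cut-offs against
        the printed per-tissue means (overlap not checkable from means)."""
        t1 = load_fixture_table("table1")
        row = t1.loc["ERBB2"]
        norms = {t: float(row[t]) for t in TISSUE_COLS}
        m, cancer, normals = two_group_matrix({"ERBB2": (float(row["HER2"]), norms)})
        rec = de_filter(m, cancer, normals)
        expected_mean = np.mean([2 ** (row["HER2"] - v) for v in norms.values()])
        assert rec.loc["ERBB2", "mean_ratio"] == pytest.approx(expected_mean)
        assert rec.loc["ERBB2", "mean_ratio"] > 2
        assert rec.loc["ERBB2", "max_normal_over_cancer"] <= 2

    def test_empty_tissue_group_raises(self):
        m, cancer, normals = two_group_matrix(
            {"g": (8.0, {"Liver": 6.0})})
        normals["Lung"] = []
        with pytest.raises(ValueError):
            de_filter(m, cancer, normals)

    def test_pass_is_monotone_in_cancer_expression(self):
        uni = generate_target_universe(n_genes=60, seed=3)
        sub = "luminal"
        cancer = uni["cancer_by_subtype"][sub]
        rec = de_filter(uni["matrix"], cancer, uni["normals_by_tissue"])
        raised = uni["matrix"].copy()
        raised[cancer] = raised[cancer] + 1.0
        rec2 = de_filter(raised, cancer, uni["normals_by_tissue"])
        passed_before = set(rec.index[rec["passed_filter"]])
        passed_after = set(rec2.index[rec2["passed_filter"]])
        assert passed_before <= passed_after


class TestMeanRankOrder:
    def test_uniform_winner_is_first(self):
        rec = pd.DataFrame({
            "ratio_Liver": [10.0, 2.0, 1.0],
            "ratio_Lung": [9.0, 3.0, 1.5],
        }, index=["win", "mid", "low"])
        out = mean_rank_order(rec)
        assert list(out.index) == ["win", "mid", "low"]
        assert out.loc["win", "mean_rank"] == 1.0

    def test_swapped_ranks_tie_broken_lexically(self):
        rec = pd.DataFrame({
            "ratio_Liver": [10.0, 5.0],
            "ratio_Lung": [5.0, 10.0],
        }, index=["zeta", "alpha"])
        out = mean_rank_order(rec)
        assert out["mean_rank"].tolist() == [1.5, 1.5]
        assert list(out.index) == ["alpha", "zeta"]

    def test_matches_rank_then_average_oracle(self, rng):
        ratios = rng.lognormal(0, 1, (100, 11))
        genes = [f"G{i:03d}" for i in range(100)]
        rec = pd.DataFrame(ratios, index=genes,
                           columns=[f"ratio_T{j}" for j in range(11)])
        out = mean_rank_order(rec)
        # brute-force oracle: per-tissue descending rank, then average
        expect = {}
        for i, g in enumerate(genes):
            ranks = []
            for j in range(11):
                col = ratios[:, j]
                ranks.append(1 + np.sum(col > col[i])
                             + 0.5 * (np.sum(col == col[i]) - 1))
            expect[g] = np.mean(ranks)
        order = sorted(genes, key=lambda g: (expect[g], g))
        assert list(out.index) == order
        assert np.allclose(out["mean_rank"].to_numpy(),
                           [expect[g] for g in out.index])


class TestLocalization:
    @staticmethod
    def _ann(rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_membrane_rule(self):
        ann = self._ann([
            {"gene_id": "ok", "gene_type": "protein-coding gene",
             "go_terms": "GO:0005886", "location": "",
             "n_transmembrane": 1, "n_extracellular_domains": 1},
            {"gene_id": "no_tm", "gene_type": "protein-coding gene",
             "go_terms": "GO:0005886", "location": "",
             "n_transmembrane": 0, "n_extracellular_domains": 1},
            {"gene_id": "pseudo", "gene_type": "pseudogene",
             "go_terms": "GO:0005886", "location": "",
             "n_transmembrane": 1, "n_extracellular_domains": 1},
            {"gene_id": "by_location", "gene_type": "protein-coding gene",
             "go_terms": "", "location": "Cell membrane",
             "n_transmembrane": 2, "n_extracellular_domains": 1},
        ])
        loc = localization_classify(ann)
        assert loc["ok"] == "MEMBRANE"
        assert loc["no_tm"] == "OTHER"
        assert loc["pseudo"] == "OTHER"
        assert loc["by_location"] == "MEMBRANE"

    def test_extracellular_rule(self):
        ann = self._ann([
            {"gene_id": "secreted", "gene_type": "protein-coding gene",
             "go_terms": "", "location": "Secreted",
             "n_transmembrane": 0, "n_extracellular_domains": 0},
            {"gene_id": "matrix", "gene_type": "protein-coding gene",
             "go_terms": "GO:0005576", "location": "",
             "n_transmembrane": 0, "n_extracellular_domains": 0},
            {"gene_id": "nucleus", "gene_type": "protein-coding gene",
             "go_terms": "GO:0005634", "location": "Nucleus",
             "n_transmembrane": 0, "n_extracellular_domains": 0},
        ])
        loc = localization_classify(ann)
        assert loc["secreted"] == "EXTRACELLULAR"
        assert loc["matrix"] == "EXTRACELLULAR"
        assert loc["nucleus"] == "OTHER"

    def test_gene_can_satisfy_both_rules(self):
        ann = self._ann([
            {"gene_id": "both", "gene_type": "protein-coding gene",
             "go_terms": "GO:0005886;GO:0005576", "location": "",
             "n_transmembrane": 1, "n_extracellular_domains": 1},
        ])
        flags = localization_flags(ann)
        assert bool(flags.loc["both", "membrane"])
        assert bool(flags.loc["both", "extracellular"])


class TestBalancedTopN:
    def test_round_robin_counts_on_disjoint_lists(self):
        lists = {
            "luminal": [f"L{i}" for i in range(20)],
            "HER2+": [f"H{i}" for i in range(20)],
            "triple-negative": [f"T{i}" for i in range(20)],
        }
        top = balanced_top_n(lists, n=50)
        assert len(top) == 50
        counts = top["subtype"].value_counts()
        assert counts["luminal"] == 17
        assert counts["HER2+"] == 17
        assert counts["triple-negative"] == 16

    def test_identical_lists_deduplicate(self):
        shared = [f"G{i}" for i in range(60)]
        top = balanced_top_n({s: shared for s in
                              ("luminal", "HER2+", "triple-negative")}, n=50)
        assert list(top.index) == shared[:50]

    def test_n_three_takes_one_per_list(self):
        lists = {"luminal": ["a"], "HER2+": ["b"], "triple-negative": ["c"]}
        top = balanced_top_n(lists, n=3)
        assert list(top.index) == ["a", "b", "c"]

    def test_short_supply_warns(self):
        with pytest.warns(UserWarning, match="only 2"):
            top = balanced_top_n({"luminal": ["a"], "HER2+": ["a", "b"],
                                  "triple-negative": []}, n=50)
        assert len(top) == 2


class TestEmtMarkers:
    @staticmethod
    def _panel(mes_shift, rng, n_lines=4, n_reps=3, sd=0.1):
        genes = list(mes_shift)
        cols, data = [], []
        lines_e = {f"E{i}": [f"E{i}_R{r}" for r in range(n_reps)]
                   for i in range(n_lines)}
        lines_m = {f"M{i}": [f"M{i}_R{r}" for r in range(n_reps)]
                   for i in range(n_lines)}
        all_cols = [c for v in lines_e.values() for c in v] + \
                   [c for v in lines_m.values() for c in v]
        X = np.empty((len(genes), len(all_cols)))
        for gi, g in enumerate(genes):
            for ci, c in enumerate(all_cols):
                base = 8.0 + (mes_shift[g] if c.startswith("M") else 0.0)
                X[gi, ci] = base + rng.normal(0, sd)
        return pd.DataFrame(X, index=genes, columns=all_cols), lines_e, lines_m

    def test_classification_by_ratio_and_overlap(self, rng):
        m, le, lm = self._panel({"mes": 2.0, "epi": -2.0, "weak": 0.4,
                                 "flat": 0.0}, rng)
        out = emt_markers(m, le, lm)
        assert out["mes"] == "MESENCHYMAL"
        assert out["epi"] == "EPITHELIAL"
        assert out["weak"] == "OTHER"   # ratio 2^0.4 < 2 regardless of OVL
        assert out["flat"] == "OTHER"

    def test_high_ratio_but_overlapping_densities_excluded(self, rng):
        # big mean shift but enormous line-to-line spread -> OVL >= 0.6
        genes = ["noisy"]
        lines_e = {f"E{i}": [f"E{i}_R0"] for i in range(6)}
        lines_m = {f"M{i}": [f"M{i}_R0"] for i in range(6)}
        cols = [v[0] for v in lines_e.values()] + [v[0] for v in lines_m.values()]
        vals = rng.normal(8.0, 6.0, 6).tolist() + rng.normal(9.5, 6.0, 6).tolist()
        m = pd.DataFrame([vals], index=genes, columns=cols)
        out = emt_markers(m, lines_e, lines_m)
        assert out["noisy"] == "OTHER"

    def test_too_few_lines_raises(self, rng):
        m, le, lm = self._panel({"g": 1.0}, rng)
        with pytest.raises(ValueError):
            emt_markers(m, {"E0": le["E0"]}, lm)


class TestFixtureIntersection:
    def test_mesenchymal_counts_match_published_tables(self):
        t1 = load_fixture_table("table1")
        t2 = load_fixture_table("table2")
        assert len(t1) == 50 and len(t2) == 50
        emt = pd.concat([t1["group"], t2["group"]]).str.upper()
        t1_targets = t1.copy()
        t1_targets["localization"] = "MEMBRANE"
        t2_targets = t2.copy()
        t2_targets["localization"] = "EXTRACELLULAR"
        both = pd.concat([t1_targets, t2_targets])
        annotated, counts = intersect_targets_emt(both, emt)
        assert counts[("MEMBRANE", "MESENCHYMAL")] == 4
        assert counts[("EXTRACELLULAR", "MESENCHYMAL")] == 13

    def test_empty_emt_set_gives_all_other(self):
        t1 = load_fixture_table("table1").copy()
        annotated, counts = intersect_targets_emt(
            t1, pd.Series(dtype=object))
        assert (annotated["emt_class"] == "OTHER").all()


class TestBatchEffects:
    @staticmethod
    def _cohort(series_sd, seed=0, marker_shift=3.0):
        from adcscreen.synthetic import CohortConfig, generate_breast_cohort
        cfg = CohortConfig(n_per_class=30, n_genes=60, series_sd=series_sd,
                           marker_shift=marker_shift, noise_sd=0.4,
                           n_series=6, seed=seed)
        return generate_breast_cohort(cfg)

    def test_null_series_effect_estimated_near_zero(self):
        m, tab, truth = self._cohort(series_sd=0.0)
        # receptor genes are bimodal within class (PR+/- inside luminal), so
        # status does not absorb their spread; use the unimodal genes
        pcs, comps = batch_effect_assessment(
            m, tab["tissue"], truth, tab["series"], n_top_var=40,
            genes=list(m.index[3:11]))
        assert (comps["sigma2_series"] < 0.01).all()

    def test_planted_series_variance_recovered(self):
        m, tab, truth = self._cohort(series_sd=0.3, seed=4)
        pcs, comps = batch_effect_assessment(
            m, tab["tissue"], truth, tab["series"], n_top_var=40,
            genes=list(m.index[3:23]))
        est = comps["sigma2_series"].mean()
        assert 0.05 <= est <= 0.15      # true sigma2 = 0.09
        # batch variance well below the squared marker effect
        assert est < (3.0 ** 2) / 10

    def test_top_variance_genes_invariant_to_sample_order(self, rng):
        m, tab, truth = self._cohort(series_sd=0.2, seed=5)
        shuffled = m[list(rng.permutation(m.columns))]
        pcs1, _ = batch_effect_assessment(m, tab["tissue"], truth,
                                          tab["series"], n_top_var=10,
                                          genes=[m.index[0]])
        pcs2, _ = batch_effect_assessment(shuffled, tab["tissue"], truth,
                                          tab["series"], n_top_var=10,
                                          genes=[m.index[0]])
        assert set(pcs1.index) == set(pcs2.index)

    def test_single_series_warns_and_skips_mixed_model(self):
        m, tab, truth = self._cohort(series_sd=0.0, seed=6)
        tab["series"] = "GSE0001"
        with pytest.warns(UserWarning, match="single series"):
            pcs, comps = batch_effect_assessment(m, tab["tissue"], truth,
                                                 tab["series"], n_top_var=20)
        assert comps.empty
        assert {"PC1", "PC2"} <= set(pcs.columns)
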