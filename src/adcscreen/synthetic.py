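"""Seeded synthetic expression data with the structure the pipeline assumes.

Real inputs to the pipeline are log2-scale normalized microarray matrices:
breast tumor/normal cohorts with bimodal receptor-gene expression driving
molecular subtype labels, panels of normal tissues, and replicated
tumor-derived cell-line panels with epithelial/mesenchymal expression
clusters. The generators here emulate those features — marker-gene blocks
shifted per class, two-mode receptor genes, additive per-series (batch)
shifts, missing receptor annotations, mislabeled seed labels, and
replicate structure — so every downstream stage is testable end to end
without external data. All generators are deterministic in their seed and
clip intensities to the plausible log2 microarray range [0, 16].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .targets import MISSING, NEG, POS

__all__ = [
    "CohortConfig",
    "PanelConfig",
    "ConfigurationError",
    "RECEPTOR_GENES",
    "CELL_LINE_CLASSES",
    "NORMAL_TISSUES",
    "generate_breast_cohort",
    "generate_normal_tissue_panel",
    "generate_cell_line_panel",
    "generate_gene_annotations",
    "generate_target_universe",
]

LOG2_MIN, LOG2_MAX = 0.0, 16.0

#: receptor genes, in (ER, PR, HER2) order
RECEPTOR_GENES = ("ESR1", "PGR", "ERBB2")

BREAST_CLASSES = ("normal", "luminal", "HER2+", "triple-negative")

#: default class sizes mirror the labeled reference panel of 59 lines
CELL_LINE_CLASSES = {"epithelial": 10, "mesenchymal": 23, "mixed": 12,
                     "melanoma": 8, "leukemia": 6}

NORMAL_TISSUES = ("Blood", "BM", "Breast", "Colon", "Heart", "Kidney",
                  "Liver", "Lung", "Pancreas", "Skin", "Stomach")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class CohortConfig:
    """Breast-cohort generator settings.

    ``receptor_gene_modes`` gives the log2 means of the negative and
    positive expression modes shared by the three receptor genes;
    ``missing_receptor_frac`` blanks the receptor annotation of that
    fraction of samples and ``mislabel_frac`` permutes that fraction of
    seed labels, emulating annotation gaps and mislabeled samples.
    """

    n_per_class: int = 100
    n_genes: int = 1000
    n_marker_genes_per_class: int = 10
    marker_shift: float = 3.0
    receptor_gene_modes: tuple = (4.0, 10.0)
    receptor_mode_sd: float = 0.7
    n_series: int = 5
    series_sd: float = 0.3
    missing_receptor_frac: float = 0.35
    mislabel_frac: float = 0.05
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _check(self.n_per_class > 0 and self.n_genes > 0
               and self.n_marker_genes_per_class > 0 and self.n_series > 0,
               "all counts must be > 0")
        _check(0 <= self.missing_receptor_frac <= 1
               and 0 <= self.mislabel_frac <= 1, "fractions must be in [0,1]")
        _check(self.marker_shift > 0, "marker_shift must be > 0")
        _check(self.receptor_gene_modes[0] < self.receptor_gene_modes[1],
               "negative receptor mode must lie below the positive mode")
        _check(self.n_genes >= len(RECEPTOR_GENES)
               + 4 * self.n_marker_genes_per_class,
               "n_genes too small for receptor + marker genes")


@dataclass(frozen=True)
class PanelConfig:
    """Cell-line panel generator settings.

    ``n_lines_per_class`` maps the five classes to line counts (defaults to
    the labeled reference panel's 10/23/12/8/6 split); each line gets
    ``n_replicates`` columns sharing a line profile.
    """

    n_lines_per_class: dict = field(default_factory=lambda: dict(CELL_LINE_CLASSES))
    n_replicates: int = 3
    cluster_genes_per_class: int = 20
    n_genes: int = 500
    line_sd: float = 0.3
    replicate_sd: float = 0.2
    cluster_high: float = 10.0
    cluster_low: float = 5.0
    seed: int = 0

    def __post_init__(self):
        _check(self.n_replicates >= 2,
               "n_replicates must be >= 2 (replicate-set CV needs a held-out set)")
        _check(set(self.n_lines_per_class) == set(CELL_LINE_CLASSES),
               f"classes must be {sorted(CELL_LINE_CLASSES)}")
        _check(all(v > 0 for v in self.n_lines_per_class.values()),
               "line counts must be > 0")
        _check(self.cluster_genes_per_class > 0 and self.n_genes
               >= 4 * self.cluster_genes_per_class,
               "n_genes too small for the four expression clusters")


def _gene_ids(n: int, prefix: str = "GENE") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _clip(x: np.ndarray) -> np.ndarray:
    return np.clip(x, LOG2_MIN, LOG2_MAX)


def generate_breast_cohort(config: CohortConfig | None = None):
    """Generate a four-class breast cohort (normal / luminal / HER2+ / TN).

    Receptor genes are drawn from the mode matching each sample's true
    subtype; each class has its own block of marker genes shifted by
    ``marker_shift``; a per-series additive shift is applied to every gene
    of a sample. Returns ``(matrix, sample_table, truth)`` where
    ``sample_table`` carries the (possibly blanked) receptor calls, the
    (possibly permuted) seed labels, tissue and series, and ``truth`` is
    the uncorrupted class label per sample.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_class
    samples = [f"S{i + 1:05d}" for i in range(4 * n)]
    truth = pd.Series(np.repeat(BREAST_CLASSES, n), index=samples, name="truth")

    neg_mu, pos_mu = cfg.receptor_gene_modes
    n_rec = len(RECEPTOR_GENES)
    n_marker = 4 * cfg.n_marker_genes_per_class
    genes = list(RECEPTOR_GENES) + _gene_ids(cfg.n_genes - n_rec)
    marker_genes = {
        cls: genes[n_rec + i * cfg.n_marker_genes_per_class:
                   n_rec + (i + 1) * cfg.n_marker_genes_per_class]
        for i, cls in enumerate(BREAST_CLASSES)
    }

    # receptor truth calls per sample
    er = np.where(truth == "luminal", POS, NEG)
    pr = np.where((truth == "luminal") & (rng.random(4 * n) < 0.5), POS, NEG)
    her2 = np.where(truth == "HER2+", POS, NEG)

    X = np.empty((cfg.n_genes, 4 * n))
    # receptor genes: two-mode Gaussian driven by the truth call
    for row, calls in zip(range(n_rec), (er, pr, her2)):
        mu = np.where(calls == POS, pos_mu, neg_mu)
        X[row] = mu + rng.normal(0.0, cfg.receptor_mode_sd, 4 * n)
    # remaining genes: per-gene baseline + class marker shifts + noise
    baseline = rng.uniform(4.0, 10.0, cfg.n_genes - n_rec)
    X[n_rec:] = baseline[:, None] + rng.normal(0.0, cfg.noise_sd,
                                               (cfg.n_genes - n_rec, 4 * n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for cls, mg in marker_genes.items():
        cols = (truth == cls).to_numpy()
        for g in mg:
            X[gene_pos[g], cols] += cfg.marker_shift
    # additive per-series shift shared by all genes of a sample
    series = rng.integers(0, cfg.n_series, 4 * n)
    shift = rng.normal(0.0, cfg.series_sd, cfg.n_series)
    X += shift[series][None, :]
    matrix = pd.DataFrame(_clip(X), index=genes, columns=samples)

    # seed labels: truth, with mislabel_frac cyclically permuted
    seed_label = truth.copy().rename("seed_label").astype(object)
    n_bad = int(round(cfg.mislabel_frac * 4 * n))
    if n_bad >= 2:
        bad = rng.choice(4 * n, size=n_bad, replace=False)
        seed_label.iloc[bad] = seed_label.iloc[np.roll(bad, 1)].to_numpy()
    # blank receptor annotations
    er, pr, her2 = er.astype(object), pr.astype(object), her2.astype(object)
    n_miss = int(round(cfg.missing_receptor_frac * 4 * n))
    if n_miss:
        miss = rng.choice(4 * n, size=n_miss, replace=False)
        for arr in (er, pr, her2):
            arr[miss] = MISSING

    table = pd.DataFrame({
        "seed_label": seed_label,
        "ER": er, "PR": pr, "HER2": her2,
        "tissue": "Breast",
        "series": [f"GSE{s + 1:04d}" for s in series],
        "annotated_normal": (truth == "normal").to_numpy(),
    }, index=samples)
    table.index.name = "sample_id"
    return matrix, table, truth


def generate_normal_tissue_panel(tissues=NORMAL_TISSUES, n_per_tissue: int = 20,
                                 spiked_targets=None, seed: int = 0,
                                 n_genes: int = 1000, noise_sd: float = 1.0,
                                 tissue_effect_sd: float = 0.5,
                                 gene_ids=None):
    """Generate normal-tissue reference samples.

    Each tissue gets its own per-gene baseline offset (tissue-specific
    profile). ``spiked_targets`` is a mapping gene id -> normal-tissue mean:
    those genes are pinned to that (typically low) mean in every tissue so
    the target-selection stage has known positives once paired with a
    cancer cohort. Returns ``(matrix, sample_table)``.
    """
    tissues = list(tissues)
    if not tissues:
        raise ConfigurationError("tissues must be non-empty")
    if len(set(tissues)) != len(tissues):
        raise ConfigurationError("duplicate tissue names")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    n_genes = len(genes)
    baseline = rng.uniform(4.0, 10.0, n_genes)
    spiked = dict(spiked_targets or {})
    unknown = set(spiked) - set(genes)
    if unknown:
        raise ConfigurationError(f"spiked targets not in gene universe: {sorted(unknown)}")

    cols, tiss_col = [], []
    blocks = []
    for t in tissues:
        offset = rng.normal(0.0, tissue_effect_sd, n_genes)
        mu = baseline + offset
        for g, val in spiked.items():
            mu[genes.index(g)] = val
        block = mu[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_per_tissue))
        blocks.append(block)
        cols += [f"N_{t}_{i + 1:03d}" for i in range(n_per_tissue)]
        tiss_col += [t] * n_per_tissue
    matrix = pd.DataFrame(_clip(np.hstack(blocks)), index=genes, columns=cols)
    table = pd.DataFrame({"tissue": tiss_col, "seed_label": "normal"}, index=cols)
    table.index.name = "sample_id"
    return matrix, table


def generate_cell_line_panel(config: PanelConfig | None = None):
    """Generate a replicated five-class cell-line panel.

    Four gene clusters (epithelial, mesenchymal, melanoma, leukemia) carry
    the class signal: the epithelial cluster is high in epithelial lines and
    low in mesenchymal lines, the mesenchymal cluster the reverse (the two
    clusters are anti-correlated across those classes), the mixed class sits
    midway on both, and the melanoma/leukemia clusters are high only in
    their own class. Each line has ``n_replicates`` columns sharing a
    line-specific profile plus replicate noise. Returns
    ``(matrix, sample_table, line_truth)``.
    """
    cfg = config or PanelConfig()
    rng = np.random.default_rng(cfg.seed)
    classes = list(CELL_LINE_CLASSES)
    genes = _gene_ids(cfg.n_genes)
    m = cfg.cluster_genes_per_class
    clusters = {
        "epithelial": genes[:m],
        "mesenchymal": genes[m:2 * m],
        "melanoma": genes[2 * m:3 * m],
        "leukemia": genes[3 * m:4 * m],
    }
    hi, lo = cfg.cluster_high, cfg.cluster_low
    mid = 0.5 * (hi + lo)
    # class mean per cluster: rows = cluster, cols = class
    cluster_mean = {
        # epithelial & mesenchymal clusters anti-correlated; mixed midway
        "epithelial": {"epithelial": hi, "mesenchymal": lo, "mixed": mid,
                       "melanoma": lo, "leukemia": lo},
        "mesenchymal": {"epithelial": lo, "mesenchymal": hi, "mixed": mid,
                        "melanoma": lo, "leukemia": lo},
        "melanoma": {"epithelial": lo, "mesenchymal": lo, "mixed": lo,
                     "melanoma": hi, "leukemia": lo},
        "leukemia": {"epithelial": lo, "mesenchymal": lo, "mixed": lo,
                     "melanoma": lo, "leukemia": hi},
    }
    baseline = rng.uniform(4.0, 10.0, cfg.n_genes)

    lines, line_truth = [], {}
    for cls in classes:
        for i in range(cfg.n_lines_per_class[cls]):
            ln = f"{cls.upper()[:3]}_{i + 1:03d}"
            lines.append(ln)
            line_truth[ln] = cls
    line_truth = pd.Series(line_truth, name="truth")

    cols, line_col = [], []
    data = []
    for ln in lines:
        cls = line_truth[ln]
        mu = baseline.copy()
        for cl_name, cl_genes in clusters.items():
            mu[genes.index(cl_genes[0]):genes.index(cl_genes[0]) + m] = \
                cluster_mean[cl_name][cls]
        mu = mu + rng.normal(0.0, cfg.line_sd, cfg.n_genes)  # line effect
        for r in range(cfg.n_replicates):
            data.append(mu + rng.normal(0.0, cfg.replicate_sd, cfg.n_genes))
            cols.append(f"{ln}_R{r + 1}")
            line_col.append(ln)
    matrix = pd.DataFrame(_clip(np.column_stack(data)), index=genes, columns=cols)
    table = pd.DataFrame({"line": line_col,
                          "seed_label": [line_truth[l] for l in line_col]},
                         index=cols)
    table.index.name = "sample_id"
    return matrix, table, line_truth


def generate_gene_annotations(n_genes: int = 1000, membrane_frac: float = 0.1,
                              extracellular_frac: float = 0.1, seed: int = 0,
                              gene_ids=None) -> pd.DataFrame:
    """Generate a gene annotation table consistent with the localization rules.

    Each gene is independently assigned membrane-qualifying evidence with
    probability ``membrane_frac`` (GO plasma-membrane term or "cell
    membrane" location, plus transmembrane and extracellular topological
    domains), extracellular-qualifying evidence with probability
    ``extracellular_frac``, or decoy annotations otherwise — including
    near-misses such as a plasma-membrane GO term without a transmembrane
    domain, and a slice of non-protein-coding genes.
    """
    _check(0 <= membrane_frac and 0 <= extracellular_frac
           and membrane_frac + extracellular_frac <= 1,
           "fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    n_genes = len(genes)
    u = rng.random(n_genes)
    rows = []
    for i, g in enumerate(genes):
        gene_type = "protein-coding gene"
        go, loc, n_tm, n_extra = "", "", 0, 0
        if u[i] < membrane_frac:
            if rng.random() < 0.5:
                go = "GO:0005886"
            else:
                loc = "Cell membrane"
            n_tm = int(rng.integers(1, 8))
            n_extra = int(rng.integers(1, 4))
        elif u[i] < membrane_frac + extracellular_frac:
            choice = rng.integers(0, 4)
            if choice == 0:
                go = "GO:0005576"
            else:
                loc = ("Extracellular matrix", "Extracellular space",
                       "Secreted")[choice - 1]
        else:
            decoy = rng.integers(0, 4)
            if decoy == 0:
                go, n_tm = "GO:0005886", 0  # membrane term, no TM domain
            elif decoy == 1:
                loc, n_tm = "Cytoplasm", int(rng.integers(0, 3))
            elif decoy == 2:
                gene_type = "pseudogene"
                go = "GO:0005886"
            else:
                go = "GO:0005634"  # nucleus
        rows.append({"gene_id": g, "gene_type": gene_type, "go_terms": go,
                     "location": loc, "n_transmembrane": n_tm,
                     "n_extracellular_domains": n_extra})
    return pd.DataFrame(rows).set_index("gene_id")


def generate_target_universe(n_genes: int = 300, n_targets_per_subtype: int = 10,
                             n_cancer_per_subtype: int = 30, n_per_tissue: int = 15,
                             target_shift: float = 3.0, noise_sd: float = 0.5,
                             tissues=NORMAL_TISSUES, seed: int = 0,
                             target_localization: str = "membrane"):
    """A shared cancer + normal gene universe with planted targets.

    Plants ``n_targets_per_subtype`` genes per breast-cancer subtype that
    sit ``target_shift`` log2 units above their flat normal-tissue mean in
    that subtype's cancer samples, gives them localization annotations that
    satisfy the requested rule, and surrounds them with decoy genes that
    fail one filter clause each (no overexpression, or high normal-tissue
    expression). Returns a dict with the matrix, sample table, annotation
    table, cancer/normal sample groupings and the planted gene ids.
    """
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    genes = _gene_ids(n_genes)
    n_targets = 3 * n_targets_per_subtype
    planted = {
        sub: genes[i * n_targets_per_subtype:(i + 1) * n_targets_per_subtype]
        for i, sub in enumerate(("luminal", "HER2+", "triple-negative"))
    }
    baseline = rng.uniform(4.0, 8.0, n_genes)

    # normal samples: flat across tissues apart from mild tissue effects
    norm_cols, norm_tissue = [], []
    norm_blocks = []
    for t in tissues:
        offset = rng.normal(0.0, 0.2, n_genes)
        mu = baseline + offset
        norm_blocks.append(mu[:, None] + rng.normal(0.0, noise_sd,
                                                    (n_genes, n_per_tissue)))
        norm_cols += [f"N_{t}_{i + 1:03d}" for i in range(n_per_tissue)]
        norm_tissue += [t] * n_per_tissue

    # cancer samples per subtype: planted targets shifted up in their subtype
    can_cols, can_sub = [], []
    can_blocks = []
    for sub in ("luminal", "HER2+", "triple-negative"):
        mu = baseline.copy()
        for g in planted[sub]:
            mu[genes.index(g)] += target_shift
        # decoy block: last tenth of genes are high in cancer AND normals
        can_blocks.append(mu[:, None] + rng.normal(0.0, noise_sd,
                                                   (n_genes, n_cancer_per_subtype)))
        tag = {"luminal": "LUM", "HER2+": "HER2", "triple-negative": "TN"}[sub]
        can_cols += [f"C_{tag}_{i + 1:03d}" for i in range(n_cancer_per_subtype)]
        can_sub += [sub] * n_cancer_per_subtype

    matrix = pd.DataFrame(_clip(np.hstack(can_blocks + norm_blocks)),
                          index=genes, columns=can_cols + norm_cols)
    table = pd.DataFrame(
        {"tissue": ["Breast"] * len(can_cols) + norm_tissue,
         "seed_label": can_sub + ["normal"] * len(norm_cols)},
        index=can_cols + norm_cols)
    table.index.name = "sample_id"

    # annotations: planted genes satisfy the requested localization rule
    ann = generate_gene_annotations(gene_ids=genes, membrane_frac=0.15,
                                    extracellular_frac=0.15,
                                    seed=int(rng.integers(0, 2**31 - 1)))
    flat = [g for sub in planted for g in planted[sub]]
    if target_localization == "membrane":
        ann.loc[flat, ["gene_type", "go_terms", "location"]] = \
            ["protein-coding gene", "GO:0005886", "Cell membrane"]
        ann.loc[flat, "n_transmembrane"] = 1
        ann.loc[flat, "n_extracellular_domains"] = 1
    else:
        ann.loc[flat, ["gene_type", "go_terms", "location"]] = \
            ["protein-coding gene", "GO:0005576", "Secreted"]
        ann.loc[flat, ["n_transmembrane", "n_extracellular_domains"]] = 0

    cancer_by_subtype = {sub: [c for c, s in zip(can_cols, can_sub) if s == sub]
                         for sub in ("luminal", "HER2+", "triple-negative")}
    normals_by_tissue = {t: [c for c, tt in zip(norm_cols, norm_tissue) if tt == t]
                         for t in tissues}
    return {
        "matrix": matrix,
        "sample_table": table,
        "annotations": ann,
        "cancer_by_subtype": cancer_by_subtype,
        "normals_by_tissue": normals_by_tissue,
        "planted": planted,
        "n_targets": n_targets,
    }
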