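"""Tumor-vs-normal target selection and prioritization.

Candidate antibody-drug-conjugate targets are genes overexpressed in a
breast-cancer molecular subtype relative to a panel of vital normal tissues.
The filter retains genes with

* max over tissues of the normal/cancer linear fold <= 2,
* mean over tissues of the cancer/normal linear fold > 2, and
* mean over tissues of the overlapping coefficient between the cancer and
  normal expression densities < 0.6,

with folds computed as 2^(difference of log2 group means). Survivors are
ordered by the mean over tissues of their per-tissue fold-change rank,
restricted to cell-membrane or extracellular protein-coding genes via
annotation rules, and assembled into a top-50 list balanced across the
luminal, HER2+ and triple-negative subtypes. Epithelial/mesenchymal marker
genes from a cell-line panel flag targets linked to the
epithelial-to-mesenchymal transition. Per-series batch structure is
assessed with principal components and a mixed model (series as random
effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kde import ovl

__all__ = [
    "FilterThresholds",
    "assign_subtype",
    "de_filter",
    "mean_rank_order",
    "localization_classify",
    "balanced_top_n",
    "emt_markers",
    "intersect_targets_emt",
    "batch_effect_assessment",
    "SUBTYPES",
]

POS, NEG, MISSING = "POS", "NEG", "MISSING"
SUBTYPES = ("luminal", "HER2+", "triple-negative")

MEMBRANE, EXTRACELLULAR, OTHER = "MEMBRANE", "EXTRACELLULAR", "OTHER"
MESENCHYMAL, EPITHELIAL = "MESENCHYMAL", "EPITHELIAL"

GO_PLASMA_MEMBRANE = "GO:0005886"
GO_EXTRACELLULAR_REGION = "GO:0005576"
EXTRACELLULAR_LOCATION_TERMS = ("extracellular matrix", "extracellular space",
                                "secreted")


@dataclass(frozen=True)
class FilterThresholds:
    """Differential-expression filter cut-offs (defaults as published use)."""

    max_normal_over_cancer: float = 2.0
    min_mean_ratio: float = 2.0
    max_mean_ovl: float = 0.6
    top_n: int = 50
    # mean of per-tissue linear folds; "geometric" averages log-folds instead
    ratio_mean: str = "arithmetic"
    # average per-tissue OVLs; "pooled" computes one OVL against all normals
    ovl_mode: str = "per_tissue"


def assign_subtype(er: str, pr: str, her2: str, annotated_normal: bool = False) -> str:
    """Molecular subtype from receptor calls.

    normal if annotated so; luminal if ER+ and/or PR+; HER2+ if ER−/PR−/HER2+;
    triple-negative if all three negative; UNASSIGNED when the available
    calls cannot settle the rule (missing values).
    """
    if annotated_normal:
        return "normal"
    if POS in (er, pr):
        return "luminal"
    if MISSING in (er, pr):
        return "UNASSIGNED"
    # ER and PR both NEG from here
    if her2 == POS:
        return "HER2+"
    if her2 == NEG:
        return "triple-negative"
    return "UNASSIGNED"


def de_filter(matrix: pd.DataFrame, cancer_samples, normals_by_tissue: dict,
              thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Per-gene differential-expression filter of cancer vs normal tissues.

    Returns a frame indexed by gene with per-tissue linear cancer/normal
    ratios (columns ``ratio_<tissue>``), ``max_normal_over_cancer``,
    ``mean_ratio``, ``mean_ovl`` and the boolean ``passed_filter``.
    """
    th = thresholds or FilterThresholds()
    cancer = matrix[list(cancer_samples)]
    if cancer.shape[1] < 2:
        raise ValueError("need >= 2 cancer samples")
    tissues = list(normals_by_tissue)
    if not tissues:
        raise ValueError("need at least one normal tissue group")
    cmean = cancer.mean(axis=1)
    out = pd.DataFrame(index=matrix.index)
    ratios = {}
    for t in tissues:
        ids = list(normals_by_tissue[t])
        if len(ids) < 2:
            raise ValueError(f"tissue {t!r} has fewer than 2 samples")
        nmean = matrix[ids].mean(axis=1)
        ratios[t] = np.power(2.0, cmean - nmean)
        out[f"ratio_{t}"] = ratios[t]
    rmat = pd.DataFrame(ratios)
    out["max_normal_over_cancer"] = (1.0 / rmat).max(axis=1)
    if th.ratio_mean == "geometric":
        out["mean_ratio"] = np.exp(np.log(rmat).mean(axis=1))
    else:
        out["mean_ratio"] = rmat.mean(axis=1)

    cvals = cancer.to_numpy(dtype=float)
    ovls = np.empty(len(matrix.index))
    if th.ovl_mode == "pooled":
        pooled_ids = [s for t in tissues for s in normals_by_tissue[t]]
        nvals = matrix[pooled_ids].to_numpy(dtype=float)
        for i in range(len(ovls)):
            ovls[i] = ovl(cvals[i], nvals[i], point_mass_convention=True).coefficient
    else:
        per_tissue = np.empty((len(ovls), len(tissues)))
        for j, t in enumerate(tissues):
            nvals = matrix[list(normals_by_tissue[t])].to_numpy(dtype=float)
            for i in range(len(ovls)):
                per_tissue[i, j] = ovl(cvals[i], nvals[i],
                                       point_mass_convention=True).coefficient
        ovls = per_tissue.mean(axis=1)
    out["mean_ovl"] = ovls
    out["passed_filter"] = (
        (out["max_normal_over_cancer"] <= th.max_normal_over_cancer)
        & (out["mean_ratio"] > th.min_mean_ratio)
        & (out["mean_ovl"] < th.max_mean_ovl)
    )
    return out


def mean_rank_order(records: pd.DataFrame) -> pd.DataFrame:
    """Order genes by the mean over tissues of their fold-change rank.

    Within each normal tissue, genes are ranked by cancer/normal ratio
    descending (rank 1 = most overexpressed); ``mean_rank`` averages the
    per-tissue ranks and the output is sorted ascending, ties broken by
    gene id.
    """
    ratio_cols = [c for c in records.columns if c.startswith("ratio_")]
    if not ratio_cols:
        raise ValueError("records carry no per-tissue ratio columns")
    ranks = records[ratio_cols].rank(ascending=False, method="average")
    out = records.copy()
    out["mean_rank"] = ranks.mean(axis=1)
    out = out.iloc[np.lexsort((out.index.astype(str), out["mean_rank"].to_numpy()))]
    return out


def localization_classify(annotations: pd.DataFrame) -> pd.Series:
    """Classify genes as MEMBRANE, EXTRACELLULAR, or OTHER.

    MEMBRANE: protein-coding and (GO plasma-membrane term or a "cell
    membrane" subcellular location) and at least one transmembrane and one
    extracellular topological domain. EXTRACELLULAR: protein-coding and
    (GO extracellular-region term or an extracellular-matrix/space/secreted
    location). A gene can satisfy both; MEMBRANE is reported, with the
    both-eligible flag available via :func:`localization_flags`.
    """
    flags = localization_flags(annotations)
    out = pd.Series(OTHER, index=annotations.index, dtype=object)
    out[flags["extracellular"]] = EXTRACELLULAR
    out[flags["membrane"]] = MEMBRANE
    return out


def localization_flags(annotations: pd.DataFrame) -> pd.DataFrame:
    """Boolean membrane/extracellular eligibility per gene.

    Expects columns: ``gene_type``, ``go_terms`` (delimited string),
    ``location`` (free-text subcellular location), ``n_transmembrane`` and
    ``n_extracellular_domains`` (topological-domain counts).
    """
    coding = annotations["gene_type"].astype(str) == "protein-coding gene"
    go = annotations["go_terms"].fillna("").astype(str)
    loc = annotations["location"].fillna("").astype(str).str.lower()
    membrane_evidence = go.str.contains(GO_PLASMA_MEMBRANE, regex=False) | \
        loc.str.contains("cell membrane", regex=False)
    topology = (annotations["n_transmembrane"].fillna(0) >= 1) & \
        (annotations["n_extracellular_domains"].fillna(0) >= 1)
    membrane = coding & membrane_evidence & topology
    extra_evidence = go.str.contains(GO_EXTRACELLULAR_REGION, regex=False)
    for term in EXTRACELLULAR_LOCATION_TERMS:
        extra_evidence |= loc.str.contains(term, regex=False)
    extracellular = coding & extra_evidence
    return pd.DataFrame({"membrane": membrane, "extracellular": extracellular})


def balanced_top_n(ordered_by_subtype: dict, n: int = 50) -> pd.DataFrame:
    """Assemble a top-n target list balanced across subtypes.

    ``ordered_by_subtype`` maps subtype -> ordered gene list (best first),
    already restricted to filter survivors with the requested localization.
    Genes are drawn round-robin in fixed subtype order (luminal, HER2+,
    triple-negative), skipping genes already taken, until ``n`` genes are
    collected or every list is exhausted (shorter table, with a warning).
    """
    import warnings

    order = [s for s in SUBTYPES if s in ordered_by_subtype]
    order += [s for s in ordered_by_subtype if s not in order]
    iters = {s: iter(list(ordered_by_subtype[s])) for s in order}
    taken: list[tuple[str, str]] = []
    seen: set = set()
    active = dict(iters)
    while len(taken) < n and active:
        for s in list(order):
            if s not in active:
                continue
            for g in active[s]:
                if g not in seen:
                    seen.add(g)
                    taken.append((g, s))
                    break
            else:
                del active[s]
            if len(taken) >= n:
                break
    if len(taken) < n:
        warnings.warn(f"only {len(taken)} of the requested {n} targets available")
    return pd.DataFrame(taken, columns=["gene_id", "subtype"]).set_index("gene_id")


def emt_markers(matrix: pd.DataFrame, epithelial_lines: dict, mesenchymal_lines: dict,
                ratio_hi: float = 2.0, ratio_lo: float = 0.5,
                max_ovl: float = 0.6) -> pd.Series:
    """Epithelial/mesenchymal marker classification from a cell-line panel.

    ``epithelial_lines`` / ``mesenchymal_lines`` map line id -> replicate
    column ids; replicates are collapsed to per-line means first. With
    ratio = 2^(mesenchymal mean − epithelial mean) over lines: MESENCHYMAL
    if ratio > 2 and OVL < 0.6; EPITHELIAL if ratio < 0.5 and OVL < 0.6;
    OTHER otherwise.
    """
    if len(epithelial_lines) < 2 or len(mesenchymal_lines) < 2:
        raise ValueError("need >= 2 lines per class")

    def line_means(lines: dict) -> pd.DataFrame:
        return pd.DataFrame({ln: matrix[list(cols)].mean(axis=1)
                             for ln, cols in lines.items()})

    epi = line_means(epithelial_lines)
    mes = line_means(mesenchymal_lines)
    ratio = np.power(2.0, mes.mean(axis=1) - epi.mean(axis=1))
    evals = epi.to_numpy(dtype=float)
    mvals = mes.to_numpy(dtype=float)
    out = pd.Series(OTHER, index=matrix.index, dtype=object)
    for i, g in enumerate(matrix.index):
        r = ratio.iloc[i]
        if r > ratio_hi or r < ratio_lo:
            coef = ovl(evals[i], mvals[i], point_mass_convention=True).coefficient
            if coef < max_ovl:
                out.iloc[i] = MESENCHYMAL if r > ratio_hi else EPITHELIAL
    return out


def intersect_targets_emt(target_table: pd.DataFrame, emt_classes: pd.Series):
    """Annotate targets with their EMT marker class and summarise counts.

    Returns (annotated table, counts): the table gains an ``emt_class``
    column (OTHER for genes absent from ``emt_classes``); counts is a
    Series indexed by (localization, emt_class) when the table carries a
    ``localization`` column, else by emt_class alone.
    """
    out = target_table.copy()
    out["emt_class"] = emt_classes.reindex(out.index).fillna(OTHER)
    if "localization" in out.columns:
        counts = out.groupby(["localization", "emt_class"]).size()
    else:
        counts = out.groupby("emt_class").size()
    return out, counts


def batch_effect_assessment(matrix: pd.DataFrame, tissue: pd.Series,
                            status: pd.Series, series: pd.Series,
                            n_top_var: int = 1000, genes=None):
    """Assess per-series (batch) structure.

    (a) PCA: the first two principal components of the ``n_top_var``
    highest-total-variance genes, returned with per-sample tissue, status
    and series tags plus the fraction of variance explained.
    (b) Per-gene variance components: a linear mixed model with tissue and
    status as fixed effects and series as a random intercept, fit by REML;
    returns sigma2_series, sigma2_resid and the fixed-effect range per gene
    (``genes`` defaults to the 20 highest-variance genes to keep the fits
    cheap).

    With a single series the random effect is inestimable: PCA-only output
    is returned with a warning and an empty components frame.
    """
    import warnings

    from sklearn.decomposition import PCA

    samples = list(matrix.columns)
    tissue = tissue.loc[samples]
    status = status.loc[samples]
    series = series.loc[samples]

    total_var = matrix.var(axis=1)
    top = total_var.sort_values(ascending=False, kind="stable").index[:n_top_var]
    X = matrix.loc[top].to_numpy(dtype=float).T
    X = X - X.mean(axis=0)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    pcs = pd.DataFrame({"PC1": coords[:, 0], "PC2": coords[:, 1],
                        "tissue": tissue.values, "status": status.values,
                        "series": series.values}, index=samples)
    pcs.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_

    if series.nunique() < 2:
        warnings.warn("single series: random effect inestimable; PCA only")
        return pcs, pd.DataFrame(columns=["sigma2_series", "sigma2_resid",
                                          "fixed_effect_range"])

    import statsmodels.formula.api as smf

    if genes is None:
        genes = list(top[:20])
    rows = {}
    for g in genes:
        df = pd.DataFrame({"y": matrix.loc[g, samples].to_numpy(dtype=float),
                           "tissue": tissue.values, "status": status.values,
                           "series": series.values})
        fixed = "y ~ C(tissue) + C(status)"
        if df["tissue"].nunique() < 2:
            fixed = "y ~ C(status)"
        if df["status"].nunique() < 2:
            fixed = "y ~ C(tissue)" if df["tissue"].nunique() >= 2 else "y ~ 1"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(fixed, df, groups=df["series"]).fit(reml=True)
            sigma2_series = float(fit.cov_re.iloc[0, 0])
            sigma2_resid = float(fit.scale)
            fe = fit.fe_params
        except (np.linalg.LinAlgError, ValueError):
            # variance component at the zero boundary: REML profile is
            # singular; report the boundary estimate from the fixed fit
            ols = smf.ols(fixed, df).fit()
            sigma2_series = 0.0
            sigma2_resid = float(ols.mse_resid)
            fe = ols.params
        rows[g] = {
            "sigma2_series": sigma2_series,
            "sigma2_resid": sigma2_resid,
            "fixed_effect_range": float(fe.max() - fe.min()),
        }
    comps = pd.DataFrame.from_dict(rows, orient="index")
    return pcs, comps
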