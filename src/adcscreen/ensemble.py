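"""Multiclass ensemble classification with abstention and self-training.

Multiclass problems are decomposed into binary ones, either one-against-one
(OAO: every unordered class pair) or one-against-all (OAA: each class versus
the rest), each solved by a binary classifier trained on features selected
in-problem by one of three ranking statistics. Votes are combined with an
abstention rule: under OAO a class must win *all* of its pairwise problems;
under OAA exactly one detector must fire. An expert = one combination of
(feature-selection method, classifier backend, feature-set size 2^k); the
ensemble's per-sample vote tally drives both accuracy estimation (repeated
stratified cross-validation with in-fold feature selection) and an iterative
self-training labeler in which labels winning more than a feedback threshold
of votes re-enter the training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ranking import RankMethod, rank_features, select_top_features

__all__ = [
    "ABSTAIN",
    "ExpertGrid",
    "VoteRecord",
    "IterationTrace",
    "make_classifier",
    "CLASSIFIER_NAMES",
    "oao_decompose",
    "oao_win_threshold",
    "oao_predict",
    "oaa_predict",
    "repeated_stratified_cv",
    "replicate_set_cv",
    "anova_factor_effects",
    "iterative_ensemble_label",
    "expert_vote_count",
    "tier_of",
]

#: sentinel returned when the decomposition's vote rule is not satisfied
ABSTAIN = "ABSTAIN"

TIER_UNANIMOUS = "UNANIMOUS"
TIER_HIGH = "HIGH"
TIER_REASONABLE = "REASONABLE"
TIER_UNLABELED = "UNLABELED"
TIERS = (TIER_UNANIMOUS, TIER_HIGH, TIER_REASONABLE, TIER_UNLABELED)

CLASSIFIER_NAMES = ("bagging", "tree", "knn", "nb", "rf", "svm")


def make_classifier(name: str, seed: int | None = None):
    """Binary classifier backends behind a single fit/predict contract.

    Defaults: bagging of 10 trees, entropy-split decision tree (C4.5-style),
    kNN with k=5, Gaussian naive Bayes, random forest with 100 trees, linear
    soft-margin SVM with C=1. Stochastic backends take a seed.
    """
    rng = None if seed is None else int(seed)
    if name == "bagging":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(criterion="entropy", random_state=rng),
            n_estimators=10, random_state=rng)
    if name == "tree":
        return DecisionTreeClassifier(criterion="entropy", random_state=rng)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "nb":
        return GaussianNB()
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=rng)
    if name == "svm":
        return SVC(kernel="linear", C=1.0, random_state=rng)
    raise ValueError(f"unknown classifier backend {name!r}")


@dataclass(frozen=True)
class ExpertGrid:
    """The factor grid defining the ensemble of experts.

    The breast-cohort expert count is |fs| · |clf| · |k|; in cell-line mode
    each expert is additionally replicated per labeled replicate set and
    votes once per unlabeled replicate (see :func:`expert_vote_count`).
    """

    fs_methods: tuple = (RankMethod.MODT_Q, RankMethod.OVL, RankMethod.SVM_WEIGHT)
    classifiers: tuple = ("svm", "rf")
    k_values: tuple = (5, 6, 7, 8, 9, 10)
    decomposition: str = "OAO"
    replicate_sets: int = 1

    def __post_init__(self):
        if not (self.fs_methods and self.classifiers and self.k_values):
            raise ValueError("fs_methods, classifiers and k_values must be non-empty")
        if self.decomposition not in ("OAO", "OAA"):
            raise ValueError("decomposition must be OAO or OAA")
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                raise ValueError(f"unknown classifier {c!r}")
        object.__setattr__(self, "fs_methods",
                           tuple(RankMethod(m) for m in self.fs_methods))

    def experts(self):
        """Iterate (fs_method, classifier, k) combinations in fixed order."""
        return itertools.product(self.fs_methods, self.classifiers, self.k_values)

    @property
    def n_experts(self) -> int:
        return len(self.fs_methods) * len(self.classifiers) * len(self.k_values)


def expert_vote_count(grid: ExpertGrid, unlabeled_replicates: int = 1) -> int:
    """Votes cast per classified unit.

    Breast mode (``replicate_sets == 1``): one vote per expert. Cell-line
    mode: each expert is trained once per labeled replicate set and votes on
    each unlabeled replicate of a line, so the per-line total is
    replicate_sets · unlabeled_replicates · |fs| · |clf| · |k|.
    """
    return grid.replicate_sets * unlabeled_replicates * grid.n_experts


# ---------------------------------------------------------------------------
# multiclass decomposition and abstention voting

def oao_decompose(classes) -> list[tuple]:
    """All unordered class pairs in deterministic (sorted) order."""
    cls = sorted(set(classes))
    if len(cls) < 2:
        raise ValueError("need at least 2 classes")
    return list(itertools.combinations(cls, 2))


def oao_win_threshold(n_classes: int) -> int:
    """Pairwise wins required for a label under OAO: all C−1 of them."""
    return n_classes - 1


def oao_predict(pairwise: dict, classes) -> str:
    """Combine one-vs-one outcomes: a class wins only by sweeping its pairs.

    ``pairwise`` maps each unordered pair (as produced by
    :func:`oao_decompose`) to the winning label of that binary problem. At
    most one class can win all its C−1 problems, so the rule is well
    defined; any other outcome abstains.
    """
    cls = sorted(set(classes))
    problems = oao_decompose(cls)
    wins = {c: 0 for c in cls}
    for pair in problems:
        if pair not in pairwise:
            raise ValueError(f"missing prediction for pair {pair}")
        winner = pairwise[pair]
        if winner not in pair:
            raise ValueError(f"label {winner!r} is not in pair {pair}")
        wins[winner] += 1
    need = oao_win_threshold(len(cls))
    winners = [c for c, w in wins.items() if w >= need]
    return winners[0] if len(winners) == 1 else ABSTAIN


def oaa_predict(per_class: dict, classes) -> str:
    """Combine one-vs-all outcomes: label iff exactly one detector fires."""
    cls = sorted(set(classes))
    positives = []
    for c in cls:
        if c not in per_class:
            raise ValueError(f"missing one-vs-all prediction for class {c!r}")
        if per_class[c]:
            positives.append(c)
    return positives[0] if len(positives) == 1 else ABSTAIN


# ---------------------------------------------------------------------------
# expert machinery

def _fit_binary_expert(matrix, pos_ids, neg_ids, fs_method, clf_name, k, seed):
    """Rank features on the two training groups, keep the top 2^k, fit."""
    ranking = rank_features(matrix, pos_ids, neg_ids, fs_method)
    feats = select_top_features(ranking, k)
    X = matrix.loc[feats, list(pos_ids) + list(neg_ids)].to_numpy(dtype=float).T
    y = np.r_[np.ones(len(pos_ids)), np.zeros(len(neg_ids))]
    clf = make_classifier(clf_name, seed)
    clf.fit(X, y)
    return feats, clf


def _predict_binary(matrix, sample_ids, feats, clf):
    X = matrix.loc[feats, list(sample_ids)].to_numpy(dtype=float).T
    return clf.predict(X).astype(bool)


def _expert_votes(matrix, labeled: pd.Series, predict_ids, grid: ExpertGrid,
                  rng: np.random.Generator, ranking_cache=None):
    """One voting round: every expert labels every sample in ``predict_ids``.

    Returns a DataFrame of shape (n_predict, n_experts) of labels/ABSTAIN.
    Feature rankings depend only on (fs_method, binary problem), so they are
    computed once and shared across classifiers and k values.
    """
    classes = sorted(labeled.unique())
    by_class = {c: list(labeled.index[labeled == c]) for c in classes}
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 labeled samples")

    if grid.decomposition == "OAO":
        problems = [(("pair",) + p, by_class[p[0]], by_class[p[1]])
                    for p in oao_decompose(classes)]
    else:
        problems = [(("rest", c), by_class[c],
                     [s for cc in classes if cc != c for s in by_class[cc]])
                    for c in classes]

    # rankings shared across (clf, k): cache keyed by (fs, problem id)
    rankings = {}
    for fs in grid.fs_methods:
        for key, pos, neg in problems:
            cache_key = (fs, key)
            if ranking_cache is not None and cache_key in ranking_cache:
                rankings[cache_key] = ranking_cache[cache_key]
            else:
                rankings[cache_key] = rank_features(matrix, pos, neg, fs)
                if ranking_cache is not None:
                    ranking_cache[cache_key] = rankings[cache_key]

    votes = {}
    for fs, clf_name, k in grid.experts():
        seed = int(rng.integers(0, 2**31 - 1))
        binary = {}
        for key, pos, neg in problems:
            feats = select_top_features(rankings[(fs, key)], k)
            X = matrix.loc[feats, pos + neg].to_numpy(dtype=float).T
            y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
            clf = make_classifier(clf_name, seed)
            if isinstance(clf, KNeighborsClassifier):
                clf.set_params(n_neighbors=min(clf.n_neighbors, len(y)))
            clf.fit(X, y)
            binary[key] = _predict_binary(matrix, predict_ids, feats, clf)
        col = []
        for i in range(len(predict_ids)):
            if grid.decomposition == "OAO":
                pairwise = {key[1:]: (key[1] if binary[key][i] else key[2])
                            for key in binary}
                col.append(oao_predict(pairwise, classes))
            else:
                per_class = {key[1]: bool(binary[key][i]) for key in binary}
                col.append(oaa_predict(per_class, classes))
        votes[(fs.value, clf_name, k)] = col
    return pd.DataFrame(votes, index=list(predict_ids))


# ---------------------------------------------------------------------------
# cross-validation and ANOVA

def repeated_stratified_cv(matrix: pd.DataFrame, labels: pd.Series,
                           grid: ExpertGrid, folds: int = 5, repeats: int = 10,
                           seed: int = 0,
                           decompositions: tuple = ("OAO", "OAA")) -> pd.DataFrame:
    """Repeated stratified k-fold CV with in-fold feature selection.

    Feature rankings are recomputed inside every training fold (no test-set
    leakage). Accuracy = correct predictions / total predictions, abstentions
    counted as incorrect. Returns one row per
    (fs_method, classifier, k, decomposition, repeat).
    """
    labels = labels.loc[matrix.columns]
    counts = labels.value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise ValueError(f"classes {small} have fewer members than folds={folds}")
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, rep_ss in enumerate(ss.spawn(repeats)):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        rng = np.random.default_rng(rep_seed)
        # accumulate correctness per expert x decomposition across folds
        correct = {}
        total = {}
        for train_idx, test_idx in skf.split(labels.index, labels.values):
            train_ids = labels.index[train_idx]
            test_ids = labels.index[test_idx]
            train_lab = labels.loc[train_ids]
            for decomp in decompositions:
                g = ExpertGrid(fs_methods=grid.fs_methods,
                               classifiers=grid.classifiers,
                               k_values=grid.k_values, decomposition=decomp,
                               replicate_sets=grid.replicate_sets)
                votes = _expert_votes(matrix, train_lab, list(test_ids), g, rng)
                truth = labels.loc[test_ids].to_numpy()
                for expert in votes.columns:
                    key = expert + (decomp,)
                    pred = votes[expert].to_numpy()
                    correct[key] = correct.get(key, 0) + int((pred == truth).sum())
                    total[key] = total.get(key, 0) + len(truth)
        for key in correct:
            fs, clf, k, decomp = key
            rows.append({"fs": fs, "clf": clf, "k": k, "decomposition": decomp,
                         "repeat": rep, "accuracy": correct[key] / total[key]})
    return pd.DataFrame(rows)


def replicate_set_cv(matrix: pd.DataFrame, line_labels: pd.Series,
                     line_of: pd.Series, grid: ExpertGrid,
                     n_train_sets: int | None = None, repeats: int = 10,
                     seed: int = 0,
                     decompositions: tuple = ("OAO", "OAA")) -> pd.DataFrame:
    """Cross-validation for replicated panels (cell-line mode).

    Each line's replicates are randomly assigned to ``grid.replicate_sets``
    sets per repeat; feature selection and training use ``n_train_sets`` of
    them (default: all but two) and validation uses the held-out sets, so a
    line never contributes both training and test columns to the same split.
    """
    n_sets = grid.replicate_sets
    if n_sets < 2:
        raise ValueError("replicate-set CV needs replicate_sets >= 2")
    if n_train_sets is None:
        n_train_sets = max(1, n_sets - 2)
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, rep_ss in enumerate(ss.spawn(repeats)):
        rng = np.random.default_rng(rep_ss)
        # per-line random assignment of replicates to sets
        set_of = pd.Series(index=line_of.index, dtype=int)
        for line, reps in line_of.groupby(line_of):
            ids = list(reps.index)
            assign = rng.permutation(len(ids)) % n_sets
            set_of.loc[ids] = assign
        correct, total = {}, {}
        for held in itertools.combinations(range(n_sets), n_sets - n_train_sets):
            test_ids = set_of.index[set_of.isin(held)]
            train_ids = set_of.index[~set_of.isin(held)]
            train_lab = line_labels.loc[line_of.loc[train_ids]].set_axis(train_ids)
            for decomp in decompositions:
                g = ExpertGrid(fs_methods=grid.fs_methods,
                               classifiers=grid.classifiers,
                               k_values=grid.k_values, decomposition=decomp,
                               replicate_sets=grid.replicate_sets)
                votes = _expert_votes(matrix, train_lab, list(test_ids), g, rng)
                truth = line_labels.loc[line_of.loc[test_ids]].to_numpy()
                for expert in votes.columns:
                    key = expert + (decomp,)
                    pred = votes[expert].to_numpy()
                    correct[key] = correct.get(key, 0) + int((pred == truth).sum())
                    total[key] = total.get(key, 0) + len(truth)
        for key in correct:
            fs, clf, k, decomp = key
            rows.append({"fs": fs, "clf": clf, "k": k, "decomposition": decomp,
                         "repeat": rep, "accuracy": correct[key] / total[key]})
    return pd.DataFrame(rows)


def anova_factor_effects(accuracy_table: pd.DataFrame) -> pd.DataFrame:
    """Main-effects factorial ANOVA of CV accuracy.

    Factors: feature-selection method, classifier, number of features (k)
    and decomposition; only factors with >= 2 levels present are analysed.
    Returns a frame indexed by factor with sum_sq, df, F and p columns.
    A factor whose sum of squares is numerically zero gets F = 0, p = 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = [f for f in ("fs", "clf", "k", "decomposition")
               if f in accuracy_table and accuracy_table[f].nunique() >= 2]
    if not factors:
        raise ValueError("need at least one factor with >= 2 levels")
    formula = "accuracy ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=accuracy_table).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    tab = tab.rename(index={f"C({f})": f for f in factors})
    zero = tab["sum_sq"] < 1e-12
    tab.loc[zero & (tab.index != "Residual"), "F"] = 0.0
    tab.loc[zero & (tab.index != "Residual"), "PR(>F)"] = 1.0
    return tab.rename(columns={"PR(>F)": "p"})


# ---------------------------------------------------------------------------
# vote records and the iterative self-training labeler

@dataclass(frozen=True)
class VoteRecord:
    """Tallied ensemble votes for one sample.

    ``top_fraction`` is the top label's share of non-abstaining votes;
    abstentions are excluded from the denominator and reported separately.
    """

    sample_id: str
    votes: dict
    total: int
    n_abstain: int
    top_label: str | None
    top_fraction: float
    tier: str


@dataclass
class IterationTrace:
    """Per-iteration tier counts of the self-training loop."""

    tiers: list = field(default_factory=list)  # list of dicts tier -> count
    converged_at: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.tiers)
        df.index.name = "iteration"
        return df


def tier_of(top_fraction: float | None) -> str:
    """Confidence tier of a vote share: 100% / >95% / >75% / unlabeled."""
    if top_fraction is None:
        return TIER_UNLABELED
    if top_fraction >= 1.0:
        return TIER_UNANIMOUS
    if top_fraction > 0.95:
        return TIER_HIGH
    if top_fraction > 0.75:
        return TIER_REASONABLE
    return TIER_UNLABELED


def _tally(vote_row) -> tuple[dict, int, int, str | None, float | None]:
    counts = {}
    n_abstain = 0
    for v in vote_row:
        if v == ABSTAIN:
            n_abstain += 1
        else:
            counts[v] = counts.get(v, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return counts, 0, n_abstain, None, None
    # deterministic tie-break on label
    top = min(counts, key=lambda c: (-counts[c], c))
    return counts, total, n_abstain, top, counts[top] / total


def iterative_ensemble_label(matrix: pd.DataFrame, seed_labels: pd.Series,
                             grid: ExpertGrid, feedback_threshold: float = 0.95,
                             final_threshold: float = 0.75, max_iter: int = 25,
                             stable_window: int = 3, seed: int = 0,
                             line_of: pd.Series | None = None):
    """Iterative ensemble self-training of sample labels.

    Starting from partial ``seed_labels`` (NaN/None = unlabeled), every
    expert of ``grid`` votes on every sample each iteration; labels winning
    strictly more than ``feedback_threshold`` of non-abstaining votes are
    fed back as training labels for the next round. Seed labels may be
    overturned the same way. The loop stops at complete convergence (the
    working label assignment stops changing), when tier counts are stable
    for ``stable_window`` iterations, or at ``max_iter`` feedback rounds
    (``max_iter=0`` reports the first-round vote tiers).

    With ``line_of`` given (cell-line mode), training samples are split into
    ``grid.replicate_sets`` replicate sets, each set trains its own copy of
    every expert, and votes are pooled per line across its replicates.

    Returns (sample_table, trace): a DataFrame with seed/ensemble labels,
    vote shares and confidence tiers, and an :class:`IterationTrace`.
    """
    seed_labels = seed_labels.reindex(matrix.columns)
    working = seed_labels.dropna().astype(str).copy()
    if working.empty:
        raise ValueError("no seed labels")
    classes = sorted(working.unique())
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    trace = IterationTrace()
    last_records = None
    stable_run = 0
    prev_tier_counts = None

    for it in range(max_iter + 1):
        if working.value_counts().min() < 2 or working.nunique() < len(classes):
            raise ValueError("a class vanished from the labeled set; cannot train")
        votes = _ensemble_round(matrix, working, grid, rng, line_of)
        records = {}
        for sid, row in votes.iterrows():
            counts, total, n_abstain, top, frac = _tally(row.tolist())
            records[sid] = VoteRecord(sample_id=sid, votes=counts, total=total,
                                      n_abstain=n_abstain, top_label=top,
                                      top_fraction=frac if frac is not None else 0.0,
                                      tier=tier_of(frac))
        last_records = records
        tier_counts = {t: 0 for t in TIERS}
        for r in records.values():
            tier_counts[r.tier] += 1
        trace.tiers.append(tier_counts)

        if it == max_iter:
            break

        # feedback: high-confidence ensemble labels (re)enter the labeled set
        new_working = working.copy()
        for uid, r in records.items():
            if r.top_label is not None and r.top_fraction > feedback_threshold:
                if line_of is not None:
                    # vote unit is a line: label all of its replicates
                    for sid in line_of.index[line_of == uid]:
                        new_working.loc[sid] = r.top_label
                else:
                    new_working.loc[uid] = r.top_label
        new_working = new_working.dropna()
        if new_working.sort_index().equals(working.sort_index()):
            trace.converged_at = it + 1
            break
        working = new_working
        if prev_tier_counts == tier_counts:
            stable_run += 1
            if stable_run >= stable_window:
                break
        else:
            stable_run = 0
        prev_tier_counts = tier_counts

    units = list(last_records)
    final_label = []
    for u in units:
        r = last_records[u]
        ok = r.top_label is not None and r.top_fraction > final_threshold
        final_label.append(r.top_label if ok else None)
    table = pd.DataFrame({
        "sample_id": units,
        "seed_label": [None if line_of is not None else seed_labels.get(u)
                       for u in units],
        "label": final_label,
        "top_label": [last_records[u].top_label for u in units],
        "top_fraction": [last_records[u].top_fraction for u in units],
        "n_votes": [last_records[u].total for u in units],
        "n_abstain": [last_records[u].n_abstain for u in units],
        "tier": [last_records[u].tier for u in units],
    }).set_index("sample_id")
    return table, trace


def _ensemble_round(matrix, working, grid, rng, line_of):
    """One voting round; per-line pooling in cell-line mode."""
    if line_of is None or grid.replicate_sets <= 1:
        return _expert_votes(matrix, working, list(matrix.columns), grid, rng)
    # cell-line mode: split labeled replicates into replicate sets; each set
    # trains every expert; votes pooled per line over its replicates
    n_sets = grid.replicate_sets
    labeled_ids = list(working.index)
    set_of = {}
    for line, reps in line_of.loc[labeled_ids].groupby(line_of):
        ids = sorted(reps.index)
        assign = rng.permutation(len(ids)) % n_sets
        for sid, s in zip(ids, assign):
            set_of[sid] = s
    all_votes = []
    for s in range(n_sets):
        ids = [sid for sid in labeled_ids if set_of[sid] == s]
        sub = working.loc[ids]
        if sub.value_counts().min() < 2:
            raise ValueError(f"replicate set {s} lost a class; "
                             "need >=2 labeled lines per class per set")
        v = _expert_votes(matrix, sub, list(matrix.columns), grid, rng)
        v.columns = [(s,) + c for c in v.columns]
        all_votes.append(v)
    per_sample = pd.concat(all_votes, axis=1)
    # pool votes of a line's replicates
    pooled = {}
    for line, reps in per_sample.groupby(line_of):
        pooled[line] = reps.to_numpy().ravel().tolist()
    return pd.DataFrame.from_dict(pooled, orient="index")
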