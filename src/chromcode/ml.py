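"""Iterated feature-selection / classification / majority-vote procedure.

The question: can the chromatin response alone (block and peak features)
predict which genes the induced repressor transcriptionally silences?

Protocol, per (selector, classifier) combination:

1. stratified 10-fold cross-validation; inside each training fold the
   selector ranks all features and the top 20 are kept (selection never
   sees held-out labels);
2. the classifier is fit on the training fold and predicts the held-out
   10%, so each gene is predicted exactly once per iteration;
3. the whole procedure repeats for 50 seeded iterations; a gene's
   aggregate class is the one predicted in more than 50% of iterations
   (an exact tie falls to the majority prior class, nonrepressed).

Selectors: information gain, symmetrical uncertainty and chi-square on
equal-frequency 10-bin discretized features (bins computed on the training
fold), plus ReliefF (10 neighbors, all training instances). Classifiers:
random forest (50 trees), Gaussian naive Bayes, 5-NN and a linear SVM
(cost 1); the two distance/margin-based classifiers see features
standardized on the training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SELECTORS = ("info_gain", "symmetrical_uncertainty", "chi_square", "relief")
CLASSIFIERS = ("random_forest", "naive_bayes", "knn", "svm")
POSITIVE = "repressed"
NEGATIVE = "nonrepressed"


@dataclass
class MLConfig:
    selectors: tuple[str, ...] = SELECTORS
    classifiers: tuple[str, ...] = CLASSIFIERS
    top_k: int = 20
    n_folds: int = 10
    n_iterations: int = 50
    vote_threshold: float = 0.5  # strict >
    base_seed: int = 0
    n_bins: int = 10  # discretization for the contingency-based selectors
    relief_neighbors: int = 10

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        unknown = set(self.selectors) - set(SELECTORS)
        unknown |= set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")


@dataclass(frozen=True)
class PredictionRecord:
    gene_id: str
    votes: tuple[str, ...]
    aggregate_class: str
    vote_fraction: float  # fraction of iterations voting the positive class
    correct: bool


@dataclass
class EvaluationReport:
    overall_accuracy: float  # %
    repressed_accuracy: float  # %
    nonrepressed_accuracy: float  # %
    baseline_overall: int  # % majority-class rate, truncated for display
    baseline_repressed: float  # % positive-class prevalence
    n_genes: int = 0


# ---------------------------------------------------------------------------
# Feature scoring
# ---------------------------------------------------------------------------


def _discretize(train_col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; returns integer bin codes for the train data."""
    edges = np.unique(np.quantile(train_col, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, train_col, side="right")


def _contingency(x_codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(bins x classes) count table, empty rows/columns dropped."""
    _, xi = np.unique(x_codes, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    n_x, n_y = xi.max() + 1, yi.max() + 1
    table = np.bincount(xi * n_y + yi, minlength=n_x * n_y).reshape(n_x, n_y)
    return table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]


def _entropy_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _entropy(codes: np.ndarray) -> float:
    return _entropy_counts(np.unique(codes, return_counts=True)[1])


def info_gain(x_codes: np.ndarray, y: np.ndarray) -> float:
    """H(y) - H(y | x), in bits, on discretized x."""
    table = _contingency(x_codes, y)
    n = table.sum()
    h_y = _entropy_counts(table.sum(axis=0))
    row_n = table.sum(axis=1)
    cond = sum(
        row_n[i] / n * _entropy_counts(table[i]) for i in range(table.shape[0])
    )
    return h_y - cond


def symmetrical_uncertainty(x_codes: np.ndarray, y: np.ndarray) -> float:
    table = _contingency(x_codes, y)
    h_x = _entropy_counts(table.sum(axis=1))
    h_y = _entropy_counts(table.sum(axis=0))
    if h_x + h_y == 0:
        return 0.0
    return 2.0 * info_gain(x_codes, y) / (h_x + h_y)


def chi_square_score(x_codes: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-square statistic of the (bins x classes) contingency table."""
    table = _contingency(x_codes, y)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    return float(((table - expected) ** 2 / expected).sum())


def relieff_scores(
    X: np.ndarray, y: np.ndarray, n_neighbors: int = 10
) -> np.ndarray:
    """ReliefF weights over all instances with k nearest hits/misses.

    Features are scaled to [0, 1] so per-feature differences are comparable;
    distances are Manhattan on the scaled matrix.
    """
    X = np.asarray(X, dtype=float)
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / span
    n = len(y)
    dist = cdist(Xs, Xs, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    weights = np.zeros(X.shape[1])
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    for i in range(n):
        same = y == y[i]
        same[i] = False
        hits = np.flatnonzero(same)
        hits = hits[np.argsort(dist[i, hits])[:n_neighbors]]
        if len(hits):
            weights -= np.abs(Xs[hits] - Xs[i]).mean(axis=0) / n
        other_prior = 1.0 - priors[y[i]]
        for cls in classes:
            if cls == y[i]:
                continue
            misses = np.flatnonzero(y == cls)
            misses = misses[np.argsort(dist[i, misses])[:n_neighbors]]
            if len(misses):
                w_cls = priors[cls] / other_prior
                weights += w_cls * np.abs(Xs[misses] - Xs[i]).mean(axis=0) / n
    return weights


def rank_features(
    table: pd.DataFrame,
    method: str,
    n_bins: int = 10,
    relief_neighbors: int = 10,
) -> pd.DataFrame:
    """Score and sort all features (descending) by one selector.

    ``table`` holds numeric feature columns plus a ``label`` column. The
    ordering is deterministic: ties break on column order.
    """
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("label column is constant; nothing to rank against")
    X = table.drop(columns="label")
    if method == "relief":
        scores = relieff_scores(X.to_numpy(), y, relief_neighbors)
    else:
        scorer = {
            "info_gain": info_gain,
            "symmetrical_uncertainty": symmetrical_uncertainty,
            "chi_square": chi_square_score,
        }[method]
        scores = np.array(
            [scorer(_discretize(X[c].to_numpy(), n_bins), y) for c in X.columns]
        )
    out = pd.DataFrame({"feature": X.columns, "score": scores})
    order = np.argsort(-scores, kind="stable")
    return out.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-validated iteration
# ---------------------------------------------------------------------------


def _make_classifier(name: str, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=50, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    raise ValueError(f"unknown classifier {name!r}")


def run_iteration(
    table: pd.DataFrame,
    selector: str,
    classifier: str,
    top_k: int = 20,
    n_folds: int = 10,
    seed: int = 0,
    n_bins: int = 10,
    relief_neighbors: int = 10,
) -> pd.Series:
    """One stratified CV pass: every gene predicted exactly once.

    Feature ranking happens inside each training fold only — held-out
    labels can never influence which features the classifier sees.
    """
    y = table["label"]
    counts = y.value_counts()
    if (counts < n_folds).any():
        raise ValueError(
            f"every class needs >= {n_folds} genes for stratified {n_folds}-fold CV"
        )
    X = table.drop(columns="label")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = pd.Series(index=table.index, dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        train = table.iloc[train_idx]
        ranking = rank_features(train, selector, n_bins, relief_neighbors)
        keep = ranking["feature"].head(top_k).tolist()
        clf = _make_classifier(classifier, seed)
        clf.fit(train[keep], y.iloc[train_idx])
        pred.iloc[test_idx] = clf.predict(X.iloc[test_idx][keep])
    return pred


def run_method(
    table: pd.DataFrame,
    selector: str,
    classifier: str,
    config: MLConfig | None = None,
) -> list[PredictionRecord]:
    """All iterations for one (selector, classifier), aggregated by vote."""
    config = config or MLConfig()
    votes = pd.DataFrame(index=table.index, dtype=object)
    for it in range(config.n_iterations):
        votes[it] = run_iteration(
            table,
            selector,
            classifier,
            top_k=config.top_k,
            n_folds=config.n_folds,
            seed=config.base_seed + it,
            n_bins=config.n_bins,
            relief_neighbors=config.relief_neighbors,
        )
    return aggregate_predictions(votes, table["label"], config.vote_threshold)


def aggregate_predictions(
    votes: pd.DataFrame,
    labels: pd.Series,
    vote_threshold: float = 0.5,
) -> list[PredictionRecord]:
    """Majority-vote aggregation: positive iff its vote fraction is strictly
    above the threshold; an exact tie goes to the nonrepressed prior class."""
    if votes.isna().any().any():
        raise ValueError("missing iteration predictions")
    records = []
    for gene_id, row in votes.iterrows():
        frac = float((row == POSITIVE).mean())
        agg = POSITIVE if frac > vote_threshold else NEGATIVE
        records.append(
            PredictionRecord(
                gene_id=str(gene_id),
                votes=tuple(row),
                aggregate_class=agg,
                vote_fraction=frac,
                correct=bool(agg == labels.loc[gene_id]),
            )
        )
    return records


def evaluate(records: list[PredictionRecord], labels: pd.Series) -> EvaluationReport:
    """Percent accuracies overall and per class, plus chance baselines.

    ``baseline_overall`` is the majority-class rate truncated to an integer
    for display (241 repressed / 342 nonrepressed -> 58); the repressed
    baseline is the positive-class prevalence.
    """
    df = pd.DataFrame(
        {
            "correct": [r.correct for r in records],
            "label": [labels.loc[r.gene_id] for r in records],
        }
    )
    counts = df["label"].value_counts()
    overall = 100.0 * df["correct"].mean()
    per_class = {
        cls: 100.0 * df.loc[df["label"] == cls, "correct"].mean()
        for cls in (POSITIVE, NEGATIVE)
        if cls in counts
    }
    return EvaluationReport(
        overall_accuracy=float(overall),
        repressed_accuracy=float(per_class.get(POSITIVE, float("nan"))),
        nonrepressed_accuracy=float(per_class.get(NEGATIVE, float("nan"))),
        baseline_overall=int(100 * counts.max() / counts.sum()),
        baseline_repressed=float(100 * counts.get(POSITIVE, 0) / counts.sum()),
        n_genes=len(records),
    )


def run_grid(
    table: pd.DataFrame, config: MLConfig | None = None
) -> tuple[dict[tuple[str, str], list[PredictionRecord]], pd.DataFrame]:
    """Every (selector, classifier) combination; returns records + a report
    table with one row per combination."""
    config = config or MLConfig()
    records_by_method: dict[tuple[str, str], list[PredictionRecord]] = {}
    rows = []
    for selector in config.selectors:
        for classifier in config.classifiers:
            records = run_method(table, selector, classifier, config)
            records_by_method[(selector, classifier)] = records
            rep = evaluate(records, table["label"])
            rows.append(
                {
                    "selector": selector,
                    "classifier": classifier,
                    "overall_accuracy": rep.overall_accuracy,
                    "repressed_accuracy": rep.repressed_accuracy,
                    "nonrepressed_accuracy": rep.nonrepressed_accuracy,
                    "baseline_overall": rep.baseline_overall,
                    "baseline_repressed": rep.baseline_repressed,
                }
            )
    return records_by_method, pd.DataFrame(rows)


def prediction_report(
    records_by_method: dict[tuple[str, str], list[PredictionRecord]],
    labels: pd.Series,
    gene_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Genes x methods matrix of aggregate calls, with the true label first.

    Useful for spotting genes consistently miscalled by every method — the
    hallmark of repression-like chromatin on a transcriptionally unmoved
    gene (errant targeting).
    """
    genes = list(gene_subset) if gene_subset is not None else list(labels.index)
    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    out["label"] = [labels.loc[g] for g in genes]
    for (selector, classifier), records in records_by_method.items():
        calls = {r.gene_id: r.aggregate_class for r in records}
        out[f"{selector}+{classifier}"] = [calls.get(g) for g in genes]
    return out
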