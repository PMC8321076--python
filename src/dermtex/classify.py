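"""The classifier zoo, image-level train/test splitting, and AUC ranking.

Twelve standard learners are trained on the patch feature table and ranked
by test-set AUC (melanoma as the positive class).  Splitting is performed
at the image level — all patches of an image land on one side — so sibling
patches can never leak between train and test.  Margin- and distance-based
learners receive z-scored features (scaler fitted on the training side
only); the multinomial naive Bayes, which requires nonnegative inputs,
receives min-max scaled features instead; tree ensembles and the remaining
naive Bayes variants see the raw features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import (ExtraTreesClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.naive_bayes import BernoulliNB, GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .evaluate import MetricReport, confusion, metrics, roc_auc
from .features import FeatureDataset, POSITIVE_LABEL
from .imaging import derive_seed

logger = logging.getLogger(__name__)

# scaler mode: "standard" (z-score), "minmax" (nonnegative learners), None (raw)
_ZOO: dict[str, tuple] = {
    "sgd": ("standard", lambda seed: SGDClassifier(random_state=seed)),
    "gaussian_nb": (None, lambda seed: GaussianNB()),
    "bernoulli_nb": ("standard", lambda seed: BernoulliNB()),
    "multinomial_nb": ("minmax", lambda seed: MultinomialNB()),
    "decision_tree": (None, lambda seed: DecisionTreeClassifier(random_state=seed)),
    "extra_trees": (None, lambda seed: ExtraTreesClassifier(random_state=seed)),
    "random_forest": (None, lambda seed: RandomForestClassifier(random_state=seed)),
    "gradient_boosting": (None, lambda seed: GradientBoostingClassifier(random_state=seed)),
    "knn": ("standard", lambda seed: KNeighborsClassifier()),
    "linear_svc": ("standard", lambda seed: LinearSVC(random_state=seed)),
    "svc": ("standard", lambda seed: SVC(random_state=seed)),
    "logistic_regression": ("standard", lambda seed: LogisticRegression(
        random_state=seed, max_iter=1000)),
}

ALL_MODELS: tuple[str, ...] = tuple(_ZOO)


@dataclass(frozen=True)
class SplitSpec:
    """Image-level stratified split specification."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass
class FittedModel:
    name: str
    pipeline: Pipeline
    feature_names: tuple[str, ...]

    def scores(self, ds: FeatureDataset) -> np.ndarray:
        """Continuous melanoma score: class probability where available,
        decision-function margin otherwise."""
        if tuple(ds.feature_names) != tuple(self.feature_names):
            raise ValueError("feature-name mismatch between model and dataset")
        X = ds.X
        clf = self.pipeline
        if hasattr(clf, "predict_proba"):
            classes = list(clf.classes_)
            return clf.predict_proba(X)[:, classes.index(POSITIVE_LABEL)]
        if hasattr(clf, "decision_function"):
            margin = clf.decision_function(X)
            # decision_function is oriented toward classes_[1]
            return margin if clf.classes_[1] == POSITIVE_LABEL else -margin
        raise AttributeError(f"model '{self.name}' exposes no continuous score")

    def predict(self, ds: FeatureDataset) -> np.ndarray:
        if tuple(ds.feature_names) != tuple(self.feature_names):
            raise ValueError("feature-name mismatch between model and dataset")
        return self.pipeline.predict(ds.X)


@dataclass
class ModelRanking:
    """Models sorted by test AUC, best first."""

    entries: list[tuple[str, float, MetricReport]]

    def top(self, k: int) -> list[tuple[str, float, MetricReport]]:
        return self.entries[:k]


def split_dataset(ds: FeatureDataset, spec: SplitSpec
                  ) -> tuple[FeatureDataset, FeatureDataset]:
    """Partition by image id, stratified by class.

    Every image's patches land entirely on one side; per class the number
    of training images is the rounded fraction (at least one image on each
    side, which requires >= 2 images per class).
    """
    df = ds.df
    rng = np.random.default_rng(spec.seed)
    img_labels = df.drop_duplicates("image_id")[["image_id", "label"]]
    groups = {label: sorted(g["image_id"])
              for label, g in img_labels.groupby("label", sort=True)}
    for label, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"class '{label}' has fewer than 2 images")
    # Largest-remainder allocation: the global train count is the rounded
    # fraction of all images, each class within one image of its quota.
    n_total = sum(len(ids) for ids in groups.values())
    n_train_total = int(round(spec.train_fraction * n_total))
    quotas = {lab: spec.train_fraction * len(ids)
              for lab, ids in groups.items()}
    counts = {lab: min(max(int(np.floor(q)), 1), len(groups[lab]) - 1)
              for lab, q in quotas.items()}
    remainders = sorted(groups, key=lambda lab: quotas[lab] - np.floor(quotas[lab]),
                        reverse=True)
    for lab in remainders:
        if sum(counts.values()) >= n_train_total:
            break
        if counts[lab] < len(groups[lab]) - 1:
            counts[lab] += 1
    train_ids: list[str] = []
    for label in sorted(groups):
        ids = groups[label]
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[i] for i in perm[:counts[label]])
    mask = df["image_id"].isin(train_ids).to_numpy()
    return ds.subset(mask), ds.subset(~mask)


def train_zoo(train: FeatureDataset, model_names=None, seed: int = 0
              ) -> list[FittedModel]:
    """Fit one model per requested name on the training table.

    Stochastic learners receive per-model sub-seeds derived from ``seed``.
    """
    names = list(model_names) if model_names is not None else list(ALL_MODELS)
    unknown = [n for n in names if n not in _ZOO]
    if unknown:
        raise ValueError(f"unknown model name(s) {unknown}; "
                         f"valid names: {sorted(_ZOO)}")
    if len(train) == 0:
        raise ValueError("training set is empty")
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = train.X
    fitted = []
    for name in names:
        scaler_mode, factory = _ZOO[name]
        steps = []
        if scaler_mode == "standard":
            steps.append(("scale", StandardScaler()))
        elif scaler_mode == "minmax":
            steps.append(("scale", MinMaxScaler()))
        steps.append(("clf", factory(derive_seed(seed, "model", name))))
        pipe = Pipeline(steps)
        pipe.fit(X, y)
        fitted.append(FittedModel(name=name, pipeline=pipe,
                                  feature_names=tuple(train.feature_names)))
    return fitted


def rank_by_auc(models: list[FittedModel], test: FeatureDataset,
                k: int | None = None) -> ModelRanking:
    """Rank fitted models by test AUC; each entry carries a full report.

    A model without any continuous score is excluded with a warning.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    if len(np.unique(test.y)) < 2:
        raise ValueError("test set must contain both classes")
    entries = []
    for m in models:
        try:
            scores = m.scores(test)
        except AttributeError:
            logger.warning("model '%s' has no continuous score; excluded "
                           "from the AUC ranking", m.name)
            continue
        curve = roc_auc(test.y, scores)
        report = metrics(confusion(test.y, m.predict(test)))
        entries.append((m.name, curve.auc, report))
    entries.sort(key=lambda e: -e[1])
    ranking = ModelRanking(entries=entries)
    if k is not None:
        ranking = ModelRanking(entries=ranking.top(k))
    return ranking


def label_permutation_audit(ds: FeatureDataset, spec: SplitSpec,
                            n_permutations: int = 4, seed: int = 0,
                            model_names=None) -> dict[str, float]:
    """Permutation-null AUC per model.

    Image labels are permuted across the whole dataset (breaking every
    feature-label association while preserving class counts and the
    patches-share-their-image's-label structure), the image-level split,
    training and AUC ranking are rerun, and each model's null AUC is
    averaged over the permutation replicates.  With no true signal left,
    a leak-free pipeline scores about 0.5 for every model.
    """
    results: dict[str, list[float]] = {}
    img_lab = ds.df.drop_duplicates("image_id")[["image_id", "label"]]
    for j in range(n_permutations):
        rng = np.random.default_rng(derive_seed(seed, "perm-labels", j))
        permuted = dict(zip(img_lab["image_id"],
                            rng.permutation(img_lab["label"].to_numpy())))
        pdf = ds.df.copy()
        pdf["label"] = pdf["image_id"].map(permuted)
        pds = FeatureDataset(pdf, ds.feature_names)
        split = SplitSpec(train_fraction=spec.train_fraction,
                          seed=derive_seed(spec.seed, "perm-split", j))
        train, test = split_dataset(pds, split)
        models = train_zoo(train, model_names=model_names, seed=seed)
        for name, auc, _ in rank_by_auc(models, test).entries:
            results.setdefault(name, []).append(auc)
    return {name: float(np.mean(aucs)) for name, aucs in results.items()}


def ranking_to_frame(ranking: ModelRanking):
    """Flatten a ranking into a tidy table (one row per model and class),
    mirroring the per-class precision/recall/F1/support report layout."""
    import pandas as pd

    rows = []
    for name, auc, rep in ranking.entries:
        for cls in ("melanoma", "nevus"):
            rows.append({
                "model": name, "auc": auc, "class": cls,
                "precision": rep.precision[cls], "recall": rep.recall[cls],
                "f1": rep.f_score[cls], "support": rep.support[cls],
                "accuracy": rep.accuracy,
            })
    return pd.DataFrame(rows)
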