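"""Consensus selection of subfamily-characteristic motifs across classifiers.

The protocol: balance classes by downsampling (300 per subfamily, smaller
classes kept whole), zero-impute and center/scale best-hit motif scores per
predictor, split 3:1 (stratified), run 3x3 repeated cross-validation for six
model families (decision tree, random forest, elastic-net logistic regression,
k-nearest neighbours, PLS-DA, multilayer perceptron), keep only models whose
best resample reaches 60% global accuracy, extract per-class predictor
importances, max-normalize them to 100 within each model, and select, per
subfamily, the motifs that clear an importance cutoff in *all* surviving
models.

Importance is measured the same way for every family — the drop in per-class
recall when a predictor's column is permuted on the training split — so that
importances are comparable across model families (native importances are not).

Exposed statsmodels-style: build a :class:`MotifSelectionModel` from the
feature table and labels, call :meth:`~MotifSelectionModel.fit`, and read the
accuracy table, importance report and consensus selection off the returned
:class:`MotifSelectionResults` (with a printable ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .io import LabelTable

__all__ = [
    "SplitSpec",
    "CVSpec",
    "GateSpec",
    "FeatureTable",
    "downsample_balanced",
    "preprocess",
    "MODEL_FAMILIES",
    "MotifSelectionModel",
    "MotifSelectionResults",
]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split; 0.75 is the 3:1 proportion."""

    train_fraction: float = 0.75


@dataclass(frozen=True)
class CVSpec:
    folds: int = 3
    repeats: int = 3


@dataclass(frozen=True)
class GateSpec:
    """Models must reach this global accuracy on their best CV resample."""

    accuracy: float = 0.60


def downsample_balanced(
    labels: LabelTable | Mapping[str, str], n: int = 300, seed: int | None = None
) -> list[str]:
    """Per class: exactly ``n`` uniformly sampled ids, or all if fewer.

    Classes are processed in sorted order and ids sorted before sampling, so the
    result depends only on the mapping content and the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mapping = labels.mapping if isinstance(labels, LabelTable) else dict(labels)
    by_class: dict[str, list[str]] = {}
    for seq_id, code in mapping.items():
        by_class.setdefault(code, []).append(seq_id)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for code in sorted(by_class):
        ids = sorted(by_class[code])
        if not ids:
            raise ValueError(f"subfamily {code!r} is empty")
        if len(ids) <= n:
            chosen.extend(ids)
        else:
            pick = rng.choice(len(ids), size=n, replace=False)
            chosen.extend(ids[i] for i in sorted(pick))
    return chosen


@dataclass
class FeatureTable:
    """Sequences x motifs score table plus its preprocessing state.

    Centering/scaling statistics are estimated on the training rows only (when
    given) and applied to everything; the sample standard deviation (n-1
    denominator) is used. Constant columns are set to zero and flagged.
    """

    values: pd.DataFrame
    zero_imputed: bool = False
    centered: bool = False
    scaled: bool = False
    constant_columns: tuple[str, ...] = ()
    center_: pd.Series | None = field(default=None, repr=False)
    scale_: pd.Series | None = field(default=None, repr=False)


def preprocess(
    table: FeatureTable | pd.DataFrame, train_ids: Iterable[str] | None = None
) -> FeatureTable:
    """Zero-impute then center and scale per predictor. Idempotent."""
    if isinstance(table, FeatureTable):
        if table.centered and table.scaled:
            return table
        df = table.values
    else:
        df = table
    df = df.fillna(0.0).astype(float)
    ref = df.loc[list(train_ids)] if train_ids is not None else df
    center = ref.mean(axis=0)
    scale = ref.std(axis=0, ddof=1)
    constant = tuple(scale.index[(scale == 0) | scale.isna()])
    safe = scale.replace(0.0, 1.0).fillna(1.0)
    out = (df - center) / safe
    out[list(constant)] = 0.0
    return FeatureTable(
        out,
        zero_imputed=True,
        centered=True,
        scaled=True,
        constant_columns=constant,
        center_=center,
        scale_=safe,
    )


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS-DA: partial-least-squares regression on one-hot classes, argmax decode.

    ``n_components=None`` picks the largest admissible count (bounded by the
    number of predictors, classes and samples), which suits wide multi-class
    problems where too few latent components underfit badly.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, codes = np.unique(y, return_inverse=True)
        Y = np.eye(len(self.classes_))[codes]
        nc = self.n_components or max(X.shape[1], len(self.classes_))
        nc = min(nc, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=nc, scale=False)
        self.pls_.fit(X, Y)
        return self

    def predict(self, X):
        scores = self.pls_.predict(np.asarray(X, dtype=float))
        return self.classes_[scores.argmax(axis=1)]


MODEL_FAMILIES: dict[str, type] = {
    "tree": DecisionTreeClassifier,
    "forest": RandomForestClassifier,
    "elasticnet": LogisticRegression,
    "knn": KNeighborsClassifier,
    "pls": PLSDAClassifier,
    "mlp": MLPClassifier,
}


def _build_model(family: str, seed: int):
    if family == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if family == "elasticnet":
        return LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=0.5, C=1.0,
            max_iter=2000, tol=1e-3, random_state=seed,
        )
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "pls":
        return PLSDAClassifier()
    if family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=500, random_state=seed,
            n_iter_no_change=10,
        )
    raise ValueError(f"unknown model family {family!r}")


def _per_class_recall(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    recalls = np.zeros(len(classes))
    for i, c in enumerate(classes):
        mask = y_true == c
        recalls[i] = (y_pred[mask] == c).mean() if mask.any() else 0.0
    return recalls


class MotifSelectionModel:
    """The selection protocol, configured but not yet run.

    Parameters
    ----------
    features : DataFrame
        Raw best-hit scores, sequences x motifs (zeros/NaN where a motif was
        not found).
    labels : LabelTable or mapping
        Sequence id -> subfamily code.
    families : sequence of str
        Model families to train; at least 4 of the registry
        ``tree, forest, elasticnet, knn, pls, mlp``.
    n_per_class, split, cv, gate, importance_cutoff, n_permutations
        Protocol knobs; defaults follow the published protocol (300 per class,
        3:1 split, 3x3 repeated CV, 60% best-resample gate) with the
        consensus cutoff at 50/100 scaled importance.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: LabelTable | Mapping[str, str],
        families: tuple[str, ...] = ("tree", "forest", "elasticnet", "knn", "pls", "mlp"),
        n_per_class: int = 300,
        split: SplitSpec = SplitSpec(),
        cv: CVSpec = CVSpec(),
        gate: GateSpec = GateSpec(),
        importance_cutoff: float = 50.0,
        n_permutations: int = 3,
    ):
        unknown = set(families) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        if len(families) < 2:
            raise ValueError("need at least 2 model families for a consensus")
        self.features = features
        self.labels = labels if isinstance(labels, LabelTable) else LabelTable(labels)
        self.families = tuple(families)
        self.n_per_class = n_per_class
        self.split = split
        self.cv = cv
        self.gate = gate
        self.importance_cutoff = importance_cutoff
        self.n_permutations = n_permutations

    def fit(self, seed: int = 0) -> "MotifSelectionResults":
        """Run downsampling, CV, gating, importance extraction and consensus."""
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

        labeled = [i for i in self.features.index if i in self.labels]
        ids = downsample_balanced(
            LabelTable({i: self.labels[i] for i in labeled}),
            n=self.n_per_class,
            seed=seeds[0],
        )
        # canonical row/column order: selection must not depend on input order
        X_raw = self.features.loc[ids].sort_index()
        X_raw = X_raw[sorted(X_raw.columns)]
        y = np.array([str(self.labels[i]) for i in X_raw.index])
        classes = [str(c) for c in np.unique(y)]
        if len(classes) < 2:
            raise ValueError("need at least 2 subfamilies")

        train_idx, test_idx = train_test_split(
            np.arange(len(y)),
            train_size=self.split.train_fraction,
            stratify=y,
            random_state=seeds[1],
        )
        train_ids = X_raw.index[np.sort(train_idx)]
        test_ids = X_raw.index[np.sort(test_idx)]
        table = preprocess(X_raw, train_ids=train_ids)
        X = table.values
        X_train, y_train = X.loc[train_ids].to_numpy(), np.array(
            [self.labels[i] for i in train_ids]
        )
        X_test, y_test = X.loc[test_ids].to_numpy(), np.array(
            [self.labels[i] for i in test_ids]
        )

        cv = RepeatedStratifiedKFold(
            n_splits=self.cv.folds, n_repeats=self.cv.repeats, random_state=seeds[2]
        )
        accuracy_rows = []
        best_acc: dict[str, float] = {}
        for family in self.families:
            model = _build_model(family, seeds[3])
            fold_acc = []
            for tr, va in cv.split(X_train, y_train):
                m = clone(model)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(X_train[tr], y_train[tr])
                fold_acc.append(float((m.predict(X_train[va]) == y_train[va]).mean()))
            best_acc[family] = max(fold_acc)

        survivors = [f for f in self.families if best_acc[f] >= self.gate.accuracy]
        if len(survivors) < 2:
            raise ValueError(
                f"fewer than 2 models reached the {self.gate.accuracy:.0%} "
                f"best-resample accuracy gate; consensus selection is undefined"
            )

        fitted: dict[str, object] = {}
        test_acc: dict[str, float] = {}
        for family in self.families:
            gated = family in survivors
            if gated:
                m = _build_model(family, seeds[3])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(X_train, y_train)
                fitted[family] = m
                test_acc[family] = float((m.predict(X_test) == y_test).mean())
            accuracy_rows.append(
                (family, best_acc[family], gated, test_acc.get(family, np.nan))
            )
        accuracy = pd.DataFrame(
            accuracy_rows,
            columns=["family", "best_resample_accuracy", "survived_gate", "test_accuracy"],
        ).set_index("family")

        motif_ids = list(X.columns)
        imp_rng = np.random.default_rng(seeds[4])
        importance_rows = []
        scaled_by_model: dict[str, pd.DataFrame] = {}
        for family in survivors:
            m = fitted[family]
            baseline = _per_class_recall(y_train, np.asarray(m.predict(X_train)), classes)
            raw = np.zeros((len(classes), len(motif_ids)))
            for j, motif in enumerate(motif_ids):
                drops = np.zeros(len(classes))
                for _ in range(self.n_permutations):
                    Xp = X_train.copy()
                    Xp[:, j] = Xp[imp_rng.permutation(len(Xp)), j]
                    rec = _per_class_recall(y_train, np.asarray(m.predict(Xp)), classes)
                    drops += baseline - rec
                raw[:, j] = drops / self.n_permutations
            raw = np.abs(raw)
            top = raw.max()
            scaled = raw / top * 100.0 if top > 0 else raw
            scaled_by_model[family] = pd.DataFrame(scaled, index=classes, columns=motif_ids)
            for ci, c in enumerate(classes):
                for j, motif in enumerate(motif_ids):
                    importance_rows.append((family, c, motif, raw[ci, j], scaled[ci, j]))
        importance = pd.DataFrame(
            importance_rows, columns=["model", "class", "motif_id", "raw", "scaled"]
        )

        selection: dict[str, pd.DataFrame] = {}
        for c in classes:
            passing = [
                motif
                for motif in motif_ids
                if all(
                    scaled_by_model[f].at[c, motif] >= self.importance_cutoff
                    for f in survivors
                )
            ]
            if not passing:
                warnings.warn(
                    f"no motif cleared the consensus cutoff for subfamily {c!r}",
                    stacklevel=2,
                )
            mean_imp = {
                motif: float(
                    np.mean([scaled_by_model[f].at[c, motif] for f in survivors])
                )
                for motif in passing
            }
            ordered = sorted(passing, key=lambda motif: (-mean_imp[motif], motif))
            selection[c] = pd.DataFrame(
                {
                    "motif_id": ordered,
                    "mean_scaled_importance": [mean_imp[motif] for motif in ordered],
                    "n_models": len(survivors),
                }
            )

        return MotifSelectionResults(
            model=self,
            seed=seed,
            accuracy=accuracy,
            survivors=tuple(survivors),
            importance=importance,
            selection=selection,
            feature_table=table,
            train_ids=tuple(train_ids),
            test_ids=tuple(test_ids),
        )


@dataclass
class MotifSelectionResults:
    """Fit artifacts: accuracy table, importances, and the consensus selection."""

    model: MotifSelectionModel
    seed: int
    accuracy: pd.DataFrame
    survivors: tuple[str, ...]
    importance: pd.DataFrame
    selection: dict[str, pd.DataFrame]
    feature_table: FeatureTable
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def top_motif(self, subfamily: str) -> str | None:
        sel = self.selection.get(subfamily)
        if sel is None or sel.empty:
            return None
        return str(sel["motif_id"].iloc[0])

    def selection_frame(self) -> pd.DataFrame:
        """Long-format consensus selection: class, motif, mean importance, models."""
        frames = []
        for c, sel in sorted(self.selection.items()):
            f = sel.copy()
            f.insert(0, "class", c)
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["class", "motif_id", "mean_scaled_importance", "n_models"]
        )

    def summary(self) -> str:
        lines = [
            "Subfamily-characteristic motif selection",
            f"  seed: {self.seed}",
            f"  sequences: {len(self.train_ids)} train / {len(self.test_ids)} test"
            f" (stratified {self.model.split.train_fraction:.0%})",
            f"  CV: {self.model.cv.repeats}x{self.model.cv.folds};"
            f" gate: best resample >= {self.model.gate.accuracy:.0%}",
            "",
            self.accuracy.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            f"Consensus (cutoff {self.model.importance_cutoff:g}/100 in all"
            f" {len(self.survivors)} surviving models):",
        ]
        sel = self.selection_frame()
        lines.append(sel.to_string(index=False) if not sel.empty else "  (empty)")
        return "\n".join(lines)
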