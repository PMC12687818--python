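"""Model interpretation: Gini importance, pairwise joint-permutation
interaction screening, and per-bird Shapley attributions.

The interaction screen measures, for every unordered feature pair, the drop
in test-set macro-F1 after permuting each of the two columns with an
independent random permutation — breaking the pair's joint distribution
(and hence any interaction the model exploits) while preserving both
marginal distributions exactly.  Pairs whose drop is >= 0.1 are retained as
candidate interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .metrics import confusion, class_metrics
from .treeshap import forest_shap

__all__ = [
    "ImportanceReport",
    "gini_importance",
    "InteractionScreen",
    "interaction_screen",
    "ShapMatrix",
    "shap_dependence",
]


@dataclass
class ImportanceReport:
    features: list
    importances: np.ndarray
    null_line: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "gini_importance": self.importances,
             "null_line": self.null_line}
        ).sort_values("gini_importance", ascending=False, ignore_index=True)


def gini_importance(forest, feature_names) -> ImportanceReport:
    """Mean-decrease-in-impurity importances, normalized to sum to one,
    with the equal-contribution null line 1/k."""
    if not hasattr(forest, "feature_importances_"):
        raise TypeError("gini importance requires a tree-based model")
    imp = np.asarray(forest.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise ValueError("feature name count does not match the model")
    return ImportanceReport(list(feature_names), imp, 1.0 / len(feature_names))


@dataclass
class InteractionScreen:
    pairs: list
    delta_f1: np.ndarray
    baseline: float
    retained: list
    cutoff: float
    n_repeats: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_a": [p[0] for p in self.pairs],
                "feature_b": [p[1] for p in self.pairs],
                "delta_f1": self.delta_f1,
                "retained": [p in self.retained for p in self.pairs],
            }
        ).sort_values("delta_f1", ascending=False, ignore_index=True)


def interaction_screen(
    bundle,
    X_test,
    y_test,
    feature_names=None,
    n_repeats: int = 1,
    seed: int = 0,
    cutoff: float = 0.1,
    shared_permutation: bool = False,
) -> InteractionScreen:
    """Joint-permutation interaction importance over all feature pairs.

    ``bundle`` is any object with predict(X) honouring its own decision
    threshold.  Each feature of a pair gets an independent permutation
    (``shared_permutation=True`` applies one common row permutation to both
    columns instead, which preserves the pair's own interaction and is kept
    only for comparison).  Delta-F1 is averaged over ``n_repeats`` draws.
    """
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test, dtype=int)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least two features")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(k)]
    baseline = class_metrics(confusion(y, bundle.predict(X))).macro_f1
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(k), 2))
    deltas = np.zeros(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        drop = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            perm_i = rng.permutation(n)
            perm_j = perm_i if shared_permutation else rng.permutation(n)
            Xp[:, i] = X[perm_i, i]
            Xp[:, j] = X[perm_j, j]
            f1 = class_metrics(confusion(y, bundle.predict(Xp))).macro_f1
            drop += baseline - f1
        deltas[idx] = drop / n_repeats
    named = [(feature_names[i], feature_names[j]) for i, j in pairs]
    retained = [p for p, d in zip(named, deltas) if d >= cutoff]
    return InteractionScreen(
        pairs=named, delta_f1=deltas, baseline=baseline, retained=retained,
        cutoff=cutoff, n_repeats=n_repeats, seed=seed,
    )


@dataclass
class ShapMatrix:
    values: np.ndarray  # (n_birds, n_features)
    base_value: float
    feature_names: list
    feature_values: np.ndarray = field(default=None)

    def dependence_table(self, feature: str) -> pd.DataFrame:
        j = self.feature_names.index(feature)
        return pd.DataFrame(
            {feature: self.feature_values[:, j], "shap": self.values[:, j]}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def shap_dependence(bundle, X, background=None, max_background: int = 25, seed: int = 0) -> ShapMatrix:
    """Exact per-bird Shapley attributions on the model's survival
    probability, plus (value, shap) dependence tables per feature.

    The background defaults to a seeded subsample of ``X`` itself.  The
    additivity identity base + row sum = predict_proba holds to float
    precision for every bird.
    """
    X = np.asarray(X, dtype=float)
    forest = bundle.forest if hasattr(bundle, "forest") else bundle
    names = list(getattr(bundle, "feature_names", [])) or [f"f{i}" for i in range(X.shape[1])]
    if background is None:
        rng = np.random.default_rng(seed)
        take = rng.choice(len(X), size=min(max_background, len(X)), replace=False)
        background = X[take]
    phi, base = forest_shap(forest, X, np.asarray(background, dtype=float))
    return ShapMatrix(values=phi, base_value=base, feature_names=names, feature_values=X)
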