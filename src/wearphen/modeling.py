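"""Class-balanced random-forest evaluation of wearable feature sets.

The central question is comparative: how much predictive value does each
wearable-derived feature set add for a binary risk target, over and beyond an
age+gender baseline?  Six model types are compared:

========================  =============================================  ==========
name                      features                                       n features
========================  =============================================  ==========
Baseline                  age + gender                                   2
RestingHR                 baseline + wearable-derived resting HR         3
SummaryStats              baseline + 10 wearable summary statistics      12
HighRes.ActiveSeg         baseline + 22 active-segment features          24
HighRes.SedenSeg          baseline + 22 sedentary-segment features       24
HighRes.SleepSeg          baseline + 22 sleep-segment features           24
Unified                   all of the above                               79
========================  =============================================  ==========

Because the targets are imbalanced, each tree's bootstrap is balanced:
floor(0.8 * n_minority) minority samples and the same number of majority
samples.  Out-of-bag (OOB) probabilities — the averaged positive-class
probability over trees whose bootstrap excluded the participant — feed the
Brier score

    BrierScore(M) = sum_i (p_i - o_i)^2 / N,

recorded over many independently seeded forests per model.  Model pairs are
compared by two-tailed Welch t tests on the replicate Brier scores, with
Benjamini-Hochberg false-discovery-rate adjustment within each target.
Variable importance is the permutation mean decrease in accuracy (MDA) over
OOB predictions, averaged across replicates.

The public surface follows the fitted-model convention: build a
:class:`RiskModel` from a feature table and labels, call :meth:`RiskModel.fit`,
and read estimates and diagnostics off the returned :class:`RiskModelResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .catch22 import FEATURE_NAMES
from .summary import SUMMARY_FEATURE_NAMES

__all__ = [
    "ModelSpec",
    "MODEL_TYPES",
    "model_spec",
    "assemble_model_features",
    "brier_score",
    "BalancedRandomForest",
    "RiskModel",
    "RiskModelResults",
    "evaluate_model",
    "compare_models",
    "rank_importance",
]

BASELINE_FEATURES = ("age", "gender")

_STATE_BLOCKS = {
    "HighRes.ActiveSeg": "active",
    "HighRes.SedenSeg": "sedentary",
    "HighRes.SleepSeg": "sleep",
}


@dataclass(frozen=True)
class ModelSpec:
    """A named feature set; non-baseline types always contain the baseline."""

    name: str
    features: tuple[str, ...]
    include_age: bool = True

    def columns(self) -> tuple[str, ...]:
        if self.include_age:
            return self.features
        return tuple(f for f in self.features if f != "age")


def _state_features(state: str) -> tuple[str, ...]:
    return tuple(f"{name}.{state}" for name in FEATURE_NAMES)


def model_spec(name: str, include_age: bool = True) -> ModelSpec:
    """The canonical feature list for one of the seven model types."""
    if name == "Baseline":
        feats = BASELINE_FEATURES
    elif name == "RestingHR":
        feats = BASELINE_FEATURES + ("resting_hr",)
    elif name == "SummaryStats":
        feats = BASELINE_FEATURES + SUMMARY_FEATURE_NAMES
    elif name in _STATE_BLOCKS:
        feats = BASELINE_FEATURES + _state_features(_STATE_BLOCKS[name])
    elif name == "Unified":
        feats = (
            BASELINE_FEATURES
            + ("resting_hr",)
            + SUMMARY_FEATURE_NAMES
            + _state_features("active")
            + _state_features("sedentary")
            + _state_features("sleep")
        )
    else:
        raise ValueError(f"unknown model type: {name!r}")
    return ModelSpec(name=name, features=feats, include_age=include_age)


MODEL_TYPES = (
    "Baseline",
    "RestingHR",
    "SummaryStats",
    "HighRes.ActiveSeg",
    "HighRes.SedenSeg",
    "HighRes.SleepSeg",
    "Unified",
)


def assemble_model_features(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Select exactly the spec's columns; raises naming any missing column."""
    cols = spec.columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks column(s) {missing} for {spec.name}")
    return table.loc[:, list(cols)]


def brier_score(p: Sequence[float], o: Sequence[float]) -> float:
    """Mean squared difference between predicted probabilities and outcomes."""
    p = np.asarray(p, dtype=float)
    o = np.asarray(o, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - o) ** 2))


class BalancedRandomForest:
    """Bagged CART trees with stratified balanced bootstrap sampling per tree.

    Each tree's bootstrap draws ``floor(0.8 * n_minority)`` minority samples
    and the same number of majority samples (with replacement by default), so
    every tree sees a balanced training set and every participant is out of
    bag for a fraction of trees.  The OOB probability for a participant
    averages the class-1 probabilities of the trees whose bootstrap excluded
    them; with ``probability_mode="vote"`` it is the positive vote fraction
    instead.  Deterministic given ``seed``.
    """

    def __init__(
        self,
        n_trees: int = 500,
        minority_fraction: float = 0.8,
        max_features: str | int = "sqrt",
        min_samples_leaf: int = 25,
        replace: bool = True,
        probability_mode: str = "proba",
        seed: int = 0,
    ) -> None:
        if probability_mode not in ("proba", "vote"):
            raise ValueError("probability_mode must be 'proba' or 'vote'")
        self.n_trees = n_trees
        self.minority_fraction = minority_fraction
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.replace = replace
        self.probability_mode = probability_mode
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.feature_names_: Optional[tuple[str, ...]] = None

    def fit(self, X, y) -> "BalancedRandomForest":
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = tuple(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("labels must contain exactly two classes")
        n = y.size
        if n < 20:
            raise ValueError("need at least 20 samples")
        n_pos = int((y == 1).sum())
        minority = 1 if n_pos <= n - n_pos else 0
        idx_min = np.nonzero(y == minority)[0]
        idx_maj = np.nonzero(y != minority)[0]
        m = int(math.floor(self.minority_fraction * idx_min.size))
        if m < 1:
            raise ValueError("minority class too small for balanced sampling")
        self.per_tree_sample_size_ = 2 * m

        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        in_bag = np.zeros((self.n_trees, n), dtype=bool)
        acc = np.zeros(n)
        counts = np.zeros(n)
        for t in range(self.n_trees):
            take_min = rng.choice(idx_min, size=m, replace=self.replace)
            take_maj = rng.choice(idx_maj, size=m, replace=self.replace)
            train = np.concatenate([take_min, take_maj])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[train], y[train])
            self.trees_.append(tree)
            in_bag[t, train] = True
            oob = ~in_bag[t]
            acc[oob] += self._tree_positive(tree, X[oob])
            counts[oob] += 1
        self._in_bag = in_bag
        self._X = X
        self._y = y
        with np.errstate(invalid="ignore"):
            self.oob_probability_ = np.where(
                counts > 0, acc / np.maximum(counts, 1), np.nan
            )
        self._oob_counts = counts
        return self

    def _tree_positive(self, tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
        if self.probability_mode == "vote":
            return (tree.predict(X) == 1).astype(float)
        pos = int(np.nonzero(tree.classes_ == 1)[0][0])
        return tree.predict_proba(X)[:, pos]

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability averaged over all trees, shape (n, )."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        out = np.zeros(len(X))
        for tree in self.trees_:
            out += self._tree_positive(tree, X)
        return out / len(self.trees_)

    def oob_brier(self) -> float:
        ok = self._oob_counts > 0
        return brier_score(self.oob_probability_[ok], self._y[ok])

    def mda_importance(self, rng: np.random.Generator) -> np.ndarray:
        """Permutation mean decrease in OOB accuracy, averaged over trees."""
        n_feat = self._X.shape[1]
        mda = np.zeros(n_feat)
        for t, tree in enumerate(self.trees_):
            oob = np.nonzero(~self._in_bag[t])[0]
            if oob.size == 0:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            acc = float(np.mean(tree.predict(Xo) == yo))
            for f in range(n_feat):
                Xp = Xo.copy()
                Xp[:, f] = rng.permutation(Xp[:, f])
                acc_perm = float(np.mean(tree.predict(Xp) == yo))
                mda[f] += acc - acc_perm
        return mda / len(self.trees_)


@dataclass
class ModelEvaluation:
    """Per-replicate OOB Brier scores and averaged importance for one model."""

    target: str
    model: str
    brier_scores: np.ndarray
    importance: Optional[pd.Series] = None
    feature_names: tuple[str, ...] = ()

    @property
    def mean_brier(self) -> float:
        return float(np.mean(self.brier_scores))


class RiskModel:
    """A (feature set, binary target) pairing ready to fit.

    Parameters
    ----------
    features
        Participant-level feature table (rows aligned with ``labels``).
    labels
        Binary outcome per participant.
    spec
        A :class:`ModelSpec` or one of the seven canonical type names.
    include_age
        Set False for genomic targets, where age must not enter the model.
    n_trees
        Trees per forest (default 500).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[int],
        spec: ModelSpec | str = "Unified",
        include_age: bool = True,
        n_trees: int = 500,
        target: str = "target",
    ) -> None:
        if isinstance(spec, str):
            spec = model_spec(spec, include_age=include_age)
        self.spec = spec
        self.X = assemble_model_features(features, spec)
        self.y = np.asarray(labels, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("features and labels are not aligned")
        self.n_trees = n_trees
        self.target = target

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        target: str,
        spec: ModelSpec | str = "Unified",
        **kwargs,
    ) -> "RiskModel":
        """Build from a single table whose ``target`` column is the outcome."""
        y = frame[target].astype(int)
        return cls(frame, y, spec=spec, target=target, **kwargs)

    def fit(
        self,
        n_replicates: int = 200,
        seed: int = 0,
        compute_importance: bool = False,
    ) -> "RiskModelResults":
        """Train ``n_replicates`` independently seeded balanced forests.

        Replicate r uses seed ``seed + r``; each contributes one OOB Brier
        score and, optionally, one permutation-importance vector.
        """
        scores = np.empty(n_replicates)
        importance = np.zeros(self.X.shape[1])
        last_forest = None
        for r in range(n_replicates):
            forest = BalancedRandomForest(n_trees=self.n_trees, seed=seed + r)
            forest.fit(self.X, self.y)
            scores[r] = forest.oob_brier()
            if compute_importance:
                rng = np.random.default_rng(seed + r + 1_000_003)
                importance += forest.mda_importance(rng)
            last_forest = forest
        imp = (
            pd.Series(importance / n_replicates, index=list(self.X.columns))
            if compute_importance
            else None
        )
        return RiskModelResults(
            model=self,
            brier_scores=scores,
            importance=imp,
            forest=last_forest,
            seed=seed,
        )


@dataclass
class RiskModelResults:
    """Fitted-replicates container: Brier scores, importance, diagnostics."""

    model: RiskModel
    brier_scores: np.ndarray
    importance: Optional[pd.Series]
    forest: Optional[BalancedRandomForest]
    seed: int

    @property
    def mean_brier(self) -> float:
        return float(np.mean(self.brier_scores))

    @property
    def sd_brier(self) -> float:
        return float(np.std(self.brier_scores, ddof=1)) if len(self.brier_scores) > 1 else 0.0

    @property
    def name(self) -> str:
        return self.model.spec.name

    def evaluation(self) -> ModelEvaluation:
        return ModelEvaluation(
            target=self.model.target,
            model=self.name,
            brier_scores=self.brier_scores,
            importance=self.importance,
            feature_names=tuple(self.model.X.columns),
        )

    def top_features(self, k: int = 10) -> list[str]:
        """Top-k features by average MDA; ties break lexicographically."""
        if self.importance is None:
            raise ValueError("fit with compute_importance=True to rank features")
        order = sorted(self.importance.items(), key=lambda kv: (-kv[1], kv[0]))
        return [name for name, _ in order[:k]]

    def summary(self) -> str:
        lines = [
            f"Risk model results: {self.name} -> {self.model.target}",
            "=" * 54,
            f"participants:        {len(self.model.y)}",
            f"positives:           {int(self.model.y.sum())}",
            f"features:            {self.model.X.shape[1]}",
            f"trees per forest:    {self.model.n_trees}",
            f"replicates:          {len(self.brier_scores)}",
            f"OOB Brier (mean):    {self.mean_brier:.4f}",
            f"OOB Brier (SD):      {self.sd_brier:.2e}",
        ]
        if self.importance is not None:
            lines.append("top features by MDA:")
            for name in self.top_features(min(10, len(self.importance))):
                lines.append(f"  {name:<45s} {self.importance[name]:+.4f}")
        return "\n".join(lines)


def evaluate_model(
    features: pd.DataFrame,
    labels: Sequence[int],
    spec: ModelSpec | str,
    n_replicates: int = 200,
    seed: int = 0,
    n_trees: int = 500,
    target: str = "target",
    compute_importance: bool = False,
) -> ModelEvaluation:
    """Functional wrapper: fit a :class:`RiskModel` and return its evaluation."""
    res = RiskModel(
        features, labels, spec=spec, n_trees=n_trees, target=target
    ).fit(n_replicates=n_replicates, seed=seed, compute_importance=compute_importance)
    return res.evaluation()


def compare_models(
    results: Sequence[RiskModelResults | ModelEvaluation],
) -> pd.DataFrame:
    """All pairwise Welch t tests on replicate Brier scores, BH-adjusted.

    Reports, per pair, the mean difference, the relative improvement of the
    second model over the first (100 * (B_a - B_b) / B_a), the two-tailed
    p-value, and the within-target Benjamini-Hochberg q-value.
    """
    evals = [r.evaluation() if isinstance(r, RiskModelResults) else r for r in results]
    if len(evals) < 2:
        raise ValueError("need at least two model evaluations to compare")
    n_rep = {len(e.brier_scores) for e in evals}
    if len(n_rep) != 1:
        raise ValueError("evaluations carry different replicate counts")
    if n_rep.pop() < 2:
        raise ValueError("need at least two replicates per model")
    rows = []
    for i, ea in enumerate(evals):
        for eb in evals[i + 1 :]:
            a, b = ea.brier_scores, eb.brier_scores
            diff = float(np.mean(a) - np.mean(b))
            if np.allclose(a, b):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "target": ea.target,
                    "model_a": ea.model,
                    "model_b": eb.model,
                    "mean_brier_a": float(np.mean(a)),
                    "mean_brier_b": float(np.mean(b)),
                    "mean_difference": diff,
                    "improvement_pct": 100 * diff / float(np.mean(a)),
                    "t_statistic": float(t),
                    "p_value": float(p),
                }
            )
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    for _, idx in table.groupby("target").groups.items():
        p = table.loc[idx, "p_value"].to_numpy()
        table.loc[idx, "q_value"] = multipletests(p, method="fdr_bh")[1]
    return table


def rank_importance(
    results: Mapping[str, RiskModelResults], k: int = 10
) -> tuple[dict[str, list[str]], list[str]]:
    """Top-k features per target (from Unified-model results) and their union."""
    per_target = {target: res.top_features(k) for target, res in results.items()}
    union: list[str] = []
    for feats in per_target.values():
        for f in feats:
            if f not in union:
                union.append(f)
    return per_target, union
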