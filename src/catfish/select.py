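"""All-relevant feature selection: shadow features, Random Forest, stability.

The multivariate mining layer asks which activity descriptors carry
information about the response (recall group or correctness score) in any —
possibly non-linear, possibly joint — form. The engine is the Boruta
shadow-feature scheme: every iteration appends a permuted ("shadow") copy of
each feature, fits a Random Forest, and counts a *hit* for every real
feature whose importance beats the best shadow; binomial tests on the hit
counts confirm or reject features, and whatever is undecided at the
iteration cap stays *tentative*. Because the animal samples are small and
tentative features are informative, tentative counts as selected. The whole
procedure (median imputation of missing descriptors, then Boruta) is
repeated with independent seeds and a feature is finally reported only when
selected in at least half of the repeats.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.impute import KNNImputer

from .errors import DataError, ParameterError

CONFIRMED, TENTATIVE, REJECTED = "confirmed", "tentative", "rejected"

#: tree count reported for the full-scale analysis; tests and the bundled
#: configs scale this down because importance rankings at n ~ 16 animals
#: stabilise far below it
PAPER_N_TREES = 50_000

RESPONSE_COLUMN = "__response__"


@dataclass
class FeatureMatrix:
    """Animals x descriptors with a response (group label or real score)."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise DataError("feature columns must be unique")
        if self.y.dropna().nunique() < 2:
            raise DataError("response needs at least 2 distinct values")

    def to_csv(self, path: str | Path) -> None:
        df = self.X.copy()
        df[RESPONSE_COLUMN] = self.y
        df.to_csv(path, index=True)

    @classmethod
    def from_csv(cls, path: str | Path, response: str = RESPONSE_COLUMN) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        if response not in df.columns:
            raise DataError(f"response column {response!r} not in {path}")
        y = df[response]
        X = df.drop(columns=[response])
        return cls(X=X, y=y)


def impute_missing(
    X: pd.DataFrame,
    rng_seed: int = 0,
    strategy: str = "median",
    n_neighbors: int = 5,
) -> pd.DataFrame:
    """Complete a feature matrix (per-column median by default, or k-NN).

    Deterministic given the seed; a column with no observed value at all is
    an error (there is nothing to impute from).
    """
    all_missing = [c for c in X.columns if X[c].isna().all()]
    if all_missing:
        raise DataError(f"all-missing columns cannot be imputed: {all_missing}")
    if not X.isna().any().any():
        return X
    if strategy == "median":
        return X.fillna(X.median())
    if strategy == "knn":
        imputer = KNNImputer(n_neighbors=min(n_neighbors, len(X) - 1))
        return pd.DataFrame(
            imputer.fit_transform(X), index=X.index, columns=X.columns
        )
    raise ParameterError(f"unknown imputation strategy {strategy!r}")


def _is_classification(y: pd.Series) -> bool:
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype) or y.dtype == bool:
        return True
    return False


def rf_importance(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    rng_seed: int = 0,
) -> pd.Series:
    """Random-Forest mean-decrease-in-impurity importances.

    Classification forest for a categorical/binary response, regression
    forest for a real-valued one. Deterministic given the seed.
    """
    if n_trees < 1:
        raise ParameterError("n_trees must be >= 1")
    if X.isna().any().any():
        raise DataError("rf_importance needs a complete matrix; impute first")
    cls = RandomForestClassifier if _is_classification(y) else RandomForestRegressor
    forest = cls(
        n_estimators=n_trees,
        random_state=int(rng_seed) % (2**31),
        n_jobs=1,
        max_features="sqrt",
    )
    forest.fit(X.to_numpy(), y.to_numpy())
    return pd.Series(forest.feature_importances_, index=X.columns)


def _shadow_seed(name: str, rng_seed: int, iteration: int) -> int:
    """Shadow-permutation seed from the feature NAME (not its position), so
    results are invariant to column order."""
    digest = hashlib.sha256(f"{name}|{rng_seed}|{iteration}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def boruta_run(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    max_iter: int = 100,
    alpha: float = 0.01,
    rng_seed: int = 0,
) -> dict[str, str]:
    """One Boruta pass: per-feature status confirmed/tentative/rejected.

    Each iteration appends a column-wise permuted shadow copy of every
    feature, fits a Random Forest on the joint matrix, and scores a hit for
    every real feature whose importance exceeds the maximum shadow
    importance. Keeping the full shadow pool (rather than only shadows of
    undecided features) holds the hit bar at the max of as many null draws
    as there are features throughout the run, which is what makes
    by-chance-correlated features at small n drift to rejection instead of
    hovering. Two-sided binomial tests on the hit counts (null: hit
    probability 1/2), Bonferroni-adjusted over the number of features as in
    the canonical algorithm, decide features at significance ``alpha``;
    features undecided after ``max_iter`` iterations remain tentative.
    """
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    if X.isna().any().any():
        raise DataError("boruta_run needs a complete matrix; impute first")
    cols = sorted(X.columns)  # canonical order: column-order invariance
    alpha_adj = alpha / len(cols)  # multiple-comparison adjustment
    status: dict[str, str] = {}
    hits: dict[str, int] = {c: 0 for c in cols}
    trials = 0
    undecided = list(cols)

    for iteration in range(1, max_iter + 1):
        shadows = {}
        for c in cols:
            rng = np.random.default_rng(_shadow_seed(c, rng_seed, iteration))
            shadows[f"shadow__{c}"] = rng.permutation(X[c].to_numpy())
        # rejected features leave the fit; confirmed and undecided stay
        active = [c for c in cols if status.get(c) != REJECTED]
        joint = pd.concat(
            [X[active], pd.DataFrame(shadows, index=X.index)], axis=1
        )
        imp = rf_importance(
            joint, y, n_trees=n_trees,
            rng_seed=_shadow_seed("__forest__", rng_seed, iteration),
        )
        shadow_max = imp[[f"shadow__{c}" for c in cols]].max()
        trials += 1
        for c in undecided:
            if imp[c] > shadow_max:
                hits[c] += 1
        still = []
        for c in undecided:
            p = binomtest(hits[c], trials, 0.5, alternative="two-sided").pvalue
            if p < alpha_adj:
                status[c] = CONFIRMED if hits[c] > trials / 2 else REJECTED
            else:
                still.append(c)
        undecided = still
        if not undecided:
            break
    for c in undecided:
        status[c] = TENTATIVE
    return {c: status[c] for c in X.columns}


@dataclass
class SelectionResult:
    """Outcome of the repeat-and-vote stability wrapper."""

    statuses: pd.DataFrame  # features x repeats
    selection_fraction: pd.Series
    final_selected: pd.Series  # boolean
    stability_threshold: float

    @property
    def selected_features(self) -> list[str]:
        return list(self.final_selected[self.final_selected].index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "selection_fraction": self.selection_fraction,
                "final_selected": self.final_selected,
            }
        )
        out.index.name = "feature"
        return out


def _repeat_seed(base_seed: int, repeat: int) -> int:
    return (int(base_seed) * 1_000_003 + 7919 * (repeat + 1)) % (2**31)


def stable_select(
    X_raw: pd.DataFrame,
    y: pd.Series,
    n_repeats: int = 30,
    stability_threshold: float = 0.5,
    base_seed: int = 0,
    n_trees: int = 500,
    max_iter: int = 100,
    alpha: float = 0.01,
    impute_strategy: str = "median",
) -> SelectionResult:
    """Impute + Boruta repeated with independent seeds; vote on selections.

    A feature counts as selected in one repeat iff its status is confirmed
    or tentative; it is finally selected iff its selection fraction reaches
    ``stability_threshold`` (default: at least half of 30 repeats).
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    if not (0 < stability_threshold <= 1):
        raise ParameterError("stability_threshold must be in (0, 1]")
    per_repeat: dict[str, dict[str, str]] = {}
    for r in range(n_repeats):
        seed = _repeat_seed(base_seed, r)
        X = impute_missing(X_raw, rng_seed=seed, strategy=impute_strategy)
        per_repeat[f"repeat_{r:02d}"] = boruta_run(
            X, y, n_trees=n_trees, max_iter=max_iter, alpha=alpha, rng_seed=seed
        )
    statuses = pd.DataFrame(per_repeat).loc[list(X_raw.columns)]
    selected = statuses.isin([CONFIRMED, TENTATIVE])
    fraction = selected.mean(axis=1)
    final = fraction >= stability_threshold
    return SelectionResult(
        statuses=statuses,
        selection_fraction=fraction,
        final_selected=final,
        stability_threshold=stability_threshold,
    )


def rank_table(X: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """Per-animal ranks (1 = lowest value) of the selected features, the form
    used for the reported heatmaps; missing values stay missing."""
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ParameterError(f"unknown features: {missing}")
    out = {}
    for f in features:
        vals = X[f].to_numpy(dtype=float)
        ranks = np.full(len(vals), np.nan)
        obs = ~np.isnan(vals)
        ranks[obs] = rankdata(vals[obs])
        out[f] = ranks
    return pd.DataFrame(out, index=X.index)
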