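"""All-relevant feature selection with shadow features around a random forest.

Each iteration appends one freshly shuffled ("shadow") copy of every
candidate column to the design, fits a random forest on a random half of
the rows, and measures each column's permutation importance: for every tree
in the forest, the column is randomly permuted and the loss of that tree's
accuracy on the held-out half is recorded; a column's importance is the
mean loss over trees. Measuring the loss per tree (rather than on the
forest vote) keeps the measure sensitive to features that only some trees
use, and measuring it on held-out rows avoids the degeneracy of an
overfitted forest whose training accuracy never moves. A real feature
scores a *hit* when its importance exceeds the best shadow importance of
that iteration. After
each iteration a two-sided binomial test compares a feature's accumulated
hits against the 50% chance level: significantly more hits confirms the
feature as ``important``, significantly fewer rejects it as ``unimportant``
(rejected columns leave the design), and features still undecided when the
iteration budget runs out are ``tentative``.

Two derived subsets feed back into modelling: the strictly selected features
(important only) and the selected features (important plus tentative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from bowspace.exceptions import DegenerateTrainingError, InvalidInputError

CATEGORIES = ("important", "tentative", "unimportant")


@dataclass
class BorutaResult:
    """Per-feature categories and hit counts from one selection run."""

    categories: np.ndarray      # of {"important", "tentative", "unimportant"}
    hits: np.ndarray            # hit count per feature
    iterations: int
    alpha: float
    seed: int
    columns: tuple[str, ...] | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "categories": self.categories.tolist(),
            "hits": self.hits.tolist(),
            "iterations": self.iterations,
            "alpha": self.alpha,
            "seed": self.seed,
            "columns": list(self.columns) if self.columns is not None else None,
            "params": self.params,
        }


def _permutation_importance(forest, X: np.ndarray, y: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Per-tree mean accuracy loss when each column is permuted once.

    A tree's accuracy is unaffected by permuting a column it never splits
    on, so only the features used by each tree are evaluated.
    """
    n, p = X.shape
    perm = rng.permutation(n)  # one shared permutation per iteration
    losses = np.zeros(p)
    X_work = np.ascontiguousarray(X, dtype=np.float32)
    for tree in forest.estimators_:
        pred = tree.predict(X_work)
        base = np.mean(pred == y)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            saved = X_work[:, j].copy()
            X_work[:, j] = saved[perm]
            losses[j] += base - np.mean(tree.predict(X_work) == y)
            X_work[:, j] = saved
    return losses / len(forest.estimators_)


def boruta_select(X, y, max_iter: int = 100, alpha: float = 0.05, seed: int = 0,
                  forest_size: int = 500, early_stop: bool = True) -> BorutaResult:
    """Classify every feature as important / tentative / unimportant.

    ``forest_size`` is the number of trees fitted per iteration; shadows are
    re-shuffled fresh each iteration, and the whole run is deterministic
    given ``seed``. With ``early_stop`` the loop ends as soon as no feature
    is undecided.
    """
    columns = tuple(map(str, X.columns)) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be 2-D with one row per label")
    if X.shape[1] < 2:
        raise InvalidInputError("need at least 2 features")
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("labels contain a single class")
    if max_iter < 1:
        raise InvalidInputError("max_iter must be >= 1")

    n, p = X.shape
    rng = np.random.default_rng(seed)
    hits = np.zeros(p, dtype=int)
    category = np.full(p, "tentative", dtype=object)
    undecided = np.ones(p, dtype=bool)
    iterations = 0

    for it in range(max_iter):
        iterations = it + 1
        active = np.flatnonzero(category != "unimportant")
        X_active = X[:, active]
        shadows = X_active.copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = shadows[rng.permutation(n), j]
        design = np.hstack([X_active, shadows])

        # fresh stratified half/half split: fit one half, score the other
        order = np.concatenate([rng.permutation(np.flatnonzero(y == c))
                                for c in np.unique(y)])
        fit_rows = np.sort(order[::2])
        eval_rows = np.sort(order[1::2])
        forest = RandomForestClassifier(
            n_estimators=forest_size, n_jobs=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(design[fit_rows], y[fit_rows])
        importances = _permutation_importance(
            forest, design[eval_rows], y[eval_rows], rng)
        real_imp = importances[:active.size]
        shadow_max = importances[active.size:].max()
        hits[active[real_imp > shadow_max]] += 1

        # Binomial decision per still-undecided feature.
        for j in np.flatnonzero(undecided):
            test = binomtest(int(hits[j]), iterations, 0.5)
            if test.pvalue < alpha:
                category[j] = "important" if hits[j] > iterations / 2 else "unimportant"
                undecided[j] = False
        if early_stop and not undecided.any():
            break

    return BorutaResult(
        categories=category.astype(str), hits=hits, iterations=iterations,
        alpha=alpha, seed=seed, columns=columns,
        params={"max_iter": max_iter, "forest_size": forest_size,
                "early_stop": early_stop},
    )


def feature_subsets(result: BorutaResult) -> dict[str, np.ndarray]:
    """The two derived index lists: strict (important) and selected (+tentative)."""
    cats = result.categories
    return {
        "strict": np.flatnonzero(cats == "important"),
        "selected": np.flatnonzero((cats == "important") | (cats == "tentative")),
    }


def subspace_attribution(result: BorutaResult, column_map) -> dict[str, int]:
    """Count selected features per subspace.

    ``column_map`` assigns each feature (by column name when the result has
    names, else by index) to a subspace label such as "protein", "ligand",
    "interaction". Counts sum to the number of selected features.
    """
    selected = feature_subsets(result)["selected"]
    counts: dict[str, int] = {}
    for idx in selected:
        key = result.columns[idx] if result.columns is not None else idx
        if key not in column_map:
            raise InvalidInputError(f"feature {key!r} missing from column_map")
        space = column_map[key]
        counts[space] = counts.get(space, 0) + 1
    return counts


def bow_column_map() -> dict[str, str]:
    """The canonical subspace assignment of the 439 bow columns."""
    from bowspace.bow import MACCSP_COLUMNS
    from bowspace.ligand import MACCSL_COLUMNS
    from bowspace.protein import PROTEIN_COLUMNS

    mapping = {c: "protein" for c in PROTEIN_COLUMNS}
    mapping.update({c: "ligand" for c in MACCSL_COLUMNS})
    mapping.update({c: "interaction" for c in MACCSP_COLUMNS})
    return mapping
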