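"""Gold-standard dataset construction: positives, sampled negatives, splits.

Positives are the edges of a known interaction network. Negatives are
(protein, ligand) pairs sampled uniformly without replacement from the cross
product of a protein pool and a ligand pool that are disjoint from every
entity appearing in a positive pair -- the pool construction used when a
curated interactome is combined with large background databases. The
negative:positive ratio is a free parameter (1:1 by default) and should be
recorded with every run, because accuracy is ratio-sensitive.

Splitting follows the evaluation protocol: a stratified 70/30 train/test
split plus stratified 10-fold cross-validation, both seed-deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split as _sk_split

from bowspace.bow import InteractionNetwork
from bowspace.exceptions import InfeasibleRequestError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledPair:
    protein_id: str
    ligand_id: str
    label: int  # 1 = interaction, 0 = non-interaction

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise InvalidInputError(f"label must be 0 or 1, got {self.label}")


@dataclass
class DatasetSplit:
    """Train/test indices (and optional CV folds) over a list of labelled pairs."""

    train: np.ndarray
    test: np.ndarray
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "train": self.train.tolist(),
            "test": self.test.tolist(),
            "folds": None if self.folds is None else [
                {"train": tr.tolist(), "test": te.tolist()} for tr, te in self.folds
            ],
            "meta": self.meta,
        }
        return json.dumps(payload, sort_keys=True)


def build_positive_set(network: InteractionNetwork) -> list[LabeledPair]:
    """One label-1 pair per network edge (set semantics: duplicates collapse)."""
    return [LabeledPair(p, l, 1) for p, l in sorted(network.edges)]


def sample_negative_pairs(protein_pool, ligand_pool, n: int, seed: int,
                          positives=None, exclude_edges=frozenset()) -> list[LabeledPair]:
    """``n`` distinct label-0 pairs drawn uniformly from pool x pool.

    The pools must be disjoint from every entity occurring in a positive pair;
    if ``positives`` is given this is verified. Pairs listed in
    ``exclude_edges`` (e.g. known interactions among pool entities) are never
    sampled. Reproducible given ``seed``.
    """
    proteins = sorted(map(str, set(protein_pool)))
    ligands = sorted(map(str, set(ligand_pool)))
    if positives is not None:
        used = {p.protein_id for p in positives} | {p.ligand_id for p in positives}
        overlap = (set(proteins) | set(ligands)) & used
        if overlap:
            raise InvalidInputError(
                f"negative pools overlap positive entities: {sorted(overlap)[:5]}"
            )
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    excluded = {tuple(map(str, e)) for e in exclude_edges}
    total = len(proteins) * len(ligands)
    n_excluded_in_pool = sum(1 for e in excluded
                             if e[0] in set(proteins) and e[1] in set(ligands))
    available = total - n_excluded_in_pool
    if n > available:
        raise InfeasibleRequestError(
            f"requested {n} negatives but only {available} pool pairs are available"
        )
    rng = np.random.default_rng(seed)
    if total <= 2_000_000:
        flat = [(p, l) for p in proteins for l in ligands if (p, l) not in excluded]
        idx = rng.choice(len(flat), size=n, replace=False)
        chosen = [flat[i] for i in idx]
    else:  # rejection sampling for very large pool products
        chosen_set: set[tuple[str, str]] = set()
        while len(chosen_set) < n:
            p = proteins[rng.integers(len(proteins))]
            l = ligands[rng.integers(len(ligands))]
            if (p, l) not in excluded:
                chosen_set.add((p, l))
        chosen = sorted(chosen_set)
    return [LabeledPair(p, l, 0) for p, l in chosen]


def sample_unlabeled_negatives(proteins, ligands, n: int, seed: int,
                               exclude_edges=frozenset()) -> list[LabeledPair]:
    """Label-0 pairs drawn from non-edges among *known* entities.

    The methodological alternative to the disjoint-pool protocol: entities
    here may also occur in positive pairs, so a model cannot learn a constant
    entity-to-label shortcut. ``exclude_edges`` must contain every known
    interaction among the given entities.
    """
    proteins = sorted(map(str, set(proteins)))
    ligands = sorted(map(str, set(ligands)))
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    excluded = {tuple(map(str, e)) for e in exclude_edges}
    flat = [(p, l) for p in proteins for l in ligands if (p, l) not in excluded]
    if n > len(flat):
        raise InfeasibleRequestError(
            f"requested {n} negatives but only {len(flat)} non-edges are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(flat), size=n, replace=False)
    return [LabeledPair(*flat[i], 0) for i in idx]


def _labels(pairs) -> np.ndarray:
    return np.array([p.label for p in pairs], dtype=int)


def split_train_test(pairs, train_fraction: float = 0.7, seed: int = 0,
                     stratify: bool = True) -> DatasetSplit:
    """Stratified train/test split over labelled pairs (sizes within 1 of exact).

    ``train_fraction`` = 1.0 puts everything in training with a warning.
    Single-class inputs fall back to an unstratified split with a warning.
    """
    n = len(pairs)
    if n < 2:
        raise InvalidInputError("need at least 2 pairs to split")
    if not 0.0 < train_fraction <= 1.0:
        raise InvalidInputError(f"train_fraction must be in (0, 1], got {train_fraction}")
    idx = np.arange(n)
    y = _labels(pairs)
    meta = {"train_fraction": train_fraction, "stratified": stratify}
    if train_fraction == 1.0:
        logger.warning("train_fraction=1.0: empty test set")
        rng = np.random.default_rng(seed)
        return DatasetSplit(train=rng.permutation(idx), test=np.array([], dtype=int),
                            seed=seed, meta=meta)
    strat = y if stratify else None
    if stratify and len(np.unique(y)) < 2:
        logger.warning("single-class input: falling back to unstratified split")
        strat = None
        meta["stratified"] = False
    train, test = _sk_split(idx, train_size=train_fraction, random_state=seed,
                            shuffle=True, stratify=strat)
    return DatasetSplit(train=np.sort(train), test=np.sort(test), seed=seed, meta=meta)


def kfold(pairs, k: int = 10, seed: int = 0,
          stratify: bool = True) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold CV folds; every pair lands in exactly one test fold."""
    n = len(pairs)
    if k < 2:
        raise InvalidInputError(f"k must be >= 2, got {k}")
    if k > n:
        raise InvalidInputError(f"k={k} exceeds number of pairs ({n})")
    y = _labels(pairs)
    idx = np.arange(n)
    if stratify and len(np.unique(y)) >= 2 and np.bincount(y).min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_y = y
    else:
        if stratify:
            logger.warning("cannot stratify folds (class too small); plain k-fold")
        from sklearn.model_selection import KFold as _KFold
        splitter = _KFold(n_splits=k, shuffle=True, random_state=seed)
        split_y = None
    return [(np.sort(tr), np.sort(te)) for tr, te in splitter.split(idx, split_y)]
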