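"""Synthetic proteins, ligands, and interaction networks with planted signal.

The generator emulates the statistical structure the bow descriptor
exploits, without imitating any real database:

* proteins fall into latent classes; each class has its own residue-frequency
  profile (drawn once from a symmetric Dirichlet), so amino-acid composition
  carries class information;
* ligands derive from latent prototypes; each ligand is its prototype's
  166-bit pattern with independent per-bit flips, so fingerprints carry
  prototype information;
* interactions follow a bipartite logistic random-graph whose edge log-odds
  combine a per-class binding propensity, a per-prototype promiscuity, and a
  sparse binary class-prototype specificity bonus:

      logit P(edge p-l) = base + signal * (a_class(p) + b_proto(l)
                                           + gamma * B[class(p), proto(l)])

  with ``base`` solved so the mean edge probability equals the configured
  density. ``signal`` = 0 collapses to a pure Erdos-Renyi bipartite graph
  (the null benchmark); ``signal`` = 1 is fully structured.

``make_benchmark`` draws two independent edge sets from the same
compatibility model: a "known" interactome used for MACCSP averaging and an
"assay" edge set used for labels. No labelled pair's own edge therefore
enters its MACCSP average, and the held-out negative pools have known edges
of their own, so orphanhood cannot leak the label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from bowspace.bow import InteractionNetwork, featurize_pairs
from bowspace.datasets import (
    build_positive_set,
    kfold,
    sample_negative_pairs,
    sample_unlabeled_negatives,
    split_train_test,
)
from bowspace.exceptions import InvalidInputError
from bowspace.ligand import MACCSL_COLUMNS, N_MACCS_BITS
from bowspace.protein import AMINO_ACIDS, ProteinSequence, protein_feature_frame

__all__ = [
    "BenchmarkConfig",
    "Benchmark",
    "simulate_proteins",
    "simulate_ligands",
    "simulate_network",
    "make_benchmark",
    "simulate_feature_selection",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for one synthetic benchmark."""

    n_proteins: int = 500          # interaction-subset proteins
    n_ligands: int = 500           # interaction-subset ligands
    n_pool_proteins: int = 150     # held-out pool for negative sampling
    n_pool_ligands: int = 200
    n_protein_classes: int = 10
    n_ligand_prototypes: int = 20
    length_range: tuple[int, int] = (120, 400)
    composition_concentration: float = 150.0  # symmetric Dirichlet; inf -> uniform
    druggable_hydro_bias: float = 0.25  # log-tilt of hydrophobic residues in druggable classes
    prototype_bit_density: float = 0.35
    bit_flip_rate: float = 0.05
    interaction_density: float = 0.004  # assay (label) edge density
    known_density: float = 0.02         # known-interactome density (MACCSP support)
    signal: float = 0.9
    class_affinity_sd: float = 1.2
    prototype_affinity_sd: float = 1.2
    specificity_bonus: float = 9.0
    n_druggable_classes: int = 3
    n_druglike_prototypes: int = 6
    specificity_fill: float = 0.6   # fraction of druggable x drug-like cells that bind
    negative_ratio: float = 1.0
    negative_mode: str = "unlabeled"   # "unlabeled" (core non-edges) or "pool"
    train_fraction: float = 0.7
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_proteins, self.n_ligands, self.n_pool_proteins,
                  self.n_pool_ligands, self.n_protein_classes,
                  self.n_ligand_prototypes)
        if any(c < 1 for c in counts):
            raise InvalidInputError("all entity/class counts must be >= 1")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise InvalidInputError("length_range must satisfy 3 <= lo <= hi")
        if not 1 <= self.n_druggable_classes <= self.n_protein_classes:
            raise InvalidInputError("n_druggable_classes out of range")
        if not 1 <= self.n_druglike_prototypes <= self.n_ligand_prototypes:
            raise InvalidInputError("n_druglike_prototypes out of range")
        for name in ("bit_flip_rate", "interaction_density", "known_density",
                     "signal", "prototype_bit_density", "specificity_fill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
        if self.negative_mode not in ("unlabeled", "pool"):
            raise InvalidInputError(
                f"negative_mode must be 'unlabeled' or 'pool', got {self.negative_mode!r}"
            )

def _spawn(config: BenchmarkConfig, tag: str) -> np.random.Generator:
    # deterministic sub-stream per generation step (never Python's salted hash)
    return np.random.default_rng([config.seed, sum(map(ord, tag))])


def simulate_proteins(config: BenchmarkConfig, n: int | None = None,
                      prefix: str = "P") -> tuple[list[ProteinSequence], np.ndarray]:
    """Class-structured sequences and their class labels.

    Each class draws a residue-frequency profile from a symmetric Dirichlet
    with the configured concentration (larger concentration -> profiles closer
    to uniform); each protein samples its residues iid from its class profile
    and a length uniform in ``length_range``.
    """
    n = config.n_proteins if n is None else n
    rng_profiles = _spawn(config, "class-profiles")
    profiles = rng_profiles.dirichlet(
        np.full(20, config.composition_concentration), size=config.n_protein_classes
    )
    if config.druggable_hydro_bias:
        # druggable target classes skew mildly hydrophobic (binding-domain
        # families); this is the protein-space share of the planted signal
        hydro = np.array([aa in "ACFILMV" for aa in AMINO_ACIDS], dtype=float)
        druggable = draw_compatibility(config).druggable
        tilt = np.exp(config.signal * config.druggable_hydro_bias
                      * np.outer(druggable, hydro))
        profiles = profiles * tilt
        profiles /= profiles.sum(axis=1, keepdims=True)
    rng = _spawn(config, f"proteins-{prefix}")
    classes = rng.integers(config.n_protein_classes, size=n)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    aa = np.array(list(AMINO_ACIDS))
    seqs = []
    for i in range(n):
        residues = "".join(aa[rng.choice(20, size=lengths[i], p=profiles[classes[i]])])
        seqs.append(ProteinSequence(id=f"{prefix}{i:04d}", residues=residues))
    return seqs, classes


def simulate_ligands(config: BenchmarkConfig, n: int | None = None,
                     prefix: str = "L") -> tuple[pd.DataFrame, np.ndarray]:
    """Prototype-derived fingerprints (id-indexed 0/1 frame) and prototype labels."""
    n = config.n_ligands if n is None else n
    rng_proto = _spawn(config, "prototypes")
    prototypes = (rng_proto.random((config.n_ligand_prototypes, N_MACCS_BITS))
                  < config.prototype_bit_density).astype(np.uint8)
    rng = _spawn(config, f"ligands-{prefix}")
    protos = rng.integers(config.n_ligand_prototypes, size=n)
    flips = (rng.random((n, N_MACCS_BITS)) < config.bit_flip_rate)
    bits = np.where(flips, 1 - prototypes[protos], prototypes[protos]).astype(np.uint8)
    ids = [f"{prefix}{i:04d}" for i in range(n)]
    return pd.DataFrame(bits, index=ids, columns=list(MACCSL_COLUMNS)), protos


@dataclass(frozen=True)
class Compatibility:
    """The latent class-prototype binding structure shared by all edge draws.

    ``specific`` is the outer product of a druggable-class indicator and a
    drug-like-prototype indicator, thinned by a per-cell binding mask:
    binding concentrates where a druggable target class meets a drug-like
    chemotype, but each druggable class recognises only a subset of the
    drug-like chemotypes (which subset is visible only through the known
    interactome), on top of smooth per-class and per-prototype affinity
    variation.
    """

    class_affinity: np.ndarray      # (K,)
    prototype_affinity: np.ndarray  # (M,)
    druggable: np.ndarray           # (K,) 0/1
    druglike: np.ndarray            # (M,) 0/1
    binds: np.ndarray               # (K, M) 0/1 per-cell thinning mask

    @property
    def specific(self) -> np.ndarray:
        return np.outer(self.druggable, self.druglike) * self.binds


def draw_compatibility(config: BenchmarkConfig) -> Compatibility:
    rng = _spawn(config, "compatibility")
    druggable = np.zeros(config.n_protein_classes)
    druggable[rng.permutation(config.n_protein_classes)[:config.n_druggable_classes]] = 1.0
    druglike = np.zeros(config.n_ligand_prototypes)
    druglike[rng.permutation(config.n_ligand_prototypes)[:config.n_druglike_prototypes]] = 1.0
    binds = (rng.random((config.n_protein_classes, config.n_ligand_prototypes))
             < config.specificity_fill).astype(float)
    return Compatibility(
        class_affinity=rng.normal(0.0, config.class_affinity_sd,
                                  config.n_protein_classes),
        prototype_affinity=rng.normal(0.0, config.prototype_affinity_sd,
                                      config.n_ligand_prototypes),
        druggable=druggable,
        druglike=druglike,
        binds=binds,
    )


def _edge_logits(config: BenchmarkConfig, compat: Compatibility,
                 protein_classes: np.ndarray, ligand_prototypes: np.ndarray) -> np.ndarray:
    eta = (compat.class_affinity[protein_classes][:, None]
           + compat.prototype_affinity[ligand_prototypes][None, :]
           + config.specificity_bonus * compat.specific[
               np.ix_(protein_classes, ligand_prototypes)])
    return config.signal * eta


def _solve_base_rate(logits: np.ndarray, density: float) -> float:
    """Offset c with mean sigmoid(logits + c) equal to the target density."""
    lo, hi = -40.0, 40.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))) < density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_network(config: BenchmarkConfig, protein_classes: np.ndarray,
                     ligand_prototypes: np.ndarray,
                     protein_ids=None, ligand_ids=None,
                     compat: Compatibility | None = None,
                     density: float | None = None,
                     tag: str = "network") -> InteractionNetwork:
    """One bipartite edge draw from the compatibility model.

    At ``signal`` = 0 every pair has the same edge probability (the configured
    density); at positive signal the class/prototype structure shapes the
    graph while the mean density is held fixed by the base-rate offset.
    """
    if compat is None:
        compat = draw_compatibility(config)
    n_p, n_l = len(protein_classes), len(ligand_prototypes)
    if protein_ids is None:
        protein_ids = [f"P{i:04d}" for i in range(n_p)]
    if ligand_ids is None:
        ligand_ids = [f"L{i:04d}" for i in range(n_l)]
    logits = _edge_logits(config, compat, np.asarray(protein_classes),
                          np.asarray(ligand_prototypes))
    if density is None:
        density = config.interaction_density
    base = _solve_base_rate(logits, density)
    prob = 1.0 / (1.0 + np.exp(-(logits + base)))
    rng = _spawn(config, tag)
    adj = rng.random((n_p, n_l)) < prob
    edges = {(protein_ids[i], ligand_ids[j]) for i, j in zip(*np.nonzero(adj))}
    return InteractionNetwork.from_edges(edges, proteins=protein_ids,
                                         ligands=ligand_ids)


@dataclass
class Benchmark:
    """A fully labelled synthetic dataset plus everything needed to refeaturize."""

    config: BenchmarkConfig
    sequences: list
    protein_classes: np.ndarray
    fingerprints: pd.DataFrame
    ligand_prototypes: np.ndarray
    known_network: InteractionNetwork
    pairs: list
    X: pd.DataFrame
    y: np.ndarray
    split: object
    folds: list
    protein_blocks: pd.DataFrame
    pool_proteins: list[str]
    pool_ligands: list[str]

    @property
    def manifest(self) -> dict:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self.config).items()}
        return {
            "config": cfg,
            "n_positive": int(self.y.sum()),
            "n_negative": int((1 - self.y).sum()),
            "n_known_edges": len(self.known_network),
        }


def make_benchmark(config: BenchmarkConfig) -> Benchmark:
    """Run the full upstream pipeline on one synthetic draw.

    Generates interaction-subset and pool entities, a known interactome (for
    MACCSP averaging) and an independent assay edge set (for labels), builds
    positives from assay edges inside the interaction subset, samples an
    equal number of negatives from the pool product (excluding any edge of
    either draw), featurizes every labelled pair against the known
    interactome, and attaches a stratified 70/30 split and 10-fold CV folds.
    """
    seqs, classes = simulate_proteins(
        config, n=config.n_proteins + config.n_pool_proteins)
    fps, protos = simulate_ligands(
        config, n=config.n_ligands + config.n_pool_ligands)
    protein_ids = [s.id for s in seqs]
    ligand_ids = list(fps.index)

    compat = draw_compatibility(config)
    known = simulate_network(config, classes, protos, protein_ids, ligand_ids,
                             compat=compat, density=config.known_density,
                             tag="known-network")
    assay = simulate_network(config, classes, protos, protein_ids, ligand_ids,
                             compat=compat, density=config.interaction_density,
                             tag="assay-network")

    core_p = set(protein_ids[:config.n_proteins])
    core_l = set(ligand_ids[:config.n_ligands])
    assay_core = InteractionNetwork.from_edges(
        {e for e in assay.edges if e[0] in core_p and e[1] in core_l},
        proteins=sorted(core_p), ligands=sorted(core_l))
    positives = build_positive_set(assay_core)
    if not positives:
        raise InvalidInputError("benchmark draw produced no positive pairs")
    # The labelled assay edges are "new" discoveries: remove any duplicate
    # from the known interactome so a pair's own edge never enters MACCSP.
    # MACCSP stays a per-protein quantity, identical across that protein's
    # positive and negative pairs.
    known = InteractionNetwork(edges=known.edges - assay_core.edges,
                               proteins=known.proteins, ligands=known.ligands)

    pool_p = protein_ids[config.n_proteins:]
    pool_l = ligand_ids[config.n_ligands:]
    n_neg = max(1, int(round(config.negative_ratio * len(positives))))
    if config.negative_mode == "unlabeled":
        negatives = sample_unlabeled_negatives(
            sorted(core_p), sorted(core_l), n=n_neg, seed=config.seed,
            exclude_edges=known.edges | assay.edges)
    else:  # the disjoint-pool protocol; entity identity then correlates with label
        negatives = sample_negative_pairs(
            pool_p, pool_l, n=n_neg, seed=config.seed, positives=positives,
            exclude_edges=known.edges | assay.edges)

    pairs = positives + negatives
    y = np.array([p.label for p in pairs], dtype=int)
    blocks = protein_feature_frame(seqs)
    X = featurize_pairs([(p.protein_id, p.ligand_id) for p in pairs],
                        blocks, fps, known, subspace_mask="all")
    split = split_train_test(pairs, config.train_fraction, seed=config.seed)
    folds = kfold(pairs, k=config.n_folds, seed=config.seed)
    return Benchmark(config=config, sequences=seqs, protein_classes=classes,
                     fingerprints=fps, ligand_prototypes=protos,
                     known_network=known, pairs=pairs, X=X, y=y, split=split,
                     folds=folds, protein_blocks=blocks,
                     pool_proteins=pool_p, pool_ligands=pool_l)


def null_config(config: BenchmarkConfig) -> BenchmarkConfig:
    """The same study conditions with the planted signal switched off."""
    return replace(config, signal=0.0)


def simulate_feature_selection(n: int = 300, n_informative: int = 5,
                               n_noise: int = 50, coef: float = 2.0,
                               seed: int = 0):
    """A planted feature-selection dataset: informative columns first.

    Labels follow a logistic model on the informative columns (shared
    coefficient ``coef``); the remaining columns are pure standard-normal
    noise. Returns (X, y, informative_index_array).
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_informative + n_noise))
    logits = coef * X[:, :n_informative].sum(axis=1)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    return X, y, np.arange(n_informative)
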