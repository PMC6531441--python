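"""Interaction space (MACCSP) and assembly of the full 439-column descriptor.

MACCSP encodes what a protein's known binding partners look like: it is the
element-wise mean of the MACCS fingerprints of the ligands the protein is
connected to in a reference interaction network. A protein with no known
partners (an orphan) receives a zero vector so that the three unknown
scenarios -- new protein, new ligand, both new -- stay predictable.

The assembled descriptor for a pair is the fixed-order concatenation

    [ protein block (107) | MACCSL (166) | MACCSP (166) ]  = 439 columns,

with frozen column names in BOW_COLUMNS so that feature-selection index
files remain portable across runs.

Leakage note: MACCSP is computed from whatever edge set is passed in.  When
evaluating a model, pass a network restricted to training-set interactions
(the conservative choice) unless you deliberately want the permissive
variant that averages over all known edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bowspace.exceptions import DanglingReferenceError, InvalidInputError
from bowspace.ligand import MACCSL_COLUMNS, N_MACCS_BITS
from bowspace.protein import PROTEIN_COLUMNS

logger = logging.getLogger(__name__)

#: Column header of the MACCSP block.
MACCSP_COLUMNS: tuple[str, ...] = tuple(f"maccsp_{i}" for i in range(1, N_MACCS_BITS + 1))

#: Frozen 439-column header of the assembled bow feature vector.
BOW_COLUMNS: tuple[str, ...] = PROTEIN_COLUMNS + MACCSL_COLUMNS + MACCSP_COLUMNS
assert len(BOW_COLUMNS) == 439

#: Named column masks for subspace ablation experiments.
SUBSPACE_MASKS: dict[str, tuple[str, ...]] = {
    "all": BOW_COLUMNS,
    "protein+ligand": PROTEIN_COLUMNS + MACCSL_COLUMNS,
    "protein": PROTEIN_COLUMNS,
    "ligand": MACCSL_COLUMNS,
    "interaction": MACCSP_COLUMNS,
}


@dataclass(frozen=True)
class InteractionNetwork:
    """A bipartite protein-ligand edge set with explicit entity universes.

    Edges are a set (duplicates collapse); the universes may include entities
    with no edges (orphans).
    """

    edges: frozenset  # of (protein_id, ligand_id)
    proteins: frozenset
    ligands: frozenset
    _by_protein: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        edges = frozenset((str(p), str(l)) for p, l in self.edges)
        proteins = frozenset(map(str, self.proteins)) | {p for p, _ in edges}
        ligands = frozenset(map(str, self.ligands)) | {l for _, l in edges}
        by_protein: dict[str, list[str]] = {}
        for p, l in sorted(edges):
            by_protein.setdefault(p, []).append(l)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "proteins", proteins)
        object.__setattr__(self, "ligands", ligands)
        object.__setattr__(self, "_by_protein", by_protein)

    @classmethod
    def from_edges(cls, edges, proteins=(), ligands=()) -> "InteractionNetwork":
        return cls(edges=frozenset(tuple(e) for e in edges),
                   proteins=frozenset(proteins), ligands=frozenset(ligands))

    def ligands_of(self, protein_id: str) -> list[str]:
        return self._by_protein.get(str(protein_id), [])

    def degree(self, protein_id: str) -> int:
        return len(self.ligands_of(protein_id))

    def subset(self, pairs) -> "InteractionNetwork":
        """Network restricted to the given (protein, ligand) pairs (same universes)."""
        keep = frozenset(tuple(map(str, p)) for p in pairs)
        return InteractionNetwork(edges=self.edges & keep,
                                  proteins=self.proteins, ligands=self.ligands)

    def __len__(self) -> int:
        return len(self.edges)


def _fingerprint_lookup(fps: pd.DataFrame, ligand_ids, context: str) -> np.ndarray:
    missing = [l for l in ligand_ids if l not in fps.index]
    if missing:
        raise DanglingReferenceError(
            f"{context}: ligands {missing[:5]} have no fingerprint record"
        )
    return fps.loc[list(ligand_ids)].to_numpy(dtype=float)


def maccsp(protein_id: str, network: InteractionNetwork, fps: pd.DataFrame) -> np.ndarray:
    """Element-wise mean fingerprint of a protein's known ligands (166 reals).

    Orphan proteins (no known ligands in ``network``) yield an all-zero
    vector with a logged warning.
    """
    protein_id = str(protein_id)
    if protein_id not in network.proteins:
        raise InvalidInputError(f"protein {protein_id!r} unknown to the network universe")
    partners = network.ligands_of(protein_id)
    if not partners:
        logger.warning("protein %r has no known ligands; MACCSP set to zero", protein_id)
        return np.zeros(N_MACCS_BITS)
    return _fingerprint_lookup(fps, partners, f"MACCSP of {protein_id!r}").mean(axis=0)


def maccsp_table(network: InteractionNetwork, fps: pd.DataFrame,
                 protein_ids=None) -> pd.DataFrame:
    """MACCSP vectors for many proteins, one row per id."""
    if protein_ids is None:
        protein_ids = sorted(network.proteins)
    rows = {str(p): maccsp(p, network, fps) for p in protein_ids}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MACCSP_COLUMNS))


def assemble_bow(protein_id: str, ligand_id: str, blocks: pd.DataFrame,
                 fps: pd.DataFrame, network: InteractionNetwork) -> np.ndarray:
    """The 439-dimensional bow feature vector for one protein-ligand pair.

    ``blocks`` is a protein-feature frame (107 columns, id-indexed) and
    ``fps`` an id-indexed 166-bit fingerprint table.
    """
    protein_id, ligand_id = str(protein_id), str(ligand_id)
    if protein_id not in blocks.index:
        raise DanglingReferenceError(f"protein {protein_id!r} has no feature block")
    if ligand_id not in fps.index:
        raise DanglingReferenceError(f"ligand {ligand_id!r} has no fingerprint record")
    return np.concatenate([
        blocks.loc[protein_id].to_numpy(dtype=float),
        fps.loc[ligand_id].to_numpy(dtype=float),
        maccsp(protein_id, network, fps),
    ])


def resolve_mask(subspace_mask) -> list[str]:
    """Turn a named mask or explicit column list into a validated column list."""
    if isinstance(subspace_mask, str):
        try:
            return list(SUBSPACE_MASKS[subspace_mask])
        except KeyError:
            raise InvalidInputError(
                f"unknown subspace mask {subspace_mask!r}; "
                f"expected one of {sorted(SUBSPACE_MASKS)} or a column list"
            ) from None
    cols = list(subspace_mask)
    if not cols:
        raise InvalidInputError("empty subspace mask")
    unknown = [c for c in cols if c not in BOW_COLUMNS]
    if unknown:
        raise InvalidInputError(f"unknown feature columns: {unknown[:5]}")
    return cols


def featurize_pairs(pairs, blocks: pd.DataFrame, fps: pd.DataFrame,
                    network: InteractionNetwork,
                    subspace_mask="all") -> pd.DataFrame:
    """Feature matrix for a sequence of (protein_id, ligand_id) pairs.

    Rows follow the input pair order (index = "protein|ligand"); columns are
    restricted by ``subspace_mask`` (a named mask from SUBSPACE_MASKS or an
    explicit column list, e.g. a feature-selection subset).
    """
    cols = resolve_mask(subspace_mask)
    pairs = [(str(p), str(l)) for p, l in pairs]

    prot_ids = sorted({p for p, _ in pairs})
    missing_p = [p for p in prot_ids if p not in blocks.index]
    if missing_p:
        raise DanglingReferenceError(f"proteins {missing_p[:5]} have no feature block")
    lig_ids = sorted({l for _, l in pairs})
    missing_l = [l for l in lig_ids if l not in fps.index]
    if missing_l:
        raise DanglingReferenceError(f"ligands {missing_l[:5]} have no fingerprint record")

    pvecs = maccsp_table(network, fps, protein_ids=prot_ids) if prot_ids else None
    parts = []
    need = set(cols)
    if need & set(PROTEIN_COLUMNS):
        parts.append(blocks.loc[[p for p, _ in pairs]].reset_index(drop=True))
    if need & set(MACCSL_COLUMNS):
        parts.append(fps.loc[[l for _, l in pairs]].reset_index(drop=True).astype(float))
    if need & set(MACCSP_COLUMNS):
        parts.append(pvecs.loc[[p for p, _ in pairs]].reset_index(drop=True))
    X = pd.concat(parts, axis=1)[cols]
    X.index = pd.Index([f"{p}|{l}" for p, l in pairs], name="pair")
    return X
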