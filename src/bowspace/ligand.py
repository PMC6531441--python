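"""Ligand-space descriptor: the 166-bit MACCS structural-key fingerprint.

Each of the 166 informative MACCS keys flags the presence (1) or absence (0)
of a predefined substructure (a SMARTS pattern) in the molecule. RDKit's key
dictionary emits 167 positions with index 0 unused; bowspace exposes exactly
the informative keys 1-166, as columns ``maccs_1 ... maccs_166``.

Key dictionaries differ slightly between software vendors; the method
consumes the bits generically, so any consistent 166-bit table (e.g. a
pre-computed one) can be supplied in place of RDKit's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bowspace.exceptions import InvalidInputError

N_MACCS_BITS = 166

#: Stable column header for fingerprint tables.
MACCSL_COLUMNS: tuple[str, ...] = tuple(f"maccs_{i}" for i in range(1, N_MACCS_BITS + 1))


@dataclass(frozen=True)
class LigandRecord:
    """A ligand identified by id, with a SMILES structure and/or precomputed bits."""

    id: str
    structure: str | None = None
    bits: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.structure is None and self.bits is None:
            raise InvalidInputError(
                f"ligand {self.id!r}: need a SMILES structure or precomputed bits"
            )
        if self.bits is not None:
            bits = np.asarray(self.bits)
            if bits.shape != (N_MACCS_BITS,):
                raise InvalidInputError(
                    f"ligand {self.id!r}: fingerprint must have {N_MACCS_BITS} bits, "
                    f"got shape {bits.shape}"
                )
            if not np.isin(bits, (0, 1)).all():
                raise InvalidInputError(f"ligand {self.id!r}: fingerprint bits must be 0/1")
            object.__setattr__(self, "bits", bits.astype(np.uint8))


def maccs_fingerprint(ligand: LigandRecord) -> np.ndarray:
    """166-bit MACCS fingerprint for one ligand.

    Precomputed bits are validated and passed through unchanged; otherwise the
    SMILES structure is parsed with RDKit and the 166 informative keys are
    computed. Unparsable structures raise InvalidInputError.
    """
    if ligand.bits is not None:
        return ligand.bits.copy()
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(ligand.structure)
    if mol is None:
        raise InvalidInputError(f"ligand {ligand.id!r}: unparsable SMILES {ligand.structure!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    return np.asarray(fp, dtype=np.uint8)[1:]  # drop the unused index-0 position


def fingerprint_table(ligands) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Fingerprints for a ligand collection: (id-indexed 0/1 matrix, rejects).

    Ligands whose structure fails to parse are reported in the rejects list as
    (id, reason) pairs, never silently dropped. Duplicate ids are an error.
    """
    ids = [lig.id for lig in ligands]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"duplicate ligand ids: {dupes}")
    rows: dict[str, np.ndarray] = {}
    rejects: list[tuple[str, str]] = []
    for lig in ligands:
        try:
            rows[lig.id] = maccs_fingerprint(lig)
        except InvalidInputError as exc:
            rejects.append((lig.id, str(exc)))
    fps = pd.DataFrame.from_dict(rows, orient="index", columns=list(MACCSL_COLUMNS),
                                 dtype=np.uint8)
    if not rows:
        fps = pd.DataFrame(np.empty((0, N_MACCS_BITS), dtype=np.uint8),
                           columns=list(MACCSL_COLUMNS))
    return fps, rejects
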