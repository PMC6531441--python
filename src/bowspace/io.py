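"""Readers and writers for the package's plain-text interchange formats.

* protein sequences: FASTA (id = first whitespace-delimited header token);
* ligands: SMILES file ("SMILES<TAB>id" per line, '#' comments) or SDF;
* fingerprints: CSV with an id column plus maccs_1 ... maccs_166;
* interactions: two-column TSV edge list ("protein_id<TAB>ligand_id",
  '#' comments);
* entity pools: one id per line;
* fitted models: a pickle archive with a JSON manifest alongside.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from bowspace.bow import InteractionNetwork
from bowspace.classifiers import FittedModel
from bowspace.exceptions import InvalidInputError
from bowspace.ligand import MACCSL_COLUMNS, LigandRecord
from bowspace.protein import ProteinSequence


def read_fasta(path, permissive: bool = False) -> list[ProteinSequence]:
    seqs = []
    for record in SeqIO.parse(str(path), "fasta"):
        seqs.append(ProteinSequence.from_raw(record.id, str(record.seq),
                                             permissive=permissive))
    if not seqs:
        raise InvalidInputError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i:i + 60] + "\n")


def read_smiles(path) -> list[LigandRecord]:
    """One "SMILES<TAB>id" record per line; '#' starts a comment line."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise InvalidInputError(f"{path}:{lineno}: expected 'SMILES<TAB>id'")
        records.append(LigandRecord(id=parts[1], structure=parts[0]))
    if not records:
        raise InvalidInputError(f"no SMILES records in {path}")
    return records


def read_sdf(path) -> list[LigandRecord]:
    from rdkit import Chem

    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            records.append(LigandRecord(id=f"sdf_{i}", structure="<unparsable>"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}"
        records.append(LigandRecord(id=name, structure=Chem.MolToSmiles(mol)))
    return records


def read_fingerprint_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in MACCSL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"fingerprint table missing {len(missing)} maccs_* columns"
        )
    df = df[list(MACCSL_COLUMNS)]
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise InvalidInputError("fingerprint table must contain only 0/1 bits")
    df.index = df.index.astype(str)
    return df.astype(np.uint8)


def write_fingerprint_csv(fps: pd.DataFrame, path) -> None:
    fps.to_csv(path, index_label="id")


def read_edge_list(path) -> InteractionNetwork:
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InvalidInputError(
                f"{path}:{lineno}: expected 'protein_id<TAB>ligand_id'"
            )
        edges.append((parts[0], parts[1]))
    return InteractionNetwork.from_edges(edges)


def write_edge_list(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tligand_id\n")
        for p, l in sorted(network.edges):
            fh.write(f"{p}\t{l}\n")


def read_id_list(path) -> list[str]:
    ids = [line.strip() for line in Path(path).read_text().splitlines()
           if line.strip() and not line.startswith("#")]
    if not ids:
        raise InvalidInputError(f"no ids in {path}")
    return ids


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def save_model(model: FittedModel, path) -> None:
    """Pickle the fitted model; a JSON manifest lands next to it."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    manifest = {
        "classifier": model.spec.name,
        "params": model.spec.resolved_params(),
        "seed": model.spec.seed,
        "n_features": (len(model.columns) if isinstance(model.columns, tuple)
                       else model.columns),
        "columns": list(model.columns) if isinstance(model.columns, tuple) else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))


def load_model(path) -> FittedModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, FittedModel):
        raise InvalidInputError(f"{path} is not a bowspace model archive")
    return model
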