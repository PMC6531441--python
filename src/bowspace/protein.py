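"""Protein-space descriptors: ten sequence feature sets, 107 dimensions.

A protein sequence is summarised by

* F1   composition vector (CV, 20) -- fraction of each amino acid;
* F2   composition moment vectors of order 1 and 2 (CMV, 2 x 20) -- residue
       positions weighted by their k-th power, normalised by
       N(N-1)...(N-k), so that order 0 collapses to CV;
* F3   basic physicochemical features (BPC, 7) -- the raw per-residue value
       of seven physicochemical property scales summed along the sequence;
* F4   neighbourhood physicochemical features (NPC, 7) -- per property,
       sum over interior sites of |P_i^2 - P_{i-1} P_{i+1}|;
* F5   index-based physicochemical features (IPC, 7) -- per property, the
       mean over lags k of the mean squared difference between residues k
       apart, computed on a property scale standardised over the 20 amino
       acids (a sequence-order correlation descriptor);
* F6-F10  five amino-acid grouping compositions (RG 5, EleG 5, ExG 6, HG 4,
       SCG 6) -- fraction of residues falling in each physicochemical group.

The blocks are concatenated in the fixed order
CV | CMV1 | CMV2 | BPC | NPC | IPC | RG | EleG | ExG | HG | SCG
(20+20+20+7+7+7+5+5+6+4+6 = 107 columns, names in PROTEIN_COLUMNS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bowspace.exceptions import DegenerateLengthError, InvalidInputError

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Property scale names, in the fixed column order of BPC/NPC/IPC.
PROPERTY_NAMES = (
    "hydrophobicity",
    "charge",
    "polarity",
    "volume",
    "flexibility",
    "isoelectric_point",
    "refractivity",
)

# Default per-residue scales (rows follow AMINO_ACIDS order):
#   hydrophobicity    Kyte & Doolittle hydropathy index
#   charge            net side-chain charge at neutral pH
#   polarity          Grantham polarity
#   volume            Zamyatnin residue volume (A^3)
#   flexibility       Bhaskaran & Ponnuswamy average flexibility index
#   isoelectric_point Zimmerman pI of the free amino acid
#   refractivity      Jones molar refractivity
_DEFAULT_SCALES = {
    "hydrophobicity": [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
                       1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3],
    "charge": [0.0, 0.0, -1.0, -1.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0,
               0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    "polarity": [8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9,
                 5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2],
    "volume": [88.6, 108.5, 111.1, 138.4, 189.9, 60.1, 153.2, 166.7, 168.6, 166.7,
               162.9, 114.1, 112.7, 143.8, 173.4, 89.0, 116.1, 140.0, 227.8, 193.6],
    "flexibility": [0.357, 0.346, 0.511, 0.497, 0.314, 0.544, 0.323, 0.462, 0.466, 0.365,
                    0.295, 0.463, 0.509, 0.493, 0.529, 0.507, 0.444, 0.386, 0.305, 0.420],
    "isoelectric_point": [6.00, 5.05, 2.77, 3.22, 5.48, 5.97, 7.59, 6.02, 9.74, 5.98,
                          5.74, 5.41, 6.30, 5.65, 10.76, 5.68, 5.66, 5.96, 5.89, 5.66],
    "refractivity": [4.34, 35.77, 12.00, 17.26, 29.40, 0.00, 21.81, 19.06, 21.29, 18.78,
                     21.64, 13.28, 10.93, 17.56, 26.66, 6.35, 11.01, 13.92, 42.53, 31.53],
}


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence over the canonical 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidInputError(f"protein {self.id!r}: empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise InvalidInputError(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        return len(self.residues)

    @classmethod
    def from_raw(cls, id: str, residues: str, permissive: bool = False) -> "ProteinSequence":
        """Build a sequence, optionally dropping non-canonical residues.

        In permissive mode residues outside the 20-letter alphabet (B, J, O,
        U, X, Z, ...) are removed with a logged count; by default they are
        rejected.
        """
        residues = residues.upper()
        if permissive:
            kept = [r for r in residues if r in _AA_INDEX]
            dropped = len(residues) - len(kept)
            if dropped:
                logger.warning(
                    "protein %r: dropped %d non-canonical residues", id, dropped
                )
            residues = "".join(kept)
        return cls(id=id, residues=residues)

    def indices(self) -> np.ndarray:
        """Residues as integer codes 0..19 in alphabetical amino-acid order."""
        return np.fromiter((_AA_INDEX[r] for r in self.residues), dtype=np.intp,
                           count=len(self.residues))


@dataclass(frozen=True)
class PropertyScaleTable:
    """Seven physicochemical property scales over the 20 amino acids.

    ``raw`` holds the published per-residue values; ``standardized`` the same
    values centred and scaled to unit standard deviation across the 20 amino
    acids (the form the IPC descriptor consumes).
    """

    raw: np.ndarray  # (20, 7)
    names: tuple[str, ...] = PROPERTY_NAMES
    standardized: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        if raw.shape != (20, len(self.names)):
            raise InvalidInputError(
                f"property table must be 20 x {len(self.names)}, got {raw.shape}"
            )
        if not np.all(np.isfinite(raw)):
            raise InvalidInputError("property table contains non-finite values")
        sd = raw.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise InvalidInputError("a property scale is constant; cannot standardize")
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "standardized", (raw - raw.mean(axis=0)) / sd)

    @classmethod
    def default(cls) -> "PropertyScaleTable":
        raw = np.column_stack([_DEFAULT_SCALES[name] for name in PROPERTY_NAMES])
        return cls(raw=raw)

    @classmethod
    def from_csv(cls, path) -> "PropertyScaleTable":
        """Read a user-supplied table: one row per residue letter, 7 named columns."""
        df = pd.read_csv(path, index_col=0)
        missing = [n for n in PROPERTY_NAMES if n not in df.columns]
        if missing:
            raise InvalidInputError(f"property table missing columns: {missing}")
        try:
            df = df.loc[list(AMINO_ACIDS), list(PROPERTY_NAMES)]
        except KeyError as exc:
            raise InvalidInputError(f"property table missing residues: {exc}") from exc
        return cls(raw=df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.raw, index=list(AMINO_ACIDS), columns=list(self.names)).to_csv(
            path, index_label="residue"
        )


# ---------------------------------------------------------------------------
# Amino-acid groupings (F6-F10)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AminoAcidGrouping:
    """A named, ordered list of residue groups (possibly overlapping)."""

    name: str
    groups: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.groups)


def _grouping(name: str, *groups: str) -> AminoAcidGrouping:
    return AminoAcidGrouping(name=name, groups=tuple(frozenset(g) for g in groups))


#: R groups: non-polar aliphatic / polar uncharged / positively charged /
#: negatively charged / aromatic. Partition of the 20 residues.
RG = _grouping("RG", "AGILMV", "CNPQST", "HKR", "DE", "FWY")

#: Electronic groups: donor / weak donor / acceptor / weak acceptor / neutral.
#: Covers 19 residues; cysteine belongs to none of the published groups.
ELEG = _grouping("EleG", "ADEP", "ILV", "KNR", "FMQTY", "GHSW")

#: Exchange groups, clustered by conservative evolutionary replacement.
EXG = _grouping("ExG", "C", "AGPST", "DENQ", "HKR", "ILMV", "FWY")

#: Hydrophobicity groups: hydrophobic / basic / acidic / polar uncharged.
HG = _grouping("HG", "ACFGILMPVWY", "HKR", "DE", "NQST")

#: Side-chain groups: tiny / bulky / polar-uncharged / charged / polar /
#: aromatic. Groups overlap by construction.
SCG = _grouping("SCG", "AG", "FHRWY", "DE", "DEHIKLRV", "DEKNQRSTWY", "FHWY")

GROUPINGS: dict[str, AminoAcidGrouping] = {
    g.name: g for g in (RG, ELEG, EXG, HG, SCG)
}


# ---------------------------------------------------------------------------
# Feature sets
# ---------------------------------------------------------------------------

def composition_vector(seq: ProteinSequence) -> np.ndarray:
    """F1: fraction of each amino acid (alphabetical order); sums to 1."""
    counts = np.bincount(seq.indices(), minlength=20)
    return counts / seq.n


def composition_moment_vector(seq: ProteinSequence, order: int) -> np.ndarray:
    """F2: per amino acid, sum of (1-based position)^order over its occurrences,
    divided by N(N-1)...(N-order).

    Order 0 reduces to the composition vector. Requires N > order so the
    normalizer is nonzero.
    """
    if order < 0:
        raise InvalidInputError(f"order must be >= 0, got {order}")
    n = seq.n
    if n <= order:
        raise DegenerateLengthError(
            f"protein {seq.id!r}: length {n} too short for CMV order {order}"
        )
    normalizer = float(np.prod([n - t for t in range(order + 1)]))
    positions = np.arange(1, n + 1, dtype=float) ** order
    out = np.zeros(20)
    np.add.at(out, seq.indices(), positions)
    return out / normalizer


def _property_profile(seq: ProteinSequence, table: PropertyScaleTable,
                      standardized: bool = False) -> np.ndarray:
    """Per-position property values, shape (N, 7)."""
    values = table.standardized if standardized else table.raw
    return values[seq.indices(), :]


def basic_physicochemical(seq: ProteinSequence, table: PropertyScaleTable) -> np.ndarray:
    """F3: raw per-residue property values summed along the sequence (7 values).

    The sum is length-dependent by definition: BPC(s1 + s2) = BPC(s1) + BPC(s2).
    """
    return _property_profile(seq, table).sum(axis=0)


def neighbourhood_physicochemical(seq: ProteinSequence,
                                  table: PropertyScaleTable) -> np.ndarray:
    """F4: per property, sum over interior sites i of |P_i^2 - P_{i-1} P_{i+1}|.

    Boundary sites have no two neighbours and are excluded. Sequences with no
    interior site (N < 3) yield a zero vector with a logged warning.
    """
    if seq.n < 3:
        logger.warning("protein %r: length %d < 3, NPC set to zero", seq.id, seq.n)
        return np.zeros(len(table.names))
    p = _property_profile(seq, table)
    return np.abs(p[1:-1] ** 2 - p[:-2] * p[2:]).sum(axis=0)


def index_physicochemical(seq: ProteinSequence, table: PropertyScaleTable) -> np.ndarray:
    """F5 (IPC): sequence-order correlation of standardized property values.

    Per property: standardize the scale over the 20 amino acids; for each lag
    k = 1..N-1 compute delta_k, the mean over i of
    [P(R_{i+k}) - P(R_i)]^2; return the mean of the delta_k. Homopolymers give
    exactly zero; any sequence mixing residues with distinct values gives a
    strictly positive result.
    """
    if seq.n < 2:
        logger.warning("protein %r: length %d < 2, IPC set to zero", seq.id, seq.n)
        return np.zeros(len(table.names))
    p = _property_profile(seq, table, standardized=True)  # (N, 7)
    n = seq.n
    acc = np.zeros(p.shape[1])
    for k in range(1, n):
        diff = p[k:] - p[:-k]
        acc += np.mean(diff * diff, axis=0)
    return acc / (n - 1)


def group_composition(seq: ProteinSequence, grouping) -> np.ndarray:
    """F6-F10: fraction of residues in each group of ``grouping``.

    ``grouping`` is an AminoAcidGrouping or one of the names
    ``RG, EleG, ExG, HG, SCG``. Overlapping groups (SCG) count a residue once
    per group it belongs to, so the entries need not sum to 1.
    """
    if isinstance(grouping, str):
        try:
            grouping = GROUPINGS[grouping]
        except KeyError:
            raise InvalidInputError(
                f"unknown grouping {grouping!r}; expected one of {sorted(GROUPINGS)}"
            ) from None
    cv = composition_vector(seq)
    return np.array([
        sum(cv[_AA_INDEX[aa]] for aa in group) for group in grouping.groups
    ])


@dataclass(frozen=True)
class ProteinFeatureBlock:
    """The assembled 107-dimensional protein-space descriptor."""

    cv: np.ndarray
    cmv1: np.ndarray
    cmv2: np.ndarray
    bpc: np.ndarray
    npc: np.ndarray
    ipc: np.ndarray
    rg: np.ndarray
    eleg: np.ndarray
    exg: np.ndarray
    hg: np.ndarray
    scg: np.ndarray

    def to_array(self) -> np.ndarray:
        vec = np.concatenate([
            self.cv, self.cmv1, self.cmv2, self.bpc, self.npc, self.ipc,
            self.rg, self.eleg, self.exg, self.hg, self.scg,
        ])
        assert vec.shape == (107,)
        return vec


def protein_feature_block(seq: ProteinSequence,
                          table: PropertyScaleTable | None = None) -> ProteinFeatureBlock:
    """Compute all ten protein-space feature sets for one sequence (N >= 3)."""
    if table is None:
        table = PropertyScaleTable.default()
    if seq.n < 3:
        raise DegenerateLengthError(
            f"protein {seq.id!r}: length {seq.n} < 3; full feature block undefined"
        )
    return ProteinFeatureBlock(
        cv=composition_vector(seq),
        cmv1=composition_moment_vector(seq, 1),
        cmv2=composition_moment_vector(seq, 2),
        bpc=basic_physicochemical(seq, table),
        npc=neighbourhood_physicochemical(seq, table),
        ipc=index_physicochemical(seq, table),
        rg=group_composition(seq, RG),
        eleg=group_composition(seq, ELEG),
        exg=group_composition(seq, EXG),
        hg=group_composition(seq, HG),
        scg=group_composition(seq, SCG),
    )


def _protein_columns() -> list[str]:
    cols = [f"cv_{aa}" for aa in AMINO_ACIDS]
    cols += [f"cmv1_{aa}" for aa in AMINO_ACIDS]
    cols += [f"cmv2_{aa}" for aa in AMINO_ACIDS]
    for prefix in ("bpc", "npc", "ipc"):
        cols += [f"{prefix}_{name}" for name in PROPERTY_NAMES]
    for g in (RG, ELEG, EXG, HG, SCG):
        cols += [f"{g.name.lower()}_{i}" for i in range(1, len(g) + 1)]
    return cols


#: Stable 107-column header for protein feature output (cv_A ... scg_6).
PROTEIN_COLUMNS: tuple[str, ...] = tuple(_protein_columns())
assert len(PROTEIN_COLUMNS) == 107


def protein_feature_frame(seqs, table: PropertyScaleTable | None = None) -> pd.DataFrame:
    """Feature blocks for a collection of sequences, one row per id."""
    if table is None:
        table = PropertyScaleTable.default()
    rows = {s.id: protein_feature_block(s, table).to_array() for s in seqs}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(PROTEIN_COLUMNS))
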