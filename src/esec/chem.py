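"""Domain types for molecules, conformational ensembles and atomic attributes.

An :class:`Ensemble` couples a sequence of conformational snapshots (e.g. MD
trajectory frames) with a per-atom :class:`AttributeTable` holding the atomic
properties from which the chiral moment vectors are built: mass, two partial
charge sets (force-field and Gasteiger), polarizability, and indicator flags
for p-orbital (aromatic) character, hydrogen-bond donor/acceptor ability and
hydrophobicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Required columns of an attribute table, one row per atom.
ATTRIBUTE_COLUMNS = (
    "mass",
    "charge_ff",
    "charge_gasteiger",
    "polarizability",
    "is_p_orbital",
    "is_hb_donor_h",
    "is_hb_acceptor",
    "is_hydrophobic",
)

#: Indicator columns restricted to {0, 1}.
INDICATOR_COLUMNS = (
    "is_p_orbital",
    "is_hb_donor_h",
    "is_hb_acceptor",
    "is_hydrophobic",
)


class AttributeTable:
    """Per-atom attribute values, backed by a :class:`pandas.DataFrame`.

    The table is validated on construction: all required columns present,
    masses strictly positive, indicator columns exactly 0 or 1.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ATTRIBUTE_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"attribute table missing columns: {missing}")
        df = data.copy()
        for col in ATTRIBUTE_COLUMNS:
            df[col] = pd.to_numeric(df[col])
        if not np.all(np.isfinite(df[list(ATTRIBUTE_COLUMNS)].to_numpy(float))):
            raise ValueError("attribute table contains non-finite values")
        if (df["mass"] <= 0).any():
            raise ValueError("atomic masses must be strictly positive")
        for col in INDICATOR_COLUMNS:
            vals = df[col].to_numpy(float)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"indicator column {col!r} must be exactly 0 or 1")
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (one row per atom)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def column(self, name: str) -> np.ndarray:
        return self._df[name].to_numpy(float)

    @property
    def masses(self) -> np.ndarray:
        return self.column("mass")

    @property
    def hydrophobic_mask(self) -> np.ndarray:
        return self.column("is_hydrophobic").astype(bool)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, AttributeTable) and self._df.equals(other._df)


def derive_hb_vectors(attrs: AttributeTable) -> AttributeTable:
    """Add the derived hydrogen-bond attribute columns ``hb`` and ``da``.

    ``hb = ha + hd`` flags every atom that can take part in a hydrogen bond;
    ``da = hd − ha`` is +1 for donor hydrogens and −1 for acceptors, so the
    resulting moment vector contrasts the donor and acceptor distributions.
    The operation is idempotent.
    """
    df = attrs.frame.copy()
    hd = df["is_hb_donor_h"].to_numpy(float)
    ha = df["is_hb_acceptor"].to_numpy(float)
    df["hb"] = ha + hd
    df["da"] = hd - ha
    return AttributeTable(df)


@dataclass(frozen=True)
class Snapshot:
    """One conformation: N×3 Cartesian coordinates in Å plus a sampling weight."""

    coords: np.ndarray
    frame_index: int = 0
    weight: float = 1.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be an N×3 array with N ≥ 1")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if self.weight < 0:
            raise ValueError("snapshot weight must be nonnegative")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    """An ordered set of snapshots sharing one attribute table.

    ``enantiomer`` is "R" or "S"; ``protonation`` and ``solvent`` are free-form
    provenance labels (e.g. "pH9"/"uncharged", "implicit_water_acn").
    """

    snapshots: Sequence[Snapshot]
    attributes: AttributeTable
    molecule_id: str = ""
    enantiomer: str = "R"
    protonation: str = ""
    solvent: str = ""

    def __post_init__(self):
        if len(self.snapshots) < 1:
            raise ValueError("ensemble needs at least one snapshot")
        n = len(self.attributes)
        for snap in self.snapshots:
            if snap.n_atoms != n:
                raise ValueError(
                    f"snapshot has {snap.n_atoms} atoms, attribute table has {n}"
                )

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    @property
    def n_atoms(self) -> int:
        return len(self.attributes)

    @property
    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as a (n_frames, n_atoms, 3) array."""
        return np.stack([s.coords for s in self.snapshots])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.snapshots], dtype=float)


_FLIP = np.array([-1.0, 1.0, 1.0])


def mirror(ensemble: Ensemble) -> Ensemble:
    """Return the enantiomeric ensemble.

    Every snapshot is reflected through the y–z plane (first coordinate axis
    negated); attributes are unchanged; the enantiomer tag is flipped.
    Reflection is an isometry, so all interatomic distances are preserved and
    ``mirror(mirror(E))`` restores the original coordinates exactly.
    """
    flipped = [
        replace(s, coords=s.coords * _FLIP) for s in ensemble.snapshots
    ]
    tag = {"R": "S", "S": "R"}.get(ensemble.enantiomer, ensemble.enantiomer)
    return Ensemble(
        snapshots=flipped,
        attributes=ensemble.attributes,
        molecule_id=ensemble.molecule_id,
        enantiomer=tag,
        protonation=ensemble.protonation,
        solvent=ensemble.solvent,
    )


def attributes_from_rdkit(mol) -> AttributeTable:
    """Heuristically fill an attribute table from an RDKit molecule.

    This is an *approximation* of a force-field-type-based assignment: Gasteiger
    charges are computed by RDKit, ``charge_ff`` is copied from them (supply
    force-field charges yourself for anything serious), the p-orbital flag marks
    aromatic atoms, donor hydrogens are those bonded to N/O/S, acceptors are
    N/O with a lone pair, and hydrophobic atoms are carbons with no heteroatom
    neighbour plus their bonded hydrogens.

    Requires the optional ``rdkit`` dependency and a molecule with explicit
    hydrogens and a 3D conformer (coordinates themselves are not used here).
    """
    from rdkit.Chem import AllChem, Chem  # deferred: optional dependency

    mol = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(mol)
    rows = []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        gast = float(atom.GetDoubleProp("_GasteigerCharge"))
        neighbours = [n.GetAtomicNum() for n in atom.GetNeighbors()]
        is_donor_h = z == 1 and any(n in (7, 8, 16) for n in neighbours)
        is_acceptor = z in (7, 8) and atom.GetTotalNumHs() < 4
        if z == 6:
            hydrophobic = all(n in (1, 6) for n in neighbours)
        elif z == 1:
            hydrophobic = any(
                n.GetAtomicNum() == 6
                and all(m.GetAtomicNum() in (1, 6) for m in n.GetNeighbors())
                for n in atom.GetNeighbors()
            )
        else:
            hydrophobic = False
        rows.append(
            {
                "name": atom.GetSymbol(),
                "mass": atom.GetMass(),
                "charge_ff": gast,
                "charge_gasteiger": gast,
                "polarizability": _POLARIZABILITY.get(z, 1.0),
                "is_p_orbital": int(atom.GetIsAromatic()),
                "is_hb_donor_h": int(is_donor_h),
                "is_hb_acceptor": int(is_acceptor),
                "is_hydrophobic": int(hydrophobic),
            }
        )
    return derive_hb_vectors(AttributeTable(pd.DataFrame(rows)))


# Rough isotropic atomic polarizabilities (Å³) for the helper above.
_POLARIZABILITY = {1: 0.39, 6: 1.33, 7: 1.09, 8: 0.87, 9: 0.44, 15: 3.0,
                   16: 3.0, 17: 2.4, 35: 3.5, 53: 5.4}
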