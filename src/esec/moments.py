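"""Attribute moment vectors and triple-product chiral descriptors.

For a centered conformation the moment vector of attribute ``x`` is the
generalized dipole v_x = Σ_i x_i r_i; the mass vector is replaced by a mass
*asymmetry* vector (the plain mass moment of centered coordinates is zero by
construction). A chiral descriptor is the scalar triple product of three such
vectors, normalised to the dimension of a length:

    abcdef = ((v_ab × v_cd) · v_ef) / (‖v_ab‖ ‖v_cd‖ ‖v_ef‖)^(2/3)

A scalar triple product is a pseudoscalar — it changes sign under reflection —
so these descriptors vanish for achiral geometries and take opposite values on
enantiomers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .chem import AttributeTable, Snapshot, derive_hb_vectors

#: Two-letter vector codes in canonical (table-row) order. Descriptor names
#: concatenate three codes in this order, e.g. "msagpi".
VECTOR_ORDER = ("ms", "ch", "ac", "gs", "ag", "al", "pi", "hd", "ha", "hb", "da")

#: Map from vector code to attribute-table column; "ms" is special-cased and
#: the abs-charge and derived HB vectors are computed on the fly.
_PLAIN_COLUMNS = {
    "ch": "charge_ff",
    "gs": "charge_gasteiger",
    "al": "polarizability",
    "pi": "is_p_orbital",
    "hd": "is_hb_donor_h",
    "ha": "is_hb_acceptor",
}

_HB_SET = frozenset({"hd", "ha", "hb", "da"})


def attribute_values(attrs: AttributeTable, code: str) -> np.ndarray:
    """Per-atom attribute x_i for one vector code (not valid for "ms")."""
    if code in _PLAIN_COLUMNS:
        return attrs.column(_PLAIN_COLUMNS[code])
    if code == "ac":
        return np.abs(attrs.column("charge_ff"))
    if code == "ag":
        return np.abs(attrs.column("charge_gasteiger"))
    if code in ("hb", "da"):
        table = attrs if "hb" in attrs.frame.columns else derive_hb_vectors(attrs)
        return table.column(code)
    raise KeyError(f"unknown vector code {code!r}")


def attribute_matrix(attrs: AttributeTable) -> np.ndarray:
    """(11, N) matrix of attribute values in VECTOR_ORDER; row "ms" holds masses."""
    rows = []
    for code in VECTOR_ORDER:
        rows.append(attrs.masses if code == "ms" else attribute_values(attrs, code))
    return np.asarray(rows, dtype=float)


def center_of_mass_frame(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Translate the center of mass to the origin.

    Centering removes the translational variance of moment vectors built from
    attributes with nonzero sum (the net-charge dipole problem).
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = masses @ coords / total
    return coords - com


def moment_vector(centered: np.ndarray, x: np.ndarray) -> np.ndarray:
    """First-order moment v = Σ_i x_i r_i of an attribute over centered coords."""
    centered = np.asarray(centered, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) != centered.shape[0]:
        raise ValueError(
            f"attribute length {len(x)} does not match atom count {centered.shape[0]}"
        )
    return x @ centered


def mass_asymmetry_vector(centered: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-distribution asymmetry v_ms = Σ m_i r_i (m_i‖r_i‖) / Σ (m_i‖r_i‖).

    The plain mass moment of centered coordinates is identically zero, so the
    mass vector instead weights each m_i r_i term by m_i‖r_i‖, emphasising
    heavy atoms far from the center of mass.
    """
    centered = np.asarray(centered, dtype=float)
    masses = np.asarray(masses, dtype=float)
    radii = np.linalg.norm(centered, axis=1)
    w = masses * radii
    denom = w.sum()
    if denom <= 0:
        raise ValueError("degenerate geometry: all atoms at the center of mass")
    return (w * masses) @ centered / denom


def moment_vectors(snapshot_coords: np.ndarray, attrs: AttributeTable) -> Dict[str, np.ndarray]:
    """All 11 moment vectors of one conformation, COM-centered first."""
    centered = center_of_mass_frame(snapshot_coords, attrs.masses)
    out: Dict[str, np.ndarray] = {}
    for code in VECTOR_ORDER:
        if code == "ms":
            out[code] = mass_asymmetry_vector(centered, attrs.masses)
        else:
            out[code] = moment_vector(centered, attribute_values(attrs, code))
    return out


def triple_product_descriptor(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray) -> float:
    """Normalised scalar triple product ((v1×v2)·v3) / (‖v1‖‖v2‖‖v3‖)^(2/3).

    The denominator reduces the descriptor's dimension to a length. If any
    vector is null the numerator vanishes too; the 0/0 limit is defined as 0.
    """
    v1, v2, v3 = (np.asarray(v, dtype=float) for v in (v1, v2, v3))
    if not all(np.all(np.isfinite(v)) for v in (v1, v2, v3)):
        raise ValueError("non-finite vector input")
    norms = np.linalg.norm(v1) * np.linalg.norm(v2) * np.linalg.norm(v3)
    if norms == 0.0:
        return 0.0
    return float(np.cross(v1, v2) @ v3 / norms ** (2.0 / 3.0))


@dataclass(frozen=True)
class DescriptorRecipe:
    """One conformation-dependent descriptor: its name, family and vectors."""

    name: str
    family: str  # "pure_triple" | "shape_triple" | "twist"
    vectors: Tuple[str, ...]  # constituent vector codes (may include so/si/fo/fi)


def _excluded(triple: Tuple[str, str, str]) -> bool:
    s = set(triple)
    if {"ch", "gs"} <= s or {"ac", "ag"} <= s:
        return True  # same physical vector from two charge models
    return len(s & _HB_SET) >= 3  # hb, da are linear in hd, ha


class DescriptorCatalog:
    """The enumerated family of conformation-dependent chiral descriptors.

    165 unordered triples of the 11 moment vectors, minus 22 redundant
    combinations (two charge models of the same quantity, or three or more of
    the linearly dependent hydrogen-bond vectors) = 143 pure triples; plus the
    two twist descriptors and the 11+11 shape-vector triples = 167.
    """

    def __init__(self):
        self.pure_triples: List[DescriptorRecipe] = []
        self.excluded_triples: List[Tuple[str, str, str]] = []
        for triple in combinations(VECTOR_ORDER, 3):
            if _excluded(triple):
                self.excluded_triples.append(triple)
            else:
                self.pure_triples.append(
                    DescriptorRecipe("".join(triple), "pure_triple", triple)
                )
        self.twists = [
            DescriptorRecipe("stwist", "twist", ("so", "si")),
            DescriptorRecipe("ftwist", "twist", ("fo", "fi")),
        ]
        self.shape_triples = [
            DescriptorRecipe(f"sosi{code}", "shape_triple", ("so", "si", code))
            for code in VECTOR_ORDER
        ] + [
            DescriptorRecipe(f"{code}fifo", "shape_triple", ("fo", "fi", code))
            for code in VECTOR_ORDER
        ]

    @property
    def n_raw_triples(self) -> int:
        return len(self.pure_triples) + len(self.excluded_triples)

    @property
    def recipes(self) -> List[DescriptorRecipe]:
        return self.pure_triples + self.twists + self.shape_triples

    @property
    def names(self) -> List[str]:
        return [r.name for r in self.recipes]

    def __len__(self) -> int:
        return len(self.recipes)

    def counts(self) -> Dict[str, int]:
        return {
            "raw_triples": self.n_raw_triples,
            "pure_triples": len(self.pure_triples),
            "twist": len(self.twists),
            "shape_triples": len(self.shape_triples),
            "total": len(self),
        }

    def to_frame(self):
        """Catalog as a DataFrame (name, family, constituent vectors)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {"name": r.name, "family": r.family, "vectors": "+".join(r.vectors)}
                for r in self.recipes
            ]
        )


def enumerate_catalog() -> DescriptorCatalog:
    """Enumerate all 167 conformation-dependent descriptor recipes."""
    return DescriptorCatalog()


def compute_snapshot_descriptors(
    snapshot: Snapshot,
    attrs: AttributeTable,
    catalog: DescriptorCatalog | None = None,
) -> Dict[str, float]:
    """Evaluate every catalog descriptor on one conformation.

    Twist and shape-triple values for frames with degenerate clustering
    (e.g. fewer than four hydrophobic atoms) are returned as NaN and excluded
    from ensemble statistics downstream.
    """
    from .shape import shape_descriptors  # local import to avoid cycle

    catalog = catalog or enumerate_catalog()
    vectors = moment_vectors(snapshot.coords, attrs)
    values: Dict[str, float] = {}
    for recipe in catalog.pure_triples:
        a, b, c = recipe.vectors
        values[recipe.name] = triple_product_descriptor(
            vectors[a], vectors[b], vectors[c]
        )
    values.update(shape_descriptors(snapshot.coords, attrs, vectors))
    return values
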