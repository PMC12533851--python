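"""Coarse-grained molecular shape: four-cluster chains, twist, shape vectors.

A conformation is reduced to a chain of four "blobs" by complete-linkage
clustering of its atomic coordinates (all atoms, or hydrophobic atoms only).
The chain A–B–C–D supports a signed dihedral — a handedness measure of the
molecule's overall shape — from which the ``stwist``/``ftwist`` descriptors
and the outer/inner shape vectors (AD→, BC→) are built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .chem import AttributeTable


@dataclass(frozen=True)
class ClusterChain:
    """Four ordered cluster centers with their member atom indices.

    A and D are the mutually farthest centers, oriented so that
    |AB|·|AC| < |BD|·|CD|; of the two middle centers, B is the one nearer A.
    """

    centers: np.ndarray          # (4, 3), rows A, B, C, D
    members: tuple               # tuple of 4 index lists, same order
    subset: str = "all_atoms"    # or "hydrophobic_only"

    @property
    def A(self) -> np.ndarray:
        return self.centers[0]

    @property
    def B(self) -> np.ndarray:
        return self.centers[1]

    @property
    def C(self) -> np.ndarray:
        return self.centers[2]

    @property
    def D(self) -> np.ndarray:
        return self.centers[3]

    @property
    def outer(self) -> np.ndarray:
        """Outer shape vector AD→."""
        return self.D - self.A

    @property
    def inner(self) -> np.ndarray:
        """Inner shape vector BC→."""
        return self.C - self.B


def four_cluster(coords: np.ndarray, subset: str = "all_atoms") -> ClusterChain:
    """Complete-linkage clustering of coordinates into exactly four clusters.

    Cluster centers are the arithmetic centroids of the member coordinates.
    Exact ties in the farthest-pair search or in the B/C product rule
    (measure-zero for real conformations) are broken by the lowest member
    atom index, keeping the chain deterministic on symmetric toy inputs.

    Raises ``DegenerateGeometry`` if fewer than four points are supplied.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 4:
        raise DegenerateGeometry(
            f"need at least 4 atoms to form a cluster chain, got {coords.shape[0]}"
        )
    labels = fcluster(linkage(coords, method="complete"), t=4, criterion="maxclust")
    groups: List[List[int]] = [
        np.flatnonzero(labels == lab).tolist() for lab in np.unique(labels)
    ]
    if len(groups) != 4:  # duplicate points can collapse the dendrogram
        raise DegenerateGeometry("clustering did not yield four clusters")
    centers = np.array([coords[g].mean(axis=0) for g in groups])

    # Farthest pair of centers -> the chain ends {A, D}.
    dist = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    best_key = None
    ends = (0, 1)
    for i in range(4):
        for j in range(i + 1, 4):
            key = (dist[i, j], -min(groups[i] + groups[j]))
            if best_key is None or key > best_key:
                best_key, ends = key, (i, j)
    mids = [k for k in range(4) if k not in ends]

    # Orient the ends: A is the end with the smaller |AB|·|AC| product.
    p, q = ends
    x, y = mids
    prod_p = dist[p, x] * dist[p, y]
    prod_q = dist[q, x] * dist[q, y]
    if prod_p < prod_q:
        a, d = p, q
    elif prod_q < prod_p:
        a, d = q, p
    else:  # tie: lowest member index is A
        a, d = (p, q) if min(groups[p]) < min(groups[q]) else (q, p)

    # B is the middle center nearer A (tie: lowest member index).
    if dist[a, x] < dist[a, y]:
        b, c = x, y
    elif dist[a, y] < dist[a, x]:
        b, c = y, x
    else:
        b, c = (x, y) if min(groups[x]) < min(groups[y]) else (y, x)

    order = [a, b, c, d]
    return ClusterChain(
        centers=centers[order],
        members=tuple(groups[k] for k in order),
        subset=subset,
    )


class DegenerateGeometry(ValueError):
    """Raised when a conformation cannot support a shape descriptor."""


def signed_sin_dihedral(a, b, c, d) -> float:
    """sin of the signed dihedral angle of four points (IUPAC sign).

    Computed directly from the plane normals, sin θ = ((n1×n2)·q̂)/(‖n1‖‖n2‖),
    which negates exactly under reflection of the inputs.
    """
    b1, q, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, q)
    n2 = np.cross(q, b3)
    nn = np.linalg.norm(n1) * np.linalg.norm(n2) * np.linalg.norm(q)
    if nn == 0.0:
        return 0.0
    return float(np.cross(n1, n2) @ q / nn)


def stwist(chain: ClusterChain) -> float:
    """Molecular twist of a cluster chain, in Å.

    stwist = ‖v‖·‖w‖·sin(θ_ABCD) / ‖q‖ with v, w the perpendicular offsets of
    A and D from the BC axis and q = BC→. The sine of the chain dihedral makes
    the value a signed (pseudoscalar) helicity measure: it flips sign under
    reflection and is unchanged by the arbitrary ABCD→DCBA relabelling.
    Returns 0 for degenerate chains (B = C, or A or D on the BC axis).
    """
    q = chain.C - chain.B
    qn = np.linalg.norm(q)
    if qn == 0.0:
        return 0.0
    qh = q / qn

    def perp_norm(point, base):
        rel = point - base
        return np.linalg.norm(rel - (rel @ qh) * qh)

    v = perp_norm(chain.A, chain.B)
    w = perp_norm(chain.D, chain.C)
    sin_t = signed_sin_dihedral(chain.A, chain.B, chain.C, chain.D)
    return v * w * sin_t / qn


def ftwist(coords: np.ndarray, attrs: AttributeTable) -> float:
    """Twist of the hydrophobic-only cluster chain (NaN if < 4 such atoms)."""
    mask = attrs.hydrophobic_mask
    if mask.sum() < 4:
        return float("nan")
    try:
        chain = four_cluster(np.asarray(coords, float)[mask], subset="hydrophobic_only")
    except DegenerateGeometry:
        return float("nan")
    return stwist(chain)


def shape_triple_descriptors(
    chain: Optional[ClusterChain],
    moments: Dict[str, np.ndarray],
    prefix_form: str,
) -> Dict[str, float]:
    """Eq-5 triple products of (outer, inner, v_xx) for all 11 moment vectors.

    ``prefix_form`` is "sosi{code}" for the all-atom chain or "{code}fifo" for
    the hydrophobic one. Inverting the chain negates both shape vectors, so
    the values are independent of the arbitrary chain orientation.
    """
    from .moments import VECTOR_ORDER, triple_product_descriptor

    out: Dict[str, float] = {}
    for code in VECTOR_ORDER:
        name = prefix_form.format(code=code)
        if chain is None:
            out[name] = float("nan")
        else:
            out[name] = triple_product_descriptor(
                chain.outer, chain.inner, moments[code]
            )
    return out


def shape_descriptors(
    coords: np.ndarray,
    attrs: AttributeTable,
    moments: Dict[str, np.ndarray],
) -> Dict[str, float]:
    """All 24 shape-based descriptors of one conformation.

    stwist + 11 sosixx from the all-atom chain; ftwist + 11 xxfifo from the
    hydrophobic-only chain. Undefined values (degenerate clustering, fewer
    than 4 hydrophobic atoms) are NaN.
    """
    coords = np.asarray(coords, dtype=float)
    values: Dict[str, float] = {}

    try:
        chain_all: Optional[ClusterChain] = four_cluster(coords, subset="all_atoms")
    except DegenerateGeometry:
        chain_all = None
    values["stwist"] = stwist(chain_all) if chain_all is not None else float("nan")
    values.update(shape_triple_descriptors(chain_all, moments, "sosi{code}"))

    mask = attrs.hydrophobic_mask
    chain_f: Optional[ClusterChain] = None
    if mask.sum() >= 4:
        try:
            chain_f = four_cluster(coords[mask], subset="hydrophobic_only")
        except DegenerateGeometry:
            chain_f = None
    values["ftwist"] = stwist(chain_f) if chain_f is not None else float("nan")
    values.update(shape_triple_descriptors(chain_f, moments, "{code}fifo"))
    return values
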