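"""Deterministic synthetic molecules, ensembles and regression datasets.

These generators stand in for MD-sampled drug conformers so that every stage
of the descriptor and modelling pipeline can be exercised without external
data: a helical chiral toy molecule whose enantiomer is an exact mirror image,
an achiral planar control, and sparse linear response datasets with
block-correlated descriptors mimicking the redundancy of real descriptor sets.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .chem import AttributeTable, Ensemble, Snapshot, derive_hb_vectors, mirror


def _toy_attributes(n_atoms: int) -> AttributeTable:
    """Attribute pattern guaranteeing every moment vector is nonzero.

    Alternates heavy/light masses, charges of both signs (slightly different
    Gasteiger values so ch/gs and ac/ag are distinct), a few p-orbital and
    HB donor/acceptor flags, and ≥ 4 hydrophobic atoms.
    """
    rows = []
    for i in range(n_atoms):
        mass = [12.011, 1.008, 14.007, 15.999][i % 4]
        q = 0.3 * np.sin(1.0 + 2.1 * i) + 0.05
        rows.append(
            {
                "mass": mass,
                "charge_ff": q,
                "charge_gasteiger": 0.8 * q + 0.04 * np.cos(0.7 * i),
                "polarizability": 0.4 + 0.15 * (i % 5),
                "is_p_orbital": int(i % 3 == 0),
                "is_hb_donor_h": int(i % 4 == 1),
                "is_hb_acceptor": int(i % 4 == 2),
                "is_hydrophobic": int(i % 2 == 0),
            }
        )
    return derive_hb_vectors(AttributeTable(pd.DataFrame(rows)))


def _helix_coords(n_atoms: int, handedness: int) -> np.ndarray:
    """A single-handed helical chain: rise along z, sense set by handedness."""
    t = np.linspace(0.0, 3.0 * np.pi, n_atoms)
    radius = 1.5
    pitch = 0.6
    return np.column_stack(
        [radius * np.cos(t), handedness * radius * np.sin(t), pitch * t]
    )


def make_chiral_toy(
    seed: int = 0,
    handedness: str = "R",
    n_atoms: int = 14,
    n_frames: int = 500,
    jitter_sigma: float = 0.05,
    torsion_sigma: float = 0.15,
) -> Ensemble:
    """A flexible chiral toy ensemble with fixed handedness.

    The scaffold is a one-handed helix (``handedness`` "R": right-handed).
    Frames perturb the backbone torsions (rotating the chain tail about
    successive bond axes by Gaussian angles, σ = ``torsion_sigma`` rad) and
    add isotropic Gaussian jitter (σ = ``jitter_sigma`` Å). The "S" ensemble
    of the same seed is the exact frame-by-frame mirror image of the "R" one.
    """
    if handedness not in ("R", "S"):
        raise ValueError("handedness must be 'R' or 'S'")
    if handedness == "S":
        return mirror(make_chiral_toy(seed, "R", n_atoms, n_frames,
                                      jitter_sigma, torsion_sigma))

    rng = np.random.default_rng(seed)
    base = _helix_coords(n_atoms, handedness=+1)
    attrs = _toy_attributes(n_atoms)
    snapshots = []
    for f in range(n_frames):
        coords = base.copy()
        # torsional flexing: rotate the tail beyond each internal bond
        for b in range(1, n_atoms - 1):
            angle = rng.normal(0.0, torsion_sigma)
            axis = coords[b] - coords[b - 1]
            axis /= np.linalg.norm(axis)
            rot = _rotation_matrix(axis, angle)
            coords[b + 1 :] = (coords[b + 1 :] - coords[b]) @ rot.T + coords[b]
        coords += rng.normal(0.0, jitter_sigma, coords.shape)
        weight = float(np.exp(rng.normal(0.0, 0.1)))  # SGLD-like weight factor
        snapshots.append(Snapshot(coords=coords, frame_index=f, weight=weight))
    return Ensemble(
        snapshots=snapshots,
        attributes=attrs,
        molecule_id=f"toy-helix-{seed}",
        enantiomer="R",
        protonation="pH9",
        solvent="synthetic",
    )


def make_achiral_toy(
    seed: int = 0,
    n_atoms: int = 12,
    n_frames: int = 100,
    jitter_sigma: float = 0.05,
) -> Ensemble:
    """A planar achiral control: all atoms in z = 0, jitter kept in-plane.

    Every moment and shape vector lies in the molecular plane, so all triple
    products vanish and the chain dihedral is flat — every conformation-
    dependent descriptor is exactly zero for every frame.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2.0 * np.pi, n_atoms, endpoint=False)
    base = np.column_stack(
        [2.0 * np.cos(t) + 0.5 * t, 1.5 * np.sin(t), np.zeros(n_atoms)]
    )
    attrs = _toy_attributes(n_atoms)
    snapshots = []
    for f in range(n_frames):
        coords = base.copy()
        coords[:, :2] += rng.normal(0.0, jitter_sigma, (n_atoms, 2))
        snapshots.append(Snapshot(coords=coords, frame_index=f))
    return Ensemble(
        snapshots=snapshots,
        attributes=attrs,
        molecule_id=f"toy-planar-{seed}",
        enantiomer="R",
        protonation="pH9",
        solvent="synthetic",
    )


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def random_snapshot(
    rng: np.random.Generator, n_atoms: Optional[int] = None
) -> Tuple[Snapshot, AttributeTable]:
    """A random conformation + attribute table for oracle cross-checks."""
    if n_atoms is None:
        n_atoms = int(rng.integers(8, 21))
    coords = rng.normal(0.0, 2.0, (n_atoms, 3))
    attrs = _toy_attributes(n_atoms)
    return Snapshot(coords=coords), attrs


def make_qser_dataset(
    seed: int = 0,
    n_molecules: int = 43,
    n_descriptors: int = 100,
    support: int = 5,
    snr: float = 10.0,
    block_size: int = 5,
    block_rho: float = 0.5,
) -> Tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Sparse linear response data with block-correlated descriptors.

    Descriptor columns come in blocks of ``block_size`` with within-block
    correlation ``block_rho`` (mimicking the strong redundancy among related
    chiral descriptors). The response is y = Xβ + ε with ``support`` nonzero
    coefficients, one per block in the first blocks, and the noise variance
    set so Var(Xβ)/Var(ε) = ``snr``. Returns (X, y, β) with β indexed by
    descriptor name for recovery tests.
    """
    if support > n_descriptors:
        raise ValueError("support cannot exceed the number of descriptors")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n_descriptors / block_size))
    cols = []
    for b in range(n_blocks):
        common = rng.normal(size=(n_molecules, 1))
        width = min(block_size, n_descriptors - b * block_size)
        own = rng.normal(size=(n_molecules, width))
        block = np.sqrt(block_rho) * common + np.sqrt(1.0 - block_rho) * own
        cols.append(block)
    X = np.hstack(cols)
    names = [f"d{j:03d}" for j in range(n_descriptors)]

    beta = np.zeros(n_descriptors)
    true_idx = [b * block_size for b in range(support)]  # one per block
    beta[true_idx] = rng.choice([-1.0, 1.0], size=support) * rng.uniform(
        0.5, 1.5, size=support
    )
    signal = X @ beta
    sigma = float(np.std(signal) / np.sqrt(snr))
    y = signal + rng.normal(0.0, sigma, size=n_molecules)
    return (
        pd.DataFrame(X, columns=names),
        y,
        pd.Series(beta, index=names, name="beta"),
    )
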