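"""File formats: multi-frame structures, attribute/weight tables, matrices.

Conformational ensembles are read from multi-model PDB files (one MODEL per
snapshot) or multi-frame (extended) XYZ files via MDAnalysis; per-atom
attributes come from a TSV with one row per atom and columns named after the
atomic attributes; optional per-frame weights are a plain text file with one
real per line. Descriptor matrices are CSV with one molecule per row and
``#``-prefixed provenance header lines.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chem import ATTRIBUTE_COLUMNS, AttributeTable, Ensemble, Snapshot, derive_hb_vectors


def read_attribute_table(path) -> AttributeTable:
    """Read a per-atom attribute TSV and derive the hb/da columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return derive_hb_vectors(AttributeTable(df))


def write_attribute_table(attrs: AttributeTable, path) -> None:
    cols = [c for c in attrs.frame.columns if c in ("name",) + ATTRIBUTE_COLUMNS]
    attrs.frame[cols].to_csv(path, sep="\t", index=False)


def read_weights(path, n_frames: int) -> np.ndarray:
    """Read one weight per line; length must equal the frame count."""
    weights = np.loadtxt(path, dtype=float, ndmin=1)
    if len(weights) != n_frames:
        raise ValueError(
            f"weight file has {len(weights)} entries but the trajectory has "
            f"{n_frames} frames"
        )
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    return weights


def write_weights(weights: Sequence[float], path) -> None:
    np.savetxt(path, np.asarray(weights, dtype=float), fmt="%.10g")


def _read_frames(path) -> List[np.ndarray]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path))
        return [universe.atoms.positions.astype(float).copy()
                for _ in universe.trajectory]


def read_ensemble(
    path,
    attr_path,
    weights_path=None,
    molecule_id: str = "",
    enantiomer: str = "R",
) -> Ensemble:
    """Load an ensemble from a structure file + attribute TSV (+ weights).

    Weights default to 1.0 per frame when no weight file is given.
    """
    attrs = read_attribute_table(attr_path)
    frames = _read_frames(path)
    if not frames:
        raise ValueError(f"no frames found in {path}")
    n_atoms = frames[0].shape[0]
    if n_atoms != len(attrs):
        raise ValueError(
            f"trajectory has {n_atoms} atoms but the attribute table has "
            f"{len(attrs)} rows"
        )
    weights = (
        read_weights(weights_path, len(frames))
        if weights_path is not None
        else np.ones(len(frames))
    )
    snapshots = [
        Snapshot(coords=c, frame_index=i, weight=float(w))
        for i, (c, w) in enumerate(zip(frames, weights))
    ]
    return Ensemble(
        snapshots=snapshots,
        attributes=attrs,
        molecule_id=molecule_id or Path(str(path)).stem,
        enantiomer=enantiomer,
    )


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as multi-model PDB or multi-frame XYZ (by suffix).

    XYZ is written with 8 decimal places and round-trips coordinates to
    better than 1e−6 Å; the fixed-width PDB format is limited to 1e−3 Å.
    """
    import MDAnalysis as mda

    path = Path(str(path))
    n = ensemble.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(n, trajectory=True)
        names = (
            ensemble.attributes.frame["name"].astype(str).tolist()
            if "name" in ensemble.attributes.frame.columns
            else ["X"] * n
        )
        universe.add_TopologyAttr("names", names)
        universe.add_TopologyAttr("elements", names)
        kwargs = {"precision": 8} if path.suffix.lower() == ".xyz" else {}
        with mda.Writer(str(path), n, multiframe=True, **kwargs) as writer:
            for snap in ensemble.snapshots:
                universe.atoms.positions = snap.coords
                writer.write(universe.atoms)


def config_hash(config: Dict) -> str:
    """Stable short hash of a configuration mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_descriptor_matrix(
    matrix: pd.DataFrame, path, metadata: Optional[Dict] = None
) -> None:
    """Write a molecules × descriptors CSV with provenance header lines."""
    meta = dict(metadata or {})
    meta.setdefault("esec_version", __version__)
    meta.setdefault("config_hash", config_hash(meta))
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        matrix.to_csv(fh, index=True, index_label="molecule")


def read_descriptor_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="molecule")


def read_response_table(path) -> pd.DataFrame:
    """Read a response CSV and ensure an ``alpha_rs`` column.

    Accepts either direct retention factors (columns ``k_R``, ``k_S``), raw
    times (``t_R1``, ``t_R2``, ``t_0`` — enantiomer order R then S), or a
    precomputed ``alpha_rs`` column. Molecule ids come from a ``molecule``
    column.
    """
    from .qser import alpha_rs

    df = pd.read_csv(path, comment="#")
    if "alpha_rs" in df.columns:
        pass
    elif {"k_R", "k_S"} <= set(df.columns):
        df["alpha_rs"] = alpha_rs(df["k_R"], df["k_S"])
    elif {"t_R1", "t_R2", "t_0"} <= set(df.columns):
        t0 = df["t_0"].to_numpy(float)
        df["alpha_rs"] = alpha_rs(
            (df["t_R1"].to_numpy(float) - t0) / t0,
            (df["t_R2"].to_numpy(float) - t0) / t0,
        )
    else:
        raise ValueError(
            "response table needs alpha_rs, (k_R, k_S) or (t_R1, t_R2, t_0)"
        )
    return df
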