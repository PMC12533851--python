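"""Reduction of per-frame descriptor series to conformation-independent values.

Each of the 167 conformation-dependent descriptors yields three ensemble
statistics: one "averaged" value (the weighted ensemble mean) and a pair of
"windowed" values obtained by max-normalising the per-frame series to [−1, 1]
and averaging a one-sided window function of it,

    abcdef± = (Σ_t w_t f_±(s·abcdef(t))) / Σ_t w_t,   s = 1 / max_t|abcdef(t)|.

The window pair satisfies f_+(−x) = f_−(x), so enantiomers — whose per-frame
series are exact negatives — have negated averaged values and swapped (+, −)
windowed values. 167 averaged + 334 windowed = 501 descriptors per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .chem import Ensemble
from .moments import DescriptorCatalog, enumerate_catalog

#: The eight provenance labels for descriptor sets: protonation state,
#: solvent system of the generating simulation, and weighting scheme.
DESCRIPTOR_SETS = {
    "I": ("pH9", "implicit_water", "unweighted"),
    "II": ("pH9", "implicit_water", "weighted"),
    "III": ("pH9", "implicit_water_acn", "unweighted"),
    "IV": ("pH9", "implicit_water_acn", "weighted"),
    "V": ("pH9", "explicit_water_acn", "unweighted"),
    "VI": ("uncharged", "implicit_water_acn", "unweighted"),
    "VII": ("uncharged", "implicit_water_acn", "weighted"),
    "VIII": ("uncharged", "explicit_water_acn", "unweighted"),
}


@dataclass(frozen=True)
class WindowFunctionPair:
    """A (+, −) pair of window functions on [−1, 1].

    Must satisfy the swap symmetry f_plus(−x) = f_minus(x); this is what makes
    the windowed descriptor pair swap between enantiomers.
    """

    f_plus: Callable[[np.ndarray], np.ndarray]
    f_minus: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"

    @staticmethod
    def ramp(exponent: float = 1.0) -> "WindowFunctionPair":
        """One-sided power ramp f_±(x) = max(±x, 0)^p (default p = 1).

        Vanishes on the opposing half-axis, so the (+) value measures sampling
        of positive descriptor values only, and vice versa.
        """

        def plus(x):
            return np.maximum(x, 0.0) ** exponent

        def minus(x):
            return np.maximum(-x, 0.0) ** exponent

        return WindowFunctionPair(plus, minus, name=f"ramp(p={exponent:g})")

    @staticmethod
    def cosine() -> "WindowFunctionPair":
        """Smooth half-cosine ramp f_±(x) = (1 − cos(π·max(±x,0)))/2."""

        def plus(x):
            return 0.5 * (1.0 - np.cos(np.pi * np.maximum(x, 0.0)))

        def minus(x):
            return 0.5 * (1.0 - np.cos(np.pi * np.maximum(-x, 0.0)))

        return WindowFunctionPair(plus, minus, name="cosine")


def default_window() -> WindowFunctionPair:
    return WindowFunctionPair.ramp(1.0)


def _masked(values, weights):
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    defined = np.isfinite(values)
    return values, weights, defined


def averaged_descriptor(values, weights=None) -> float:
    """Weighted ensemble mean over defined (finite) frames.

    Frames flagged undefined (NaN) are dropped and the remaining weights are
    implicitly renormalised; uniform weights reproduce the plain mean.
    """
    values, weights, defined = _masked(values, weights)
    wsum = weights[defined].sum()
    if not defined.any() or wsum <= 0:
        raise ValueError("no defined frames with positive total weight")
    return float(values[defined] @ weights[defined] / wsum)


def windowed_descriptor_pair(
    values, weights=None, window: Optional[WindowFunctionPair] = None
) -> Tuple[float, float]:
    """The (+, −) windowed pair of a per-frame descriptor series.

    The series is scaled by s = 1/max|value| over defined frames so the scaled
    values span [−1, 1]; each output is the weighted mean of f_± of the scaled
    series. An all-zero series returns (f_+(0), f_−(0)).
    """
    window = window or default_window()
    values, weights, defined = _masked(values, weights)
    wsum = weights[defined].sum()
    if not defined.any() or wsum <= 0:
        raise ValueError("no defined frames with positive total weight")
    v = values[defined]
    w = weights[defined]
    vmax = np.abs(v).max()
    x = v / vmax if vmax > 0 else v
    plus = float(np.asarray(window.f_plus(x)) @ w / wsum)
    minus = float(np.asarray(window.f_minus(x)) @ w / wsum)
    return plus, minus


def discard_burn_in(values: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` frames (equilibration) before statistics."""
    values = np.asarray(values)
    if not 0 <= n_discard < len(values):
        raise ValueError(
            f"n_discard must be in [0, {len(values)}), got {n_discard}"
        )
    return values[n_discard:]


def running_mean(values, weights=None) -> np.ndarray:
    """Cumulative weighted mean per frame — the convergence diagnostic.

    Element k is the weighted mean of frames 0..k (undefined frames carried
    over); the final element equals :func:`averaged_descriptor`.
    """
    values, weights, defined = _masked(values, weights)
    w = np.where(defined, weights, 0.0)
    v = np.where(defined, values, 0.0)
    cw = np.cumsum(w)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.cumsum(v * w) / cw


def zscore_standardize(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Z-score each descriptor column (mean 0, sample SD 1, ddof = 1).

    Columns with zero variance carry no information across molecules and are
    dropped; their names are returned alongside the standardized matrix.
    """
    if len(matrix) < 2:
        raise ValueError("standardization needs at least two molecules")
    sd = matrix.std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    kept = matrix.drop(columns=dropped)
    return (kept - kept.mean()) / kept.std(ddof=1), dropped


@dataclass
class EnsembleDescriptorSet:
    """Per-molecule conformation-independent descriptors with provenance.

    ``averaged`` holds the 167 ensemble means; ``windowed`` the 334 values
    named ``<descriptor>+`` / ``<descriptor>-``. ``null_vectors`` lists moment
    vectors that were identically zero (e.g. no HB donors present) and
    ``n_undefined`` counts frames dropped per descriptor.
    """

    molecule_id: str
    averaged: Dict[str, float]
    windowed: Dict[str, float]
    set_label: str = ""
    weighted: bool = False
    null_vectors: List[str] = field(default_factory=list)
    n_undefined: Dict[str, int] = field(default_factory=dict)

    def as_row(self) -> pd.Series:
        """All 501 values as one named row (averaged first, catalog order)."""
        return pd.Series({**self.averaged, **self.windowed}, name=self.molecule_id)


def compute_series(
    ensemble: Ensemble,
    catalog: Optional[DescriptorCatalog] = None,
) -> pd.DataFrame:
    """Per-frame values of every catalog descriptor (rows = frames).

    The 143 pure triple products are evaluated in a vectorised pass over all
    frames; the shape descriptors require per-frame clustering and loop.
    """
    from .moments import (
        VECTOR_ORDER,
        attribute_matrix,
        mass_asymmetry_vector,
    )
    from .shape import shape_descriptors

    catalog = catalog or enumerate_catalog()
    attrs = ensemble.attributes
    amat = attribute_matrix(attrs)  # (11, N); row 0 is mass
    masses = attrs.masses
    coords = ensemble.coords_array  # (T, N, 3)

    com = np.einsum("n,tnc->tc", masses, coords) / masses.sum()
    centered = coords - com[:, None, :]

    # All plain moment vectors for all frames at once: (T, 11, 3).
    vecs = np.einsum("an,tnc->tac", amat, centered)
    radii = np.linalg.norm(centered, axis=2)  # (T, N)
    w = masses[None, :] * radii
    denom = w.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("degenerate geometry: all atoms at the center of mass")
    vecs[:, 0, :] = np.einsum("tn,tnc->tc", w * masses[None, :], centered) / denom[:, None]

    idx = {code: k for k, code in enumerate(VECTOR_ORDER)}
    norms = np.linalg.norm(vecs, axis=2)  # (T, 11)

    data: Dict[str, np.ndarray] = {}
    for recipe in catalog.pure_triples:
        ia, ib, ic = (idx[c] for c in recipe.vectors)
        num = np.einsum(
            "tc,tc->t", np.cross(vecs[:, ia], vecs[:, ib]), vecs[:, ic]
        )
        nn = norms[:, ia] * norms[:, ib] * norms[:, ic]
        vals = np.zeros(len(num))
        nz = nn > 0
        vals[nz] = num[nz] / nn[nz] ** (2.0 / 3.0)
        data[recipe.name] = vals

    shape_rows = []
    for t, snap in enumerate(ensemble.snapshots):
        moments_t = {code: vecs[t, idx[code]] for code in VECTOR_ORDER}
        shape_rows.append(shape_descriptors(centered[t], attrs, moments_t))
    shape_df = pd.DataFrame(shape_rows)
    for name in shape_df.columns:
        data[name] = shape_df[name].to_numpy()

    return pd.DataFrame(data, columns=catalog.names)


def compute_ensemble_descriptors(
    ensemble: Ensemble,
    catalog: Optional[DescriptorCatalog] = None,
    burn_in: int = 0,
    window: Optional[WindowFunctionPair] = None,
    weighted: bool = True,
    set_label: str = "",
) -> EnsembleDescriptorSet:
    """Full reduction of an ensemble to its 501 conformation-independent values.

    ``burn_in`` frames are discarded first; per-frame weights are applied when
    ``weighted`` is true (unit weights otherwise). Undefined frames (NaN,
    from degenerate shape clustering) are dropped per descriptor with their
    weights renormalised, and counted in ``n_undefined``.
    """
    catalog = catalog or enumerate_catalog()
    window = window or default_window()
    series = compute_series(ensemble, catalog)
    weights_all = ensemble.weights if weighted else np.ones(len(ensemble))
    if burn_in:
        series = series.iloc[burn_in:].reset_index(drop=True)
        weights_all = discard_burn_in(weights_all, burn_in)

    averaged: Dict[str, float] = {}
    windowed: Dict[str, float] = {}
    n_undefined: Dict[str, int] = {}
    for name in catalog.names:
        vals = series[name].to_numpy()
        n_bad = int(np.sum(~np.isfinite(vals)))
        if n_bad:
            n_undefined[name] = n_bad
        averaged[name] = averaged_descriptor(vals, weights_all)
        plus, minus = windowed_descriptor_pair(vals, weights_all, window)
        windowed[f"{name}+"] = plus
        windowed[f"{name}-"] = minus

    # Report moment vectors that were identically null across the ensemble
    # (descriptors involving them are 0 by convention).
    from .moments import VECTOR_ORDER, attribute_matrix

    amat = attribute_matrix(ensemble.attributes)
    null_vectors = [
        code
        for k, code in enumerate(VECTOR_ORDER)
        if code != "ms" and not np.any(amat[k])
    ]

    return EnsembleDescriptorSet(
        molecule_id=ensemble.molecule_id,
        averaged=averaged,
        windowed=windowed,
        set_label=set_label,
        weighted=weighted,
        null_vectors=null_vectors,
        n_undefined=n_undefined,
    )
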