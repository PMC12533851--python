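"""Independent brute-force reference implementations used only by tests.

Everything here is written straight from the defining formulas with plain
loops (naive agglomerative clustering, explicit sums, MDAnalysis dihedrals)
and deliberately shares no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---- moment vectors -------------------------------------------------------

def oracle_center(coords, masses):
    com = np.zeros(3)
    for m, r in zip(masses, coords):
        com += m * r
    return np.asarray(coords, float) - com / np.sum(masses)


def oracle_moment(centered, x):
    v = np.zeros(3)
    for xi, ri in zip(x, centered):
        v += xi * ri
    return v


def oracle_mass_asymmetry(centered, masses):
    num = np.zeros(3)
    den = 0.0
    for m, r in zip(masses, centered):
        num += m * r * (m * np.linalg.norm(r))
        den += m * np.linalg.norm(r)
    return num / den


def oracle_triple(v1, v2, v3):
    cross = np.array(
        [
            v1[1] * v2[2] - v1[2] * v2[1],
            v1[2] * v2[0] - v1[0] * v2[2],
            v1[0] * v2[1] - v1[1] * v2[0],
        ]
    )
    num = float(cross @ v3)
    den = (
        np.linalg.norm(v1) * np.linalg.norm(v2) * np.linalg.norm(v3)
    ) ** (2.0 / 3.0)
    return 0.0 if den == 0 else num / den


# ---- naive complete-linkage clustering ------------------------------------

def oracle_complete_linkage(coords, k=4):
    """Agglomerative complete linkage by exhaustive pairwise search."""
    coords = np.asarray(coords, float)
    n = len(coords)
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted([sorted(c) for c in clusters])


def oracle_chain(coords, k=4):
    """Ordered A,B,C,D centroids per the farthest-pair / product rules."""
    coords = np.asarray(coords, float)
    groups = oracle_complete_linkage(coords, k)
    centers = [coords[g].mean(axis=0) for g in groups]
    pairs = list(itertools.combinations(range(4), 2))
    dmax, (p, q) = max(
        (np.linalg.norm(centers[i] - centers[j]), (i, j)) for i, j in pairs
    )
    mids = [m for m in range(4) if m not in (p, q)]
    x, y = mids

    def prod(end):
        return np.linalg.norm(centers[end] - centers[x]) * np.linalg.norm(
            centers[end] - centers[y]
        )

    a, d = (p, q) if prod(p) < prod(q) else (q, p)
    b, c = (
        (x, y)
        if np.linalg.norm(centers[a] - centers[x])
        < np.linalg.norm(centers[a] - centers[y])
        else (y, x)
    )
    return np.array([centers[a], centers[b], centers[c], centers[d]])


def oracle_dihedral(A, B, C, D):
    """Signed dihedral by the atan2 normal-vector formula (float64).

    Same sign convention as MDAnalysis ``calc_dihedrals`` (verified in the
    shape tests) but computed at full precision.
    """
    b1, b2, b3 = B - A, C - B, D - C
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    return np.arctan2(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)), n1 @ n2)


def oracle_stwist_mda(chain):
    """stwist with the dihedral taken from MDAnalysis (float32 precision)."""
    from MDAnalysis.lib.distances import calc_dihedrals

    A, B, C, D = (np.asarray(p, np.float64) for p in chain)
    theta = float(calc_dihedrals(A[None], B[None], C[None], D[None])[0])
    return _stwist_from_theta(chain, theta)


def oracle_stwist(chain):
    """stwist via an independent atan2 dihedral evaluation."""
    A, B, C, D = chain
    return _stwist_from_theta(chain, oracle_dihedral(A, B, C, D))


def _stwist_from_theta(chain, theta):
    A, B, C, D = chain
    q = C - B
    qn = np.linalg.norm(q)
    if qn == 0:
        return 0.0

    def perp(point, base):
        rel = point - base
        return np.linalg.norm(rel - (rel @ q) * q / qn**2)

    return perp(A, B) * perp(D, C) * np.sin(theta) / qn


# ---- full per-snapshot descriptor set -------------------------------------

VECTOR_ORDER = ("ms", "ch", "ac", "gs", "ag", "al", "pi", "hd", "ha", "hb", "da")


def oracle_vectors(coords, attrs_df):
    masses = attrs_df["mass"].to_numpy(float)
    centered = oracle_center(coords, masses)
    cols = {
        "ch": attrs_df["charge_ff"].to_numpy(float),
        "ac": np.abs(attrs_df["charge_ff"].to_numpy(float)),
        "gs": attrs_df["charge_gasteiger"].to_numpy(float),
        "ag": np.abs(attrs_df["charge_gasteiger"].to_numpy(float)),
        "al": attrs_df["polarizability"].to_numpy(float),
        "pi": attrs_df["is_p_orbital"].to_numpy(float),
        "hd": attrs_df["is_hb_donor_h"].to_numpy(float),
        "ha": attrs_df["is_hb_acceptor"].to_numpy(float),
    }
    cols["hb"] = cols["ha"] + cols["hd"]
    cols["da"] = cols["hd"] - cols["ha"]
    vecs = {"ms": oracle_mass_asymmetry(centered, masses)}
    for code, x in cols.items():
        vecs[code] = oracle_moment(centered, x)
    return centered, vecs


def oracle_snapshot_descriptors(coords, attrs_df):
    """All 167 descriptor values, straight from the definitions."""
    centered, vecs = oracle_vectors(coords, attrs_df)
    hb_like = {"hd", "ha", "hb", "da"}
    values = {}
    for triple in itertools.combinations(VECTOR_ORDER, 3):
        s = set(triple)
        if {"ch", "gs"} <= s or {"ac", "ag"} <= s or len(s & hb_like) >= 3:
            continue
        values["".join(triple)] = oracle_triple(*(vecs[c] for c in triple))

    chain_all = oracle_chain(centered)
    values["stwist"] = oracle_stwist(chain_all)
    so = chain_all[3] - chain_all[0]
    si = chain_all[2] - chain_all[1]
    for code in VECTOR_ORDER:
        values[f"sosi{code}"] = oracle_triple(so, si, vecs[code])

    mask = attrs_df["is_hydrophobic"].to_numpy(float).astype(bool)
    if mask.sum() >= 4:
        chain_f = oracle_chain(centered[mask])
        values["ftwist"] = oracle_stwist(chain_f)
        fo = chain_f[3] - chain_f[0]
        fi = chain_f[2] - chain_f[1]
        for code in VECTOR_ORDER:
            values[f"{code}fifo"] = oracle_triple(fo, fi, vecs[code])
    else:
        values["ftwist"] = float("nan")
        for code in VECTOR_ORDER:
            values[f"{code}fifo"] = float("nan")
    return values


# ---- brute-force LOOCV ----------------------------------------------------

def oracle_loocv(X, y, rescale=True):
    """Held-out predictions by explicit per-fold refits with numpy only."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    preds = []
    for i in range(n):
        idx = [j for j in range(n) if j != i]
        Xtr, ytr = X[idx], y[idx]
        xte = X[i]
        if X.shape[1] and rescale:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            xte = (xte - mu) / sd
        if X.shape[1] == 0:
            preds.append(ytr.mean())
            continue
        A = np.column_stack([np.ones(len(Xtr)), Xtr])
        beta = np.linalg.solve(A.T @ A, A.T @ ytr)
        preds.append(beta[0] + xte @ beta[1:])
    return np.array(preds)
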