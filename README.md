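# esec — Ensemble Steric and Electrostatic Chirality descriptors

`esec` computes conformation-dependent chiral molecular descriptors and
reduces them over conformational ensembles into a fixed-length, conformation-
independent fingerprint, then builds quantitative structure–enantioselectivity
(QSER) models on top. It is aimed at separation scientists and computational
chemists who want to predict which enantiomer of a chiral drug elutes first
on a chiral stationary phase (CSP), and by how much, from simulated
conformational ensembles alone.

## The descriptors

For a conformation with atoms at positions **r**<sub>i</sub> (Å, centered on
the center of mass), each atomic attribute *x* (mass, force-field or
Gasteiger partial charge and their absolute values, polarizability,
p-orbital/HB-donor/HB-acceptor indicators and their linear combinations
hb = ha + hd, da = hd − ha) defines a first-order moment vector — a
generalized dipole:

    v_x = Σ_i x_i r_i

(the mass vector uses an asymmetry-weighted form, Σ m_i r_i (m_i‖r_i‖) /
Σ m_i‖r_i‖, because the plain mass moment of centered coordinates vanishes).
A chiral descriptor is a scalar triple product of three such vectors,
normalised to the dimension of a length:

    abcdef = ((v_ab × v_cd) · v_ef) / (‖v_ab‖ ‖v_cd‖ ‖v_ef‖)^(2/3)

A triple product is a pseudoscalar: it is invariant under rotation and
translation but changes sign under reflection, so it vanishes for achiral
geometries and takes exactly opposite values on enantiomers. Of the
11!/(8!·3!) = 165 unordered vector triples, 22 redundant combinations (two
charge models of the same quantity; three or more of the linearly dependent
hydrogen-bond vectors) are excluded, leaving **143** pure triples.

Molecular shape contributes 24 more descriptors. Complete-linkage clustering
of the atomic coordinates into exactly four clusters yields an ordered chain
of centroids A–B–C–D (A, D the farthest pair; orientation fixed by
|AB||AC| < |BD||CD|); the signed chain dihedral gives the twist descriptor

    stwist = ‖v‖ ‖w‖ sin(θ_ABCD) / ‖q‖

with v, w the offsets of A and D from the BC axis and q = BC→. `ftwist` is
the same quantity on the hydrophobic atoms only. The outer/inner shape
vectors so = AD→, si = BC→ (and fo, fi for the hydrophobic chain) combine
with each moment vector into 11 `sosixx` and 11 `xxfifo` triples. In total:
**167** conformation-dependent descriptors.

Over an ensemble of snapshots (optionally carrying per-frame sampling
weights, e.g. from enhanced-sampling MD), each descriptor is reduced to an
**averaged** value (the weighted ensemble mean) and a **windowed** pair

    abcdef± = Σ_t w_t f_±(s·abcdef(t)) / Σ_t w_t,   s = 1/max_t|abcdef(t)|

whose window functions satisfy f₊(−x) = f₋(x), so enantiomers have negated
averaged values and swapped (+, −) windowed values. That yields
167 + 334 = **501** conformation-independent descriptors per molecule.

The QSER layer models the selectivity factor α_RS = k_R/k_S (or log₁₀ α_RS)
by forward stepwise multiple linear regression on autoscaled descriptors,
chooses the model complexity from the leave-one-out cross-validation error
curve (interior minimum, else a ΔRMSECV ≤ 0.02 / bending-point anchor
followed by an F(0.05, N, N) criterion), reports RMSEC, RMSECV, their
range-normalised versions, r², q² and the mean percentage α_RS prediction
error, scores predictions on three schemes (±0.05 accuracy band,
[0.95, 1.05] separated/unseparated band, elution sequence), and flags
molecules outside a kNN applicability domain (k = round(n^⅓), threshold =
mean + 2·SD of training neighbour distances).

## Worked example

```python
from esec import compute_ensemble_descriptors, mirror
from esec.synthetic import make_chiral_toy

r = make_chiral_toy(seed=0, n_frames=500)   # right-handed helical toy
s = mirror(r)                               # its exact enantiomer
dr = compute_ensemble_descriptors(r, burn_in=20, set_label="IV")
ds = compute_ensemble_descriptors(s, burn_in=20, set_label="IV")
for name in ("msagpi", "stwist", "ftwist"):
    print(f"{name:8s}  R: {dr.averaged[name]:+.4f}   S: {ds.averaged[name]:+.4f}")
print(f"stwist+   R: {dr.windowed['stwist+']:.4f}   S: {ds.windowed['stwist+']:.4f}")
print(f"stwist-   R: {dr.windowed['stwist-']:.4f}   S: {ds.windowed['stwist-']:.4f}")
```

prints

```
msagpi    R: +0.0887   S: -0.0887
stwist    R: +1.6896   S: -1.6896
ftwist    R: +1.6366   S: -1.6366
stwist+   R: 0.5569   S: 0.0434
stwist-   R: 0.0434   S: 0.5569
```

The averaged descriptors negate exactly between enantiomers; the windowed
(+, −) pair swaps. The positive mean twist (≈ +1.69 Å) reflects the
right-handed helical scaffold of the toy; its mirror image is left-handed.

The same pipeline is available from the shell:

```sh
esec fixtures --seed 7 --outdir fixtures        # synthetic test data
esec compute fixtures/helix_R.xyz fixtures/helix.attributes.tsv \
     --weights fixtures/helix_R.weights --burn-in 20 -o R.csv
esec model matrix.csv responses.csv --response log-alpha -o report.json
esec domain matrix.csv --model-report report.json
```

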