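# Methods

This note documents the models and procedures implemented in `esec`, the
numerical conventions chosen where the design was genuinely open, what the
synthetic fixtures do and do not emulate, and the known limitations.

## Conformation-dependent descriptors

**Moment vectors.** All moment vectors are computed on coordinates translated
so that the center of mass is at the origin. Centering removes the
translational variance that any moment Σ x_i r_i acquires when Σ x_i ≠ 0 (the
classical net-charge dipole problem); the center of mass is used because it is
the physically distinguished choice for the dipole of a charged species. The
eleven vectors are: the mass-asymmetry vector (see below), force-field and
Gasteiger dipoles (`ch`, `gs`), their absolute-charge polarity analogues
(`ac`, `ag`), polarizability (`al`), p-orbital/aromaticity (`pi`), hydrogen-
bond donor hydrogens (`hd`), acceptors (`ha`), and the derived combinations
`hb = ha + hd` and `da = hd − ha`. The `da` sign convention (+1 donors,
−1 acceptors) is fixed and documented here; flipping it would negate the
affected descriptors globally and cannot change model quality.

**Mass asymmetry.** With centered coordinates the plain mass moment is
identically zero, so the mass vector is v_ms = Σ m_i r_i (m_i‖r_i‖) /
Σ (m_i‖r_i‖) — a (m‖r‖)-weighted mean of the m·r terms that emphasises heavy
atoms far from the center. A useful consequence tested in the suite: for any
two-atom system this vector vanishes identically.

**Triple products.** abcdef = ((v_ab × v_cd)·v_ef)/(‖v_ab‖‖v_cd‖‖v_ef‖)^(2/3).
The exponent 2/3 reduces the dimension to a length, which improves robustness
to small conformational changes. When any constituent vector is null (e.g. a
molecule with no HB donors) the numerator vanishes too; the 0/0 limit is
defined as 0 so descriptor matrices stay rectangular across heterogeneous
chemistry, and null vectors are reported per molecule. Of the 165 unordered
triples, 22 are excluded: 9 containing both `ch` and `gs`, 9 containing both
`ac` and `ag` (the same physical quantity from two charge models), and 4
containing three or more of {`hd`, `ha`, `hb`, `da`} (any such triple is
linearly dependent because `hb` and `da` are linear combinations of `hd` and
`ha`). The enumeration test re-derives 143 by brute force. Names concatenate
the two-letter codes in the fixed table order (`msagpi`); since a scalar
triple product is invariant under cyclic permutation, the canonical order
also fixes the sign convention.

**Shape coarse-graining.** Conformations are clustered by complete linkage
(SciPy) with the dendrogram cut at exactly four clusters; cluster centers are
the arithmetic centroids of the member coordinates (a literal coordinate-wise
geometric mean is undefined for negative coordinates, so "geometric center"
is implemented as the centroid). The farthest pair of centers are the chain
ends; the end with the smaller |AB|·|AC| product is A; of the two middle
centers, B is the one nearer A. Exact ties (measure-zero for real
conformations) fall back to the lowest member atom index, making the chain
deterministic on symmetric toys. The twist stwist = ‖v‖‖w‖ sin(θ_ABCD)/‖q‖ is
computed with sin θ taken directly from the plane normals
((n₁×n₂)·q̂/‖n₁‖‖n₂‖), which negates bit-exactly under reflection of the
inputs. The dihedral sign follows the IUPAC convention as implemented by
MDAnalysis `calc_dihedrals`, against which it is validated in the tests;
under this convention a right-handed helical chain has positive twist. The
chain orientation ambiguity (ABCD vs DCBA) does not affect any descriptor:
the dihedral is reversal-invariant and both shape vectors so = AD→, si = BC→
flip together in the shape triples. Frames whose clustering is degenerate
(fewer than four atoms in the subset, or coincident points collapsing the
dendrogram) yield NaN and are excluded from ensemble statistics with their
weights renormalised; counts are reported.

## Ensemble reduction

Averaged descriptors are weighted arithmetic means over defined frames.
Windowed descriptors scale each series by s = 1/max|value| (computed after
burn-in over defined frames; identical for both enantiomers by construction,
which preserves the swap property) and average f_±(s·value). The window pair
must satisfy f₊(−x) = f₋(x). The default is the one-sided linear ramp
f_±(x) = max(±x, 0)^p with p = 1 — it vanishes on the opposing half-axis, so
the (+) value is the one-sided first moment of the scaled distribution — and
the exponent and a smooth half-cosine alternative are configuration options
so other window shapes can be dropped in. Burn-in discards the first
n frames before any statistic (matching the practice of dropping the
equilibration segment of an MD trajectory; e.g. 200 of 200,000 frames for a
0.5 ps-sampled 100 ns run). The running weighted mean is exposed as the
convergence diagnostic. Across-molecule standardization uses Z-scores with
the sample SD (n − 1); zero-variance columns are dropped and reported.

Eight descriptor-set labels (I–VIII) record provenance: protonation state
(pH 9 vs uncharged), generating solvent model (implicit water, implicit
water/ACN, explicit water/ACN), and whether per-frame weights were applied.

## QSER modelling

Predictors are autoscaled before selection. Forward stepwise MLR enters, at
each step, the candidate with the smallest partial-F p-value if it is below
α_enter (default 0.05); terms whose p-value rises above α_remove (default
0.10) are then dropped, except the term that just entered — this exemption,
together with using max(α_remove, α_enter) as the effective removal
threshold, prevents enter/remove cycling when α_enter is raised (it is
raised in 0.05 steps whenever fewer than 15 nested models result, so the
complexity-selection rule has enough curve to work with). Coefficients are
refit by OLS at every step.

Model complexity is chosen from the LOOCV error curve: a genuine interior
minimum (the curve rises again afterwards) is taken directly; otherwise the
first complexity where the relative RMSECV drop reaches ≤ 0.02 — or, if that
never happens, the knee of the curve by maximum chord distance — anchors a
window, the mean squared RMSECV of the next 10 complexities defines a
critical variance via the F(0.05, N, N) quantile (N = training-set size), and
the simplest model whose RMSECV² does not exceed it is selected. When fewer
than 10 complexities exist beyond the anchor the available tail is averaged
and a warning is emitted.

LOOCV refits the autoscaling inside every training fold by default
(fold-honest scaling keeps q² unbiased and makes predictions invariant to
affine rescaling of raw columns; scaling once globally is available as an
option since either convention is defensible). Metrics: RMSEC, RMSECV, both
normalised by the experimental response range; r² on fitted and q² on
cross-validated predictions; the mean percentage prediction error is always
reported on the α_RS scale — in log mode predictions are back-transformed
with base-10 (the convention used for selectivity factors in
chromatography). The three evaluation schemes are: accurate when
|α_pred − α_exp| ≤ 0.05; separation correct when experiment and prediction
fall on the same side of the [0.95, 1.05] band; elution sequence correct
when both lie on the same side of 1.0, with experimentally unresolved
molecules excluded from the denominator.

The applicability domain uses mean Euclidean distance (on the model's
selected, scaled descriptor columns) to the k = round(n^⅓) nearest training
neighbours, self excluded; the threshold is the training mean + 2·SD,
i.e. roughly 95% coverage under normality.

## Synthetic fixtures

The generators replace MD-sampled drug ensembles with geometric surrogates;
descriptor correctness depends only on geometry and attributes, so nothing
is lost for testing the pipeline, but the fixtures do not emulate force-field
energetics, solvent structure, realistic torsional barriers or the
autocorrelation structure of real trajectories — passing tests therefore
validate the mathematics and software, not the chromatographic predictivity
of any particular simulation protocol.

* `make_chiral_toy`: a 14-atom single-handed helix, flexed by Gaussian
  torsion perturbations (σ = 0.15 rad per internal bond) plus isotropic
  coordinate jitter (σ = 0.05 Å), 500 frames by default, with log-normal
  per-frame weights standing in for enhanced-sampling weight factors. The S
  enantiomer is the exact frame-by-frame mirror image of the R ensemble, so
  symmetry tests are exact rather than statistical.
* `make_achiral_toy`: a planar scaffold with strictly in-plane jitter; every
  moment and shape vector lies in the molecular plane, so all 167 per-frame
  descriptors are exactly zero — the sharpest possible nullity control.
* `make_qser_dataset`: n = 43 molecules (a realistic chiral test-set size)
  × p = 100 descriptors in blocks of 5 with within-block correlation 0.5,
  mimicking the strong redundancy among related chiral descriptors; the
  response is y = Xβ + ε with 5 nonzero coefficients of random sign and
  magnitude U(0.5, 1.5), one per block, and noise calibrated to
  Var(Xβ)/Var(ε) = 10. These defaults were fixed once as the study
  conditions for the recovery simulations. At these settings exact recovery
  of the full support within the first five selections occurs in roughly
  80% of replicates — the remaining failures are a genuine small-sample
  effect (a 0.5-correlated block sibling or one of 95 noise columns
  overtaking the weakest true predictor at n = 43), not an algorithmic
  defect: the per-predictor selection rate is ≈ 95% and recovery is exact
  as σ → 0.

## Numerical notes

* Enantiomer antisymmetry is exact in floating point (negating one
  coordinate axis negates every triple product bit-for-bit and leaves all
  interatomic distances bit-identical, so clustering is unchanged), which is
  why the symmetry tests can use 1e−9 absolute tolerances comfortably.
* Zero-norm moment vectors give descriptor 0 by the defined 0/0 limit;
  degenerate cluster chains (B = C, or an end on the BC axis) give twist 0.
* The multi-frame XYZ writer uses 8 decimal places (round-trips to < 1e−6 Å);
  the fixed-width PDB format is limited to 1e−3 Å.
* The F and t quantiles come from SciPy; complete-linkage clustering from
  SciPy's hierarchy module (an independent naive implementation exists in
  the test suite as an oracle); kNN distances from scikit-learn.

## Limitations

* Attributes are supplied as an input table; the optional RDKit helper that
  fills Gasteiger charges and heuristic donor/acceptor/aromatic/hydrophobic
  flags is an approximation of force-field-type-based assignment and is not
  a substitute for curated atom typing.
* The window-function form is a configurable default (linear ramp), chosen
  for its symmetry and interpretability; alternative shapes plug in through
  `WindowFunctionPair`.
* No MD engine integration: ensembles come from files (multi-model PDB,
  multi-frame XYZ) or the synthetic generators. Binary trajectory formats
  (DCD/XTC) are out of scope for the core.
* Single-system modelling only; PLS and PCA-based applicability domains are
  not implemented.
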