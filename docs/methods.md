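# Methods

This document records the algorithms, their parameter defaults and the
reasoning behind the numerical choices. Nothing here claims empirical
performance beyond what the test suite and `scripts/acceptance.py`
actually compute.

## Molecular graphs (`moltk.graph`, `moltk.sdf`)

Molecules are stored hydrogen-suppressed with integral kekulized bond
orders {1, 2, 3} and separate per-atom/per-bond aromatic flags. Rationale:
integral orders keep valence arithmetic exact (implicit hydrogen counts,
molecular weight), while the flags preserve the chemistry needed for
aromatic-aware matching.

- Ring perception: smallest set of smallest rings via shortest-path ring
  closure over the cycle space; aromaticity by Hückel 4n+2 π-electron
  counting per SSSR ring, with lone-pair donors (pyrrole N, furan O,
  thiophene S) contributing 2 electrons.
- Kekulization of order-4 (aromatic) SDF input: maximum matching over the
  aromatic subgraph assigns alternating double bonds; a perfect matching is
  required in strict mode.
- SDF: V2000 only, gzip-transparent, `M  CHG` blocks, multi-line data
  fields. Writing with `explicit_aromaticity=True` emits order 4 for
  aromatic bonds; reading either form yields identical graphs.

## Descriptors (`moltk.descriptors`)

Descriptor text is parsed into a tree of operators (`Combine`, arithmetic,
comparison, `Molecule*` statistics, autocorrelations) over named atomic or
molecular properties. Parentheses, brackets and braces are interchangeable;
`Define(alias = ...)` introduces aliases and `@file` includes files.

### Partial charges (PEOE)

Six iterations of electronegativity equalization with damping factor
0.5^k, χ(q) = a + b·q + c·q², hydrogens folded into their heavy atom.
Parameters are the published PEOE electronegativity table, extended with
the published S(sp2) row (10.88, 9.49, 1.33). Hybridization typing: sp from
triple bonds/cumulated doubles, sp2 from double bonds or aromaticity, and —
important for agreement with reference implementations — a lone-pair N/O/S
attached to an aromatic atom or to a multiply-bonded neighbor is typed sp2
(conjugated donor: aniline N, amide N/O, ester O). Six iterations is where
the geometric damping makes further updates numerically negligible while
matching the historical convention.

### TPSA

Ertl fragment contributions for N/O (and the polar S/P extension) keyed on
element, charge, aromaticity, attached hydrogens and bond pattern. Water
scores 0: it has no published fragment, and inventing a fallback increment
would silently change sums. This is a deliberate domain restriction;
isolated water is outside the intended drug-like domain.

### Autocorrelations (2DA/3DA)

Ordered atom pairs including i = j. 2DA uses unit bins on bond-count
distance (default 11 steps); 3DA uses 0.25 Å bins (default 24 steps) with
triangular smoothing: a pair at distance r contributes weight 1 − |x − b|
to bins b, where x = r/width − 0.5, i.e. bin centers sit at
(b + 0.5)·width. Weight that falls below bin 0 (half of each self-pair) is
dropped rather than reflected, keeping the transform linear. Sign-split
variants route each product p(i)p(j) into −/−, +/+ or mixed sub-bins; the
mixed sub-bin keeps its negative sign so the three sub-bins sum exactly to
the unsigned profile.

## Similarity (`moltk.similarity`)

MCS via maximum clique on the modular product graph: vertices are
atom-compatible pairs; a *strong* edge joins two pairs whose bonds exist
and match on both sides, a *weak* edge joins pairs with no bond on either
side. Non-induced (common-substructure) matching additionally tolerates a
bond on one side only. The connected search (Koch's c-clique
branch-and-bound) requires the growing clique to stay strong-connected;
`connected=False, min_piece<=1` runs the exact unconstrained clique search;
`min_piece>=2` extracts connected pieces greedily (largest first, matched
atoms removed) and keeps pieces of at least that size — small accidental
fragments would otherwise inflate similarity.

Matching levels: atoms by `ElementType` (default) or `AtomType`
(element + charge + aromaticity + degree); bonds by `BondOrderOrAromatic`
(default: aromatic matches aromatic, non-aromatic bonds match regardless
of kekulized order) or strict `BondOrder`. The default bond level treats a
Kekulé structure as an artifact of perception, not chemistry.

`rmsd`/`symmetry_rmsd` are in-place (no superposition); `symmetry_rmsd`
minimizes over heavy-atom graph automorphisms, which removes the
arbitrary atom numbering of symmetric structures. Rigid superposition is a
separate operation (`kabsch_superimpose`, SVD with reflection guard).

## Datasets (`moltk.dataset`)

Feature matrices are float32 on disk ("partial binary" `.bin`: ASCII
header + little-endian payload + per-result presence mask) and float64 in
arithmetic. float32 halves storage for screening-scale datasets while the
mask distinguishes "missing" from "zero". CSV writing uses
shortest-round-trip formatting so `.csv` round trips are float32-exact
too. Transformations: seeded shuffling, contiguous chunking (the basis of
cross-validation), row/column combination, minor-class oversampling
(`balance`), PCA (covariance eigendecomposition, keep the smallest k with
cumulative variance ≥ fraction) and seeded k-means++ with Lloyd
iterations.

## Models (`moltk.models`)

All estimators: `fit`/`predict`, `get_params`/`set_params`, fitted state
in trailing-underscore attributes, JSON text serialization
(`model_save`/`model_load`).

- **NeuralNetwork.** Sigmoid (default), Rectifier (leak 0.05) or Linear
  transfer; weight init U(−0.5, 0.5); classical momentum update
  Δw_t = −η ∇MSE + α Δw_{t−1} with defaults η = 0.05, α = 0.5; minibatch
  size `steps_per_update` (0 = full batch); inverted-dropout at train time
  with (1 − p) weight scaling at test time so p = 0 is exactly the
  identity; masked results contribute zero gradient; optional monitor set
  keeps the best epoch under `objective`. Input scaling `AveStd` (default),
  `MinMax` or `none`.
- **DecisionTree.** Best-first expansion, split candidates at midpoints of
  consecutive unique feature values, partitioners InformationGain, Gini,
  ROC (balanced accuracy of the two-leaf split) and Sequence
  (pure-child-only). `dt_to_logic` exports a fitted tree both as readable
  if/else text and as a descriptor expression
  (`Add` of `Multiply` of `Less`/`Greater` conditions) that reproduces the
  tree's ≥ 0.5 decisions; inputs exactly equal to a threshold follow the
  "greater" branch in both forms.
- **LinearRegression.** Ridge normal equations (X'X + λI) by Cholesky,
  unpenalized intercept via centering; λ = 0 refuses ill-conditioned
  systems (condition number > 1e12) with guidance to set `smoothing`.
- **KohonenMap.** Rectangular SOM; radius decays linearly,
  radius(t) = radius₀·(1 − (t + 1)/(4·length)), reaching exactly 0 at the
  final iteration (defaults radius₀ = 7.5, length = 140 ⇒ 7.48661 at
  t = 0). Updates: BMU weight 0.8, in-radius neighbors 0.2, Bubble
  (α = 1) or Gaussian (α = e^(−d²/2r²)) kernel, batch-averaged.
  `freeze_radius = 0` with the Bubble kernel reduces the update to
  winner-only online k-means — a degenerate case used as a correctness
  anchor. Applicability domain: `ad_score(x)` is the fraction of training
  rows whose own nearest-node distance is strictly below x's, so scores on
  the training set are approximately uniform on [0, 1] by construction.

## Objectives (`moltk.objectives`)

Contingency-based metrics (accuracy, PPV, MCC — MCC defined as 0 when a
margin is empty), enrichment at top-x% (prevalence-normalized, so
EF(100%) = 1 identically), ROC with tie grouping, and windowed AUC. The
log-x-axis AUC integrates TPR against log₁₀ FPR over [min_fpr, max_fpr]
(defaults 0.001–0.1) normalized by the log-span; for the chance diagonal
TPR = FPR on [a, b] the closed form is (b − a)/ln(b/a), numerically
0.099/ln(100) ≈ 0.0215 on [0.001, 0.1]. The trapezoid runs over the raw
curve points with duplicate FPR values retained, because collapsing a
vertical segment to one interpolated point biases the area on tied
predictions. `local_ppv_fit` estimates a calibration curve by
sliding-window PPV (window = max(50, 1% of rows)) followed by
pool-adjacent-violators isotonic smoothing.

## Cross-validation (`moltk.cv`)

`run_cv` trains one model per fold on a pre-randomized dataset, uses the
held-out chunk as both monitor and independent set, pools independent
predictions (each row exactly once) and scores them with the final
objective. Storage layout: `<prefix>NNNNNN.model`,
`<prefix>NNNNNN.predictions.csv`, `<prefix>.pooled.csv`,
`<prefix>.log_merge.txt`, `<prefix>.features` (the descriptor text) and
`<prefix>.calibration` (localPPV JSON). Stored model committees can be
re-entered into the descriptor engine: `prediction_mean_property` yields
the committee-mean prediction of a molecule as a descriptor leaf and
`prediction_info_property` maps it through the stored calibration, so
expressions like `Multiply(PredictionMean, Greater(lhs = PredictionInfo,
rhs = 0.5))` gate predictions by calibrated confidence.

## Synthetic data (`moltk.fixtures`)

`synthetic_qsar` emulates a screening dataset with a known generating
rule: standard-normal features, latent score w·x (optionally tanh-squashed
for a bounded nonlinear response), Gaussian noise, and — for
classification — a threshold placed so that exactly `n_actives` rows are
active (defaults 50 actives / 450 inactives mirror the heavy class
imbalance of real screens). Returning the generating weights and threshold
enables parameter-recovery tests (e.g. cosine similarity between fitted
and true weights) that real datasets cannot support. `random_molecule`
grows seeded valence-legal C/N/O graphs for fuzzing parsers and
graph algorithms.

## Limitations

- Aromaticity perception covers single SSSR rings; macrocyclic or fused
  borderline aromatic systems outside the bundled chemistry are not
  guaranteed.
- TPSA returns 0 for atoms without a published fragment (e.g. isolated
  water) instead of approximating.
- PEOE parameters cover H, C, N, O, F, Cl, Br, I, S, P in common
  hybridizations; exotic elements raise an error rather than guessing.
- The MCS exact searches are exponential in the worst case; the greedy
  multi-piece mode trades optimality for speed and may under-report the
  true disconnected optimum on adversarial inputs.
- 3D descriptors require coordinates in the input; no conformer generation
  is included.
- The SOM applicability-domain score is a rank statistic of one distance;
  it does not model density anisotropy.
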