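# Methods

## Site definition from interaction fingerprints

A ligand instance's fingerprint is the set of UniProt residue numbers of
chain residues with any heavy atom within a cutoff of any ligand heavy
atom.  The cutoff (default **4.5 Å**) is a plain distance-threshold
stand-in for a full interatomic-contact typing tool; it is configurable
and no interaction types (H-bonds, π-stacking, …) are assigned.  A
contacting residue without a UniProt mapping is an error, not a silent
omission: fingerprints must be complete in UniProt space because site
identity lives there.  Working in UniProt numbering is what allows
interfaces to be aggregated across structures of one protein with no
structural superposition.

Similarity of two fingerprints is the relative intersection
I_rel = |A ∩ B| / min(|A|, |B|), i.e. the observed intersection relative
to the maximum attainable one — the only normalisation that keeps
I_rel ∈ [0, 1] with I_rel(A, A) = 1.  Instances with *identical*
fingerprints are collapsed first (interface multiplicity is recorded),
then average-linkage hierarchical clustering runs on D = 1 − I_rel and the
tree is cut at **D = 0.5**.  Boundary convention: a pair at cophenetic
distance exactly 0.5 merges (the `fcluster` "distance" criterion); the
alternative (strict inequality) is not distinguishable from published
descriptions, so the inclusive reading was chosen and is exposed through
the `cut` parameter.  Groups are sorted by (minimum residue, size,
lexicographic fingerprint) before linkage so the clustering is invariant
to input order.  Ligands with empty fingerprints are excluded with a
warning — the distance is undefined for empty sets.

The observed-site centroid used for distance-based evaluation is the
unweighted mean of the heavy atoms of the site's residues found on the
evaluation chain.  A ligand-atom-based centroid would privilege one
member ligand of a site aggregated over many; the residue-based choice is
canonical for the aggregated object.  Ligand-atom distances are still
available separately as DCA.

## Chain geometry

Chains are centred on the unweighted heavy-atom centre of mass (no mass
weighting — coordinates are averaged directly) and rotated so the largest
principal component lies on Y, the second on X, and their cross product
on Z.  The rotation is built from rows (pc2, pc1, pc1 × pc2), which has
determinant −1, and multiplied by the negative identity to restore a
proper rotation: det(R) = +1 for every valid input, so chirality is never
flipped.  Eigenvector signs are pinned (largest-magnitude entry positive)
to make the frame deterministic.  Width/height/depth are reported as the
standard deviation of the aligned coordinates per axis (square root of
the PCA eigenvalues), keeping Å units.

Size descriptors: Rg = sqrt(mean ‖r − CM‖²); the enclosing sphere is
centred on the CM with R = max ‖r − CM‖ (deliberately *not* the minimal
enclosing sphere) and volume 4/3 π R³.  The chain volume for the volume
ratio VR = V_chain / V_sphere comes from the package's own grid engine:
lattice points within the van der Waals radius of any heavy atom, 1 Å
spacing, radii from gemmi's element table.  Chains with VR ≤ **0.08** are
elongated, chains of ≤ **100** residues tiny; both thresholds inclusive
(the "≤" phrasing of the classification), giving four classes.  Chains
with fewer than three non-collinear atoms are reported unclassified
rather than failing a pipeline run.

## Pocket characterisation and redundancy

Pockets missing a reported residue set get one from geometry: residues
with any heavy atom within **6 Å** of the pocket's points (cloud/grid
points, or the centroid for centroid-only methods).  An empty result is
legitimate and flagged, not raised.  Centroids of residues-only pockets
are the mean of pocket-residue heavy atoms; of point-cloud pockets, the
mean of the points.

Two pockets are redundant when their centroids are ≤ **5 Å** apart or
their residue Jaccard index is ≥ **0.75**.  The published descriptions
use both "> 0.75" and "at least ¾"; the inclusive reading is implemented
and both thresholds are parameters.  Removal is a greedy sweep in
descending score order (ties: original rank, then pocket id): a pocket is
kept iff it is not redundant with an already-kept one — this is exactly
"always keep the higher-scoring pocket" and makes the operation
idempotent with a pairwise non-redundant output, which the test suite
checks explicitly.  Survivors are re-ranked 1..k.  Unscored inputs fall
back to rank order as the score proxy, with a warning.

## Scoring schemes

Ensemble residue ligandability is the arithmetic mean of per-model
binding probabilities (default width 40, configurable so tests need not
build 40 models).  Atom-scored methods collapse to residues by the
maximum over the residue's atoms.  Pocket re-scoring schemes: residue
count (`aa_count`), sum of squared residue ligandability scores
(`ss_residue`, over the pocket's 6 Å-derived residue set), sum of squared
grid-point scores (`ss_grid`), or the method's native scores (`native`).
Pocket residues without a ligandability score contribute 0 to the sum of
squares — conservative and monotone; a missing score never boosts a
pocket.  Re-ranking is a stable descending sort with ranks reassigned
1..n and is idempotent.

## Grid volumes

All volumes live on one global lattice: points at integer multiples of
the spacing (default **1 Å**), anchored at the origin.  Because every
volume shares this lattice, intersections are exact set operations and
relative volume overlap RVO = |V_pred ∩ V_obs| / |V_obs| needs no
alignment.  RVO is undefined (and excluded from means) when the observed
volume is empty.

A pocket volume starts from the smallest axis-aligned prism containing
the pocket atoms, centred on the pocket centroid; degenerate axes are
padded +1 Å so flat pockets still enclose lattice points.  Lattice points
clashing with protein heavy atoms (within vdW radius + **1.09 Å**
padding, configurable) are deleted, points outside the convex hull of the
pocket atoms are deleted (points exactly on the hull kept; with fewer
than four non-coplanar pocket atoms the hull filter is skipped), and
finally only the 26-connected lattice component(s) reachable from seed
points within **5 Å** of the centroid are retained.  The clash padding
and connectivity rule are implementation choices where the published
protocol is silent; no exclusion regions are used.  The same engine
supplies chain volumes (points within vdW radius of any atom) for the
shape classification above — it does not attempt to reproduce any
probe-based reference volume algorithm exactly, only to be internally
monotone and consistent.

## Evaluation

Residue level: hard labels give confusion counts, F1 and MCC with the
degenerate-denominator → 0 convention (no predicted positives, or
single-class truth, score 0).  Score tracks give ROC and PR curves on a
shared grid of 101 thresholds in [0, 1] for probability-like tracks; for
unbounded tracks the per-chain score quantiles define the grid.  A
residue is positive when LS > t (strict).  AUC integrates TPR over FPR
along the descending-threshold traversal of the curve; AP sums
precision-weighted recall increments.  Chains with single-class truth are
excluded from curve means with a reason.  Mean curves are pointwise means
across chains at each grid threshold; mean AUC/AP are means of per-chain
values.  Precision at thresholds with no predicted positives is defined
as 1 (the conventional PR-curve endpoint).

Pocket level: N is the number of observed sites of the protein, and
predictions are restricted to the top-(N+X) window (default X = 2) by
rank.  For each site the best windowed prediction is the one minimising
DCC (or maximising I_rel when residue overlap is the criterion); the site
is recalled when DCC ≤ **12 Å** (I_rel ≥ 0.5).  The threshold is a
parameter (a 4 Å setting reproduces the conservative variant).  A
windowed prediction counts as correct for precision when it lies within
the threshold of *any* observed site centroid — so each redundant
duplicate counts separately, which is precisely how redundancy inflates
pre-removal precision; a prediction within the threshold of two sites is
counted once.  Dataset-wide: predictions are pooled across chains, sorted
by descending score, and summarised by the cumulative TP/FP curve
truncated at 100 false positives and by the precision of the top 1000;
with fewer predictions the available count is used and flagged.
Descriptive metrics carry no multiple-testing correction; a two-proportion
z-test utility supports pairwise method comparisons at α = 0.05.

## Synthetic fixtures

Generators are pure functions of their spec (seed included): repeated
calls are bit-identical.  The backbone is an ideal helix — rise 1.5 Å,
radius 2.3 Å, 100° twist per residue — with one CA and one outward CB
pseudo-atom per residue.  This is deliberately not a physical protein
model: it provides closed-form, non-degenerate 3-D geometry for contacts,
centroids, alignment and grids at negligible cost.  Site windows are
disjoint residue ranges separated by at least two residues; one
pseudo-ligand atom sits 1.2 Å outside each window residue's CB, far
enough (> 4.5 Å) from all neighbouring residues that the fingerprint
equals the window exactly at zero jitter and stays inside it for the
default 0.25 Å jitter.  Defaults: 100 residues, 3 sites of 8 residues.

Prediction sets are built with margins that make correctness a
constructed property: "correct" centroids are within half the DCC
threshold of a site centroid (Gaussian noise, default σ = 2 Å, rescaled
into the margin), "false" ones sit on the helix-axis extension at more
than twice the threshold from every site, "redundant" ones within 2 Å of
their parent with strictly lower scores.  Score models: `calibrated`
draws correct scores around 0.5 + s/2 and false around 0.5 − s/2
(separation s defaults to 0.4, controlling ranking quality),
`anti_correlated` swaps them, `constant` is uninformative — the model
under which top-k precision estimates the generating correct fraction,
used for the parameter-recovery test.  What passing tests on these
fixtures shows: the metrics, clustering and redundancy logic are
algorithmically correct.  What they cannot show: behaviour on real
side-chain packing, solvent-exposed cavity shapes, or biologically
relevant ligand chemistry — none of which the helix fixture emulates.

## Problem sizes and determinism

The test suite runs the exhaustive F1/MCC oracle over all 2⁸ × 2⁸
8-residue label pairs, AUC-vs-pair-counting on score sets of ≤ 12 points
(scores on the 0.01 grid so the default threshold grid resolves every
step), ranking-curve recounts on 2000-prediction sets, and site-recovery
over 200 random fixture specs — a few seconds in total.  Property tests
(hypothesis) run derandomised.  The acceptance script's seed applies a
rigid-body shift to the worked configuration; all reported metrics are
invariant to that placement by construction.
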