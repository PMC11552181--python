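# pocketeval

Defining observed protein–ligand binding sites from structural data and
benchmarking binding-site prediction methods against them.

## The problem

Ligand binding-site predictors are usually judged against a single
protein–ligand complex, but a protein's binding capability is spread over
many structures, assemblies and ligands — and the same protein–ligand
interface is often crystallographically duplicated.  `pocketeval`
implements both halves of a rigorous benchmark:

1. **Site definition.**  Every ligand instance is reduced to an
   *interaction fingerprint* — the set of UniProt residue numbers whose
   heavy atoms lie within a contact cutoff (default 4.5 Å) of the ligand.
   Working in UniProt space makes aggregation across structures free of
   any superposition.  Identical fingerprints (the same interface repeated
   across assembly copies or entries) are collapsed, then the unique
   fingerprints are clustered with average linkage on the distance

   D(A, B) = 1 − I_rel(A, B),  I_rel(A, B) = |A ∩ B| / min(|A|, |B|),

   cutting the dendrogram at D = 0.5.  Each cluster is one observed
   binding site (the union of its member fingerprints).

2. **Prediction evaluation.**  Residue level: confusion counts, F1, MCC,
   ROC/PR curves with per-chain means, AUC and average precision from
   ligandability score tracks.  Pocket level: for each observed site the
   best prediction by centroid distance (DCC) inside a top-(N+2) rank
   window; a site is recalled when DCC ≤ 12 Å.  Dataset-wide ranking
   quality via the cumulative TP-vs-FP curve truncated at 100 false
   positives and the precision of the top-1000 predictions.  Shape
   agreement via relative residue overlap (RRO) and relative volume
   overlap (RVO) on a shared 1 Å grid.  Redundant predictions (centroids
   ≤ 5 Å apart or residue Jaccard ≥ 0.75) can be removed greedily,
   keeping the higher-scoring pocket, and pockets re-scored by residue
   count or the sum of squared ligandability scores.

Supporting machinery includes PDB/mmCIF reading (with SIFTS UniProt
cross-references), principal-axis chain alignment with chirality
preservation, radius of gyration, enclosing-sphere volume ratio and
globular/elongated/tiny shape classification, and a deterministic
synthetic-fixture generator used throughout the test suite.

## Worked example

`examples/redundancy_and_evaluation.py` builds a configuration of 5
observed sites and 10 ranked predictions in which ranks 1–7 redundantly
hit the same site:

```
before removal: recall 20% (1/5 sites), precision 100% (7/7 windowed predictions)
redundancy removal: kept 4/10, 60% redundant
after removal:  recall 60%, precision 75%
```

The seven duplicates fill the top-(N+2) window, so only one of five sites
is recalled while every windowed prediction looks correct — an inflated
100% precision.  Removing the duplicates frees the window: recall triples
to 60% and precision drops to an honest 75% (one surviving prediction is a
genuine false positive).  The other examples show fingerprint clustering
(`define_sites.py`) and chain/pocket geometry (`geometry_and_volumes.py`).

A thin CLI mirrors the library: `pocketeval synth | define-sites |
characterise | redundancy | rescore | volume | evaluate` (see
`pocketeval --help`).

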