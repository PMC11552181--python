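"""Why redundant pocket predictions distort precision and recall.

Reproduces the worked configuration: 5 observed sites, 10 ranked
predictions of which ranks 1–7 redundantly hit the same site.  Top-(N+2)
evaluation is misleading before redundancy removal and informative after.
"""
import pocketeval as pe

sites, predictions = pe.redundancy_scenario()

before = pe.match_and_recall(sites, predictions, window="top-N+2")
print(f"before removal: recall {before.recall:.0%} "
      f"({int(before.recall * len(sites))}/{len(sites)} sites), "
      f"precision {before.precision:.0%} "
      f"({int(before.precision * before.n_windowed)}/{before.n_windowed} windowed predictions)")

report = pe.remove_redundancy(predictions)  # centroid <= 5 Å or Jaccard >= 0.75
print(f"redundancy removal: kept {len(report.kept)}/10, "
      f"{report.redundancy_fraction:.0%} redundant")

after = pe.match_and_recall(sites, report.kept, window="top-N+2")
print(f"after removal:  recall {after.recall:.0%}, precision {after.precision:.0%}")

# The seven duplicates of site 1 fill the top-(N+2) window, hiding the
# correct rank-8/9 predictions: recall looks like 20% with a perfect 100%
# precision.  Removing duplicates frees the window: recall rises to 60%
# while precision drops to an honest 75% (one surviving prediction is a
# genuine false positive).
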