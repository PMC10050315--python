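"""Identify four glycans from event-cloud features with five classifiers.

Simulates 40,000 events for each of four glycans, extracts 3x3
equal-frequency-binning features (20 subsets of 2,000 events per glycan),
and runs the repeated stratified evaluation: per cycle an 80/20 split
(16 train / 4 test rows per glycan), 20 cycles per experiment and 2
replicates here to keep the demo quick (the full protocol uses 100 x 10).
"""

import glycopore as gp

library = gp.builtin_library()
names = ["3SL-MPB", "6SL-MPB", "6S2FL-MPB", "LNT-DPE-6SL"]
tables = {n: gp.sample_events(library[n], 40_000, seed=i, with_times=False)
          for i, n in enumerate(names)}

matrix = gp.build_feature_matrix(tables, k=3, subset_size=2_000, seed=0)
print(f"feature matrix: {matrix.X.shape[0]} rows x {matrix.X.shape[1]} features "
      f"({len(matrix.classes)} glycans, 20 subsets each)")

reports = gp.run_replicates(
    tables, gp.default_model_specs(), k=3, subset_size=2_000,
    replicates=2, cycles=20, base_seed=42,
)
for rep in reports:
    print(f"{rep.algorithm:>20s}: F1={rep.f1:.4f}  precision={rep.precision:.4f}  "
          f"recall={rep.recall:.4f}")
print("scores near 1.0 mean the four synthetic populations are fully separable "
      "from their binned event-cloud features; each confusion-matrix row sums to "
      f"{int(reports[0].confusion.sum(axis=1)[0])} accumulated test-set predictions.")
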