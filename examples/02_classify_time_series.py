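"""Fit the six time-series classifier families and print the accuracy grid.

Reproduces the reference-table layout: held-out accuracy per family on the
raw (intensity + patterning) and relative (patterning only) representations,
then classifies one held-out assemblage as a stand-in archaeological query.
"""

from taphoseries import default_profiles, simulate_dataset
from taphoseries.pipeline import run_all, split

dataset = simulate_dataset(default_profiles(30, n_samples_per_class=40, seed=7))
train, test = split(dataset, test_fraction=0.25, seed=7)

query = test.series[0]  # pretend this is an unlabelled archaeological site
report = run_all(train, test, queries=[query], seed=7, with_ensembles=False)

print("held-out accuracy (rows: family, columns: representation)")
print(report.accuracy_table().round(3))
print()
print(f"verdicts for query {query.sample_id!r} "
      f"(true class {test.labels[0]}):")
print(report.verdict_table().to_string(index=False))
print()
print("P = primary access (fully fleshed carcass), S = secondary access;")
print("probabilities are reported only by KNN-DTW (vote fraction) and MTF")
print("(backend class probability), as in the reference table format.")
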