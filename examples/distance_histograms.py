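"""Cell-to-cell distance distributions of a post-confluence field.

Generates a synthetic centroid field -- a dense tumor cluster inside a
spaced normal-cell background -- and prints the same-type pairwise distance
histogram modes plus the normal-cell density in bands of distance from the
tumor cluster with its exponential-decay fit.
"""

from exclusim import (
    SyntheticPatternSpec,
    density_by_distance_band,
    distance_distribution,
    synthetic_point_pattern,
)

pattern = synthetic_point_pattern(SyntheticPatternSpec(seed=11))
n1 = (pattern.cell_type == 1).sum()
n2 = (pattern.cell_type == 2).sum()
print(f"field {pattern.field_um:g} um with {n1} tumor and {n2} normal centroids")

for cell_type, name in [(1, "tumor"), (2, "normal")]:
    dist = distance_distribution(pattern, cell_type, bin_width=5.0)
    print(f"{name}: mode {dist.mode:g} um over {dist.n_pairs} pairs")

summary, (a, lam) = density_by_distance_band(pattern)
print()
print(summary[["band_lo", "band_hi", "n_quadrats", "median_count", "mean_count"]]
      .to_string(index=False))
print(f"\nexponential fit of normal-cell quadrat counts vs distance: "
      f"A = {a:.2f}, lambda = {lam:.4f} per um")
print(
    "\nThe tumor mode sits well below the normal mode: tolerant cells pack"
    "\nat shorter separations, the signature of weak contact inhibition."
    "\nlambda ~ 0 here because the synthetic background is uniform beyond"
    "\nits clearance; experimental fields show a positive decay instead."
)
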