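"""Cluster morphometrics of the simulated tumor phase.

Runs the co-culture chain until tumor clusters form, averages snapshots
into an occupancy heatmap, labels the connected tumor regions and prints
their shape descriptors: area and perimeter (in pixels and micrometres at
the ~93 um^2-per-pixel calibration), Area/ConvexArea and the moment-ellipse
aspect ratio.
"""

from exclusim import ModelParams, cluster_features, label_clusters, occupancy_heatmap, run

snapshot_steps = tuple(range(1_000_000, 1_500_001, 100_000))
params = ModelParams(L=60, seed=4, n_steps=1_500_000, record_every=500_000,
                     snapshot_steps=snapshot_steps)
_, snapshots = run(params)

heatmap = occupancy_heatmap(snapshots, cell_type=1)
labels = label_clusters(heatmap.values >= 0.5)
features = cluster_features(labels)

print(features.round(2).to_string(index=False))
print(
    f"\n{labels.max()} tumor cluster(s) from {heatmap.n_snapshots} snapshots."
    "\narea_um2/perimeter_um use the default 9.64 um pixel side;"
    "\nconvex_hull_ratio <= 1 measures solidity, aspect_ratio >= 1 elongation."
)
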