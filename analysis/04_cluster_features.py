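#!/usr/bin/env python
"""Reduce the feature table by k-medoids clustering under correlation distance.

On the full cohort's features (illustration only — inside the survival CV
the clustering is re-run per training fold), k-medoids with Pearson
correlation distance 1 - R is run 10 times per candidate k; the Silhouette
method picks the optimal cluster count and the medoid features form the
unsupervised reduced pool. Writes results/silhouette_curve.csv.
"""

import numpy as np

from common import CONFIG, get_feature_table, results_dir

from seg2surv.cluster import drop_constant_features, silhouette_sweep


def main() -> None:
    table = get_feature_table()
    keep = drop_constant_features(table.values)
    print(f"{table.n_features} features, {keep.size} non-constant")
    k_opt, curve, results = silhouette_sweep(
        table.values[:, keep],
        range(CONFIG.k_range[0], CONFIG.k_range[1] + 1),
        n_init=CONFIG.n_init,
        seed=CONFIG.stage_seed("cluster-demo"),
    )
    out = results_dir() / "silhouette_curve.csv"
    curve.to_csv(out, index=False)
    best = results[k_opt]
    print(curve.to_string(index=False))
    print(
        f"optimal k = {k_opt} (mean silhouette "
        f"{curve.loc[curve['k'] == k_opt, 'mean_silhouette'].iloc[0]:.3f}); "
        f"medoid columns: {keep[best.medoid_indices].tolist()}"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
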