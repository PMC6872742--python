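#!/usr/bin/env python
"""Harvest bottleneck features and compute conventional PET baselines.

Every patient's CT and PET ROI is pushed through the trained encoders; the
post-ReLU bottleneck activations are flattened (x fastest, channel slowest)
into a patients x features table, CT block first. For comparison with the
learned features, the conventional metabolic burden metrics (SUV_max,
SUV_mean, MTV, TLG = MTV x SUV_mean) are computed over the truth masks.
Writes results/baseline_metrics.csv; the feature table is cached in scratch.
"""

import pandas as pd

from common import get_feature_table, get_patients, results_dir

from seg2surv.features import baseline_metrics


def main() -> None:
    patients = get_patients()
    table = get_feature_table(patients=patients)
    print(
        f"feature table: {len(table.patient_ids)} patients x {table.n_features} features "
        f"({(table.feature_index['modality'] == 'CT').sum()} CT + "
        f"{(table.feature_index['modality'] == 'PET').sum()} PET)"
    )

    rows = []
    for p in patients:
        m = baseline_metrics(p.rois["PET"], p.mask)
        rows.append(
            {"patient_id": p.patient_id, "label": p.label,
             "suv_max": m.suv_max, "suv_mean": m.suv_mean, "mtv": m.mtv, "tlg": m.tlg}
        )
    df = pd.DataFrame(rows)
    out = results_dir() / "baseline_metrics.csv"
    df.to_csv(out, index=False)
    by = df.groupby("label")[["tlg", "mtv"]].mean()
    print(f"mean TLG: dead {by.loc[0, 'tlg']:.0f} vs alive {by.loc[1, 'tlg']:.0f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
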