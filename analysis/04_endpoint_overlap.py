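#!/usr/bin/env python
"""Colocalize the group endpoint map with each subregion ROI via Dice.

Averages the per-subject endpoint maps, binarizes the average at the
chance-level critical count, and computes the Dice coefficient against each
subregion ROI in both modes: the 2D-collapse variant (volumes projected
along the third axis before overlap, for fidelity with legacy pipelines)
and the plain volumetric overlap.  Writes results/dice.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from amyconn import endpoints, overlap, volumes

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    labels = volumes.read_labeled_volume(ROOT / "phantom" / "labels.nii.gz", ROOT / "phantom" / "labels.tsv")
    maps = [
        volumes.read_endpoint_map(p, subject_id=p.name.removeprefix("endpoints_").removesuffix(".nii.gz"))
        for p in sorted((ROOT / "phantom").glob("endpoints_*.nii.gz"))
    ]
    meta = json.loads((ROOT / "null.json").read_text())
    null = endpoints.build_null(meta["lambda_hat"], n_draws=meta["n_draws"], alpha=meta["alpha"], seed=meta["seed"])
    group = overlap.group_endpoint_map(maps)
    endpoint_mask = overlap.threshold_binarize(group, null)

    rows = []
    for lab, (region, hemi) in labels.label_table.items():
        roi = labels.values == lab
        for mode in ("collapse2d", "volume3d"):
            res = overlap.dice(endpoint_mask, roi, mode=mode, region_name=region,
                               threshold_used=null.critical_count)
            rows.append({"region": region, "hemisphere": hemi, "mode": mode, "dice": res.dice})
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "dice.tsv", sep="\t", index=False)

    print(f"group endpoint map thresholded at > {null.critical_count} endpoint(s)/voxel "
          f"({int(endpoint_mask.sum())} suprathreshold voxels)")
    wide = table.pivot_table(index=["region", "hemisphere"], columns="mode", values="dice")
    print(wide.to_string(float_format="%.3f"))
    mean_by_region = table[table["mode"] == "volume3d"].groupby("region")["dice"].mean().sort_values(ascending=False)
    print("volume3d Dice, mean over hemispheres (descending):")
    print(mean_by_region.to_string(float_format="%.3f"))


if __name__ == "__main__":
    main()
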