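#!/usr/bin/env python
"""Validate voxel-mask fraction extraction against geometric phantoms.

Builds planar GM/WM(/CSF) probability-map phantoms with analytically
known fractions inside any axis-aligned MRS box, extracts fractions at
several supersampling levels (including a 30-degree oblique voxel), and
tabulates the discretization error.  Writes results/phantom_fractions.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import segquant as sq
from segquant.synthetic import generate_phantom_maps

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    cases = [
        ("half_split", generate_phantom_maps(),
         sq.VoxelGeometry(np.zeros(3), [30.0] * 3, np.eye(3))),
        ("offset_split_with_csf", generate_phantom_maps(split_x_mm=4.0, csf_z_mm=8.0),
         sq.VoxelGeometry(np.zeros(3), [30.0] * 3, np.eye(3))),
        ("oblique_30deg", generate_phantom_maps(),
         sq.VoxelGeometry(np.zeros(3), [30.0] * 3,
                          Rotation.from_euler("z", 30, degrees=True).as_matrix())),
    ]
    for name, phantom, geom in cases:
        exact = phantom.analytic_fractions(geom).as_array()
        for ss in (1, 3, 5):
            mask = sq.build_voxel_mask(phantom.maps, geom, supersample=ss)
            got = sq.extract_fractions(phantom.maps, mask).as_array()
            rows.append({
                "case": name, "supersample": ss,
                "f_gm": got[0], "f_wm": got[1], "f_csf": got[2],
                "max_abs_error": float(np.max(np.abs(got - exact))),
            })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "phantom_fractions.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    worst = df[df.supersample == 5]["max_abs_error"].max()
    print(f"\nworst-case error at supersample=5: {worst:.4f} (target < 0.01)")


if __name__ == "__main__":
    main()
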