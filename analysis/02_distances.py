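#!/usr/bin/env python
"""Compute the glaciality index and all site-pair distance matrices.

Reads the dataset written by 01_simulate.py, computes the glaciality index
(non-centred PCA of the four harshness variables), attributes glaciality to
segments, and writes the five distance matrices (overland/watercourse x
geographic/altitudinal, plus watercourse glaciality) as labelled CSV.
"""

import argparse
from pathlib import Path

from dendropart.dataset import Dataset
from dendropart.glaciality import (
    assign_segment_glaciality,
    glaciality_distance_matrix,
    glaciality_index,
)
from dendropart.network import (
    overland_altitudinal_matrix,
    overland_distance_matrix,
    watercourse_altitudinal_matrix,
    watercourse_distance_matrix,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/distances"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ds = Dataset.read(args.data)
    index = glaciality_index(ds.env)
    index.to_csv(args.out / "glaciality_index.csv", header=True)
    assign_segment_glaciality(ds.network, index)
    ds.network.segments.to_csv(args.out / "segments_attributed.csv", index=False)

    matrices = {
        "overland_geo": overland_distance_matrix(ds.network),
        "watercourse_geo": watercourse_distance_matrix(ds.network),
        "watercourse_alt": watercourse_altitudinal_matrix(ds.network),
        "watercourse_gla": glaciality_distance_matrix(ds.network, index),
    }
    if ds.raster is not None:
        matrices["overland_alt"] = overland_altitudinal_matrix(ds.network, ds.raster)
    for name, dm in matrices.items():
        dm.to_csv(args.out / f"{name}.csv")
        print(f"{name}: n={dm.n}, max={dm.values.max():.1f}")


if __name__ == "__main__":
    main()
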