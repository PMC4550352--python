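#!/usr/bin/env python
"""Build the spatial eigenfunction sets (MEM and AEM) for every distance
family and write them with their metadata.

Overland and watercourse variables come from Moran's eigenvector maps of
the corresponding distance matrices; downstream variables from asymmetric
eigenvector maps of the flow-directed network.  Overland glaciality is
never built (glaciality does not vary through the air).
"""

import argparse
from pathlib import Path

from dendropart.dataset import Dataset
from dendropart.pipeline import (
    SPATIAL_VARS,
    AnalysisConfig,
    build_spatial_block,
    prepare_distances,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/eigenfunctions"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ds = Dataset.read(args.data)
    cfg = AnalysisConfig()
    dists = prepare_distances(ds, cfg)
    sites = ds.network.site_ids
    for sv in SPATIAL_VARS:
        families = ["geographic", "altitudinal"]
        if sv != "overland":
            families.append("glaciality")
        for fam in families:
            es = build_spatial_block(ds, dists, sv, fam, sites, cfg)
            stem = args.out / f"{sv}_{fam}"
            es.to_csv(f"{stem}.csv", meta_path=f"{stem}.json")
            print(f"{sv}/{fam}: {es.k} positive eigenfunctions")


if __name__ == "__main__":
    main()
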