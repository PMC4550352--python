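"""Bundled analysis inputs and their plain-text on-disk layout.

A :class:`Dataset` holds everything one study needs: the stream network,
an elevation raster, the site environment table, the community abundance
matrix, taxon traits, and (for synthetic data) the generating truth.

On disk a dataset is a directory of plain-text files::

    nodes.csv        node_id,x,y,elevation,is_site,site_class
    segments.csv     segment_id,up_node,down_node,length[,glaciality]
    dem.asc          ESRI ASCII elevation grid
    environment.csv  site_id + 10 variable columns
    community.csv    site_id x taxon columns (counts)
    traits.csv       taxon_id,flying
    truth.json       latent glaciality and generating effects (synthetic only)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .network import StreamNetwork, build_network
from .raster import ElevationRaster, read_ascii_grid, write_ascii_grid

__all__ = ["Dataset", "ENV_COLUMNS"]

ENV_COLUMNS = [
    "temperature",
    "conductivity",
    "turbidity",
    "pfankuch",
    "width",
    "depth",
    "slope",
    "ph",
    "epilithic_algae",
    "benthic_om",
]


@dataclass
class Dataset:
    network: StreamNetwork
    raster: ElevationRaster | None
    env: pd.DataFrame          # index: site_id
    community: pd.DataFrame    # index: site_id, columns: taxon ids
    traits: pd.DataFrame       # index: taxon_id, column: flying (0/1)
    truth: dict | None = None

    def __post_init__(self) -> None:
        sites = self.network.site_ids
        self.env = self.env.loc[sites]
        self.community = self.community.loc[sites]
        missing = set(self.community.columns) - set(self.traits.index)
        if missing:
            raise ValueError(f"taxa missing a trait value: {sorted(missing)[:5]}")

    @property
    def site_classes(self) -> pd.Series:
        nodes = self.network.nodes
        s = nodes.set_index("node_id").loc[self.network.site_ids, "site_class"]
        s.index.name = "site_id"
        return s

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.network.nodes.to_csv(out / "nodes.csv", index=False)
        self.network.segments.to_csv(out / "segments.csv", index=False)
        if self.raster is not None:
            write_ascii_grid(self.raster, out / "dem.asc")
        self.env.to_csv(out / "environment.csv", index_label="site_id")
        self.community.to_csv(out / "community.csv", index_label="site_id")
        self.traits.to_csv(out / "traits.csv", index_label="taxon_id")
        if self.truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(self.truth, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, indir) -> "Dataset":
        ind = Path(indir)
        nodes = pd.read_csv(ind / "nodes.csv")
        segments = pd.read_csv(ind / "segments.csv")
        network = build_network(nodes, segments)
        raster = None
        if (ind / "dem.asc").exists():
            raster = read_ascii_grid(ind / "dem.asc")
        env = pd.read_csv(ind / "environment.csv", index_col="site_id")
        community = pd.read_csv(ind / "community.csv", index_col="site_id")
        traits = pd.read_csv(ind / "traits.csv", index_col="taxon_id")
        truth = None
        if (ind / "truth.json").exists():
            with open(ind / "truth.json") as fh:
                truth = json.load(fh)
        return cls(network, raster, env, community, traits, truth)
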