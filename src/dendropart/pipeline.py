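"""Orchestration of the three comparative variation-partitioning models.

Model 1: environmental components only — Glacier (temperature,
conductivity, 1/turbidity, 1/Pfankuch) vs Instream (width, depth, slope,
pH) vs Resources (epilithic algae, benthic organic matter).

Model 2: Glacier vs three spatial variables (overland MEM, watercourse
MEM, downstream AEM) built from one distance family (geographic or
altitudinal), with forward selection of eigenfunctions.

Model 3: two spatial variables built from glaciality distances
(watercourse MEM, downstream AEM).  Overland glaciality eigenfunctions
are never constructed: glaciality does not vary through the air.

Each model runs on four taxon matrices (all / flying / non-flying /
first-order sites), and the confounding report cross-partitions each
spatial variable across distance families to separate unique from
confounded distance effects.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canonical import (
    ForwardSelectionResult,
    VarpartResult,
    forward_select,
    hellinger,
    variation_partition,
)
from .dataset import Dataset
from .eigenmaps import (
    EigenfunctionSet,
    aem_edge_weights,
    aem_eigenfunctions,
    mem_eigenfunctions,
    positive_eigenfunction_filter,
)
from .glaciality import (
    GLACIER_VARS,
    INSTREAM_VARS,
    RESOURCE_VARS,
    assign_segment_glaciality,
    glaciality_distance_matrix,
    glaciality_index,
    minmax_scale,
)
from .network import (
    DistanceMatrix,
    overland_altitudinal_matrix,
    overland_distance_matrix,
    watercourse_altitudinal_matrix,
    watercourse_distance_matrix,
)

logger = logging.getLogger("dendropart")

__all__ = [
    "AnalysisConfig",
    "ModelReport",
    "split_taxa",
    "environment_blocks",
    "build_spatial_block",
    "run_model1",
    "run_model2",
    "run_model3",
    "confounding_report",
    "run_all",
]

SPLITS = ["all", "flying", "nonflying", "firstorder"]
SPATIAL_VARS = ["overland", "watercourse", "downstream"]
FAMILIES = {"geographic", "altitudinal", "glaciality"}


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    mem_truncation: float | None = None
    aem_alpha: float = 1.0
    relief_step: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")


def _seed_for(config: AnalysisConfig, *labels) -> np.random.SeedSequence:
    """Deterministic child seed from the master seed and context labels."""
    tags = [zlib.crc32(str(label).encode()) for label in labels]
    return np.random.SeedSequence([int(config.seed) % (2**31), *tags])


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def split_taxa(
    community: pd.DataFrame, traits: pd.DataFrame, site_classes: pd.Series
) -> dict[str, pd.DataFrame]:
    """The four taxon matrices: all / flying / non-flying / first-order.

    Flying and non-flying subset columns by the trait flag; first-order
    subsets rows to first-order sites and drops taxa absent there.  Sites
    whose row total becomes zero in a split are dropped (they carry no
    information for that community subset).
    """
    missing = set(community.columns) - set(traits.index)
    if missing:
        raise ValueError(f"taxa without trait values: {sorted(missing)[:5]}")
    fly = traits.loc[community.columns, "flying"].astype(bool)
    out = {"all": community.copy()}
    out["flying"] = community.loc[:, fly[fly].index]
    out["nonflying"] = community.loc[:, fly[~fly].index]
    first = site_classes[site_classes == "first_order"].index
    fo = community.loc[community.index.intersection(first)]
    out["firstorder"] = fo.loc[:, fo.sum(axis=0) > 0]
    for name in list(out):
        m = out[name]
        if m.shape[1] == 0:
            raise ValueError(f"empty matrix for split {name!r}")
        nonzero = m.sum(axis=1) > 0
        if not nonzero.all():
            logger.info("split %s: dropping %d empty site row(s)", name, (~nonzero).sum())
            out[name] = m.loc[nonzero]
    return out


def environment_blocks(env: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Glacier / Instream / Resources predictor blocks, scaled to [0, 1]."""
    glacier = pd.DataFrame(
        {
            "temperature": env["temperature"].astype(float),
            "conductivity": env["conductivity"].astype(float),
            "inv_turbidity": 1.0 / env["turbidity"].astype(float),
            "inv_pfankuch": 1.0 / env["pfankuch"].astype(float),
        },
        index=env.index,
    )
    instream = env[INSTREAM_VARS].astype(float)
    resources = env[RESOURCE_VARS].astype(float)
    return {
        "Glacier": minmax_scale(glacier),
        "Instream": minmax_scale(instream),
        "Resources": minmax_scale(resources),
    }


def _subset_distance(dm: DistanceMatrix, sites) -> DistanceMatrix:
    idx = [dm.labels.index(s) for s in sites]
    return DistanceMatrix(dm.values[np.ix_(idx, idx)], list(sites), dm.dist_type)


@dataclass
class _Distances:
    """Cache of full-network distance matrices and AEM edge values."""

    overland_geo: DistanceMatrix
    watercourse_geo: DistanceMatrix
    overland_alt: DistanceMatrix | None
    watercourse_alt: DistanceMatrix
    watercourse_gla: DistanceMatrix
    aem_edge: dict[str, dict]  # family -> {segment_id: distance value}


def prepare_distances(ds: Dataset, config: AnalysisConfig) -> _Distances:
    """All distance matrices and per-segment AEM distance values.

    Cached on the dataset: the matrices are deterministic functions of the
    inputs, and several models share them.
    """
    cached = getattr(ds, "_dist_cache", None)
    if cached is not None:
        return cached
    net = ds.network
    index = glaciality_index(ds.env)
    assign_segment_glaciality(net, index)
    elev = net.node_attr("elevation")
    seg = net.segments
    aem_edge = {
        "geographic": dict(zip(seg["segment_id"], seg["length"].astype(float))),
        "altitudinal": {
            r.segment_id: abs(elev[r.up_node] - elev[r.down_node])
            for r in seg.itertuples(index=False)
        },
        "glaciality": dict(zip(seg["segment_id"], seg["glaciality"].astype(float))),
    }
    gla = glaciality_distance_matrix(net, index)
    if np.nanmax(gla.values) == 0:
        raise ValueError("degenerate distance matrix: glaciality constant across network")
    result = _Distances(
        overland_geo=overland_distance_matrix(net),
        watercourse_geo=watercourse_distance_matrix(net),
        overland_alt=(
            overland_altitudinal_matrix(net, ds.raster, step=config.relief_step)
            if ds.raster is not None
            else None
        ),
        watercourse_alt=watercourse_altitudinal_matrix(net),
        watercourse_gla=gla,
        aem_edge=aem_edge,
    )
    ds._dist_cache = result
    return result


def build_spatial_block(
    ds: Dataset,
    dists: _Distances,
    spatial_var: str,
    family: str,
    sites,
    config: AnalysisConfig,
) -> EigenfunctionSet:
    """Positive-autocorrelation eigenfunctions for one (variable, family).

    ``spatial_var`` is overland / watercourse (MEM) or downstream (AEM).
    Overland + glaciality is rejected by construction.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown distance family {family!r}")
    if spatial_var == "overland" and family == "glaciality":
        raise ValueError(
            "overland glaciality eigenfunctions are not defined: "
            "glaciality does not vary through the air"
        )
    if spatial_var == "downstream":
        edge = dists.aem_edge[family]
        order = list(ds.network.segments["segment_id"])
        w = aem_edge_weights(
            np.array([edge[e] for e in order]), alpha=config.aem_alpha
        )
        es = aem_eigenfunctions(
            ds.network,
            dict(zip(order, w)),
            dist_type={"geographic": "downstream_geo", "altitudinal": "downstream_alt",
                       "glaciality": "downstream_gla"}[family],
            site_subset=list(sites),
        )
    else:
        key = {
            ("overland", "geographic"): "overland_geo",
            ("overland", "altitudinal"): "overland_alt",
            ("watercourse", "geographic"): "watercourse_geo",
            ("watercourse", "altitudinal"): "watercourse_alt",
            ("watercourse", "glaciality"): "watercourse_gla",
        }[(spatial_var, family)]
        dm = getattr(dists, key)
        if dm is None:
            raise ValueError(f"distance matrix {key} unavailable (no raster)")
        es = mem_eigenfunctions(_subset_distance(dm, sites), truncation=config.mem_truncation)
    return positive_eigenfunction_filter(es)


# ---------------------------------------------------------------------------
# model reports
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Per-split variation-partitioning results for one model run."""

    model: str
    family: str | None
    varpart: dict[str, VarpartResult]
    selections: dict[str, dict[str, ForwardSelectionResult]] = field(default_factory=dict)
    excluded_blocks: dict[str, list] = field(default_factory=dict)

    def fraction_frame(self) -> pd.DataFrame:
        frames = []
        for split, vp in self.varpart.items():
            t = vp.fraction_table()
            t.insert(0, "split", split)
            frames.append(t)
        df = pd.concat(frames, ignore_index=True)
        df.insert(0, "family", self.family or "")
        df.insert(0, "model", self.model)
        return df

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "family": self.family,
            "splits": {},
        }
        for split, vp in self.varpart.items():
            entry = {
                "fractions": {
                    "+".join(sorted(k)): v for k, v in vp.fractions.items()
                },
                "unique": {
                    b: {"adj_r2": u[0], "F": u[1], "p": u[2]}
                    for b, u in vp.unique.items()
                },
                "residual": vp.residual,
                "subset_adj_r2": {
                    "+".join(k): v for k, v in vp.subset_adj_r2.items()
                },
                "n_perm": vp.n_perm,
                "excluded_blocks": self.excluded_blocks.get(split, []),
            }
            if split in self.selections:
                entry["selection"] = {
                    b: {
                        "selected": list(map(int, sel.selected)),
                        "global_p": sel.global_p,
                        "global_adj_r2": sel.global_adj_r2,
                        "step_p": sel.step_p,
                    }
                    for b, sel in self.selections[split].items()
                }
            payload["splits"][split] = entry
        return json.dumps(payload, indent=2, sort_keys=True)


def _hellinger_y(counts: pd.DataFrame) -> np.ndarray:
    return hellinger(counts.to_numpy(dtype=float))


def run_model1(ds: Dataset, config: AnalysisConfig) -> ModelReport:
    """Glacier vs Instream vs Resources, per taxon matrix."""
    blocks_full = environment_blocks(ds.env)
    splits = split_taxa(ds.community, ds.traits, ds.site_classes)
    varpart = {}
    for split, counts in splits.items():
        y = _hellinger_y(counts)
        blocks = {k: v.loc[counts.index].to_numpy() for k, v in blocks_full.items()}
        varpart[split] = variation_partition(
            y, blocks, n_perm=config.n_perm, seed=_seed_for(config, "model1", split)
        )
    return ModelReport(model="model1", family=None, varpart=varpart)


def _select_spatial_blocks(
    ds: Dataset,
    dists: _Distances,
    spatial_vars: list[str],
    family: str,
    counts: pd.DataFrame,
    y: np.ndarray,
    config: AnalysisConfig,
    split: str,
    model: str,
):
    """Forward-select each spatial variable; return kept blocks + bookkeeping."""
    blocks, selections, excluded = {}, {}, []
    for sv in spatial_vars:
        es = build_spatial_block(ds, dists, sv, family, list(counts.index), config)
        if es.is_empty:
            logger.info("%s/%s/%s: no positive eigenfunctions", model, split, sv)
            excluded.append(sv)
            continue
        sel = forward_select(
            y,
            es.basis,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=_seed_for(config, model, family, split, sv),
        )
        selections[sv] = sel
        if not sel.any_selected:
            logger.info(
                "%s/%s/%s: global test p=%.3f, no spatial structure retained",
                model, split, sv, sel.global_p,
            )
            excluded.append(sv)
            continue
        blocks[sv] = es.select(sel.selected)
    return blocks, selections, excluded


def run_model2(ds: Dataset, config: AnalysisConfig, family: str) -> ModelReport:
    """Glacier vs overland/watercourse/downstream spatial variables."""
    if family not in {"geographic", "altitudinal"}:
        raise ValueError("model 2 runs on the geographic or altitudinal family")
    dists = prepare_distances(ds, config)
    env_blocks = environment_blocks(ds.env)
    splits = split_taxa(ds.community, ds.traits, ds.site_classes)
    varpart, selections, excluded = {}, {}, {}
    for split, counts in splits.items():
        y = _hellinger_y(counts)
        blocks, sel, exc = _select_spatial_blocks(
            ds, dists, SPATIAL_VARS, family, counts, y, config, split, "model2"
        )
        blocks["Glacier"] = env_blocks["Glacier"].loc[counts.index].to_numpy()
        selections[split] = sel
        excluded[split] = exc
        varpart[split] = variation_partition(
            y, blocks, n_perm=config.n_perm,
            seed=_seed_for(config, "model2", family, split),
        )
    return ModelReport("model2", family, varpart, selections, excluded)


def run_model3(ds: Dataset, config: AnalysisConfig) -> ModelReport:
    """Watercourse + downstream spatial variables from glaciality distances."""
    dists = prepare_distances(ds, config)
    splits = split_taxa(ds.community, ds.traits, ds.site_classes)
    varpart, selections, excluded = {}, {}, {}
    for split, counts in splits.items():
        y = _hellinger_y(counts)
        blocks, sel, exc = _select_spatial_blocks(
            ds, dists, ["watercourse", "downstream"], "glaciality",
            counts, y, config, split, "model3",
        )
        selections[split] = sel
        excluded[split] = exc
        if not blocks:
            logger.info("model3/%s: no spatial structure in any block", split)
            varpart[split] = None
            continue
        varpart[split] = variation_partition(
            y, blocks, n_perm=config.n_perm, seed=_seed_for(config, "model3", split)
        )
    varpart = {k: v for k, v in varpart.items() if v is not None}
    return ModelReport("model3", "glaciality", varpart, selections, excluded)


def confounding_report(
    ds: Dataset,
    config: AnalysisConfig,
    reports: dict[str, ModelReport],
) -> pd.DataFrame:
    """Cross-family partition per spatial variable: unique vs confounded.

    For each spatial variable the selected eigenfunctions of every
    distance family form one block; their joint partition classifies each
    family's effect per taxon matrix as ``unique_significant`` (unique
    fraction significant), ``confounded_significant`` (selected, overall
    effect but no significant unique fraction), or ``not_significant``.
    Overland never includes a glaciality family.
    """
    for key in ("model2_geographic", "model2_altitudinal", "model3"):
        if key not in reports:
            raise ValueError(f"missing upstream report {key!r}")
    splits = split_taxa(ds.community, ds.traits, ds.site_classes)
    dists = prepare_distances(ds, config)
    rows = []
    fam_of = {
        "overland": ["geographic", "altitudinal"],
        "watercourse": ["geographic", "altitudinal", "glaciality"],
        "downstream": ["geographic", "altitudinal", "glaciality"],
    }
    rep_of = {
        "geographic": reports["model2_geographic"],
        "altitudinal": reports["model2_altitudinal"],
        "glaciality": reports["model3"],
    }
    for sv in SPATIAL_VARS:
        for split, counts in splits.items():
            y = _hellinger_y(counts)
            blocks = {}
            for fam in fam_of[sv]:
                sel = rep_of[fam].selections.get(split, {}).get(sv)
                if sel is None or not sel.any_selected:
                    rows.append((sv, split, fam, np.nan, np.nan, "not_significant"))
                    continue
                es = build_spatial_block(ds, dists, sv, fam, list(counts.index), config)
                blocks[fam] = es.select(sel.selected)
            if not blocks:
                continue
            vp = variation_partition(
                y, blocks, n_perm=config.n_perm,
                seed=_seed_for(config, "confounding", sv, split),
            )
            for fam in blocks:
                uniq, f_stat, p = vp.unique[fam]
                status = (
                    "unique_significant" if p <= config.alpha else "confounded_significant"
                )
                rows.append((sv, split, fam, uniq, p, status))
    return pd.DataFrame(
        rows, columns=["spatial_var", "split", "family", "unique_adj_r2", "p", "status"]
    )


def run_all(ds: Dataset, config: AnalysisConfig) -> dict:
    """Models 1-3 plus the confounding report, deterministically seeded."""
    reports = {
        "model1": run_model1(ds, config),
        "model2_geographic": run_model2(ds, config, "geographic"),
        "model2_altitudinal": run_model2(ds, config, "altitudinal"),
        "model3": run_model3(ds, config),
    }
    confounding = confounding_report(ds, config, reports)
    return {"reports": reports, "confounding": confounding}
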