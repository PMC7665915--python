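"""Readers and writers for the pipeline's on-disk formats.

All tables are UTF-8 comma-delimited CSV with a header row; set-valued fields
are pipe-delimited.  Run metadata (package version, seed) is embedded as
``#``-prefixed comment lines which every reader skips — no timestamps, so
reruns with the same configuration are byte-identical.  Pathway collections
use standard GMT (tab-separated: name, description, members) with a
two-column category CSV alongside; networks export as GraphML and as a
tab-separated edge list.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .enrich import PathwayCollection

__all__ = [
    "write_table",
    "read_table",
    "write_gmt",
    "read_gmt",
    "write_categories",
    "read_categories",
    "write_network",
    "write_edge_list",
    "load_config",
    "dump_config",
]


def _metadata_lines(metadata: Mapping[str, object] | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def write_table(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV, skipping '#' metadata comments."""
    path = Path(path)
    try:
        return pd.read_csv(path, comment="#", encoding="utf-8", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Standard GMT: name <tab> description <tab> member proteins."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(collection.pathways):
            desc = collection.categories.get(name, "")
            members = "\t".join(sorted(collection.pathways[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> PathwayCollection:
    path = Path(path)
    pathways: dict[str, frozenset] = {}
    categories: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"malformed GMT {path}, line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in pathways:
                raise ValueError(f"malformed GMT {path}, line {lineno}: duplicate pathway {name!r}")
            pathways[name] = frozenset(members)
            if desc:
                categories[name] = desc
    return PathwayCollection(
        pathways=pathways,
        categories=categories,
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_categories(categories: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(categories.items()), columns=["pathway", "category"])
    write_table(df, path)


def read_categories(path: str | Path) -> dict[str, str]:
    df = read_table(path)
    return dict(zip(df["pathway"], df["category"]))


def write_network(g: nx.Graph, path: str | Path) -> None:
    """GraphML with node attributes (prevalence, type, cluster, is_core)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # stable node/edge order => byte-identical output for identical graphs
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes(data=True)))
    h.add_edges_from(sorted((min(u, v), max(u, v), d) for u, v, d in g.edges(data=True)))
    nx.write_graphml(h, path, named_key_ids=True)


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [
        (u, v, d.get("support"), d.get("confidence"), d.get("lift"))
        for u, v, d in sorted((min(u, v), max(u, v), d) for u, v, d in g.edges(data=True))
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "support", "confidence", "lift"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------

CONFIG_DEFAULTS: dict = {
    "seed": 42,
    "out_dir": "chmnet-out",
    "n_prescriptions": 20_000,
    "n_cohort_scale": 0.2,  # fraction of the published group sizes to simulate
    "co_draw": 0.8,
    "background_mass": 0.05,
    "min_support": 1.0,
    "min_confidence": 15.0,
    "min_lift": 1.0,
    "top_n": 100,
    "cluster_method": "greedy",
    "ob_min": 0.30,
    "dl_min": 0.18,
    "ob_units": "fraction",
    "alpha": 0.05,
    "correction": "fdr_bh",
    "n_proteins": 10_000,
}

_CONFIG_RANGES = {
    "min_support": (0, 100),
    "min_confidence": (0, 100),
    "min_lift": (0, float("inf")),
    "ob_min": (0, 1),
    "dl_min": (0, 1),
    "alpha": (0, 1),
    "co_draw": (0, 1),
    "background_mass": (0, 1),
    "n_cohort_scale": (0, 1),
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge YAML/JSON config over defaults and validate ranges."""
    cfg = dict(CONFIG_DEFAULTS)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(CONFIG_DEFAULTS)}")
        cfg.update(loaded)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    for key, (lo, hi) in _CONFIG_RANGES.items():
        if not lo <= cfg[key] <= hi:
            raise ValueError(f"config {key}={cfg[key]} outside [{lo}, {hi}]")
    if cfg["top_n"] < 1 or cfg["n_prescriptions"] < 1:
        raise ValueError("top_n and n_prescriptions must be >= 1")
    return cfg


def dump_config(cfg: Mapping, path: str | Path) -> None:
    """Resolved-config snapshot written next to the run's outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
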