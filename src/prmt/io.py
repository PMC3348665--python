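"""Tabular readers/writers, network export, and run configuration.

Everything tabular is UTF-8 TSV with '#' comment lines; every output
file carries a provenance header (tool version, config hash, seed, and
a timestamp that can be suppressed for byte-reproducible runs).
Networks export to Cytoscape-compatible SIF (with a node-attribute
sidecar TSV) or GraphML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import PARAMETER_CLASSES
from .emm import MetabolicNetwork, metabolite_degree

logger = logging.getLogger(__name__)

LONG_COUNT_COLUMNS = {"sample", "enzyme_id", "count"}


def provenance_header(seed: int | None = None, config_hash: str | None = None,
                      timestamp: bool = True) -> str:
    lines = [f"# prmt {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash is not None:
        lines.append(f"# config-sha256={config_hash}")
    if timestamp:
        lines.append(f"# created={datetime.now(timezone.utc).isoformat()}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, index_label: str, float_format: str = "%.17g",
              seed: int | None = None, config_hash: str | None = None,
              timestamp: bool = True) -> None:
    """Write a labeled DataFrame as TSV with a provenance comment header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed, config_hash, timestamp))
        df.to_csv(fh, sep="\t", index_label=index_label, float_format=float_format)


def read_tsv_matrix(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` back into a DataFrame."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_triplets(df: pd.DataFrame, path, value_name: str = "value", **kw) -> None:
    """Sparse triplet export: one (row id, column id, value) line per non-zero."""
    rows = []
    arr = df.to_numpy()
    for i, r in enumerate(df.index):
        for j, c in enumerate(df.columns):
            if arr[i, j] != 0:
                rows.append((r, c, arr[i, j]))
    trip = pd.DataFrame(rows, columns=["metabolite", "enzyme", value_name])
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(provenance_header(**kw))
        trip.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_count_table(path) -> pd.DataFrame:
    """Read an enzyme-function read-count table (wide or long TSV).

    Wide: rows = enzyme_id, columns = samples. Long: columns
    ``sample``, ``enzyme_id``, ``count`` in any order, detected by
    header. Counts must be non-negative integers; absent cells are 0.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = set(raw.columns)
    if LONG_COUNT_COLUMNS <= cols:
        df = raw.pivot_table(
            index="enzyme_id", columns="sample", values="count",
            aggfunc="first", fill_value="0",
        )
        df.columns.name = None
    else:
        df = raw.set_index(raw.columns[0])
        df.index.name = "enzyme_id"
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        series = df[col].fillna("0")
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            row = series.index[bad][0]
            raise ValueError(
                f"count table {path}: non-integer or negative count "
                f"{series[row]!r} at enzyme {row!r}, sample {col!r}"
            )
        out[col] = numeric.astype(np.int64)
    return out.sort_index()


def read_parameter_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a parameter table: rows = parameter, columns = samples + 'class'.

    Returns (values, classes). Unknown class labels and duplicated
    parameter ids are errors.
    """
    raw = pd.read_csv(path, sep="\t", comment="#")
    if "class" not in raw.columns:
        raise ValueError(f"parameter table {path}: missing 'class' column")
    id_col = raw.columns[0]
    if raw[id_col].duplicated().any():
        dup = raw[id_col][raw[id_col].duplicated()].iloc[0]
        raise ValueError(f"parameter table {path}: duplicated parameter id {dup!r}")
    raw = raw.set_index(id_col)
    raw.index.name = "parameter_id"
    classes = raw.pop("class")
    unknown = set(classes) - set(PARAMETER_CLASSES)
    if unknown:
        raise ValueError(
            f"parameter table {path}: unknown class labels {sorted(unknown)}; "
            f"expected one of {PARAMETER_CLASSES}"
        )
    return raw.astype(float), classes


def write_parameter_table(values: pd.DataFrame, classes: pd.Series, path, **kw) -> None:
    df = values.copy()
    df.insert(0, "class", classes.reindex(values.index))
    write_tsv(df, path, index_label="parameter_id", **kw)


def write_prmt_table(scores: pd.DataFrame, emm: pd.DataFrame, path, **kw) -> None:
    """Score export: rows = metabolites, sample columns, plus EMM degree."""
    df = scores.copy()
    df["emm_degree"] = metabolite_degree(emm).reindex(scores.index).fillna(0).astype(int)
    write_tsv(df, path, index_label="metabolite", **kw)


def _as_graph(graph) -> nx.Graph | nx.MultiDiGraph:
    if isinstance(graph, MetabolicNetwork):
        return graph.to_networkx()
    return graph


def export_network(graph, fmt: str, path, timestamp: bool = True,
                   seed: int | None = None, config_hash: str | None = None) -> None:
    """Export a network for Cytoscape.

    SIF: one ``source<TAB>interaction<TAB>target`` line per edge, with
    interaction ``pos``/``neg`` for correlation edges and
    ``enzyme:<EC>`` for metabolic edges, plus a ``<path>.nodes.tsv``
    node-attribute sidecar. GraphML: node type and edge sign/PCC (or
    enzyme/direction) as attributes.
    """
    g = _as_graph(graph)
    path = Path(path)
    if fmt == "sif":
        lines = [provenance_header(seed, config_hash, timestamp).rstrip("\n")]
        seen = set()
        for u, v, data in g.edges(data=True):
            if "enzyme" in data:
                interaction = f"enzyme:{data['enzyme']}"
            else:
                interaction = data.get("sign", "pos")
            key = (u, interaction, v)
            if key in seen:
                continue
            seen.add(key)
            lines.append(f"{u}\t{interaction}\t{v}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        nodes = pd.DataFrame(
            {"type": [g.nodes[n].get("type", "metabolite") for n in g.nodes]},
            index=sorted(g.nodes),
        )
        write_tsv(nodes, path.with_suffix(path.suffix + ".nodes.tsv"),
                  index_label="node", seed=seed, config_hash=config_hash,
                  timestamp=timestamp)
    elif fmt == "graphml":
        g = g.copy()
        for n in g.nodes:
            g.nodes[n].setdefault("type", "metabolite")
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        u, interaction, v = line.split("\t")
        g.add_edge(u, v, interaction=interaction)
    return g


@dataclass
class RunConfig:
    """Paths and knobs of one pipeline run; hashed into output headers."""

    catalog: str | None = None
    blacklist: str | None = None
    counts: str | None = None
    parameters: str | None = None
    output_dir: str = "."
    transform: str = "log2p1"
    reference_samples: list[str] | None = None
    iterations: int = 10_000
    seed: int = 0
    sign_convention: str = "consumption-positive"
    pseudocount: str | float | None = "auto"
    pathways: list[str] = field(default_factory=list)
    timestamp: bool = True

    def validate_paths(self) -> None:
        for name in ("catalog", "blacklist", "counts", "parameters"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name}={value!r} does not exist")

    def hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "timestamp"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)
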