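"""Readers and writers for the external formats the pipeline touches.

Tables travel as TSV, gene sets as GMT, interaction networks as 2- or
3-column edge lists, sub-networks as GraphML and pipeline reports as JSON.
Gene symbols are case-normalized to upper case everywhere, because STRING
dumps and GMT files mix cases freely. The published target table uses the
Unicode minus (U+2212); it is normalized to ASCII on input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

log = logging.getLogger("samirnet")

#: canonical column order of an expression table
EXPRESSION_COLUMNS = ["gene_symbol", "transcript_id", "sr_rpkm", "sen_rpkm"]
#: canonical column order of a target-prediction table
TARGET_COLUMNS = ["mirna_id", "gene_symbol", "transcript_id", "mirsvr_score"]


class ConfigError(ValueError):
    """Raised when a config file or column mapping is unusable."""


class DataValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


def _normalize_minus(s: pd.Series) -> pd.Series:
    return s.astype(str).str.replace("−", "-", regex=False).str.strip()


def _to_numeric(s: pd.Series, name: str, path) -> pd.Series:
    out = pd.to_numeric(_normalize_minus(s), errors="coerce")
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise DataValidationError(
            f"{path}: column {name!r} has a non-numeric value at row {row}"
        )
    return out


def read_expression_table(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a gene-level SR/SEN expression table from TSV.

    Parameters
    ----------
    path : str or Path
        TSV file with a header row.
    columns : dict, optional
        Mapping from canonical names (``gene_symbol``, ``transcript_id``,
        ``sr_rpkm``, ``sen_rpkm``) to the column names used in the file.
        ``transcript_id`` may be omitted.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene_symbol, transcript_id, sr_rpkm, sen_rpkm``; gene
        symbols upper-cased; RPKM finite and non-negative;
        (gene, transcript) unique.
    """
    columns = columns or {}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty and len(raw.columns) > 0:
        log.warning("%s: expression table has a header but no rows", path)
    out = pd.DataFrame(index=raw.index)
    for canon in EXPRESSION_COLUMNS:
        src = columns.get(canon, canon)
        if src not in raw.columns:
            if canon == "transcript_id":
                out[canon] = ""
                continue
            raise ConfigError(
                f"{path}: required column {canon!r} (mapped to {src!r}) not found; "
                f"available: {list(raw.columns)}"
            )
        out[canon] = raw[src]
    out["gene_symbol"] = out["gene_symbol"].astype(str).str.strip().str.upper()
    out["transcript_id"] = out["transcript_id"].fillna("").astype(str).str.strip()
    if (out["gene_symbol"] == "").any():
        row = int(out.index[out["gene_symbol"] == ""][0])
        raise DataValidationError(f"{path}: empty gene symbol at row {row}")
    for col in ("sr_rpkm", "sen_rpkm"):
        out[col] = _to_numeric(out[col], col, path)
        if (out[col] < 0).any():
            row = int(out.index[out[col] < 0][0])
            raise DataValidationError(
                f"{path}: negative RPKM in column {col!r} at row {row}"
            )
    dup = out.duplicated(subset=["gene_symbol", "transcript_id"])
    if dup.any():
        row = int(out.index[dup][0])
        raise DataValidationError(
            f"{path}: duplicate (gene, transcript) pair at row {row}: "
            f"{out.loc[row, 'gene_symbol']}/{out.loc[row, 'transcript_id']}"
        )
    return out.reset_index(drop=True)


def read_target_table(path) -> pd.DataFrame:
    """Read a miRNA -> transcript target-prediction table (TSV).

    Expected columns (by name): ``mirna_id``, ``gene_symbol``,
    ``transcript_id``, ``mirsvr_score``. Extra columns are ignored.
    Exact duplicate (mirna, transcript) keys are collapsed to the most
    negative score with a warning, since published tables contain such
    repeats.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TARGET_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: target table missing columns {missing}")
    out = raw[TARGET_COLUMNS].copy()
    out["mirna_id"] = out["mirna_id"].astype(str).str.strip()
    out["gene_symbol"] = out["gene_symbol"].astype(str).str.strip().str.upper()
    out["transcript_id"] = out["transcript_id"].astype(str).str.strip()
    out["mirsvr_score"] = _to_numeric(out["mirsvr_score"], "mirsvr_score", path)
    dup = out.duplicated(subset=["mirna_id", "transcript_id"], keep=False)
    if dup.any():
        n = int(out.loc[dup].groupby(["mirna_id", "transcript_id"]).ngroups)
        log.warning(
            "%s: %d duplicated (mirna, transcript) keys; keeping most negative score",
            path, n,
        )
        out = (
            out.sort_values("mirsvr_score", kind="mergesort")
            .drop_duplicates(subset=["mirna_id", "transcript_id"], keep="first")
            .sort_index()
        )
    return out.reset_index(drop=True)


def read_protein_matrix(path, design: dict[str, str]) -> tuple[pd.DataFrame, dict]:
    """Read a protein abundance matrix (TSV) plus a sample->group design.

    The first column holds protein identifiers; remaining columns are
    samples. ``design`` maps sample column names to ``"SR"`` or ``"SEN"``.

    Returns the matrix (proteins x samples, identifier upper-cased as
    index) and the design restricted to present columns, with both groups
    required and equally sized.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 3:
        raise DataValidationError(f"{path}: need an id column plus >=2 samples")
    idcol = raw.columns[0]
    mat = raw.set_index(idcol)
    mat.index = mat.index.astype(str).str.strip().str.upper()
    mat.index.name = "protein_id"
    keep = [c for c in mat.columns if c in design]
    if not keep:
        raise ConfigError(f"{path}: no sample column matches the design mapping")
    mat = mat[keep].apply(lambda s: _to_numeric(s.reset_index(drop=True), s.name, path).values)
    groups = {g: [c for c in keep if design[c] == g] for g in ("SR", "SEN")}
    for g, cols in groups.items():
        if len(cols) < 2:
            raise DataValidationError(f"{path}: group {g} has {len(cols)} replicates; need >=2")
    if mat.isna().any().any():
        raise DataValidationError(f"{path}: missing intensities are not allowed")
    return mat.astype(float), {c: design[c] for c in keep}


def read_network(path, min_confidence: float = 0.0) -> nx.Graph:
    """Read an undirected interaction network from an edge list.

    Lines are whitespace-separated ``node node [confidence]``; the optional
    third field is a confidence in [0, 1]. Edges below ``min_confidence``
    are dropped, self-loops removed, duplicate edges collapsed keeping the
    highest confidence, and node names upper-cased.
    """
    g = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise DataValidationError(f"{path}:{ln}: edge line needs 2 or 3 fields")
            u, v = parts[0].upper(), parts[1].upper()
            w = 1.0
            if len(parts) >= 3:
                try:
                    w = float(parts[2].replace("−", "-"))
                except ValueError as e:
                    raise DataValidationError(f"{path}:{ln}: bad confidence {parts[2]!r}") from e
            if u == v:
                continue
            if w < min_confidence:
                continue
            if g.has_edge(u, v):
                g[u][v]["confidence"] = max(g[u][v]["confidence"], w)
            else:
                g.add_edge(u, v, confidence=w)
    return g


def write_network(graph: nx.Graph, path) -> None:
    """Write a network as a 3-column edge list (sorted, canonical form)."""
    with open(path, "w") as fh:
        for u, v, d in sorted(
            (tuple(sorted((a, b))) + (dat,) for a, b, dat in graph.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        ):
            fh.write(f"{u}\t{v}\t{d.get('confidence', 1.0):g}\n")


@dataclass
class GeneSet:
    """A named, categorised set of gene symbols."""

    name: str
    category: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, name: str, category: str, genes) -> None:
        if name in self.sets:
            raise DataValidationError(f"duplicate gene-set name {name!r}")
        genes = frozenset(str(g).strip().upper() for g in genes if str(g).strip())
        if not genes:
            raise DataValidationError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(name, category, genes)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT (name, description/category, genes...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataValidationError(f"{path}:{ln}: GMT line needs >=2 tab-separated fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            coll.add(name, desc or name, genes)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.category, *sorted(gs.genes)]) + "\n")


def write_graphml(subnetworks, graph: nx.Graph, path) -> None:
    """Export annotated category sub-networks as GraphML.

    Nodes carry ``category`` and ``role`` (seed/steiner); edges carry
    ``edge_class`` (tree/intra/inter). Only nodes belonging to at least one
    sub-network are exported.
    """
    out = nx.Graph()
    for sub in subnetworks:
        for n in sorted(sub.seed_nodes):
            out.add_node(n, category=sub.category, role="seed")
        for n in sorted(sub.steiner_nodes):
            if n not in out:
                out.add_node(n, category=sub.category, role="steiner")
        for u, v in sorted(tuple(sorted(e)) for e in sub.tree_edges):
            out.add_edge(u, v, edge_class="tree")
        for u, v in sorted(tuple(sorted(e)) for e in sub.intra_edges):
            if not out.has_edge(u, v):
                out.add_edge(u, v, edge_class="intra")
        for u, v in sorted(tuple(sorted(e)) for e in sub.inter_edges):
            if not out.has_edge(u, v):
                out.add_edge(u, v, edge_class="inter")
    nx.write_graphml(out, path)


def write_report(report: dict, path) -> None:
    """Write the pipeline report as deterministic JSON (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level of config must be a mapping")
    return cfg
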