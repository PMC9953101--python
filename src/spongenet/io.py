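"""Readers and writers for the pipeline's external formats.

Everything tabular is TSV, UTF-8, Unix newlines. Readers validate and
reject malformed input with the offending file and location in the
message; they never silently coerce.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import GenomicFeature
from .network import GeneSet
from .simulate import SampleDesign

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "read_targets_tsv",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "read_gtf",
    "write_network",
    "read_network_edges",
]

EDGE_COLUMNS = ["edge_type", "source", "target", "statistic", "pvalue", "shared_mirnas"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Abundance matrix: first column transcript_id, remaining numeric samples."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "transcript_id":
        raise ValueError(f"{path}: first column must be 'transcript_id', got {df.columns[0]!r}")
    ids = df["transcript_id"]
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate transcript ids: {sorted(set(dup))}")
    out = df.set_index("transcript_id")
    for col in out.columns:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() | ~np.isfinite(parsed)
        if bad.any():
            row = out.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric or non-finite value at transcript {row!r}, column {col!r}"
            )
        if (parsed < 0).any():
            row = out.index[(parsed < 0).to_numpy().argmax()]
            raise ValueError(f"{path}: negative abundance at transcript {row!r}, column {col!r}")
        out[col] = parsed.astype(float)
    return out


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("transcript_id").to_csv(
        Path(path), sep="\t", float_format="%.10g", lineterminator="\n"
    )


def read_design_tsv(path: str | Path) -> list[SampleDesign]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "tissue"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dup}")
    try:
        return [
            SampleDesign(r.sample_id, r.group, r.tissue)
            for r in df.itertuples(index=False)
        ]
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def read_targets_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["mirna_id", "target_id", "target_class"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    if df[["mirna_id", "target_id"]].duplicated().any():
        d = df[df[["mirna_id", "target_id"]].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate pair ({d.mirna_id}, {d.target_id})")
    bad = ~df["target_class"].isin(["lncRNA", "mRNA"])
    if bad.any():
        raise ValueError(f"{path}: invalid target_class {df['target_class'][bad].iloc[0]!r}")
    if (df["mirna_id"].str.len() == 0).any() or (df["target_id"].str.len() == 0).any():
        raise ValueError(f"{path}: empty ids not allowed")
    return df[required].copy()


def read_de_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "log2fc", "pvalue", "fdr", "is_de", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    df["is_de"] = df["is_de"].astype(bool)
    return df.set_index("transcript_id")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("transcript_id").to_csv(
        Path(path), sep="\t", float_format="%.10g", lineterminator="\n"
    )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT gene sets: name <tab> description <tab> member ids...

    The description column is ignored; empty sets are rejected.
    """
    path = Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        members = frozenset(p for p in parts[2:] if p)
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {parts[0]!r} has no members")
        sets.append(GeneSet(name=parts[0], members=members))
    return sets


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> list[GenomicFeature]:
    """Minimal GTF reader: gene/transcript/exon features, 1-based inclusive.

    Other feature types (CDS, UTR, ...) are skipped. Every error names the
    file and line number.
    """
    path = Path(path)
    feats: list[GenomicFeature] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
        chrom, _, ftype, start, end, _, strand, _, attrs = cols
        if ftype not in ("gene", "transcript", "exon"):
            continue
        try:
            s, e = int(start), int(end)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}") from None
        if s > e:
            raise ValueError(f"{path}:{lineno}: start > end ({s} > {e})")
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
        attr = dict(_ATTR_RE.findall(attrs))
        gene_id = attr.get("gene_id", "")
        tx_id = attr.get("transcript_id", "")
        if not gene_id:
            raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
        if ftype in ("transcript", "exon") and not tx_id:
            raise ValueError(f"{path}:{lineno}: missing transcript_id on {ftype}")
        feats.append(GenomicFeature(chrom, s, e, strand, ftype, gene_id, tx_id))
    return feats


def write_network(net: nx.Graph, out_dir: str | Path) -> list[Path]:
    """Edge TSV + node TSV + GraphML for a ceRNA network; returns manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for u, v, d in net.edges(data=True):
        et = d["edge_type"]
        if et == "lnc_mrna":
            src, tgt = (u, v) if net.nodes[u]["node_type"] == "lncRNA" else (v, u)
            stat, p, shared = d["statistic"], d["pvalue"], d["shared_mirnas"]
        else:
            src, tgt = (u, v) if net.nodes[u]["node_type"] == "miRNA" else (v, u)
            stat, p, shared = d["statistic"], "", ""
        rows.append((et, src, tgt, stat, p, shared))
    edges = pd.DataFrame(sorted(rows), columns=EDGE_COLUMNS)
    edges_path = out / "edges.tsv"
    edges.to_csv(edges_path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")

    nodes = pd.DataFrame(
        sorted((n, d["node_type"]) for n, d in net.nodes(data=True)),
        columns=["node_id", "node_type"],
    )
    nodes_path = out / "nodes.tsv"
    nodes.to_csv(nodes_path, sep="\t", index=False, lineterminator="\n")

    gml_path = out / "network.graphml"
    nx.write_graphml(net, gml_path, named_key_ids=True, edge_id_from_attribute=None)
    return [edges_path, nodes_path, gml_path]


def read_network_edges(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"shared_mirnas": str}, keep_default_na=False)
    if list(df.columns) != EDGE_COLUMNS:
        raise ValueError(f"{path}: expected columns {EDGE_COLUMNS}, got {list(df.columns)}")
    return df
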