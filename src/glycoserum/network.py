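"""Glycan biosynthesis network over a detected panel.

N-glycan biosynthesis proceeds by single monosaccharide additions, so the
detected compositions form a directed acyclic graph: an edge a -> b exists
when b equals a plus exactly one residue of one kind.  Nodes carry the
theoretical m/z, the structural type, and — once a cohort is attached —
the log2 ratio of the patient-group arithmetic mean abundance over the
control-group mean.  Exports target Cytoscape (GraphML, or SIF plus a
node-attribute table).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .classify import PREDICATES, classify_type
from .core import GlycanPanel, RESIDUE_KINDS

__all__ = [
    "build_network",
    "annotate_fold_change",
    "class_summary",
    "export_graph",
    "read_sif",
]

SIF_RELATION = "addition"


def build_network(panel: GlycanPanel) -> nx.DiGraph:
    """Directed single-residue-addition graph restricted to panel members."""
    g = nx.DiGraph()
    for comp, mz, label in zip(panel.compositions, panel.mz, panel.labels):
        g.add_node(
            comp.code,
            theoretical_mz=float(mz),
            label=int(label),
            type=classify_type(comp).type,
        )
    comps = {c.counts: c for c in panel.compositions}
    for comp in panel.compositions:
        for i, kind in enumerate(RESIDUE_KINDS):
            target = list(comp.counts)
            target[i] += 1
            hit = comps.get(tuple(target))
            if hit is not None:
                g.add_edge(comp.code, hit.code, residue=kind)
    return g


def annotate_fold_change(
    graph: nx.DiGraph,
    matrix: pd.DataFrame,
    groups: pd.Series,
    case: str = "UC",
    control: str = "HLT",
) -> nx.DiGraph:
    """Attach log2(case mean / control mean) to every node, arithmetic means.

    ``matrix`` columns must be composition codes matching the graph nodes;
    ``groups`` maps the matrix index to group names.
    """
    groups = groups.reindex(matrix.index)
    case_rows = matrix.loc[groups == case]
    ctrl_rows = matrix.loc[groups == control]
    if len(case_rows) == 0 or len(ctrl_rows) == 0:
        raise ValueError(f"both groups need >= 1 sample (got {len(case_rows)} {case}, {len(ctrl_rows)} {control})")
    for code in graph.nodes:
        if code not in matrix.columns:
            raise KeyError(f"graph node {code} has no matrix column")
        m_case = float(case_rows[code].mean())
        m_ctrl = float(ctrl_rows[code].mean())
        if m_ctrl <= 0:
            raise ValueError(f"control mean for {code} is {m_ctrl}; log ratio undefined")
        graph.nodes[code]["log2fc"] = float(np.log2(m_case / m_ctrl))
    return graph


def class_summary(graph: nx.DiGraph) -> pd.DataFrame:
    """Mean/median log2 fold change per structural class and aggregate flag."""
    if any("log2fc" not in d for _, d in graph.nodes(data=True)):
        raise ValueError("graph is not annotated with log2fc; run annotate_fold_change first")
    from .core import parse_code

    rows = []
    comps = {code: parse_code(code) for code in graph.nodes}
    for name in (
        "high-mannose",
        "hybrid",
        "complex",
        "bi-antennary",
        "tri-antennary",
        "tetra-antennary",
        "sialylated",
        "fucosylated",
        "agalactosyl_bi",
        "highly_sialylated_multibranched",
    ):
        pred = PREDICATES[name]
        vals = [graph.nodes[c]["log2fc"] for c, comp in comps.items() if pred(comp)]
        rows.append(
            {
                "class": name,
                "n": len(vals),
                "mean_log2fc": float(np.mean(vals)) if vals else np.nan,
                "median_log2fc": float(np.median(vals)) if vals else np.nan,
            }
        )
    return pd.DataFrame(rows)


def export_graph(graph: nx.DiGraph, path: str | Path, fmt: str = "graphml") -> list[Path]:
    """Write the graph as GraphML or as SIF plus a node-attribute table.

    For ``fmt="sif"`` two files are written: ``<path>`` with one
    ``source addition target`` line per edge, and ``<path
    stem>.attrs.tsv`` with columns code, label, type[, log2fc].  Returns
    the written paths.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return [path]
    if fmt == "sif":
        lines = [f"{u}\t{SIF_RELATION}\t{v}" for u, v in sorted(graph.edges)]
        # isolated nodes still need a SIF record
        connected = {n for e in graph.edges for n in e}
        lines += [str(n) for n in sorted(graph.nodes) if n not in connected]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        attr_cols = ["label", "type"] + (
            ["log2fc"] if all("log2fc" in d for _, d in graph.nodes(data=True)) else []
        )
        attrs = pd.DataFrame(
            [{"code": n, **{k: graph.nodes[n][k] for k in attr_cols}} for n in sorted(graph.nodes)],
            columns=["code"] + attr_cols,
        )
        attr_path = path.with_suffix(".attrs.tsv")
        attrs.to_csv(attr_path, sep="\t", index=False)
        return [path, attr_path]
    raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'sif'")


def read_sif(path: str | Path) -> nx.DiGraph:
    """Re-import a SIF edge list (node attributes are not restored)."""
    g = nx.DiGraph()
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        tokens = raw.split("\t")
        if len(tokens) == 1:
            g.add_node(tokens[0].strip())
        elif len(tokens) == 3:
            g.add_edge(tokens[0], tokens[2], residue=None)
        else:
            raise ValueError(f"malformed SIF line: {raw!r}")
    return g
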