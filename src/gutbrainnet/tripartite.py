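"""Tripartite association-network assembly and effect classification.

Significant cross-block associations become edges of a graph whose
nodes come from the three blocks (metabolite, clinical, brain metric);
within-block edges do not exist by construction.  Two thresholdings
are first-class: the q < 0.05 (FDR-corrected) network and the p < 0.05
visualization network, the latter carrying a q-tier flag per edge.

The reported subnetwork keeps the metabolites and their first
neighbors — the induced subgraph on metabolite nodes plus everything
adjacent to them, which also retains clinical-brain edges among
retained nodes.  Metabolite-partner relations are then classified:
*direct* when the pair shares an edge; *indirect* when it does not but
at least one brain-metric node is adjacent to both.  Shared brain
neighbors (``mediators``) are reported for every pair, so a direct
association can additionally exhibit brain-mediated length-2 paths.

Brain-metric node identifiers carry their modality as a prefix
(``func:S_R_NAcc``, ``anat:B_L_Amg``); metabolite and clinical nodes
use their display names.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from .association import DISPLAY_NAMES

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("graphml", "sif", "tsv")
_MOD_CODE = {"functional": "func", "anatomical": "anat"}


def load_printed_associations() -> pd.DataFrame:
    """The shipped fixture of printed association-table rows.

    Every row of the two published association tables (variable pair,
    block labels, modality, r, p, q, df), with the inequality-printed
    p/q bounds stored numerically just below their bound (the exact
    value only matters relative to the 0.05 thresholds).
    """
    with resources.files("gutbrainnet.data").joinpath(
            "tables_1_2.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False,
                         na_values=[""])
    df["modality"] = df["modality"].fillna("")
    return df


def _node_id(block: str, variable: str, modality: str) -> str:
    if block == "brain":
        if ":" in variable:        # already modality-prefixed
            return variable
        code = _MOD_CODE.get(modality, modality or "brain")
        return f"{code}:{variable}"
    return DISPLAY_NAMES.get(variable, variable)


def build_network(records: pd.DataFrame, threshold_mode: str = "p",
                  alpha: float = 0.05) -> nx.Graph:
    """Assemble the tripartite graph from association records.

    ``threshold_mode`` selects the statistic compared against
    ``alpha`` (strict).  Duplicate unordered pairs (e.g. the same
    association printed in two tables) are deduplicated keeping the
    first row; conflicting r beyond 1e-3 is logged.
    """
    if threshold_mode not in ("p", "q"):
        raise ValueError(f"threshold_mode must be 'p' or 'q', "
                         f"got {threshold_mode!r}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    G = nx.Graph(threshold_mode=threshold_mode, alpha=alpha)
    for _, row in records.iterrows():
        if row.get("excluded", False):
            continue
        stat = row[threshold_mode]
        if not np.isfinite(stat) or stat >= alpha:
            continue
        mod = row.get("modality", "") or ""
        u = _node_id(row["block_a"], row["variable_a"],
                     mod if row["block_a"] == "brain" else "")
        v = _node_id(row["block_b"], row["variable_b"],
                     mod if row["block_b"] == "brain" else "")
        if u == v:
            raise ValueError(f"self-loop for variable {u}")
        for node, block, var in ((u, row["block_a"], row["variable_a"]),
                                 (v, row["block_b"], row["variable_b"])):
            if node not in G:
                G.add_node(node, block=block,
                           display=DISPLAY_NAMES.get(var, var),
                           modality=mod if block == "brain" else "")
        if G.has_edge(u, v):
            if abs(G[u][v]["r"] - float(row["r"])) > 1e-3:
                logger.warning("conflicting r for duplicate edge %s-%s "
                               "(%.5f vs %.5f); keeping first",
                               u, v, G[u][v]["r"], row["r"])
            continue
        q = float(row["q"]) if np.isfinite(row["q"]) else np.nan
        G.add_edge(u, v, r=float(row["r"]), p=float(row["p"]), q=q,
                   sig_tier="q<0.05" if (np.isfinite(q) and q < 0.05)
                   else "p<0.05")
    return G


def metabolite_first_neighbors(G: nx.Graph) -> nx.Graph:
    """Metabolites, their first neighbors, and all adjacent edges.

    Every edge with at least one endpoint in the metabolite-plus-
    neighbor set is kept, together with its other endpoint — so a
    clinical node linked only to a metabolite's brain neighbor stays
    in the reported subnetwork (this is what certifies brain-mediated
    indirect paths).
    """
    mets = [n for n, d in G.nodes(data=True) if d["block"] == "metabolite"]
    if not mets:
        logger.warning("network has no metabolite nodes; returning empty")
        return nx.Graph(**G.graph)
    core = set(mets)
    for m in mets:
        core.update(G.neighbors(m))
    edges = [(u, v) for u, v in G.edges if u in core or v in core]
    H = nx.Graph(**G.graph)
    keep = core | {n for e in edges for n in e}
    H.add_nodes_from((n, G.nodes[n]) for n in keep)
    H.add_edges_from((u, v, G[u][v]) for u, v in edges)
    return H


def classify_effects(G: nx.Graph, metabolites: list[str] | None = None,
                     partners: list[str] | None = None) -> pd.DataFrame:
    """Direct / indirect classification per (metabolite, partner) pair.

    Partners default to the non-brain nodes present in the network
    (clinical scores and the other metabolites).  ``status`` is
    ``direct`` when the pair shares an edge, ``indirect`` when it does
    not but a brain-metric node neighbors both, else ``none``.
    ``mediators`` always lists the shared brain-metric neighbors.
    """
    if metabolites is None:
        metabolites = sorted(n for n, d in G.nodes(data=True)
                             if d.get("block") == "metabolite")
    if partners is None:
        partners = sorted(n for n, d in G.nodes(data=True)
                          if d.get("block") != "brain")
    rows = []
    for m in metabolites:
        m_nbrs = set(G.neighbors(m)) if m in G else set()
        m_brain = {v for v in m_nbrs
                   if G.nodes[v].get("block") == "brain"}
        for c in partners:
            if c == m:
                continue
            c_nbrs = set(G.neighbors(c)) if c in G else set()
            mediators = sorted(m_brain & {
                v for v in c_nbrs if G.nodes[v].get("block") == "brain"})
            direct = G.has_edge(m, c) if (m in G and c in G) else False
            if direct:
                status = "direct"
            elif mediators:
                status = "indirect"
            else:
                status = "none"
            rows.append({"metabolite": m, "partner": c, "status": status,
                         "mediators": mediators})
    return pd.DataFrame(rows, columns=["metabolite", "partner", "status",
                                       "mediators"])


# -- export / import --------------------------------------------------

def export_graph(G: nx.Graph, path, fmt: str | None = None) -> None:
    """Write the network as GraphML, SIF, or a TSV edge list.

    GraphML and TSV round-trip losslessly through
    :func:`read_graph`; SIF encodes only topology plus the sign of r
    (interaction token ``pos`` / ``neg``).
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r}; "
                         f"expected one of {EXPORT_FORMATS}")
    if fmt == "graphml":
        H = G.copy()
        for _, d in H.nodes(data=True):
            for key, val in list(d.items()):
                if val is None:
                    d[key] = ""
        nx.write_graphml(H, path)
    elif fmt == "sif":
        with open(path, "w", newline="") as fh:
            for u, v, d in sorted(G.edges(data=True)):
                token = "neg" if d.get("r", 0.0) < 0 else "pos"
                fh.write(f"{u}\t{token}\t{v}\n")
            for n in sorted(nx.isolates(G)):
                fh.write(f"{n}\n")
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "source_block", "target", "target_block",
                        "r", "p", "q", "sig_tier"])
            for u, v, d in sorted(G.edges(data=True)):
                w.writerow([u, G.nodes[u]["block"], v,
                            G.nodes[v]["block"], repr(d["r"]), repr(d["p"]),
                            repr(d["q"]), d["sig_tier"]])


def read_graph(path, fmt: str | None = None) -> nx.Graph:
    """Read a network written by :func:`export_graph` (graphml/tsv)."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "tsv":
        G = nx.Graph()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                G.add_node(row["source"], block=row["source_block"])
                G.add_node(row["target"], block=row["target_block"])
                G.add_edge(row["source"], row["target"],
                           r=float(row["r"]), p=float(row["p"]),
                           q=float(row["q"]), sig_tier=row["sig_tier"])
        return G
    raise ValueError(f"cannot read format {fmt!r}")
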