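"""Endogenous-exogenous chemical correlation network over confidently
annotated (Level 1-2) compounds."""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import Annotation, FeatureTable, ValidationError, NOISE_FLOOR

log = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.5
DEFAULT_LEVELS = (1, 2)


def node_category(sources: frozenset) -> str:
    """endogenous / exogenous / unknown from an annotation's source set."""
    if "endogenous_metabolite" in sources:
        return "endogenous"
    real = sources - {"unknown"}
    return "exogenous" if real else "unknown"


def build_network(
    table: FeatureTable,
    annotations: Mapping[str, Annotation],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    levels: Sequence[int] = DEFAULT_LEVELS,
    adjust_edges: bool = False,
) -> nx.Graph:
    """Correlation network between endogenous metabolites and all other
    annotated compounds.

    Nodes are annotated features at the allowed confidence levels. Candidate
    edges are pairs with at least one endogenous endpoint; an edge is kept
    iff |Pearson R| of the log10 abundance vectors exceeds ``r_threshold``.
    Negative correlations are retained with their sign recorded so an
    exporter can filter to positive-only display. With ``adjust_edges`` the
    candidate edges' correlation p-values get a BH adjustment and edges with
    q >= 0.05 are removed (off by default).
    """
    if table.n_samples < 3:
        raise ValidationError("network correlation needs at least 3 samples")
    node_ids = [
        fid
        for fid in table.abundance.index
        if fid in annotations and annotations[fid].level in levels
    ]
    graph = nx.Graph(r_threshold=r_threshold, levels=list(levels))
    logx = {}
    for fid in node_ids:
        ann = annotations[fid]
        vals = table.abundance.loc[fid].to_numpy(dtype=float)
        mean_area = float(np.nanmean(vals)) if np.isfinite(vals).any() else 0.0
        graph.add_node(
            fid,
            name=ann.compound_name or fid,
            category=node_category(ann.sources),
            level=ann.level,
            mean_area=mean_area,
        )
        with np.errstate(invalid="ignore"):
            logx[fid] = np.log10(vals)
    edges = []
    for i, a in enumerate(node_ids):
        for b in node_ids[i + 1:]:
            cat_a = graph.nodes[a]["category"]
            cat_b = graph.nodes[b]["category"]
            if cat_a != "endogenous" and cat_b != "endogenous":
                continue
            ok = np.isfinite(logx[a]) & np.isfinite(logx[b])
            if ok.sum() < 3:
                continue
            if logx[a][ok].std() == 0 or logx[b][ok].std() == 0:
                continue  # correlation undefined for a constant vector
            r, p = stats.pearsonr(logx[a][ok], logx[b][ok])
            if abs(r) > r_threshold:
                edges.append((a, b, r, p))
    if adjust_edges and edges:
        from .diffstats import bh_adjust

        q = bh_adjust(np.array([e[3] for e in edges]))
        edges = [e for e, qv in zip(edges, q) if qv < 0.05]
    for a, b, r, p in edges:
        graph.add_edge(a, b, r=float(r), sign="positive" if r > 0 else "negative", p=float(p))
    log.info("build_network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges())
    return graph


def group_proportions(
    graph: nx.Graph,
    table: FeatureTable,
    group_label: str = "outcome",
    groups: tuple[str, str] = ("preterm", "term"),
    noise_floor: float = NOISE_FLOOR,
) -> nx.Graph:
    """Annotate each node with the percentage of its detections occurring in
    each group (the Fig.-style node pies); the two percentages sum to 100
    for every node detected at least once."""
    out = graph.copy()
    detected = table.detected(noise_floor)
    labels = table.samples[group_label]
    for fid in out.nodes:
        if fid not in detected.index:
            warnings.warn(f"network node {fid!r} missing from table; proportions unset")
            continue
        det_cols = detected.columns[detected.loc[fid]]
        det_labels = labels.loc[det_cols].dropna()
        n_det = len(det_labels)
        if n_det == 0:
            warnings.warn(f"compound {fid!r} never detected; proportions unset")
            out.nodes[fid][f"pct_{groups[0]}"] = None
            out.nodes[fid][f"pct_{groups[1]}"] = None
            continue
        for group in groups:
            out.nodes[fid][f"pct_{group}"] = float(
                100.0 * (det_labels == group).sum() / n_det
            )
    return out


def network_summary(graph: nx.Graph) -> dict:
    cats = [d["category"] for _, d in graph.nodes(data=True)]
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_endogenous": sum(c == "endogenous" for c in cats),
        "n_exogenous": sum(c == "exogenous" for c in cats),
        "n_unknown": sum(c == "unknown" for c in cats),
        "n_positive_edges": sum(
            1 for _, _, d in graph.edges(data=True) if d["sign"] == "positive"
        ),
        "n_negative_edges": sum(
            1 for _, _, d in graph.edges(data=True) if d["sign"] == "negative"
        ),
    }
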