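"""Case/control species enrichment and co-abundance networks.

Species relative abundances (MetaPhlAn2-style profiles) are compared between
case and control samples with unpaired two-sided rank-sum tests,
BH-corrected across species; a species is called enriched in the group with
the higher mean rank when q < 0.05. Among the enriched species, a
co-abundance network is built from Pearson correlations over ALL samples
(both groups pooled): an edge requires p < 0.05 and cc > 0.4 (positive) or
cc < -0.1 (negative). Edge widths bin |cc| (thick >= 0.7, medium [0.4, 0.7),
thin (0.1, 0.4)); node sizes bin mean relative abundance by decade. Edge
p-values are deliberately not multiplicity-corrected (only node selection
uses q-values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .stats import bh_fdr, pearson, ranksum

__all__ = [
    "AbundanceTable",
    "EnrichmentCall",
    "differential_enrichment",
    "build_coabundance_network",
    "abundance_decade_bin",
    "edge_width_category",
    "mapping_ratio_compare",
    "read_metaphlan_profiles",
]


@dataclass
class AbundanceTable:
    """Samples-by-species relative abundances with case/control labels.

    ``scale`` declares whether rows sum to ~100 (percent) or ~1 (fractions);
    per-sample totals may fall short by unclassified mass but never exceed
    the scale beyond a small tolerance.
    """

    data: pd.DataFrame  # samples x species
    groups: pd.Series  # sample -> "case" | "control"
    scale: float = 100.0

    def __post_init__(self):
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        totals = self.data.sum(axis=1)
        if (totals > self.scale * 1.001).any():
            raise ValueError("per-sample totals exceed the declared scale")

    @property
    def case(self) -> pd.DataFrame:
        return self.data[self.groups == "case"]

    @property
    def control(self) -> pd.DataFrame:
        return self.data[self.groups == "control"]


def read_metaphlan_profiles(profiles: pd.DataFrame | str,
                            meta: pd.DataFrame | str,
                            scale: float = 100.0) -> AbundanceTable:
    """Build an :class:`AbundanceTable` from a MetaPhlAn2-merged table.

    ``profiles``: TSV (or DataFrame) with clade names in the first column and
    one column per sample; species rows are those whose name contains
    ``s__`` and no strain-level ``t__`` suffix. ``meta``: TSV (or DataFrame)
    with columns sample_id and group.
    """
    if isinstance(profiles, str):
        profiles = pd.read_csv(profiles, sep="\t", index_col=0)
    if isinstance(meta, str):
        meta = pd.read_csv(meta, sep="\t")
    is_species = profiles.index.str.contains("s__") & ~profiles.index.str.contains("t__")
    species = profiles[is_species]
    species.index = [name.split("s__")[-1] for name in species.index]
    groups = meta.set_index("sample_id")["group"]
    return AbundanceTable(species.T.loc[groups.index], groups, scale=scale)


@dataclass(frozen=True)
class EnrichmentCall:
    species: str
    p: float
    q: float
    direction: str  # "case_enriched" | "control_enriched" | "ns"


def differential_enrichment(table: AbundanceTable, q_threshold: float = 0.05
                            ) -> list[EnrichmentCall]:
    """Per-species case-vs-control rank-sum tests with BH correction.

    Species absent from every sample are skipped (no test is meaningful);
    direction is assigned by the group with the higher mean rank and only
    when q < threshold.
    """
    if len(table.case) < 2 or len(table.control) < 2:
        raise ValueError("both groups need at least 2 samples")
    tested, skipped = [], []
    for sp in table.data.columns:
        col = table.data[sp]
        if (col == 0).all():
            skipped.append(sp)
            continue
        res = ranksum(table.case[sp].to_numpy(), table.control[sp].to_numpy())
        tested.append((sp, res.p, res.direction))
    if not tested:
        return []
    qs = bh_fdr([p for _, p, _ in tested])
    calls = []
    for (sp, p, direction), q in zip(tested, qs):
        if q < q_threshold and direction is not None:
            label = "case_enriched" if direction == "x" else "control_enriched"
        else:
            label = "ns"
        calls.append(EnrichmentCall(sp, float(p), float(q), label))
    return calls


def abundance_decade_bin(mean_fraction: float) -> str:
    """Decade bin of a mean relative abundance expressed as a fraction:
    "1/10", "1/100", ..., "1/10^6", or "<1/10^6"."""
    if mean_fraction <= 0 or mean_fraction < 1e-6:
        return "<1/10^6"
    k = max(1, math.ceil(-math.log10(mean_fraction) - 1e-12))
    if k > 6:
        return "<1/10^6"
    return {1: "1/10", 2: "1/100", 3: "1/1000"}.get(k, f"1/10^{k}")


def edge_width_category(cc: float) -> str:
    """Width bin on |cc|: thick >= 0.7, medium [0.4, 0.7), thin (0.1, 0.4)."""
    a = abs(cc)
    if a >= 0.7:
        return "thick"
    if a >= 0.4:
        return "medium"
    if a > 0.1:
        return "thin"
    return "none"


@dataclass
class CoabundanceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # a, b, cc, p, sign, width
    nodes: pd.DataFrame  # species, direction, mean_abundance, decade_bin,
    #                      degree, top10_degree, top10_abundance
    notes: list[str] = field(default_factory=list)

    def to_graphml(self, path):
        nx.write_graphml(self.graph, path)


def build_coabundance_network(table: AbundanceTable, enriched,
                              edge_p: float = 0.05, pos_cc: float = 0.4,
                              neg_cc: float = -0.1) -> CoabundanceNetwork:
    """Thresholded Pearson co-abundance network over the enriched species.

    ``enriched`` is the :func:`differential_enrichment` output (only calls
    with a non-``ns`` direction become nodes). Correlations pool all samples
    regardless of group. Constant species yield no edges and are noted.
    """
    if len(table.data) < 3:
        raise ValueError("need at least 3 samples")
    calls = {c.species: c for c in enriched if c.direction != "ns"}
    if not calls:
        raise ValueError("no enriched species to build a network from")
    species = sorted(calls)
    notes = []
    frac = table.data[species] / table.scale  # fractions for decade binning

    edges = []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            cc, p = pearson(table.data[a].to_numpy(), table.data[b].to_numpy())
            if math.isnan(cc):
                notes.append(f"constant abundance vector: pair ({a}, {b}) skipped")
                continue
            if p < edge_p and (cc > pos_cc or cc < neg_cc):
                edges.append({"a": a, "b": b, "cc": cc, "p": p,
                              "sign": "positive" if cc > 0 else "negative",
                              "width": edge_width_category(cc)})
    edge_df = pd.DataFrame(edges, columns=["a", "b", "cc", "p", "sign", "width"])

    graph = nx.Graph()
    mean_ab = frac.mean(axis=0)
    for sp in species:
        graph.add_node(sp, direction=calls[sp].direction,
                       mean_abundance=float(mean_ab[sp]),
                       decade_bin=abundance_decade_bin(float(mean_ab[sp])))
    for e in edges:
        graph.add_edge(e["a"], e["b"], cc=e["cc"], p=e["p"],
                       sign=e["sign"], width=e["width"])

    degree = {sp: graph.degree(sp) for sp in species}
    # stable rankings: ties broken lexicographically by species name
    by_degree = sorted(species, key=lambda s: (-degree[s], s))
    by_abundance = sorted(species, key=lambda s: (-mean_ab[s], s))
    top_deg = set(by_degree[:10])
    top_ab = set(by_abundance[:10])
    node_rows = []
    for sp in species:
        graph.nodes[sp]["degree"] = degree[sp]
        graph.nodes[sp]["top10_degree"] = sp in top_deg
        graph.nodes[sp]["top10_abundance"] = sp in top_ab
        node_rows.append({
            "species": sp, "direction": calls[sp].direction,
            "mean_abundance": float(mean_ab[sp]),
            "decade_bin": abundance_decade_bin(float(mean_ab[sp])),
            "degree": degree[sp],
            "top10_degree": sp in top_deg, "top10_abundance": sp in top_ab,
        })
    node_df = pd.DataFrame(node_rows)
    return CoabundanceNetwork(graph, edge_df, node_df, notes)


def mapping_ratio_compare(mapped_reads: pd.DataFrame, total_reads: pd.Series,
                          groups: pd.Series) -> pd.DataFrame:
    """Per-target mapping-ratio comparison between groups.

    ``mapped_reads``: samples x targets mapped-read counts; ``total_reads``:
    per-sample totals. The ratio is mapped/total; each target gets an
    unpaired rank-sum test between the groups, BH-corrected across targets.
    Returns a DataFrame with target, p, q, direction and group means.
    """
    if isinstance(mapped_reads, pd.Series):
        mapped_reads = mapped_reads.to_frame(name="target")
    total_reads = total_reads.reindex(mapped_reads.index)
    groups = groups.reindex(mapped_reads.index)
    if (total_reads <= 0).any():
        raise ValueError("total reads must be positive")
    if mapped_reads.gt(total_reads, axis=0).any().any():
        raise ValueError("mapped reads cannot exceed total reads")
    ratios = mapped_reads.div(total_reads, axis=0)
    rows = []
    for target in ratios.columns:
        case = ratios.loc[groups == "case", target].to_numpy()
        control = ratios.loc[groups == "control", target].to_numpy()
        res = ranksum(case, control)
        direction = {"x": "case", "y": "control", None: "ns"}[res.direction]
        rows.append({"target": target, "p": res.p, "direction": direction,
                     "mean_case": float(case.mean()),
                     "mean_control": float(control.mean())})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    return out[["target", "p", "q", "direction", "mean_case", "mean_control"]]
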