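"""Core-TF identification and initial (unsigned) GRN assembly.

TFs whose known target sets are over-represented in a trajectory cluster
(one-sided Fisher exact test, BH-adjusted q < 0.1 across all TF x cluster
pairs) become the candidate core regulators. TF pairs with near-identical
target sets (overlap p < 1e-20) are deduplicated in favour of the TF with the
more variable expression. The initial network unions literature-curated edges
with motif-predicted edges scoring NES > 1, then drops disconnected nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import EnrichConfig, GeneSetCollection, ValidationError, make_edge_table


@dataclass
class EnrichmentRecord:
    tf: str
    cluster: str
    overlap: int
    p_value: float
    q_value: float = np.nan


def fisher_greater(overlap: int, cluster_size: int, target_size: int,
                   background_size: int) -> float:
    """One-sided (greater) Fisher exact p: P[X >= overlap] for the 2x2 table.

    Equivalent to the upper hypergeometric tail with N = background,
    K = target set size, n = cluster size.
    """
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, background_size, target_size,
                              cluster_size))


def enrich_cluster(cluster_genes, tf: str, targets, background) -> EnrichmentRecord:
    """Fisher enrichment of one TF's targets in one cluster."""
    background = set(background)
    cluster_genes = set(cluster_genes) & background
    targets = set(targets) & background
    overlap = len(cluster_genes & targets)
    if not cluster_genes or not targets:
        return EnrichmentRecord(tf, "", 0, 1.0)
    p = fisher_greater(overlap, len(cluster_genes), len(targets), len(background))
    return EnrichmentRecord(tf, "", overlap, p)


def enrich_all(clusters: dict, collection: GeneSetCollection) -> pd.DataFrame:
    """Enrichment of every TF x cluster pair; background = expressed genes."""
    coll = collection.restricted()
    rows = []
    for label, genes in clusters.items():
        for tf, targets in coll.sets.items():
            rec = enrich_cluster(genes, tf, targets, coll.background)
            rows.append((tf, label, rec.overlap, rec.p_value))
    df = pd.DataFrame(rows, columns=["tf", "cluster", "overlap", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df


def select_core_tfs(records: pd.DataFrame, q_cutoff: float = 0.1) -> list:
    """TFs with any BH-adjusted pair below the cutoff, in ascending best-q order."""
    hits = records[records["q_value"] < q_cutoff]
    best = hits.groupby("tf")["q_value"].min().sort_values()
    return list(best.index)


def deduplicate_tfs(selected, collection: GeneSetCollection,
                    variance: dict, dedup_p: float = 1e-20) -> list:
    """Drop the less-variable TF of every pair with near-identical target sets.

    Pairs are tested with Fisher's exact test on target-set overlap within the
    collection's background and resolved in ascending-p order; a TF already
    dropped no longer eliminates others.
    """
    coll = collection.restricted()
    n_bg = len(coll.background)
    pairs = []
    for a, b in combinations([tf for tf in selected if tf in coll.sets], 2):
        ta, tb = coll.sets[a], coll.sets[b]
        p = fisher_greater(len(ta & tb), len(ta), len(tb), n_bg)
        if p < dedup_p:
            pairs.append((p, a, b))
    dropped = set()
    for p, a, b in sorted(pairs):
        if a in dropped or b in dropped:
            continue
        dropped.add(a if variance.get(a, 0.0) < variance.get(b, 0.0) else b)
    return [tf for tf in selected if tf not in dropped]


@dataclass
class InitialGRN:
    """Unsigned candidate network over the core TFs."""

    nodes: list
    edges: pd.DataFrame        # columns source, target, provenance, nes, sign

    def regulators_of(self, gene: str) -> list:
        return sorted(set(self.edges.loc[self.edges["target"] == gene, "source"]))

    def edge_set(self) -> set:
        return set(zip(self.edges["source"], self.edges["target"]))


def build_initial_grn(core_tfs, curated_edges: pd.DataFrame,
                      motif_edges: pd.DataFrame,
                      nes_threshold: float = 1.0) -> InitialGRN:
    """Union curated edges with motif edges above the NES threshold.

    Both tables are restricted to core-TF sources and targets; nodes left
    without any edge are removed.
    """
    core = set(core_tfs)

    def _restrict(df):
        return df[df["source"].isin(core) & df["target"].isin(core)]

    curated = _restrict(curated_edges)
    motif = _restrict(motif_edges)
    motif = motif[motif["nes"].astype(float) > nes_threshold]
    seen: dict = {}
    for row in curated.itertuples():
        seen[(row.source, row.target)] = ["curated", np.nan]
    for row in motif.itertuples():
        key = (row.source, row.target)
        if key in seen:
            seen[key][0] = "both"
            seen[key][1] = row.nes
        else:
            seen[key] = ["motif", row.nes]
    if not seen:
        raise ValidationError("initial GRN is empty after restriction/filtering")
    edges = make_edge_table([(s, t, prov, nes) for (s, t), (prov, nes) in seen.items()])
    graph = nx.DiGraph()
    graph.add_nodes_from(core_tfs)
    graph.add_edges_from(seen.keys())
    connected = [n for n in core_tfs if graph.degree(n) > 0]
    edges = edges[edges["source"].isin(connected) & edges["target"].isin(connected)]
    return InitialGRN(nodes=list(connected), edges=edges.reset_index(drop=True))


def identify_core_tfs(clusters: dict, collection: GeneSetCollection,
                      variance: dict, config: EnrichConfig | None = None) -> tuple:
    """Full enrichment -> selection -> deduplication sweep.

    Returns ``(core_tfs, enrichment_table)``.
    """
    cfg = config or EnrichConfig()
    table = enrich_all(clusters, collection)
    selected = select_core_tfs(table, cfg.q_cutoff)
    core = deduplicate_tfs(selected, collection, variance, cfg.dedup_p)
    return core, table
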