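"""Cross-sample clustering of merged SV calls into allelic events.

Pipeline, per SV type and chromosome:

1. calls overlapping by at least 1 bp are grouped transitively;
2. within each group, a similarity graph connects calls with >= 90%
   reciprocal overlap, or >= 70% RO with breakpoint error <= 10 bp (the
   weak rule admits small events with large relative but tiny absolute
   boundary differences);
3. the graph splits into connected components;
4. each component is clustered hierarchically by complete linkage on the
   distance d(a, b) = (|a.start - b.start| + |a.end - b.end|) /
   (length(a) + length(b)), cutting the tree at height 0.1 (inclusive).

Each resulting cell is one allelic event.  Insertions chain by single
linkage on positional distance <= 10 bp instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import SVCall, SVCluster, breakpoint_error, reciprocal_overlap, sort_calls


@dataclass(frozen=True)
class ClusterParams:
    ro_strong: float = 0.9
    ro_weak: float = 0.7
    bp_error_cap: int = 10  # inclusive
    linkage: str = "complete"
    height_cutoff: float = 0.1  # inclusive
    ins_gap: int = 10
    #: breakpoint-distance normalisation: "sum" of the two lengths (default)
    #: or their "mean" (differs only by a factor of 2).
    length_norm: str = "sum"

    def __post_init__(self):
        if not self.ro_weak < self.ro_strong:
            raise ValueError("ro_weak must be below ro_strong")
        if self.height_cutoff <= 0:
            raise ValueError("height_cutoff must be positive")
        if self.length_norm not in ("sum", "mean"):
            raise ValueError("length_norm must be 'sum' or 'mean'")


def pair_distance(a: SVCall, b: SVCall, params: ClusterParams) -> float:
    """Breakpoint distance normalised by the two calls' total length."""
    norm = a.length + b.length
    if params.length_norm == "mean":
        norm /= 2
    return breakpoint_error(a, b) / norm


def group_by_overlap(calls: Sequence[SVCall]) -> List[List[SVCall]]:
    """Transitive closure of >= 1-bp overlap, by sweep over sorted intervals.

    Calls must be non-INS; calls on different chromosomes never group.
    """
    groups: List[List[SVCall]] = []
    for chrom in sorted({c.chrom for c in calls}):
        chrom_calls = sort_calls([c for c in calls if c.chrom == chrom])
        current: List[SVCall] = []
        max_end = -1
        for c in chrom_calls:
            if current and c.start < max_end:
                current.append(c)
            else:
                if current:
                    groups.append(current)
                current = [c]
            max_end = max(max_end, c.end)
        if current:
            groups.append(current)
    return groups


def build_similarity_graph(group: Sequence[SVCall], params: ClusterParams) -> nx.Graph:
    """Edges between calls passing the strong-RO or weak-RO+error rule."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(group)))
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            ro = reciprocal_overlap(group[i], group[j])
            if ro >= params.ro_strong or (
                ro >= params.ro_weak
                and breakpoint_error(group[i], group[j]) <= params.bp_error_cap
            ):
                graph.add_edge(i, j)
    return graph


def split_components(graph: nx.Graph) -> List[List[int]]:
    return [sorted(comp) for comp in nx.connected_components(graph)]


def _median_int(values: Sequence[int]) -> int:
    return int(np.floor(np.median(np.asarray(values, dtype=float))))


def make_cluster(
    members: Sequence[SVCall],
    cluster_id: str,
    panel_size: int,
) -> SVCluster:
    """Build a cluster record: per-side median representative breakpoints,
    carrier count, allele frequency and tightness (mean per-side breakpoint
    deviation from the representative over the representative length)."""
    members = sort_calls(members)
    svtype = members[0].svtype
    if svtype == "INS":
        rep_start = rep_end = _median_int([m.start for m in members])
        rep_length = _median_int([m.length for m in members])
    else:
        rep_start = _median_int([m.start for m in members])
        rep_end = _median_int([m.end for m in members])
        if rep_end <= rep_start:
            rep_end = rep_start + 1
        rep_length = rep_end - rep_start
    deviations = [
        abs(m.start - rep_start) + abs(m.end - rep_end) for m in members
    ]
    if svtype == "INS":
        deviations = [2 * abs(m.start - rep_start) for m in members]
    tightness = float(np.mean(deviations)) / (2.0 * rep_length)
    n_samples = len({m.sample_id for m in members})
    return SVCluster(
        cluster_id=cluster_id,
        svtype=svtype,
        members=list(members),
        rep_start=rep_start,
        rep_end=rep_end,
        rep_length=rep_length,
        n_samples=n_samples,
        allele_frequency=n_samples / panel_size,
        tightness=tightness,
    )


def cluster_component(
    component: Sequence[SVCall],
    params: ClusterParams,
) -> List[List[SVCall]]:
    """Complete-linkage agglomeration of one connected component, cut at the
    height cutoff (inclusive).  Returns member lists, deterministically
    ordered; a singleton component yields one singleton cell."""
    members = sort_calls(component)
    n = len(members)
    if n == 1:
        return [members]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pair_distance(members[i], members[j], params)
    tree = linkage(squareform(dist, checks=False), method=params.linkage)
    labels = fcluster(tree, t=params.height_cutoff, criterion="distance")
    cells: Dict[int, List[SVCall]] = {}
    for label, call in zip(labels, members):
        cells.setdefault(int(label), []).append(call)
    out = [sort_calls(cell) for cell in cells.values()]
    out.sort(key=lambda cell: (cell[0].chrom, cell[0].start, cell[0].end))
    return out


def cluster_insertions(
    calls: Sequence[SVCall],
    params: ClusterParams,
) -> List[List[SVCall]]:
    """Single-linkage positional chaining of insertion sites (gap <= 10 bp)."""
    out: List[List[SVCall]] = []
    by_chrom: Dict[str, List[SVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chain: List[SVCall] = []
        for c in sorted(by_chrom[chrom], key=lambda c: (c.start, c.sample_id)):
            if chain and c.start - chain[-1].start <= params.ins_gap:
                chain.append(c)
            else:
                if chain:
                    out.append(chain)
                chain = [c]
        if chain:
            out.append(chain)
    return out


@dataclass
class ClusterCatalog:
    """Result of a full clustering run."""

    clusters: List[SVCluster]
    membership: pd.DataFrame  # samples x clusters, presence/absence
    panel_size: int

    def summary(self) -> Dict[str, object]:
        tightness = [c.tightness for c in self.clusters]
        freqs = pd.Series([c.n_samples for c in self.clusters])
        return {
            "n_clusters": len(self.clusters),
            "n_calls": sum(len(c.members) for c in self.clusters),
            "mean_tightness": float(np.mean(tightness)) if tightness else None,
            "frequency_spectrum": freqs.value_counts().sort_index().to_dict(),
        }

    def labels_for(self, calls: Sequence[SVCall]) -> List[str]:
        """Cluster id per input call (calls matched by identity of fields)."""
        index = {}
        for cl in self.clusters:
            for m in cl.members:
                index[(m.chrom, m.start, m.end, m.svtype, m.length,
                       m.sample_id, m.caller_id)] = cl.cluster_id
        return [
            index[(c.chrom, c.start, c.end, c.svtype, c.length,
                   c.sample_id, c.caller_id)]
            for c in calls
        ]


def cluster_all(
    calls: Sequence[SVCall],
    params: Optional[ClusterParams] = None,
    panel_size: Optional[int] = None,
    sample_panel: Optional[Sequence[str]] = None,
) -> ClusterCatalog:
    """Cluster a multi-sample call collection into allelic events.

    Runs group -> graph -> components -> complete-linkage cut per SV type
    (single-linkage chaining for INS), then builds the catalog sorted by
    coordinate and a samples x clusters presence/absence matrix.
    """
    params = params or ClusterParams()
    calls = sort_calls(calls)
    if sample_panel is None:
        sample_panel = sorted({c.sample_id for c in calls})
    if panel_size is None:
        panel_size = max(len(sample_panel), 1)

    cells: List[List[SVCall]] = []
    for svtype in sorted({c.svtype for c in calls}):
        typed = [c for c in calls if c.svtype == svtype]
        if svtype == "INS":
            cells.extend(cluster_insertions(typed, params))
            continue
        for group in group_by_overlap(typed):
            graph = build_similarity_graph(group, params)
            for comp in split_components(graph):
                cells.extend(cluster_component([group[i] for i in comp], params))

    cells.sort(key=lambda cell: (cell[0].chrom, cell[0].start, cell[0].end,
                                 cell[0].svtype))
    clusters = [
        make_cluster(cell, f"cl_{i:06d}", panel_size)
        for i, cell in enumerate(cells)
    ]
    clusters.sort(key=lambda c: (c.chrom, c.rep_start, c.rep_end, c.svtype))
    for i, cl in enumerate(clusters):
        cl.cluster_id = f"cl_{i:06d}"

    membership = pd.DataFrame(
        False, index=list(sample_panel), columns=[c.cluster_id for c in clusters]
    )
    for cl in clusters:
        for sample in cl.samples:
            if sample in membership.index:
                membership.loc[sample, cl.cluster_id] = True
    return ClusterCatalog(clusters=clusters, membership=membership,
                          panel_size=panel_size)
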