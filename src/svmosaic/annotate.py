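"""Intersect SV clusters with genome annotations.

Covers transposable-element classification, genic-feature assignment with a
severity-ordered precedence, TSS-relative coverage profiles split by event
length, the deleted-gene rule (full CDS union coverage), and sliding-window
variant density with high-density flagging.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import pearsonr

from .core import SVCall, SVCluster
from .io_formats import AnnotationTrack, GeneModel

FEATURE_PRECEDENCE = ("CDS", "5'UTR", "3'UTR", "intron", "promoter", "intergenic")


def _cluster_interval(cluster: Union[SVCluster, SVCall]) -> Tuple[str, int, int, str, int]:
    if isinstance(cluster, SVCluster):
        return (cluster.chrom, cluster.rep_start, cluster.rep_end,
                cluster.svtype, cluster.rep_length)
    return (cluster.chrom, cluster.start, cluster.end, cluster.svtype,
            cluster.length)


# ---------------------------------------------------------------------------
# Transposable elements
# ---------------------------------------------------------------------------

def _union_coverage(start: int, end: int, records) -> int:
    """Base pairs of [start, end) covered by the union of the records."""
    spans = sorted(
        (max(r.start, start), min(r.end, end))
        for r in records
        if r.start < end and r.end > start
    )
    covered = 0
    cur_end = start
    for s, e in spans:
        s = max(s, cur_end)
        if e > s:
            covered += e - s
            cur_end = e
    return covered


def classify_te_overlap(
    cluster: Union[SVCluster, SVCall],
    te_track: AnnotationTrack,
    repeat_track: Optional[AnnotationTrack] = None,
) -> Tuple[str, Optional[str]]:
    """Classify a cluster against a TE (and optional repeat) track.

    ``strict_te``: some TE record has >= 80% reciprocal overlap with the
    cluster (each covers at least 80% of the other).  Otherwise
    ``repeat_associated``: at least 50% of the cluster length is covered by
    the union of TE/repeat records.  Otherwise ``none``.  The best label is
    the class of the maximum-RO TE.

    Insertions carry no reference extent; with an inserted sequence present
    they are compared by length (ratio >= 80%) against TEs in a one-length
    neighbourhood of the site, otherwise classified ``none``.
    """
    chrom, start, end, svtype, length = _cluster_interval(cluster)
    records = te_track.by_chrom(chrom)

    if svtype == "INS":
        seq = getattr(cluster, "inserted_seq", None)
        if isinstance(cluster, SVCluster):
            seq = next((m.inserted_seq for m in cluster.members if m.inserted_seq),
                       None)
        if not seq:
            return "none", None
        best, best_ratio = None, 0.0
        for r in records:
            if r.start < start + length and r.end > start - length:
                ratio = min(length, r.length) / max(length, r.length)
                if ratio > best_ratio:
                    best, best_ratio = r, ratio
        if best is not None and best_ratio >= 0.8:
            return "strict_te", best.class_label
        return "none", None

    best, best_ro = None, 0.0
    for r in records:
        overlap = min(end, r.end) - max(start, r.start)
        if overlap <= 0:
            continue
        ro = min(overlap / (end - start), overlap / r.length)
        if ro > best_ro:
            best, best_ro = r, ro
    if best is not None and best_ro >= 0.8:
        return "strict_te", best.class_label
    all_records = list(records)
    if repeat_track is not None:
        all_records += repeat_track.by_chrom(chrom)
    if end > start and _union_coverage(start, end, all_records) >= 0.5 * (end - start):
        return "repeat_associated", best.class_label if best else None
    return "none", best.class_label if best else None


# ---------------------------------------------------------------------------
# Genic features
# ---------------------------------------------------------------------------

@dataclass
class FeatureAssignment:
    cluster_id: str
    feature: str
    gene_id: Optional[str] = None
    overlap_bp: int = 0


def promoter_interval(gene: GeneModel, promoter_len: int) -> Tuple[int, int]:
    """Strand-aware promoter: the ``promoter_len`` bp immediately upstream of
    the TSS (higher coordinates for minus-strand genes)."""
    if gene.strand == "+":
        return (max(gene.tss - promoter_len, 0), gene.tss)
    return (gene.tss + 1, gene.tss + 1 + promoter_len)


class GeneIndex:
    """Interval index over gene models (span extended by the promoter)."""

    def __init__(self, genes: Sequence[GeneModel], promoter_len: int = 500):
        self.promoter_len = promoter_len
        self.genes = list(genes)
        self._trees: Dict[str, IntervalTree] = {}
        for i, g in enumerate(self.genes):
            lo, hi = g.span
            ps, pe = promoter_interval(g, promoter_len)
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(min(lo, ps), max(hi, pe), i)

    def overlapping(self, chrom: str, start: int, end: int) -> List[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.genes[i] for i in hits]


def _overlap_bp(start: int, end: int, intervals: Iterable[Tuple[int, int]]) -> int:
    total = 0
    for s, e in intervals:
        total += max(0, min(end, e) - max(start, s))
    return total


def assign_feature(
    cluster: Union[SVCluster, SVCall],
    gene_models: Union[Sequence[GeneModel], GeneIndex],
    promoter_len: int = 500,
) -> FeatureAssignment:
    """Assign one genic-feature label per cluster.

    Precedence CDS > 5'UTR > 3'UTR > intron > promoter > intergenic over all
    overlapping genes, mirroring functional severity; ties at one level go
    to the larger overlap.
    """
    index = (
        gene_models
        if isinstance(gene_models, GeneIndex)
        else GeneIndex(gene_models, promoter_len)
    )
    chrom, start, end, svtype, _ = _cluster_interval(cluster)
    if svtype == "INS":
        end = start + 1  # point events intersect by site
    cluster_id = getattr(cluster, "cluster_id", "")
    best: Optional[FeatureAssignment] = None
    best_rank = len(FEATURE_PRECEDENCE)
    for gene in index.overlapping(chrom, start, end):
        feature_sets = [
            ("CDS", gene.cds_intervals),
            ("5'UTR", gene.utr5_intervals),
            ("3'UTR", gene.utr3_intervals),
            ("intron", gene.intron_intervals),
            ("promoter", [promoter_interval(gene, index.promoter_len)]),
        ]
        for rank, (feature, intervals) in enumerate(feature_sets):
            bp = _overlap_bp(start, end, intervals)
            if bp > 0 and (
                rank < best_rank
                or (rank == best_rank and best is not None and bp > best.overlap_bp)
            ):
                best = FeatureAssignment(cluster_id, feature, gene.gene_id, bp)
                best_rank = rank
                break  # higher-precedence features of this gene already won
    if best is None:
        return FeatureAssignment(cluster_id, "intergenic", None, 0)
    return best


# ---------------------------------------------------------------------------
# TSS-relative profiles
# ---------------------------------------------------------------------------

@dataclass
class TssProfile:
    """Per-position gene-coverage fractions around the TSS, split into short
    (< cutoff) and long (>= cutoff) events."""

    positions: np.ndarray  # [-half_window .. +half_window]
    short_counts: np.ndarray
    long_counts: np.ndarray
    denominators: np.ndarray
    short_cutoff: int

    @property
    def short_fraction(self) -> np.ndarray:
        return _safe_div(self.short_counts, self.denominators)

    @property
    def long_fraction(self) -> np.ndarray:
        return _safe_div(self.long_counts, self.denominators)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    mask = den > 0
    out[mask] = num[mask] / den[mask]
    return out


def _relative_window(
    gene: GeneModel, start: int, end: int, half_window: int
) -> Tuple[int, int]:
    """Map a genomic interval to TSS-relative coordinates (upstream < 0)."""
    if gene.strand == "+":
        lo, hi = start - gene.tss, end - gene.tss
    else:
        lo, hi = gene.tss - end + 1, gene.tss - start + 1
    return max(lo, -half_window), min(hi, half_window + 1)


def tss_profile(
    clusters: Sequence[Union[SVCluster, SVCall]],
    gene_models: Sequence[GeneModel],
    half_window: int = 1000,
    short_cutoff: int = 40,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> TssProfile:
    """Per-position count of genes whose TSS-relative position is covered by
    an SV, split by event length.

    Coverage is binary per gene per position.  Genes closer than
    ``half_window`` to a contig edge contribute only to the positions that
    exist, through a per-position denominator.
    """
    n_pos = 2 * half_window + 1
    positions = np.arange(-half_window, half_window + 1)
    short = np.zeros(n_pos)
    long_ = np.zeros(n_pos)
    denom = np.zeros(n_pos)

    intervals_by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    for cl in clusters:
        chrom, start, end, svtype, length = _cluster_interval(cl)
        if svtype == "INS":
            end = start + 1
        intervals_by_chrom.setdefault(chrom, []).append((start, end, length))
    for lst in intervals_by_chrom.values():
        lst.sort()

    for gene in gene_models:
        win_lo, win_hi = -half_window, half_window
        if contig_lengths is not None:
            clen = contig_lengths.get(gene.chrom)
            if clen is not None:
                if gene.strand == "+":
                    win_lo = max(win_lo, -gene.tss)
                    win_hi = min(win_hi, clen - 1 - gene.tss)
                else:
                    win_lo = max(win_lo, gene.tss - clen + 1)
                    win_hi = min(win_hi, gene.tss)
        denom[win_lo + half_window : win_hi + half_window + 1] += 1

        lst = intervals_by_chrom.get(gene.chrom, [])
        g_lo, g_hi = gene.tss - half_window, gene.tss + half_window + 1
        short_cov = np.zeros(n_pos, dtype=bool)
        long_cov = np.zeros(n_pos, dtype=bool)
        i = bisect.bisect_left(lst, (g_lo - 2_000_000, -1, -1))
        for start, end, length in lst[i:]:
            if start >= g_hi:
                break
            if end <= g_lo:
                continue
            rel_lo, rel_hi = _relative_window(gene, start, end, half_window)
            rel_lo, rel_hi = max(rel_lo, win_lo), min(rel_hi, win_hi + 1)
            if rel_hi <= rel_lo:
                continue
            target = short_cov if length < short_cutoff else long_cov
            target[rel_lo + half_window : rel_hi + half_window] = True
        short += short_cov
        long_ += long_cov

    return TssProfile(positions, short, long_, denom, short_cutoff)


# ---------------------------------------------------------------------------
# Deleted genes
# ---------------------------------------------------------------------------

@dataclass
class DeletedGenesResult:
    per_sample: Dict[str, set]
    per_group: Dict[str, set]
    sharing: pd.Series  # group combination -> number of shared deleted genes
    per_sample_fraction: Dict[str, float]
    gene_frequency: Dict[str, int]


def _union_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _covers(union: List[Tuple[int, int]], start: int, end: int) -> bool:
    i = bisect.bisect_right(union, (start, float("inf"))) - 1
    return i >= 0 and union[i][0] <= start and union[i][1] >= end


def deleted_genes(
    del_clusters: Sequence[SVCluster],
    gene_models: Sequence[GeneModel],
    group_assignments: Optional[Dict[str, str]] = None,
    min_group_freq: int = 5,
) -> DeletedGenesResult:
    """Identify genes whose coding sequence is deleted over its entire length
    in at least one sample.

    A gene is deleted in sample *s* when the union of the DEL intervals
    carried by *s* covers every CDS base of the gene.  Genes with no CDS are
    excluded with a warning.  The sharing table counts genes per
    variety-group combination, restricted to genes deleted in at least
    ``min_group_freq`` samples.
    """
    by_sample: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    for cl in del_clusters:
        if cl.svtype != "DEL":
            continue
        for m in cl.members:
            by_sample.setdefault(m.sample_id, {}).setdefault(m.chrom, []).append(
                (m.start, m.end)
            )
    unions = {
        sample: {chrom: _union_intervals(ivs) for chrom, ivs in chroms.items()}
        for sample, chroms in by_sample.items()
    }

    genes = []
    for g in gene_models:
        if not g.cds_intervals:
            warnings.warn(f"gene {g.gene_id} has no CDS; excluded")
            continue
        genes.append(g)

    per_sample: Dict[str, set] = {s: set() for s in unions}
    for sample, chrom_unions in unions.items():
        for g in genes:
            union = chrom_unions.get(g.chrom)
            if union and all(_covers(union, s, e) for s, e in g.cds_intervals):
                per_sample[sample].add(g.gene_id)

    n_genes = len(genes)
    per_sample_fraction = {
        s: (len(gset) / n_genes if n_genes else 0.0)
        for s, gset in per_sample.items()
    }
    gene_frequency: Dict[str, int] = {}
    for gset in per_sample.values():
        for gid in gset:
            gene_frequency[gid] = gene_frequency.get(gid, 0) + 1

    per_group: Dict[str, set] = {}
    if group_assignments:
        for sample, gset in per_sample.items():
            group = group_assignments.get(sample)
            if group is not None:
                per_group.setdefault(group, set()).update(gset)

    frequent = {g for g, n in gene_frequency.items() if n >= min_group_freq}
    combos: Dict[str, int] = {}
    for gid in sorted(frequent):
        groups = tuple(sorted(gr for gr, gset in per_group.items() if gid in gset))
        if groups:
            key = "+".join(groups)
            combos[key] = combos.get(key, 0) + 1
    sharing = pd.Series(combos, dtype=int).sort_index()

    return DeletedGenesResult(
        per_sample=per_sample,
        per_group=per_group,
        sharing=sharing,
        per_sample_fraction=per_sample_fraction,
        gene_frequency=gene_frequency,
    )


# ---------------------------------------------------------------------------
# Density windows
# ---------------------------------------------------------------------------

@dataclass
class DensityTrack:
    """Sliding-window variant counts with high-density flags."""

    windows: pd.DataFrame  # chrom, start, end, count, flagged
    window: int
    step: int
    mean_count: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.windows[self.windows["flagged"]]


@dataclass
class DensityResult:
    track_a: DensityTrack
    track_b: Optional[DensityTrack] = None
    correlation: Optional[float] = None
    correlation_p: Optional[float] = None


def _window_counts(
    positions: Dict[str, List[int]],
    chrom_lengths: Dict[str, int],
    window: int,
    step: int,
) -> pd.DataFrame:
    rows = []
    for chrom in sorted(chrom_lengths):
        clen = chrom_lengths[chrom]
        pos = np.asarray(sorted(positions.get(chrom, [])))
        start = 0
        while True:
            end = min(start + window, clen)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "count": int(hi - lo)})
            if end >= clen:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def density_windows(
    variants_a: Sequence[Union[SVCluster, SVCall]],
    variants_b: Optional[Sequence[Union[SVCluster, SVCall]]] = None,
    window: int = 100_000,
    step: int = 50_000,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> DensityResult:
    """Sliding-window variant density (100-kb windows, 50-kb step).

    A variant is counted in every window containing its start position.
    Windows with count >= 2 x the track mean are flagged.  With a second
    variant set, the Pearson correlation over aligned windows is reported.
    """
    if window % step != 0:
        raise ValueError("step must divide window")

    def positions_of(variants) -> Dict[str, List[int]]:
        out: Dict[str, List[int]] = {}
        for v in variants:
            chrom, start, _, _, _ = _cluster_interval(v)
            out.setdefault(chrom, []).append(start)
        return out

    pos_a = positions_of(variants_a)
    pos_b = positions_of(variants_b) if variants_b is not None else None
    if chrom_lengths is None:
        chrom_lengths = {}
        for pos in filter(None, [pos_a, pos_b]):
            for chrom, pp in pos.items():
                chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0),
                                           max(pp) + 1)

    def build(pos) -> DensityTrack:
        df = _window_counts(pos, chrom_lengths, window, step)
        mean = float(df["count"].mean()) if len(df) else 0.0
        df["flagged"] = df["count"] >= 2 * mean if mean > 0 else False
        return DensityTrack(df, window, step, mean)

    track_a = build(pos_a)
    if pos_b is None:
        return DensityResult(track_a=track_a)
    track_b = build(pos_b)
    r, p = pearsonr(track_a.windows["count"], track_b.windows["count"])
    return DensityResult(track_a=track_a, track_b=track_b,
                         correlation=float(r), correlation_p=float(p))
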