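"""Within-sample integration of multiple callers' call sets.

Retention rules (for deletions, inversions and duplications):

* every anchor-caller call whose FILTER is PASS is kept unconditionally —
  the anchor is the caller selected for breakpoint precision;
* every inversion from the designated keep-all caller is kept (deduplicated
  against anchor inversions);
* any other call is kept when supported by at least two callers, where two
  calls support each other at 70% reciprocal overlap if the relaxed caller
  is one of the pair and 90% otherwise, and the call is not already
  represented by a retained anchor call at those thresholds.

Insertions merge separately: sites within 10 bp are chained by single
linkage, one representative per chain, and unchained unique insertions from
either caller are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .core import SVCall, reciprocal_overlap, sort_calls


@dataclass(frozen=True)
class MergePolicy:
    anchor_caller: str = "pindel"
    inversion_keep_all_caller: str = "lumpy"
    support_min: int = 2
    ro_default: float = 0.9
    ro_with_relaxed_caller: float = 0.7
    relaxed_caller: str = "lumpy"
    ins_cluster_radius: int = 10
    caller_priority: Tuple[str, ...] = (
        "pindel", "delly", "grom", "lumpy", "metasv", "mindthegap"
    )

    def __post_init__(self):
        if self.support_min < 2:
            raise ValueError("support_min must be at least 2")
        for thr in (self.ro_default, self.ro_with_relaxed_caller):
            if not 0 < thr <= 1:
                raise ValueError("RO thresholds must be in (0, 1]")

    def pair_threshold(self, caller_a: str, caller_b: str) -> float:
        if self.relaxed_caller in (caller_a, caller_b):
            return self.ro_with_relaxed_caller
        return self.ro_default

    def priority_rank(self, caller_id: str) -> int:
        try:
            return self.caller_priority.index(caller_id)
        except ValueError:
            return len(self.caller_priority)


def _pair_supports(a: SVCall, b: SVCall, policy: MergePolicy) -> bool:
    if a.svtype != b.svtype or a.chrom != b.chrom or a.svtype == "INS":
        return False
    thr = policy.pair_threshold(a.caller_id, b.caller_id)
    return reciprocal_overlap(a, b) >= thr


def merge_sample_calls(
    callsets: Dict[str, List[SVCall]],
    policy: Optional[MergePolicy] = None,
) -> List[SVCall]:
    """Merge one sample's non-INS calls from several callers.

    Each retained multi-caller group is emitted once with breakpoints from
    the highest-priority caller present; the supporting callers are recorded
    on the representative call.
    """
    policy = policy or MergePolicy()
    samples = {c.sample_id for calls in callsets.values() for c in calls}
    if len(samples) > 1:
        raise ValueError(f"merge_sample_calls saw multiple samples: {samples}")
    known = set(policy.caller_priority)
    for caller in callsets:
        if caller not in known:
            import warnings

            warnings.warn(f"caller {caller!r} not in policy priority list")

    anchor_pass = [
        c for c in callsets.get(policy.anchor_caller, [])
        if c.svtype != "INS" and c.filter_status == "PASS"
    ]
    anchor_pass = _dedup_within(anchor_pass, policy)
    output: List[SVCall] = list(anchor_pass)

    keep_all_inv = [
        c for c in callsets.get(policy.inversion_keep_all_caller, [])
        if c.svtype == "INV"
    ]
    keep_all_inv = _dedup_within(keep_all_inv, policy)
    for call in keep_all_inv:
        if not any(_pair_supports(call, a, policy) for a in anchor_pass):
            output.append(call)
    represented = list(output)

    # multi-caller support among non-anchor calls
    candidates: List[SVCall] = []
    for caller, calls in callsets.items():
        if caller == policy.anchor_caller:
            continue
        for c in calls:
            if c.svtype == "INS":
                continue
            if caller == policy.inversion_keep_all_caller and c.svtype == "INV":
                continue  # already retained unconditionally
            candidates.append(c)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            if a.caller_id == b.caller_id and not _same_provenance_overlap(a, b):
                continue
            if _pair_supports(a, b, policy):
                graph.add_edge(i, j)

    for comp in nx.connected_components(graph):
        members = [candidates[i] for i in sorted(comp)]
        callers = set()
        for m in members:
            callers.update(m.supporting_callers or (m.caller_id,))
        if len(callers) < policy.support_min:
            continue
        rep = min(
            members,
            key=lambda c: (policy.priority_rank(c.caller_id), c.start, c.end),
        )
        if any(_pair_supports(rep, r, policy) for r in represented):
            continue  # already represented by an anchor (or keep-all) call
        rep = replace(rep, supporting_callers=tuple(sorted(callers)))
        output.append(rep)
        represented.append(rep)

    return sort_calls(output)


def _same_provenance_overlap(a: SVCall, b: SVCall) -> bool:
    """Calls re-entering the merge carry multi-caller provenance; only those
    may support each other despite sharing a caller_id."""
    return len(set(a.supporting_callers) | set(b.supporting_callers)) > 1


def _dedup_within(calls: List[SVCall], policy: MergePolicy) -> List[SVCall]:
    """Collapse near-duplicate calls of one retention rule (keep leftmost)."""
    kept: List[SVCall] = []
    for c in sort_calls(calls):
        if not any(_pair_supports(c, k, policy) for k in kept):
            kept.append(c)
    return kept


def merge_sample_insertions(
    callsets: Dict[str, List[SVCall]],
    policy: Optional[MergePolicy] = None,
) -> List[SVCall]:
    """Merge one sample's insertion sites across callers.

    Sites within ``ins_cluster_radius`` bp chain by single linkage; each
    chain yields one representative (leftmost site, longest assembled
    sequence); unchained insertions from either caller are kept as-is.
    """
    policy = policy or MergePolicy()
    ins = [c for calls in callsets.values() for c in calls if c.svtype == "INS"]
    merged: List[SVCall] = []
    by_chrom: Dict[str, List[SVCall]] = {}
    for c in ins:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chain: List[SVCall] = []
        for c in sorted(by_chrom[chrom], key=lambda c: (c.start, c.caller_id)):
            if chain and c.start - chain[-1].start <= policy.ins_cluster_radius:
                chain.append(c)
            else:
                if chain:
                    merged.append(_ins_representative(chain))
                chain = [c]
        if chain:
            merged.append(_ins_representative(chain))
    return sort_calls(merged)


def _ins_representative(chain: List[SVCall]) -> SVCall:
    if len(chain) == 1:
        return chain[0]
    leftmost = min(chain, key=lambda c: c.start)
    best_seq = max(chain, key=lambda c: (c.length, c.inserted_seq or ""))
    callers = sorted({x for c in chain for x in c.supporting_callers})
    return replace(
        leftmost,
        length=best_seq.length,
        inserted_seq=best_seq.inserted_seq,
        supporting_callers=tuple(callers),
    )


def merge_sample(
    callsets: Dict[str, List[SVCall]],
    policy: Optional[MergePolicy] = None,
) -> List[SVCall]:
    """Full per-sample merge: interval rules plus INS chaining."""
    return sort_calls(
        merge_sample_calls(callsets, policy)
        + merge_sample_insertions(callsets, policy)
    )
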