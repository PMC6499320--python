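"""Match predicted SV calls against a truth set and score sensitivity and
precision per SV type and size bin.

A prediction matches a truth event when it passes a minimum reciprocal
overlap and a breakpoint-error cap.  The default criterion is RO >= 0.9 with
e < min(10 bp, 10% of the combined length), which tightens the error budget
for events whose combined size is below 100 bp; duplications, whose
breakpoints are poorly resolved by short-read callers, relax to RO >= 0.7
with no error constraint.  Insertions are point events and match by
positional distance.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .core import SVCall, breakpoint_error, reciprocal_overlap, size_bin


@dataclass(frozen=True)
class MatchCriteria:
    """Thresholds deciding whether a predicted call hits a truth event."""

    ro_threshold: float = 0.9
    use_bp_error: bool = True
    bp_error_cap: int = 10
    bp_error_frac: float = 0.1
    ins_distance_cap: int = 10
    #: "min": e < min(cap, frac * combined length) — the fractional rule only
    #: ever tightens the cap.  "or": e < cap OR e < frac * combined length.
    combine_rule: str = "min"

    def __post_init__(self):
        if not 0 < self.ro_threshold <= 1:
            raise ValueError("ro_threshold must be in (0, 1]")
        if self.bp_error_cap < 0 or self.ins_distance_cap < 0:
            raise ValueError("error caps must be non-negative")
        if self.combine_rule not in ("min", "or"):
            raise ValueError("combine_rule must be 'min' or 'or'")

    @classmethod
    def for_dup(cls) -> "MatchCriteria":
        """Relaxed duplication criterion: 70% RO, no error constraint."""
        return cls(ro_threshold=0.7, use_bp_error=False)

    @classmethod
    def default_by_type(cls) -> Dict[str, "MatchCriteria"]:
        base = cls()
        return {"DEL": base, "INS": base, "INV": base, "DUP": cls.for_dup()}


CriteriaLike = Union[MatchCriteria, Dict[str, MatchCriteria], None]


def _criteria_for(svtype: str, criteria: CriteriaLike) -> MatchCriteria:
    if criteria is None:
        criteria = MatchCriteria.default_by_type()
    if isinstance(criteria, MatchCriteria):
        return criteria
    return criteria.get(svtype, MatchCriteria())


def is_match(p: SVCall, s: SVCall, criteria: CriteriaLike = None) -> bool:
    """True when prediction ``p`` is a correct call of truth event ``s``."""
    if p.svtype != s.svtype or p.chrom != s.chrom:
        return False
    c = _criteria_for(p.svtype, criteria)
    if p.svtype == "INS":
        return abs(p.start - s.start) <= c.ins_distance_cap
    if reciprocal_overlap(p, s) < c.ro_threshold:
        return False
    if not c.use_bp_error:
        return True
    e = breakpoint_error(p, s)
    combined = p.length + s.length
    if c.combine_rule == "min":
        return e < min(c.bp_error_cap, c.bp_error_frac * combined)
    return e < c.bp_error_cap or e < c.bp_error_frac * combined


@dataclass
class MatchResult:
    pairs: List[Tuple[SVCall, SVCall]]
    unmatched_predictions: List[SVCall]
    unmatched_truth: List[SVCall]


def _candidate_pairs(
    predictions: Sequence[SVCall],
    truth: Sequence[SVCall],
    criteria: CriteriaLike,
) -> List[Tuple[tuple, int, int]]:
    """All (sort_key, pred_idx, truth_idx) pairs that pass the criterion.

    Candidates are looked up through a per-chromosome sweep over truth
    events sorted by start; the search window is padded by the largest truth
    extent so every possible overlap (or INS neighbourhood) is considered.
    """
    by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    max_extent: Dict[str, int] = {}
    for j, s in enumerate(truth):
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end, j))
        extent = max(s.end - s.start, 50)
        max_extent[s.chrom] = max(max_extent.get(s.chrom, 0), extent)
    for lst in by_chrom.values():
        lst.sort()

    out: List[Tuple[tuple, int, int]] = []
    for i, p in enumerate(predictions):
        lst = by_chrom.get(p.chrom)
        if not lst:
            continue
        pad = max_extent[p.chrom]
        lo = bisect.bisect_left(lst, (p.start - pad, -1, -1))
        hi = bisect.bisect_right(lst, (p.end + pad, 1 << 62, 1 << 62))
        for _, _, j in lst[lo:hi]:
            s = truth[j]
            if not is_match(p, s, criteria):
                continue
            if p.svtype == "INS":
                key = (1.0, abs(p.start - s.start), p.start, s.start, i, j)
            else:
                key = (
                    -reciprocal_overlap(p, s),
                    breakpoint_error(p, s),
                    p.start, p.end, s.start, i, j,
                )
            out.append((key, i, j))
    out.sort(key=lambda t: t[0])
    return out


def match_callsets(
    predictions: Sequence[SVCall],
    truth: Sequence[SVCall],
    criteria: CriteriaLike = None,
) -> MatchResult:
    """Greedy one-to-one assignment of predictions to truth events.

    Candidate pairs are taken in order of descending reciprocal overlap,
    then ascending breakpoint error, then coordinate order (ascending
    positional distance for insertions); each side is used at most once.
    The deterministic tie-break makes the matching invariant to input order.
    """
    pred = sorted(predictions, key=lambda c: (c.chrom, c.start, c.end, c.length))
    tru = sorted(truth, key=lambda c: (c.chrom, c.start, c.end, c.length))
    pairs: List[Tuple[SVCall, SVCall]] = []
    used_p, used_t = set(), set()
    for _, i, j in _candidate_pairs(pred, tru, criteria):
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((pred[i], tru[j]))
    unmatched_p = [p for i, p in enumerate(pred) if i not in used_p]
    unmatched_t = [s for j, s in enumerate(tru) if j not in used_t]
    return MatchResult(pairs, unmatched_p, unmatched_t)


@dataclass
class BenchmarkResult:
    """TP/FP/FN tallies and rates per (svtype, size bin).

    Sensitivity and precision are ``None`` (missing) when their denominator
    is zero, never zero by convention.
    """

    counts: Dict[Tuple[str, str], Dict[str, int]] = field(default_factory=dict)

    def _cell(self, svtype: str, bin_label: str) -> Dict[str, int]:
        return self.counts.setdefault(
            (svtype, bin_label), {"tp": 0, "fp": 0, "fn": 0}
        )

    def sensitivity(self, svtype: str, bin_label: str) -> Optional[float]:
        c = self.counts.get((svtype, bin_label))
        if not c or c["tp"] + c["fn"] == 0:
            return None
        return c["tp"] / (c["tp"] + c["fn"])

    def precision(self, svtype: str, bin_label: str) -> Optional[float]:
        c = self.counts.get((svtype, bin_label))
        if not c or c["tp"] + c["fp"] == 0:
            return None
        return c["tp"] / (c["tp"] + c["fp"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (svtype, bin_label), c in sorted(self.counts.items()):
            rows.append(
                {
                    "svtype": svtype, "bin": bin_label,
                    "tp": c["tp"], "fp": c["fp"], "fn": c["fn"],
                    "sensitivity": self.sensitivity(svtype, bin_label),
                    "precision": self.precision(svtype, bin_label),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["svtype", "bin", "tp", "fp", "fn", "sensitivity", "precision"],
        )


def evaluate(
    predictions: Sequence[SVCall],
    truth: Sequence[SVCall],
    criteria: CriteriaLike = None,
) -> BenchmarkResult:
    """Benchmark a call set: match, then tally per (svtype, bin).

    True positives and false negatives are binned by the truth event's
    length; false positives by the predicted length.
    """
    result = BenchmarkResult()
    match = match_callsets(predictions, truth, criteria)
    for p, s in match.pairs:
        result._cell(s.svtype, size_bin(s.length))["tp"] += 1
    for p in match.unmatched_predictions:
        result._cell(p.svtype, size_bin(p.length))["fp"] += 1
    for s in match.unmatched_truth:
        result._cell(s.svtype, size_bin(s.length))["fn"] += 1
    return result
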