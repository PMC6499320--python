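"""Domain types and primitive comparison operators for structural-variant calls.

Coordinates are 0-based half-open throughout the package; VCF/GFF readers and
writers convert at the boundary.  An insertion (INS) is modelled as a point
event (``start == end``) carrying the inserted-sequence length, so interval
operators such as reciprocal overlap are undefined for it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Tuple

SV_TYPES = ("DEL", "INS", "INV", "DUP")

#: Smallest event length the discovery pipeline keeps (events shorter than
#: 10 bp are the territory of indel callers, not SV callers).
MIN_SV_LENGTH = 10

#: Sentinel returned by :func:`size_bin` for lengths outside the binned range.
UNBINNED = "unbinned"

#: Size-bin bounds in bp, inclusive on both ends.  The 500-bp boundary is
#: assigned to bin B, so B = [151, 500] and C = [501, 5000].
SIZE_BINS: Tuple[Tuple[str, int, int], ...] = (
    ("A", 50, 150),
    ("B", 151, 500),
    ("C", 501, 5000),
    ("D", 5001, 50000),
    ("E", 50001, 250000),
    ("F", 250001, 1000000),
)


class SVTypeError(ValueError):
    """Raised when an operator is applied to an SV type it is undefined for."""


@dataclass(frozen=True)
class SVCall:
    """One variant call in one sample from one caller.

    ``start``/``end`` are 0-based half-open.  For DEL/INV/DUP the length is
    the interval extent; for INS ``start == end`` and ``length`` is the
    inserted-sequence length.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    sample_id: str = ""
    caller_id: str = ""
    filter_status: str = "PASS"
    inserted_seq: Optional[str] = None
    supporting_callers: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise SVTypeError(f"unknown SV type {self.svtype!r}")
        if self.svtype == "INS":
            if self.start != self.end:
                raise ValueError("INS must be a point event (start == end)")
            if self.inserted_seq is not None and len(self.inserted_seq) != self.length:
                raise ValueError("INS length does not match inserted sequence")
        else:
            if not self.start < self.end:
                raise ValueError(f"{self.svtype} requires start < end")
            if self.length != self.end - self.start:
                raise ValueError("length must equal end - start for interval events")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not self.supporting_callers:
            object.__setattr__(
                self, "supporting_callers", (self.caller_id,) if self.caller_id else ()
            )

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def with_coords(self, start: int, end: int) -> "SVCall":
        length = self.length if self.svtype == "INS" else end - start
        return replace(self, start=start, end=end, length=length)


@dataclass
class SVCluster:
    """A cross-sample allelic event: calls in different samples inferred to
    descend from a single ancestral mutation."""

    cluster_id: str
    svtype: str
    members: list
    rep_start: int
    rep_end: int
    rep_length: int
    n_samples: int
    allele_frequency: float
    tightness: float

    def __post_init__(self):
        chroms = {m.chrom for m in self.members}
        if len(chroms) > 1:
            raise ValueError("cluster members must share a chromosome")
        if any(m.svtype != self.svtype for m in self.members):
            raise ValueError("cluster members must share the SV type")
        if self.n_samples > len(self.members):
            raise ValueError("n_samples cannot exceed member count")
        if not (0 < self.allele_frequency <= 1):
            raise ValueError("allele frequency must be in (0, 1]")
        if self.tightness < 0:
            raise ValueError("tightness must be non-negative")

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def samples(self) -> Tuple[str, ...]:
        return tuple(sorted({m.sample_id for m in self.members}))


def reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    """Reciprocal overlap of two interval calls.

    Returns ``min(overlap/len(a), overlap/len(b))`` — the smaller of the two
    mutual coverage fractions, so thresholding at *t* requires each call to
    cover at least *t* of the other.  Zero for disjoint intervals or calls on
    different chromosomes.  Undefined (raises) for INS point events.
    """
    if a.svtype == "INS" or b.svtype == "INS":
        raise SVTypeError("reciprocal overlap is undefined for INS point events")
    if a.chrom != b.chrom:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return min(overlap / (a.end - a.start), overlap / (b.end - b.start))


def breakpoint_error(a: SVCall, b: SVCall) -> int:
    """Breakpoint error *e*: sum of absolute start- and end-coordinate
    differences between two calls on the same chromosome."""
    if a.chrom != b.chrom:
        raise ValueError("breakpoint error requires calls on one chromosome")
    return abs(a.start - b.start) + abs(a.end - b.end)


def size_bin(length: int) -> str:
    """Size-bin label (A–F) for an event length in bp.

    Lengths outside [50, 1e6] return the :data:`UNBINNED` sentinel — such
    events are still clusterable, just excluded from binned benchmarking.
    """
    for label, lo, hi in SIZE_BINS:
        if lo <= length <= hi:
            return label
    return UNBINNED


def filter_min_length(calls: Iterable[SVCall], min_length: int = MIN_SV_LENGTH) -> list:
    """Drop calls shorter than the pipeline's minimum SV length."""
    return [c for c in calls if c.length >= min_length]


def sort_calls(calls: Iterable[SVCall]) -> list:
    """Canonical deterministic ordering used throughout the pipeline."""
    return sorted(
        calls, key=lambda c: (c.chrom, c.start, c.end, c.length, c.sample_id, c.caller_id)
    )
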