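"""Seeded synthetic-data generation: truth SV sets, emulated caller output,
multi-sample panels with planted allelic events, and annotation tracks.

The generators work at the call level: instead of simulating sequencing
reads and running external callers, caller behaviour is emulated directly by
breakpoint jitter, false-negative dropout and false-positive injection.
Truth events are coordinate-only, so genome sizes are not limited by memory.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import SVCall, SIZE_BINS
from .io_formats import AnnotationTrack, BedRecord, GeneModel

#: Read-design constants of the short-read study the emulation stands in for;
#: recorded for provenance, not used computationally.
READ_DESIGN = {"read_length": 83, "insert_size": 500, "insert_sd": 50, "error_rate": 0.02}

DEFAULT_BIN_COUNTS = {"A": 1000, "B": 1000, "C": 1000, "D": 1000, "E": 200, "F": 100}

TE_CLASSES = ("DTT", "DTH", "DTM", "RLG", "RSU")

#: Reference-footprint width reserved for an insertion point during truth
#: placement, keeping neighbouring INS sites unambiguous under 10-bp matching.
INS_FOOTPRINT = 100


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark and panel generators."""

    seed: int = 0
    genome_lengths: Dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 100_000_000 for i in range(1, 13)}
    )
    bin_counts: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BIN_COUNTS))
    svtypes: Tuple[str, ...] = ("DEL", "INS", "INV", "DUP")
    jitter_sd: float = 0.0
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    panel_size: int = 20
    panel_jitter_rel: float = 0.02
    freq_range: Tuple[float, float] = (0.4, 1.0)
    max_place_attempts: int = 1000
    read_design: Dict[str, float] = field(default_factory=lambda: dict(READ_DESIGN))

    def __post_init__(self):
        for name in ("fn_rate", "fp_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(n < 0 for n in self.bin_counts.values()):
            raise ValueError("bin counts must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Simulated ground-truth events, non-overlapping within each chromosome."""

    events: List[SVCall]
    ids: List[str]

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def by_type(self, svtype: str) -> List[SVCall]:
        return [e for e in self.events if e.svtype == svtype]


class _Packer:
    """Non-overlapping interval placement by rejection sampling."""

    def __init__(self, genome_lengths: Dict[str, int], rng: np.random.Generator):
        self.chroms = sorted(genome_lengths)
        self.lengths = np.array([genome_lengths[c] for c in self.chroms], dtype=float)
        self.weights = self.lengths / self.lengths.sum()
        self.rng = rng
        self.occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in self.chroms}

    def place(self, footprint: int, attempts: int) -> Tuple[str, int]:
        for _ in range(attempts):
            ci = self.rng.choice(len(self.chroms), p=self.weights)
            chrom = self.chroms[ci]
            limit = int(self.lengths[ci]) - footprint
            if limit <= 0:
                continue
            start = int(self.rng.integers(0, limit))
            if self._free(chrom, start, start + footprint):
                self._insert(chrom, start, start + footprint)
                return chrom, start
        raise RuntimeError(f"could not place event of footprint {footprint} bp")

    def _free(self, chrom: str, start: int, end: int) -> bool:
        occ = self.occupied[chrom]
        i = bisect.bisect_left(occ, (start, start))
        if i > 0 and occ[i - 1][1] > start:
            return False
        if i < len(occ) and occ[i][0] < end:
            return False
        return True

    def _insert(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self.occupied[chrom], (start, end))


def simulate_truth_set(
    cfg: SimConfig,
    svtypes: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> TruthSet:
    """Plant non-overlapping truth events with per-bin counts.

    Event lengths are drawn uniformly within each size bin.  Placement is
    rejection-sampled, largest events first; an infeasible packing raises an
    error naming the bin that failed.
    """
    svtypes = tuple(svtypes) if svtypes is not None else cfg.svtypes
    rng = rng if rng is not None else cfg.rng()
    bounds = {label: (lo, hi) for label, lo, hi in SIZE_BINS}
    requests: List[Tuple[str, str, int]] = []
    for svtype in svtypes:
        for label, count in cfg.bin_counts.items():
            lo, hi = bounds[label]
            for length in rng.integers(lo, hi + 1, size=count):
                requests.append((svtype, label, int(length)))
    requests.sort(key=lambda r: -r[2])

    packer = _Packer(cfg.genome_lengths, rng)
    events: List[SVCall] = []
    for svtype, label, length in requests:
        footprint = length if svtype != "INS" else INS_FOOTPRINT
        try:
            chrom, start = packer.place(footprint, cfg.max_place_attempts)
        except RuntimeError as exc:
            raise RuntimeError(f"truth packing failed in bin {label}: {exc}") from exc
        if svtype == "INS":
            pos = start + footprint // 2
            events.append(
                SVCall(chrom, pos, pos, "INS", length, sample_id="truth",
                       caller_id="truth")
            )
        else:
            events.append(
                SVCall(chrom, start, start + length, svtype, length,
                       sample_id="truth", caller_id="truth")
            )
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    ids = [f"truth_{i:06d}" for i in range(len(events))]
    return TruthSet(events=events, ids=ids)


def _jitter_call(
    call: SVCall, sd: float, rng: np.random.Generator
) -> Tuple[int, int]:
    ds, de = (int(round(x)) for x in rng.normal(0.0, sd, size=2))
    start, end = call.start + ds, call.end + de
    if call.svtype == "INS":
        return start, start
    if end <= start:  # clip so the interval keeps positive extent
        end = start + 1
    return max(start, 0), max(end, 1)


def emulate_caller(
    truth: TruthSet,
    cfg: SimConfig,
    caller_id: str,
    sample_id: str = "sample",
    rng: Optional[np.random.Generator] = None,
) -> List[SVCall]:
    """Emulate a caller on a truth set: FN dropout, breakpoint jitter and
    uniformly placed bin-matched false positives."""
    rng = rng if rng is not None else cfg.rng()
    calls: List[SVCall] = []
    for event in truth.events:
        if cfg.fn_rate > 0 and rng.random() < cfg.fn_rate:
            continue
        if cfg.jitter_sd > 0:
            start, end = _jitter_call(event, cfg.jitter_sd, rng)
        else:
            start, end = event.start, event.end
        length = event.length if event.svtype == "INS" else end - start
        calls.append(
            SVCall(event.chrom, start, end, event.svtype, length,
                   sample_id=sample_id, caller_id=caller_id)
        )
    n_fp = int(round(cfg.fp_rate * len(truth.events)))
    if n_fp:
        chroms = sorted(cfg.genome_lengths)
        weights = np.array([cfg.genome_lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        templates = truth.events
        for i in rng.integers(0, len(templates), size=n_fp):
            tmpl = templates[int(i)]
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[int(ci)]
            limit = cfg.genome_lengths[chrom] - tmpl.length - 1
            start = int(rng.integers(0, max(limit, 1)))
            if tmpl.svtype == "INS":
                calls.append(
                    SVCall(chrom, start, start, "INS", tmpl.length,
                           sample_id=sample_id, caller_id=caller_id)
                )
            else:
                calls.append(
                    SVCall(chrom, start, start + tmpl.length, tmpl.svtype,
                           tmpl.length, sample_id=sample_id, caller_id=caller_id)
                )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


# ---------------------------------------------------------------------------
# Multi-sample panels with planted allelic events
# ---------------------------------------------------------------------------

@dataclass
class PanelResult:
    """Per-sample calls plus the planted-cluster answer key."""

    planted: List[SVCall]
    planted_ids: List[str]
    calls_by_sample: Dict[str, List[SVCall]]
    #: answer key: one (event_id, call) row per emitted call
    key: List[Tuple[str, SVCall]]

    @property
    def all_calls(self) -> List[SVCall]:
        return [call for _, call in self.key]

    @property
    def true_labels(self) -> List[str]:
        return [event_id for event_id, _ in self.key]


def simulate_panel(
    cfg: SimConfig,
    n_clusters: int = 50,
    length_range: Tuple[int, int] = (300, 3000),
    svtype: str = "DEL",
    rng: Optional[np.random.Generator] = None,
) -> PanelResult:
    """Plant allelic events across a sample panel.

    Each event is carried by ``Binomial(panel_size, freq)`` samples (freq
    drawn from ``cfg.freq_range``; events with no carrier are re-drawn), with
    per-sample breakpoint jitter of standard deviation
    ``panel_jitter_rel x length``.  Events are spaced with a 50 %-of-length
    margin so jittered calls from distinct events never touch.
    """
    rng = rng if rng is not None else cfg.rng()
    samples = [f"S{i:03d}" for i in range(cfg.panel_size)]
    packer = _Packer(cfg.genome_lengths, rng)
    planted: List[SVCall] = []
    for _ in range(n_clusters):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        margin = length // 2
        chrom, start = packer.place(length + 2 * margin, cfg.max_place_attempts)
        start += margin
        if svtype == "INS":
            planted.append(SVCall(chrom, start, start, "INS", length,
                                  sample_id="truth", caller_id="truth"))
        else:
            planted.append(SVCall(chrom, start, start + length, svtype, length,
                                  sample_id="truth", caller_id="truth"))
    planted.sort(key=lambda e: (e.chrom, e.start, e.end))
    planted_ids = [f"event_{i:04d}" for i in range(len(planted))]

    calls_by_sample: Dict[str, List[SVCall]] = {s: [] for s in samples}
    key: List[Tuple[str, SVCall]] = []
    for event_id, event in zip(planted_ids, planted):
        freq = rng.uniform(*cfg.freq_range)
        carriers = [s for s in samples if rng.random() < freq]
        while not carriers:
            carriers = [s for s in samples if rng.random() < freq]
        sd = cfg.panel_jitter_rel * event.length
        for sample in carriers:
            start, end = _jitter_call(event, sd, rng)
            length = event.length if event.svtype == "INS" else end - start
            call = SVCall(event.chrom, start, end, event.svtype, length,
                          sample_id=sample, caller_id="merged")
            calls_by_sample[sample].append(call)
            key.append((event_id, call))
    for sample in samples:
        calls_by_sample[sample].sort(key=lambda c: (c.chrom, c.start, c.end))
    return PanelResult(planted, planted_ids, calls_by_sample, key)


def write_panel(panel: PanelResult, out_dir: str, cfg: SimConfig) -> None:
    """Write per-sample VCFs and the answer-key TSV."""
    import os

    from .io_formats import write_sv_vcf

    os.makedirs(out_dir, exist_ok=True)
    for sample, calls in panel.calls_by_sample.items():
        write_sv_vcf(
            calls, os.path.join(out_dir, f"{sample}.merged.vcf"),
            contig_lengths=cfg.genome_lengths, meta={"seed": cfg.seed},
        )
    with open(os.path.join(out_dir, "answer_key.tsv"), "w") as fh:
        fh.write("event_id\tsample_id\tchrom\tstart\tend\tsvtype\tlength\n")
        for event_id, call in panel.key:
            fh.write(
                f"{event_id}\t{call.sample_id}\t{call.chrom}\t{call.start}\t"
                f"{call.end}\t{call.svtype}\t{call.length}\n"
            )


# ---------------------------------------------------------------------------
# Annotation tracks, gene models and sequence
# ---------------------------------------------------------------------------

@dataclass
class SimAnnotations:
    genes: List[GeneModel]
    te_track: AnnotationTrack
    tfbs_track: AnnotationTrack
    sv_calls: List[SVCall]
    sequences: Dict[str, str]


def simulate_indicator_tracks(
    n_genes: int,
    n_positions: int,
    p_tfbs: float,
    p_sv: float,
    avoidance: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-gene, per-position boolean TFBS and SV indicators.

    With ``avoidance == 0`` the two tracks are independent Bernoulli fields;
    with strength ``a`` the SV probability at TFBS-covered cells is reduced
    to ``p_sv * (1 - a)``, producing negative association.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    tfbs = rng.random((n_genes, n_positions)) < p_tfbs
    p = np.where(tfbs, p_sv * (1.0 - avoidance), p_sv)
    sv = rng.random((n_genes, n_positions)) < p
    return tfbs, sv


def simulate_annotations(
    cfg: SimConfig,
    n_genes: int = 50,
    chrom: str = "chr1",
    chrom_len: Optional[int] = None,
    te_density: float = 0.1,
    tfbs_per_gene: int = 3,
    sv_per_gene: float = 1.0,
    avoidance: float = 0.0,
    ssr_insets: Optional[Sequence[Tuple[int, str, int]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimAnnotations:
    """Generate gene models, TE/TFBS tracks, promoter deletions and sequence.

    Genes have a fixed 5'UTR(200) / 3-exon CDS with 2 introns / 3'UTR(200)
    layout on alternating strands.  Promoter deletions are placed uniformly
    in [TSS-500, TSS+500]; with ``avoidance > 0`` a deletion overlapping a
    TFBS is rejected with that probability.  ``ssr_insets`` writes
    ``motif x repeats`` into the 5' UTR of the given gene index, producing a
    low-complexity inset.
    """
    rng = rng if rng is not None else cfg.rng()
    gene_pitch = 10_000
    if chrom_len is None:
        chrom_len = (n_genes + 2) * gene_pitch
    seq = rng.choice(list("ACGT"), size=chrom_len)

    genes: List[GeneModel] = []
    utr5_len, utr3_len, exon_len, intron_len = 200, 200, 300, 150
    gene_len = utr5_len + 3 * exon_len + 2 * intron_len + utr3_len  # 1600
    for i in range(n_genes):
        lo = (i + 1) * gene_pitch
        hi = lo + gene_len
        strand = "+" if i % 2 == 0 else "-"
        # block roles in transcript order; reversed on the genomic axis for -
        roles = ["utr5", "cds", "intron", "cds", "intron", "cds", "utr3"]
        blocks = [utr5_len, exon_len, intron_len, exon_len, intron_len,
                  exon_len, utr3_len]
        if strand == "-":
            roles = roles[::-1]
            blocks = blocks[::-1]
        edges = np.concatenate([[0], np.cumsum(blocks)]) + lo
        by_role: Dict[str, List[Tuple[int, int]]] = {
            "utr5": [], "cds": [], "intron": [], "utr3": []
        }
        for j, role in enumerate(roles):
            by_role[role].append((int(edges[j]), int(edges[j + 1])))
        utr5, utr3 = by_role["utr5"][0], by_role["utr3"][0]
        tss = lo if strand == "+" else hi - 1
        tes = hi - 1 if strand == "+" else lo
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}", chrom=chrom, strand=strand,
                tss=tss, transcription_end=tes,
                cds_intervals=sorted(by_role["cds"]),
                utr5_intervals=[utr5], utr3_intervals=[utr3],
                intron_intervals=sorted(by_role["intron"]),
            )
        )

    te_records: List[BedRecord] = []
    covered = 0
    idx = 0
    while chrom_len and covered / chrom_len < te_density:
        length = int(rng.integers(100, 5001))
        start = int(rng.integers(0, max(chrom_len - length, 1)))
        label = TE_CLASSES[int(rng.integers(0, len(TE_CLASSES)))]
        te_records.append(
            BedRecord(chrom, start, start + length, f"TE{idx:05d}", label)
        )
        covered += length
        idx += 1

    tfbs_records: List[BedRecord] = []
    for g in genes:
        for j in range(tfbs_per_gene):
            offset = int(rng.integers(-500, 491))
            pos = g.tss + offset if g.strand == "+" else g.tss - offset - 10
            tfbs_records.append(
                BedRecord(chrom, max(pos, 0), max(pos, 0) + 10,
                          f"{g.gene_id}_tfbs{j}", "TFBS")
            )
    tfbs_track = AnnotationTrack(records=tfbs_records)

    sv_calls: List[SVCall] = []
    n_sv = int(round(sv_per_gene * n_genes))
    for k in range(n_sv):
        g = genes[int(rng.integers(0, n_genes))]
        length = int(rng.integers(10, 60))
        offset = int(rng.integers(-500, 501 - length))
        if g.strand == "+":
            start = g.tss + offset
        else:
            start = g.tss - offset - length
        start = max(start, 0)
        end = start + length
        if avoidance > 0 and any(
            r.start < end and r.end > start for r in tfbs_track.by_chrom(chrom)
        ):
            if rng.random() < avoidance:
                continue
        sv_calls.append(
            SVCall(chrom, start, end, "DEL", length, sample_id="S000",
                   caller_id="sim")
        )

    for inset in ssr_insets or ():
        gene_idx, motif, repeats = inset
        g = genes[gene_idx]
        s, e = g.utr5_intervals[0]
        ssr = (motif * repeats)[: e - s]
        seq[s : s + len(ssr)] = list(ssr)

    return SimAnnotations(
        genes=genes,
        te_track=AnnotationTrack(records=te_records),
        tfbs_track=tfbs_track,
        sv_calls=sorted(sv_calls, key=lambda c: (c.chrom, c.start, c.end)),
        sequences={chrom: "".join(seq)},
    )
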