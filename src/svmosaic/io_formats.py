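"""Readers and writers for the standard formats the toolkit touches.

Dialect choices, pinned down:

* VCF 4.2 with ``SVTYPE``/``END``/``SVLEN`` INFO keys and symbolic ALTs
  (``<DEL>``, ``<INS>``, ``<DUP>``, ``<INV>``).  Internally 0-based half-open;
  DEL ``SVLEN`` is stored positive and written negative per VCF convention.
* GFF3 gene models, one :class:`GeneModel` per gene built from the longest
  mRNA isoform.
* BED 4+ annotation tracks, taken as already 0-based half-open.
* FASTA via Biopython.

All readers are loss-counting: ``records_in == parsed + skipped`` and the
tally is exposed on the returned :class:`LoadResult`.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .core import SVCall, SVCluster, sort_calls

SYMBOLIC_TYPES = ("DEL", "INS", "DUP", "INV")


@dataclass
class LoadResult:
    """Items parsed from a file plus the loss-counting tally."""

    items: list
    n_records: int = 0
    n_skipped: int = 0
    messages: List[str] = field(default_factory=list)

    @property
    def n_parsed(self) -> int:
        return self.n_records - self.n_skipped

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    class_label: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("BED record requires start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationTrack:
    """A set of labelled genomic intervals (TEs, repeats, TFBS...)."""

    records: List[BedRecord]

    def __post_init__(self):
        self._by_chrom: Dict[str, List[BedRecord]] = {}
        for rec in self.records:
            self._by_chrom.setdefault(rec.chrom, []).append(rec)
        for recs in self._by_chrom.values():
            recs.sort(key=lambda r: (r.start, r.end))

    def by_chrom(self, chrom: str) -> List[BedRecord]:
        return self._by_chrom.get(chrom, [])

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class GeneModel:
    """A gene with its longest-isoform sub-structure, half-open internal
    coordinates.  For minus-strand genes ``tss`` is the larger coordinate."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    transcription_end: int
    cds_intervals: List[Tuple[int, int]] = field(default_factory=list)
    utr5_intervals: List[Tuple[int, int]] = field(default_factory=list)
    utr3_intervals: List[Tuple[int, int]] = field(default_factory=list)
    intron_intervals: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def span(self) -> Tuple[int, int]:
        lo = min(self.tss, self.transcription_end)
        hi = max(self.tss, self.transcription_end)
        return (lo, hi + 1)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(path: str, sample_id: str, caller_id: str) -> LoadResult:
    """Read SV calls from a VCF into internal coordinates.

    Records missing ``SVTYPE``, or whose ``END`` and ``SVLEN`` disagree by
    more than 1 bp for interval types, are skipped and counted.
    """
    result = LoadResult(items=[])
    for rec in VCF(path):
        result.n_records += 1
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in SYMBOLIC_TYPES:
            result.n_skipped += 1
            result.messages.append(
                f"{path}:{rec.CHROM}:{rec.POS}: missing/unknown SVTYPE, skipped"
            )
            continue
        svlen = rec.INFO.get("SVLEN")
        svlen = abs(int(svlen)) if svlen is not None else None
        start = rec.POS - 1  # first affected base, 0-based
        filter_status = rec.FILTER or "PASS"
        try:
            if svtype == "INS":
                seq = None
                if rec.ALT and not rec.ALT[0].startswith("<"):
                    seq = rec.ALT[0][1:] or None
                length = svlen if svlen is not None else (len(seq) if seq else None)
                if length is None:
                    raise ValueError("INS without SVLEN or sequence")
                call = SVCall(
                    chrom=rec.CHROM, start=start, end=start, svtype="INS",
                    length=length, sample_id=sample_id, caller_id=caller_id,
                    filter_status=filter_status, inserted_seq=seq,
                )
            else:
                end_info = rec.INFO.get("END")
                if end_info is not None:
                    end = int(end_info)  # last affected base == half-open end
                elif svlen is not None:
                    end = start + svlen
                else:
                    raise ValueError("interval event without END or SVLEN")
                length = end - start
                if svlen is not None and abs(length - svlen) > 1:
                    raise ValueError(
                        f"irreconcilable END vs SVLEN ({length} vs {svlen})"
                    )
                call = SVCall(
                    chrom=rec.CHROM, start=start, end=end, svtype=svtype,
                    length=length, sample_id=sample_id, caller_id=caller_id,
                    filter_status=filter_status,
                )
        except ValueError as exc:
            result.n_skipped += 1
            result.messages.append(f"{path}:{rec.CHROM}:{rec.POS}: {exc}, skipped")
            continue
        result.items.append(call)
    return result


def _vcf_header_lines(
    sample_panel: Sequence[str],
    contig_lengths: Dict[str, int],
    meta: Optional[Dict[str, object]] = None,
) -> List[str]:
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted(contig_lengths):
        lines.append(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of SV">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=NSAMP,Number=1,Type=Integer,Description="Carrier samples">',
        '##INFO=<ID=TIGHTNESS,Number=1,Type=Float,'
        'Description="Mean per-side breakpoint deviation / length">',
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,'
        'Description="Presence (1) or absence (.)">',
    ]
    for key, value in (meta or {}).items():
        lines.append(f"##svmosaic_{key}={value}")
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
               "FORMAT", *sample_panel]
    lines.append("\t".join(columns))
    return lines


# The dialect writes POS as the first affected base (1-based) and END as the
# last affected base, so END - POS + 1 == SVLEN for interval events.  VCF
# records are written as text: htslib's VCF 4.4 semantics re-derive END from
# SVLEN for symbolic alleles, which is one off from this dialect.
def write_cluster_vcf(
    clusters: Sequence[SVCluster],
    sample_panel: Sequence[str],
    path: str,
    contig_lengths: Optional[Dict[str, int]] = None,
    meta: Optional[Dict[str, object]] = None,
) -> None:
    """Write one VCF record per cluster with presence/absence genotypes.

    Genotypes use a haploid-style 1/. encoding because the pipeline genotypes
    presence of the allelic event, not zygosity.
    """
    clusters = sorted(clusters, key=lambda c: (c.chrom, c.rep_start, c.rep_end))
    if contig_lengths is None:
        contig_lengths = {}
        for cl in clusters:
            cur = contig_lengths.get(cl.chrom, 0)
            contig_lengths[cl.chrom] = max(cur, cl.rep_end + 1000)
    with open(path, "w") as fh:
        for line in _vcf_header_lines(sample_panel, contig_lengths, meta):
            fh.write(line + "\n")
        for cl in clusters:
            svlen = -cl.rep_length if cl.svtype == "DEL" else cl.rep_length
            end = cl.rep_end if cl.svtype != "INS" else cl.rep_start + 1
            info = (
                f"END={end};SVTYPE={cl.svtype};SVLEN={svlen};"
                f"NSAMP={cl.n_samples};TIGHTNESS={cl.tightness:.6g}"
            )
            carriers = set(cl.samples)
            gts = ["1" if s in carriers else "." for s in sample_panel]
            fh.write(
                f"{cl.chrom}\t{cl.rep_start + 1}\t{cl.cluster_id}\tN\t"
                f"<{cl.svtype}>\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_sv_vcf(
    calls: Sequence[SVCall],
    path: str,
    contig_lengths: Optional[Dict[str, int]] = None,
    meta: Optional[Dict[str, object]] = None,
) -> None:
    """Write per-sample SV calls (one sample column) as a symbolic-ALT VCF."""
    calls = sort_calls(calls)
    sample = calls[0].sample_id if calls else "sample"
    if contig_lengths is None:
        contig_lengths = {}
        for c in calls:
            cur = contig_lengths.get(c.chrom, 0)
            contig_lengths[c.chrom] = max(cur, c.end + c.length + 1000)
    with open(path, "w") as fh:
        for line in _vcf_header_lines([sample], contig_lengths, meta):
            fh.write(line + "\n")
        for c in calls:
            svlen = -c.length if c.svtype == "DEL" else c.length
            end = c.end if c.svtype != "INS" else c.start + 1
            info = f"END={end};SVTYPE={c.svtype};SVLEN={svlen}"
            filt = c.filter_status if c.filter_status else "PASS"
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t.\tN\t<{c.svtype}>\t.\t{filt}\t"
                f"{info}\tGT\t1\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff_genes(path: str) -> LoadResult:
    """Build :class:`GeneModel` objects from a GFF3 file.

    One model per gene, from its longest mRNA (by summed exon length, then
    span).  Genes whose CDS falls outside the gene span are rejected with a
    warning and counted as skipped.
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    result = LoadResult(items=[])
    for gene in db.features_of_type("gene"):
        result.n_records += 1
        mrnas = list(db.children(gene, featuretype="mRNA"))
        target = gene if not mrnas else max(
            mrnas,
            key=lambda m: (
                sum(e.end - e.start + 1 for e in db.children(m, featuretype="exon")),
                m.end - m.start,
            ),
        )
        cds = _child_intervals(db, target, "CDS")
        utr5 = _child_intervals(db, target, "five_prime_UTR")
        utr3 = _child_intervals(db, target, "three_prime_UTR")
        exons = _child_intervals(db, target, "exon")
        span_lo, span_hi = gene.start - 1, gene.end  # to half-open
        if any(s < span_lo or e > span_hi for s, e in cds):
            result.n_skipped += 1
            msg = f"gene {gene.id}: CDS outside gene span, rejected"
            result.messages.append(msg)
            warnings.warn(msg)
            continue
        if not exons:
            exons = sorted(cds + utr5 + utr3) or [(span_lo, span_hi)]
        introns = _gaps(sorted(exons))
        if gene.strand == "-":
            tss, tes = span_hi - 1, span_lo
        else:
            tss, tes = span_lo, span_hi - 1
        result.items.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                tss=tss, transcription_end=tes,
                cds_intervals=sorted(cds), utr5_intervals=sorted(utr5),
                utr3_intervals=sorted(utr3), intron_intervals=introns,
            )
        )
    return result


def _child_intervals(db, feature, featuretype) -> List[Tuple[int, int]]:
    return [(f.start - 1, f.end) for f in db.children(feature, featuretype=featuretype)]


def _gaps(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    gaps = []
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 > e1:
            gaps.append((e1, s2))
    return gaps


# ---------------------------------------------------------------------------
# BED / FASTA
# ---------------------------------------------------------------------------

def read_bed_track(path: str) -> AnnotationTrack:
    """Read a BED4+ file as an annotation track (0-based half-open as-is).

    Column 5, when present, is the class label (e.g. TE superfamily);
    otherwise the name doubles as the label.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str},
    )
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED4+ requires at least 4 columns")
    records = [
        BedRecord(
            chrom=str(row[0]), start=int(row[1]), end=int(row[2]),
            name=str(row[3]),
            class_label=str(row[4]) if df.shape[1] > 4 else str(row[3]),
        )
        for row in df.itertuples(index=False)
    ]
    return AnnotationTrack(records=records)


def write_bed_track(track: AnnotationTrack, path: str) -> None:
    with open(path, "w") as fh:
        for r in sorted(track.records, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.class_label}\n")


def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA into a name→sequence map; duplicate IDs are an error."""
    opener = gzip.open if str(path).endswith(".gz") else open
    seqs: Dict[str, str] = {}
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff_genes(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.span)):
            lo, hi = g.span
            base = f"{g.chrom}\tsvmosaic\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(base + f"gene\t{lo + 1}\t{hi}" + tail + f".\tID={g.gene_id}\n")
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                base + f"mRNA\t{lo + 1}\t{hi}" + tail
                + f".\tID={mrna_id};Parent={g.gene_id}\n"
            )
            exons = sorted(g.cds_intervals + g.utr5_intervals + g.utr3_intervals)
            features = (
                [("exon", iv) for iv in _merge_adjacent(exons)]
                + [("CDS", iv) for iv in g.cds_intervals]
                + [("five_prime_UTR", iv) for iv in g.utr5_intervals]
                + [("three_prime_UTR", iv) for iv in g.utr3_intervals]
            )
            for idx, (ftype, (s, e)) in enumerate(features, 1):
                phase = "0" if ftype == "CDS" else "."
                fh.write(
                    f"{g.chrom}\tsvmosaic\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{phase}\tID={mrna_id}.{ftype}.{idx};Parent={mrna_id}\n"
                )


def _merge_adjacent(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
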