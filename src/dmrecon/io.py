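"""Readers and writers for the standard formats the pipeline consumes.

Segments arrive as BED-like TSV (``chrom  start  end  log2r``), alignments
as SAM (via pysam), SNVs as TSV or minimal VCF, the reference as FASTA.
Everything is converted to 1-based inclusive coordinates at this edge and
converted back on write.  All writers emit deterministically ordered output.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from .model import AlignmentRecord, GenomicSegment, SnvRecord

__all__ = [
    "read_segment_table",
    "write_segment_table",
    "read_alignments",
    "write_alignments",
    "read_snv_table",
    "write_snv_table",
    "write_report",
    "read_report",
    "Reference",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Reference:
    """Reference sequence source: an in-memory dict or a FASTA file.

    ``fetch`` uses 1-based inclusive coordinates and clamps to the contig;
    the returned string is uppercase.
    """

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {k: str(v).upper() for k, v in source.items()}
            self._fasta = None
        else:
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._seqs = None

    def contigs(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom:start-end`` (1-based inclusive, clamped)."""
        if start > end:
            return ""
        n = self.length(chrom)
        start = max(1, start)
        end = min(n, end)
        if start > end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end]).upper()


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

def read_segment_table(path, dialect: str = "onebased") -> list[GenomicSegment]:
    """Read a ``chrom start end log2r`` TSV into sorted, id-assigned segments.

    ``dialect='bed'`` declares 0-based half-open input, which is shifted to
    1-based inclusive.  A header line is tolerated.  Rows may be unsorted;
    segments are sorted by (chrom, start) and assigned ids 1..n.
    """
    if dialect not in ("onebased", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, s, e, r = fields[:4]
            try:
                start, end, log2r = int(s), int(e), float(r)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
            if dialect == "bed":
                start += 1
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end ({start} > {end})")
            rows.append((chrom, start, end, log2r))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        GenomicSegment(i, chrom, start, end, log2r)
        for i, (chrom, start, end, log2r) in enumerate(rows, 1)
    ]


def write_segment_table(segments: Sequence[GenomicSegment], path, dialect: str = "onebased") -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlog2r\n")
        for seg in sorted(segments, key=lambda s: (s.chrom, s.start, s.end)):
            start = seg.start - 1 if dialect == "bed" else seg.start
            fh.write(f"{seg.chrom}\t{start}\t{seg.end}\t{seg.log2r:.6g}\n")


# ---------------------------------------------------------------------------
# Alignments (SAM via pysam)
# ---------------------------------------------------------------------------

def _from_pysam(rec: pysam.AlignedSegment, barcode_tag: str) -> AlignmentRecord:
    barcode = None
    if barcode_tag and rec.has_tag(barcode_tag):
        barcode = str(rec.get_tag(barcode_tag))
    cigar = tuple(
        ("MIDNSHP=XB"[op], n) for op, n in (rec.cigartuples or ())
    )
    return AlignmentRecord(
        name=rec.query_name,
        flag=rec.flag,
        chrom=rec.reference_name,
        pos=rec.reference_start + 1,
        cigar=cigar,
        mate_chrom=rec.next_reference_name,
        mate_pos=(rec.next_reference_start + 1) if rec.next_reference_start >= 0 else None,
        seq=rec.query_sequence,
        mapq=rec.mapping_quality,
        barcode=barcode,
    )


def read_alignments(
    path,
    region: Optional[tuple[str, int, int]] = None,
    barcode_tag: str = "BX",
) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a SAM/BAM file in file order.

    ``region=(chrom, start, end)`` keeps records whose 1-based leftmost
    position falls inside the interval.  CIGAR/sequence length mismatches
    raise a record-level error naming the read (from AlignmentRecord).
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if region is not None:
                chrom, start, end = region
                pos = rec.reference_start + 1
                if rec.reference_name != chrom or not (start <= pos <= end):
                    continue
            yield _from_pysam(rec, barcode_tag)


def write_alignments(
    records: Iterable[AlignmentRecord],
    path,
    contigs: dict[str, int],
    barcode_tag: str = "BX",
) -> None:
    """Write records as plain SAM with an @SQ header built from ``contigs``."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(contigs)}
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = r.flag
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos - 1
            a.mapping_quality = r.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            if r.mate_chrom is not None and r.mate_pos is not None:
                a.next_reference_id = tid[r.mate_chrom]
                a.next_reference_start = r.mate_pos - 1
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.template_length = 0
            a.query_sequence = r.seq
            if r.seq is not None:
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            if r.barcode is not None:
                a.set_tag(barcode_tag, r.barcode, value_type="Z")
            out.write(a)


# ---------------------------------------------------------------------------
# SNV tables
# ---------------------------------------------------------------------------

def read_snv_table(path) -> list[SnvRecord]:
    """Read SNVs from TSV (``chrom pos ref alt ref_count alt_count origin``)
    or from a minimal VCF (AD-style counts, ``ORIGIN`` INFO tag optional)."""
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_snv_vcf(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "chrom":  # header
                continue
            if len(f) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            out.append(
                SnvRecord(
                    chrom=f[0],
                    pos=int(f[1]),
                    ref_allele=f[2],
                    alt_allele=f[3],
                    ref_count=int(f[4]),
                    alt_count=int(f[5]),
                    origin=f[6],
                )
            )
    return out


def _read_snv_vcf(path) -> list[SnvRecord]:
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            origin = str(rec.info.get("ORIGIN", "germline"))
            ad = None
            for sample in rec.samples.values():
                ad = sample.get("AD")
                break
            if ad is None:
                continue
            out.append(
                SnvRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    ref_count=int(ad[0]),
                    alt_count=int(ad[1]),
                    origin=origin,
                )
            )
    return out


def write_snv_table(snvs: Sequence[SnvRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tref_count\talt_count\torigin\n")
        for s in sorted(snvs, key=lambda s: (s.chrom, s.pos, s.alt_allele)):
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{s.ref_count}\t{s.alt_count}\t{s.origin}\n"
            )


# ---------------------------------------------------------------------------
# Generic reports
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_report(objects: Sequence, path, format: str = "TSV", sort_keys: Optional[list[str]] = None) -> None:
    """Serialize a list of dicts/dataclasses deterministically.

    TSV column order is the (stable) union of keys in first-seen order; rows
    are sorted by ``sort_keys`` when given.  JSON round-trips losslessly.
    """
    rows = [_to_plain(o) for o in objects]
    if sort_keys:
        rows = sorted(rows, key=lambda r: tuple(str(r.get(k)) for k in sort_keys))
    fmt = format.upper()
    if fmt == "JSON":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "TSV":
        cols: list[str] = []
        for r in rows:
            for k in r:
                if k not in cols:
                    cols.append(k)
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write(
                    "\t".join(
                        json.dumps(r.get(c)) if isinstance(r.get(c), (dict, list))
                        else str(r.get(c, ""))
                        for c in cols
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path):
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
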