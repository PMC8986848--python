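"""Read-level I/O: molecular-tag extraction and tagged-read streams.

The tag extraction stage consumes aligned raw reads whose base string still
carries the molecular tag as a 5' prefix and, for fragments shorter than the
read, a residual duplex-adapter suffix at the 3' end.  It emits
:class:`TaggedRead` records with the tag split off and the adapter trimmed.

Reads are exchanged either as a plain TSV dialect (columns ``read_id, tag,
chrom, start, strand, cigar, bases, quals``; quals phred+33 encoded) or as
SAM with the tag in an auxiliary string field (default ``RX``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

log = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_TAG_RE = re.compile(r"^[ACGTN]+$")


class ReadRejected(Exception):
    """A raw read that cannot yield a usable tagged read; .reason says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_query_length(cigar: str) -> int:
    """Number of read bases consumed by the alignment (M/I/S/=/X ops)."""
    return sum(n for op, n in parse_cigar(cigar) if op in "MIS=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases spanned (M/D/N/=/X ops)."""
    return sum(n for op, n in parse_cigar(cigar) if op in "MDN=X")


@dataclass(frozen=True)
class AdapterSpec:
    """Layout of the tag and residual duplex adapter on a raw read.

    The tag is a single contiguous stretch at the read's 5' end
    (``tag_position='prefix_5p'``); its length is a configuration knob,
    default 10 nt.
    """

    tag_length: int = 10
    tag_position: str = "prefix_5p"
    duplex_adapter_seq: str = "ATCTCGTATGCC"
    max_adapter_mismatches: int = 1
    min_adapter_overlap: int = 6

    def __post_init__(self) -> None:
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        if self.tag_position != "prefix_5p":
            raise ValueError(f"unsupported tag_position {self.tag_position!r}")
        if not re.fullmatch(r"[ACGT]+", self.duplex_adapter_seq):
            raise ValueError("duplex_adapter_seq must be over {A,C,G,T}")


@dataclass
class TaggedRead:
    """One aligned read with its molecular tag split off and adapter trimmed."""

    read_id: str
    tag: str
    chrom: str
    start: int  # 0-based leftmost reference position
    strand: str  # '+' (forward) or '-' (reverse)
    cigar: str
    bases: str
    quals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"bad strand {self.strand!r}")
        if not _TAG_RE.fullmatch(self.tag):
            raise ValueError(f"bad tag {self.tag!r}")
        if not self.quals:
            self.quals = [30] * len(self.bases)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases/quals length mismatch")

    @property
    def end(self) -> int:
        """One past the last reference position covered."""
        return self.start + cigar_reference_span(self.cigar)


@dataclass
class RawRead:
    """An aligned read before tag extraction: bases = tag + insert [+ adapter].

    ``cigar`` describes the insert's alignment (tag and adapter excluded), as
    produced by realignment of the trimmed sequence; it may be ``None`` for
    unaligned dialects, in which case adapter trimming falls back to suffix
    scanning.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    bases: str
    quals: Optional[list[int]] = None
    cigar: Optional[str] = None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_tag(raw: RawRead, spec: AdapterSpec) -> TaggedRead:
    """Split the molecular tag off a raw read and trim the 3' adapter residue.

    Raises :class:`ReadRejected` with reason ``too_short`` (read shorter than
    tag + 1 base), ``ambiguous_tag`` (more than one N in the tag), or
    ``adapter_mismatch`` (the suffix beyond the aligned insert does not match
    the duplex adapter within ``max_adapter_mismatches``).
    """
    L = spec.tag_length
    if len(raw.bases) < L + 1:
        raise ReadRejected("too_short")
    tag = raw.bases[:L]
    if tag.count("N") > 1:
        raise ReadRejected("ambiguous_tag")
    insert = raw.bases[L:]
    quals = raw.quals[L:] if raw.quals is not None else None

    adapter = spec.duplex_adapter_seq
    if raw.cigar is not None:
        qlen = cigar_query_length(raw.cigar)
        if qlen > len(insert):
            raise ReadRejected("cigar_mismatch")
        suffix = insert[qlen:]
        if suffix:
            if len(suffix) > len(adapter) or _hamming(
                suffix, adapter[: len(suffix)]
            ) > spec.max_adapter_mismatches:
                raise ReadRejected("adapter_mismatch")
            insert = insert[:qlen]
            quals = quals[:qlen] if quals is not None else None
        cigar = raw.cigar
    else:
        cut = _scan_adapter(insert, adapter, spec)
        insert = insert[:cut]
        quals = quals[:cut] if quals is not None else None
        cigar = f"{len(insert)}M"

    if not insert:
        raise ReadRejected("too_short")
    return TaggedRead(
        read_id=raw.read_id,
        tag=tag,
        chrom=raw.chrom,
        start=raw.start,
        strand=raw.strand,
        cigar=cigar,
        bases=insert,
        quals=quals if quals is not None else [],
    )


def _scan_adapter(insert: str, adapter: str, spec: AdapterSpec) -> int:
    """Longest 3' suffix of ``insert`` matching a prefix of ``adapter``."""
    lo = max(0, len(insert) - len(adapter))
    for i in range(lo, len(insert) - spec.min_adapter_overlap + 1):
        tail = insert[i:]
        if _hamming(tail, adapter[: len(tail)]) <= spec.max_adapter_mismatches:
            return i
    return len(insert)


def extract_tags(
    raws: Iterable[RawRead], spec: AdapterSpec, rejections: Optional[dict] = None
) -> Iterator[TaggedRead]:
    """Run :func:`extract_tag` over a stream, counting rejections by reason."""
    for raw in raws:
        try:
            yield extract_tag(raw, spec)
        except ReadRejected as exc:
            if rejections is not None:
                rejections[exc.reason] = rejections.get(exc.reason, 0) + 1
            log.warning("read %s rejected: %s", raw.read_id, exc.reason)


# ---------------------------------------------------------------------------
# TSV dialect

TSV_COLUMNS = ["read_id", "tag", "chrom", "start", "strand", "cigar", "bases", "quals"]


def _encode_quals(quals: list[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def _decode_quals(s: str) -> list[int]:
    return [ord(c) - 33 for c in s]


def write_tagged_reads(reads: Iterable[TaggedRead], path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.tag}\t{r.chrom}\t{r.start}\t{r.strand}\t"
                f"{r.cigar}\t{r.bases}\t{_encode_quals(r.quals)}\n"
            )
            n += 1
    return n


def _parse_tsv_line(line: str, colidx: dict[str, int]) -> TaggedRead:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != len(colidx):
        raise ValueError("wrong field count")
    get = lambda c: fields[colidx[c]]
    return TaggedRead(
        read_id=get("read_id"),
        tag=get("tag"),
        chrom=get("chrom"),
        start=int(get("start")),
        strand=get("strand"),
        cigar=get("cigar"),
        bases=get("bases"),
        quals=_decode_quals(get("quals")),
    )


def read_aligned_reads(
    path: str, format: str = "tsv_dialect", tag_field: str = "RX",
    skipped: Optional[dict] = None,
) -> Iterator[TaggedRead]:
    """Stream TaggedReads from a TSV-dialect or SAM file.

    Malformed records are counted (into ``skipped`` if given), logged and
    skipped; a SAM record without the tag auxiliary field raises
    ``ValueError("untagged_input")``.
    """
    if format == "tsv_dialect":
        yield from _read_tsv(path, skipped)
    elif format == "sam_like":
        yield from _read_sam(path, tag_field, skipped)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: str, skipped: Optional[dict]) -> Iterator[TaggedRead]:
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return
        cols = header.rstrip("\n").split("\t")
        if set(TSV_COLUMNS) - set(cols):
            raise ValueError(f"missing columns in {path}: need {TSV_COLUMNS}")
        colidx = {c: i for i, c in enumerate(cols)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                yield _parse_tsv_line(line, colidx)
            except (ValueError, IndexError) as exc:
                if skipped is not None:
                    skipped["malformed"] = skipped.get("malformed", 0) + 1
                log.warning("%s line %d skipped: %s", path, lineno, exc)


def _read_sam(path: str, tag_field: str, skipped: Optional[dict]) -> Iterator[TaggedRead]:
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                if skipped is not None:
                    skipped["unmapped"] = skipped.get("unmapped", 0) + 1
                continue
            if not rec.has_tag(tag_field):
                raise ValueError("untagged_input")
            quals = list(rec.query_qualities) if rec.query_qualities is not None else []
            try:
                yield TaggedRead(
                    read_id=rec.query_name,
                    tag=rec.get_tag(tag_field),
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand=REVERSE if rec.is_reverse else FORWARD,
                    cigar=rec.cigarstring,
                    bases=rec.query_sequence,
                    quals=quals,
                )
            except ValueError as exc:
                if skipped is not None:
                    skipped["malformed"] = skipped.get("malformed", 0) + 1
                log.warning("SAM record %s skipped: %s", rec.query_name, exc)


def write_sam(
    reads: Iterable[TaggedRead], path: str, contig_lengths: dict[str, int],
    tag_field: str = "RX",
) -> int:
    """Write tagged reads as SAM with the tag in an auxiliary field."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contig_lengths.items()],
    }
    n = 0
    with pysam.AlignmentFile(path, "w", header=header) as out:
        tid = {c: i for i, c in enumerate(contig_lengths)}
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.query_sequence = r.bases
            a.query_qualities = pysam.qualitystring_to_array(_encode_quals(r.quals))
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.cigarstring = r.cigar
            a.flag = 16 if r.strand == REVERSE else 0
            a.mapping_quality = 60
            a.set_tag(tag_field, r.tag)
            out.write(a)
            n += 1
    return n


def filter_on_panel(
    reads: Iterable[TaggedRead], panel, dropped: Optional[dict] = None
) -> Iterator[TaggedRead]:
    """Keep reads whose alignment start falls in a panel interval (on-target)."""
    for r in reads:
        if panel.contains(r.chrom, r.start) or panel.contains(r.chrom, max(r.end - 1, r.start)):
            yield r
        else:
            if dropped is not None:
                dropped["off_panel"] = dropped.get("off_panel", 0) + 1
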