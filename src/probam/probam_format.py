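"""The proBAM record model and its SAM-dialect text serialization.

proBAM is a SAM dialect in which the aligned unit is a peptide-spectrum
match rather than a sequencing read. A mapped record stores the peptide's
coding nucleotides (forward-genome orientation) as SEQ, a junction-aware
CIGAR (M segments separated by N introns), and proteomics payloads as
optional tags:

======  ====  =====================================================
tag     type  meaning
======  ====  =====================================================
XP      Z     peptide sequence
XM      Z     modifications, ``pos:delta;...`` or ``-``
XS      f     search score
XC      i     precursor charge
NH      i     number of genomic locations of this PSM
XD      i     decoy indicator (1 = matched the decoy database)
======  ====  =====================================================

Only five FLAG values are legal (dialect version 1): 0/16 primary mapped
forward/reverse, 256/272 secondary mapped, 4 unmapped. MAPQ is fixed at
255 (unavailable) — confidence lives in XS. Binary BAM encoding, sorting
and indexing are delegated to samtools; this module reads and writes the
text dialect only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .psm_io import format_modifications, parse_modifications

log = logging.getLogger(__name__)

DIALECT_VERSION = "1"

FLAG_FORWARD = 0
FLAG_REVERSE = 16
FLAG_UNMAPPED = 4
FLAG_SECONDARY_FORWARD = 256
FLAG_SECONDARY_REVERSE = 272
ALLOWED_FLAGS = (
    FLAG_FORWARD,
    FLAG_UNMAPPED,
    FLAG_REVERSE,
    FLAG_SECONDARY_FORWARD,
    FLAG_SECONDARY_REVERSE,
)

_CIGAR_RE = re.compile(r"^\d+M(\d+N\d+M)*$")
_CIGAR_OP_RE = re.compile(r"(\d+)([MN])")


@dataclass
class ProBAMRecord:
    """One genome-aligned (or unmapped) peptide-spectrum match."""

    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0  # 1-based leftmost mapped base; 0 when unmapped
    mapq: int = 255
    cigar: str = "*"
    seq: str = "*"
    peptide: Optional[str] = None
    modifications: List[Tuple[int, float]] = field(default_factory=list)
    score: Optional[float] = None
    charge: Optional[int] = None
    nh: Optional[int] = None
    decoy: int = 0
    extra_tags: List[str] = field(default_factory=list)  # raw TAG:TYPE:VALUE strings

    @property
    def is_mapped(self) -> bool:
        return self.flag != FLAG_UNMAPPED

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 256)

    @property
    def strand(self) -> str:
        """Genomic strand of the alignment ('+' when the reverse bit is unset)."""
        return "-" if self.flag & 16 else "+"

    def blocks(self) -> List[Tuple[int, int]]:
        """Aligned genomic intervals (0-based half-open) from pos + CIGAR."""
        if not self.is_mapped:
            return []
        out = []
        cursor = self.pos - 1
        for length, op in _CIGAR_OP_RE.findall(self.cigar):
            length = int(length)
            if op == "M":
                out.append((cursor, cursor + length))
            cursor += length
        return out

    def validate(self, sq: Optional[Dict[str, int]] = None) -> None:
        if self.flag not in ALLOWED_FLAGS:
            raise ValueError(
                f"record {self.qname}: flag {self.flag} not in allowed set {ALLOWED_FLAGS}"
            )
        if not self.is_mapped:
            return
        if self.pos < 1 or self.rname == "*":
            raise ValueError(f"record {self.qname}: mapped record needs rname and pos ≥ 1")
        if not _CIGAR_RE.match(self.cigar):
            raise ValueError(
                f"record {self.qname}: CIGAR {self.cigar!r} must be M segments "
                "separated by N gaps"
            )
        m_total = sum(
            int(n) for n, op in _CIGAR_OP_RE.findall(self.cigar) if op == "M"
        )
        if self.seq != "*" and len(self.seq) != m_total:
            raise ValueError(
                f"record {self.qname}: SEQ length {len(self.seq)} != M total {m_total}"
            )
        if self.peptide is not None and m_total != 3 * len(self.peptide):
            raise ValueError(
                f"record {self.qname}: M total {m_total} != 3 × peptide length "
                f"{len(self.peptide)}"
            )
        if sq is not None and self.rname not in sq:
            raise ValueError(f"record {self.qname}: rname {self.rname!r} not in header")


@dataclass
class ProBAMFile:
    """A proBAM file: sequence dictionary, provenance lines, records."""

    sq: Dict[str, int] = field(default_factory=dict)
    pg_lines: List[str] = field(default_factory=list)
    co_lines: List[str] = field(default_factory=list)
    records: List[ProBAMRecord] = field(default_factory=list)

    def mapped_records(self, include_decoys: bool = True) -> List[ProBAMRecord]:
        return [
            r
            for r in self.records
            if r.is_mapped and (include_decoys or not r.decoy)
        ]


def _format_tags(rec: ProBAMRecord) -> List[str]:
    tags = []
    if rec.peptide is not None:
        tags.append(f"XP:Z:{rec.peptide}")
    tags.append(f"XM:Z:{format_modifications(rec.modifications)}")
    if rec.score is not None:
        tags.append(f"XS:f:{rec.score!r}")
    if rec.charge is not None:
        tags.append(f"XC:i:{rec.charge}")
    if rec.nh is not None:
        tags.append(f"NH:i:{rec.nh}")
    tags.append(f"XD:i:{rec.decoy}")
    tags.extend(rec.extra_tags)
    return tags


def write_sam(file: ProBAMFile, path: str) -> None:
    """Serialize to SAM text; fails on any record violating the dialect."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in file.sq.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for line in file.pg_lines:
            fh.write(line + "\n")
        for line in file.co_lines:
            fh.write(line + "\n")
        for rec in file.records:
            rec.validate(file.sq)
            fields = [
                rec.qname,
                str(rec.flag),
                rec.rname,
                str(rec.pos),
                str(rec.mapq),
                rec.cigar,
                "*",
                "0",
                "0",
                rec.seq,
                "*",
            ] + _format_tags(rec)
            fh.write("\t".join(fields) + "\n")


def read_sam(path: str) -> ProBAMFile:
    """Parse a proBAM SAM file; inverse of :func:`write_sam`."""
    out = ProBAMFile()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                _parse_header_line(line, out)
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: truncated alignment line")
            flag = int(fields[1])
            if flag not in ALLOWED_FLAGS:
                raise ValueError(
                    f"{path}:{lineno}: flag {flag} is not a proBAM flag; "
                    f"allowed values are {ALLOWED_FLAGS}"
                )
            rec = ProBAMRecord(
                qname=fields[0],
                flag=flag,
                rname=fields[2],
                pos=int(fields[3]),
                mapq=int(fields[4]),
                cigar=fields[5],
                seq=fields[9],
            )
            seen = set()
            for tag in fields[11:]:
                name, typ, value = tag.split(":", 2)
                seen.add(name)
                if name == "XP":
                    rec.peptide = value
                elif name == "XM":
                    rec.modifications = parse_modifications(value)
                elif name == "XS":
                    rec.score = float(value)
                elif name == "XC":
                    rec.charge = int(value)
                elif name == "NH":
                    rec.nh = int(value)
                elif name == "XD":
                    rec.decoy = int(value)
                else:
                    rec.extra_tags.append(tag)
            for mandatory in ("XP", "XM", "XS", "XC", "XD"):
                if mandatory not in seen:
                    log.warning(
                        "%s:%d: record %s missing mandatory tag %s; kept with tag unset",
                        path,
                        lineno,
                        rec.qname,
                        mandatory,
                    )
            out.records.append(rec)
    return out


def _parse_header_line(line: str, out: ProBAMFile) -> None:
    if line.startswith("@SQ"):
        parts = dict(
            item.split(":", 1) for item in line.split("\t")[1:] if ":" in item
        )
        out.sq[parts["SN"]] = int(parts["LN"])
    elif line.startswith("@PG"):
        out.pg_lines.append(line)
    elif line.startswith("@CO"):
        out.co_lines.append(line)
    # @HD carries no dialect information; regenerated on write


def merge_probam(files: Sequence[ProBAMFile]) -> ProBAMFile:
    """Combine proBAM files sharing one sequence dictionary.

    The record multiset is the union; per-file provenance (@PG/@CO) is
    concatenated so the origin of every study remains visible.
    """
    if not files:
        raise ValueError("nothing to merge")
    first = files[0]
    for other in files[1:]:
        if list(other.sq.items()) != list(first.sq.items()):
            for name in first.sq:
                if other.sq.get(name) != first.sq[name]:
                    raise ValueError(
                        f"sequence dictionaries differ at {name!r}: "
                        f"{first.sq[name]} vs {other.sq.get(name)}"
                    )
            extra = next(iter(set(other.sq) - set(first.sq)), None)
            raise ValueError(f"sequence dictionaries differ at {extra!r}")
    merged = ProBAMFile(sq=dict(first.sq))
    for f in files:
        merged.pg_lines.extend(f.pg_lines)
        merged.co_lines.extend(f.co_lines)
        merged.records.extend(replace(r) for r in f.records)
    return merged


def provenance_comment(annotation_name: str, psm_fdr: Optional[float]) -> str:
    fdr_text = "NA" if psm_fdr is None else f"{psm_fdr:g}"
    return f"@CO\tproBAM:annotation={annotation_name};psm_fdr={fdr_text}"
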