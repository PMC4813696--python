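"""Genome annotation model and protein↔CDS↔genome coordinate arithmetic.

A :class:`GenomeAnnotation` holds transcript models (ordered exon and CDS
blocks, strand, gene and protein links) together with the genome sequence,
and answers the two questions every peptide-to-genome mapper needs:

* what is the coding nucleotide sequence of a transcript, and
* which genomic bases encode amino acids ``aa_start..aa_end`` of a protein.

Coordinates are 0-based half-open internally; 1-based coordinates appear
only at SAM serialization time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from . import intervals

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class GenomicBlock:
    """A contiguous genomic interval, 0-based half-open, on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty block {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS blocks in transcription order.

    Transcription order means ascending genomic coordinates on ``+`` and
    descending on ``-``. ``protein_id`` is set only for transcripts whose
    CDS passed validation (length a multiple of 3, CDS inside exons).
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: List[GenomicBlock] = field(default_factory=list)
    cds: List[GenomicBlock] = field(default_factory=list)
    protein_id: Optional[str] = None

    @property
    def chrom(self) -> str:
        return (self.cds or self.exons)[0].chrom

    @property
    def cds_length(self) -> int:
        return sum(len(b) for b in self.cds)

    def cds_sorted(self) -> List[GenomicBlock]:
        """CDS blocks in ascending genomic order regardless of strand."""
        return sorted(self.cds, key=lambda b: b.start)

    def introns(self) -> List[Tuple[int, int]]:
        """Gaps between consecutive CDS blocks, ascending genomic order."""
        blocks = self.cds_sorted()
        return [(blocks[i].end, blocks[i + 1].start) for i in range(len(blocks) - 1)]


class GenomeAnnotation:
    """Indexed transcript models plus the genome they live on.

    ``genome`` may be a :class:`pyfaidx.Fasta` or a plain mapping of
    chromosome name to sequence string; both support the slicing used here.
    """

    def __init__(
        self,
        transcripts: Dict[str, TranscriptModel],
        chrom_lengths: Dict[str, int],
        genome: Optional[Mapping[str, object]] = None,
        name: str = "unnamed",
    ) -> None:
        self.transcripts = transcripts
        self.chrom_lengths = dict(chrom_lengths)
        self.genome = genome
        self.name = name
        self.genes: Dict[str, List[str]] = {}
        self.protein_index: Dict[str, str] = {}
        for tid, tx in transcripts.items():
            self.genes.setdefault(tx.gene_id, []).append(tid)
            if tx.protein_id is not None:
                if tx.protein_id in self.protein_index:
                    raise ValueError(
                        f"protein_id {tx.protein_id} linked to more than one transcript"
                    )
                self.protein_index[tx.protein_id] = tid

    # -- sequence access ---------------------------------------------------

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand genome sequence for [start, end), uppercase."""
        if self.genome is None:
            raise ValueError("annotation was loaded without a genome sequence")
        seq = self.genome[chrom][start:end]
        return str(seq).upper()

    def coding_sequence(self, transcript_id: str, trim_stop: bool = False) -> str:
        """Concatenated CDS nucleotides in transcription order.

        Minus-strand blocks are reverse-complemented, so the result reads
        5'→3' in mRNA orientation. With ``trim_stop`` a trailing stop codon
        (annotation dialects differ on whether the CDS includes it) is
        removed.
        """
        tx = self._get_transcript(transcript_id)
        parts = []
        for b in tx.cds:
            s = self.fetch(b.chrom, b.start, b.end)
            if tx.strand == "-":
                s = str(Seq(s).reverse_complement())
            parts.append(s)
        seq = "".join(parts)
        if trim_stop and len(seq) >= 3 and seq[-3:] in ("TAA", "TAG", "TGA"):
            seq = seq[:-3]
        return seq

    # -- coordinate arithmetic ---------------------------------------------

    def cds_to_genome(self, transcript_id: str, off_start: int, off_end: int) -> List[GenomicBlock]:
        """Map a half-open CDS-offset range to genomic blocks.

        Offsets count nucleotides along the coding sequence in transcription
        order. Blocks are returned in transcription order; a new block starts
        exactly where the CDS jumps an intron.
        """
        tx = self._get_transcript(transcript_id)
        if not 0 <= off_start < off_end <= tx.cds_length:
            raise ValueError(
                f"CDS offsets [{off_start},{off_end}) out of range for "
                f"{transcript_id} (CDS length {tx.cds_length})"
            )
        out: List[GenomicBlock] = []
        walked = 0
        for b in tx.cds:
            blen = len(b)
            lo = max(off_start, walked)
            hi = min(off_end, walked + blen)
            if lo < hi:
                if tx.strand == "+":
                    gs, ge = b.start + (lo - walked), b.start + (hi - walked)
                else:
                    gs, ge = b.end - (hi - walked), b.end - (lo - walked)
                out.append(GenomicBlock(b.chrom, gs, ge, tx.strand))
            walked += blen
        return out

    def protein_to_genome(self, protein_id: str, aa_start: int, aa_end: int) -> List[GenomicBlock]:
        """Genomic blocks encoding amino acids ``aa_start..aa_end`` (1-based,
        inclusive) of a protein, in transcription order."""
        if protein_id not in self.protein_index:
            raise KeyError(f"unknown protein_id {protein_id!r}")
        tid = self.protein_index[protein_id]
        tx = self.transcripts[tid]
        n_codons = tx.cds_length // 3
        if not 1 <= aa_start <= aa_end <= n_codons:
            raise ValueError(
                f"amino-acid range {aa_start}-{aa_end} out of bounds for "
                f"{protein_id} ({n_codons} codons)"
            )
        return self.cds_to_genome(tid, 3 * (aa_start - 1), 3 * aa_end)

    def genome_offset_in_cds(self, transcript_id: str, chrom: str, pos: int) -> Optional[int]:
        """CDS offset (transcription order) of genomic base ``pos``, or None."""
        tx = self._get_transcript(transcript_id)
        walked = 0
        for b in tx.cds:
            if b.chrom == chrom and b.start <= pos < b.end:
                if tx.strand == "+":
                    return walked + (pos - b.start)
                return walked + (b.end - 1 - pos)
            walked += len(b)
        return None

    def gene_cds_union(self, gene_id: str) -> List[GenomicBlock]:
        """Merged union of CDS intervals over all transcripts of a gene."""
        if gene_id not in self.genes:
            raise KeyError(f"unknown gene_id {gene_id!r}")
        by_chrom: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for tid in self.genes[gene_id]:
            tx = self.transcripts[tid]
            for b in tx.cds:
                by_chrom.setdefault((b.chrom, tx.strand), []).append((b.start, b.end))
        out: List[GenomicBlock] = []
        for (chrom, strand), ivs in sorted(by_chrom.items()):
            out.extend(GenomicBlock(chrom, s, e, strand) for s, e in intervals.merge(ivs))
        return out

    def transcripts_by_chrom(self) -> Dict[str, List[TranscriptModel]]:
        by_chrom: Dict[str, List[TranscriptModel]] = {}
        for tx in self.transcripts.values():
            if tx.cds:
                by_chrom.setdefault(tx.chrom, []).append(tx)
        return by_chrom

    def _get_transcript(self, transcript_id: str) -> TranscriptModel:
        try:
            return self.transcripts[transcript_id]
        except KeyError:
            raise KeyError(f"unknown transcript_id {transcript_id!r}") from None


def _transcription_sort(blocks: List[GenomicBlock], strand: str) -> List[GenomicBlock]:
    return sorted(blocks, key=lambda b: b.start, reverse=(strand == "-"))


def load_annotation(
    gtf_path: str,
    fasta_path: str,
    name: Optional[str] = None,
    protein_fasta: Optional[str] = None,
    protein_link_pattern: str = r"transcript[:=](\S+)",
) -> GenomeAnnotation:
    """Load a GTF/GFF annotation and genome FASTA into a GenomeAnnotation.

    Transcripts whose CDS length is not a multiple of 3, or whose CDS falls
    outside the annotated exons, are kept but excluded from the protein
    index with a logged warning — these usually reflect incorrect
    annotation rather than bad input. If the GTF lacks ``protein_id``
    attributes, links can be recovered from protein FASTA headers whose
    description matches ``protein_link_pattern`` against a transcript id.
    """
    genome = Fasta(fasta_path)
    chrom_lengths = {name_: len(rec) for name_, rec in genome.items()}

    try:
        db = gffutils.create_db(
            gtf_path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        features = list(db.all_features())
    except gffutils.exceptions.EmptyInputError:
        features = []

    raw: Dict[str, dict] = {}
    for feature in features:
        if feature.featuretype not in ("exon", "CDS"):
            continue
        attrs = feature.attributes
        tid = _first_attr(attrs, "transcript_id", "Parent")
        gid = _first_attr(attrs, "gene_id") or tid
        if tid is None:
            raise ValueError(f"feature without transcript_id/Parent at line {feature}")
        if feature.seqid not in chrom_lengths:
            raise ValueError(
                f"chromosome {feature.seqid!r} in annotation is absent from the genome FASTA"
            )
        entry = raw.setdefault(
            tid, {"gene": gid, "strand": feature.strand, "exons": [], "cds": [], "protein": None}
        )
        block = GenomicBlock(feature.seqid, feature.start - 1, feature.end, feature.strand)
        entry["exons" if feature.featuretype == "exon" else "cds"].append(block)
        if feature.featuretype == "CDS":
            pid = _first_attr(attrs, "protein_id")
            if pid is not None:
                entry["protein"] = pid

    transcripts: Dict[str, TranscriptModel] = {}
    for tid, entry in raw.items():
        strand = entry["strand"]
        exons = _transcription_sort(entry["exons"], strand)
        cds = _transcription_sort(entry["cds"], strand)
        tx = TranscriptModel(tid, entry["gene"], strand, exons, cds, None)
        pid = entry["protein"]
        if pid is not None and cds:
            if tx.cds_length % 3 != 0:
                log.warning(
                    "transcript %s: CDS length %d not a multiple of 3; "
                    "excluded from protein index",
                    tid,
                    tx.cds_length,
                )
            elif exons and not _cds_within_exons(cds, exons):
                log.warning(
                    "transcript %s: CDS extends outside annotated exons; "
                    "excluded from protein index",
                    tid,
                )
            else:
                tx.protein_id = pid
        transcripts[tid] = tx

    if protein_fasta is not None:
        _link_from_fasta(transcripts, protein_fasta, protein_link_pattern)

    return GenomeAnnotation(
        transcripts, chrom_lengths, genome, name=name or gtf_path
    )


def _first_attr(attrs, *keys) -> Optional[str]:
    for key in keys:
        if key in attrs and attrs[key]:
            return attrs[key][0]
    return None


def _cds_within_exons(cds: Sequence[GenomicBlock], exons: Sequence[GenomicBlock]) -> bool:
    exon_ivs = [(e.start, e.end) for e in exons]
    return all(intervals.contains(exon_ivs, c.start, c.end) for c in cds)


def _link_from_fasta(transcripts: Dict[str, TranscriptModel], fasta_path: str, pattern: str) -> None:
    """Link protein ids to transcripts via FASTA header tokens."""
    rx = re.compile(pattern)
    with open(fasta_path) as fh:
        for line in fh:
            if not line.startswith(">"):
                continue
            header = line[1:].strip()
            pid = header.split()[0]
            m = rx.search(header)
            if m is None:
                continue
            tid = m.group(1)
            tx = transcripts.get(tid)
            if tx is not None and tx.protein_id is None and tx.cds and tx.cds_length % 3 == 0:
                tx.protein_id = pid
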