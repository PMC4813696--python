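"""Three-step mapping of filtered PSMs to genome-aligned proBAM records.

Step 1 locates the peptide in each matched protein sequence; step 2 pulls
the corresponding slice of the protein's coding sequence; step 3 converts
that slice to genomic blocks via the transcript's exon structure. Every
candidate location is validated by translating the genomic bases back:
a location whose presumed coding sequence does not reproduce the peptide
(usually incorrect annotation) is discarded.

Decoy PSMs carry reversed peptide sequences. They are placed at the
genomic location of their forward (un-reversed) twin with the strand flag
flipped and XD:i:1, so decoy matches stay visible to protein- and
gene-level FDR estimation downstream.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Sequence, Tuple

from Bio.Seq import Seq

from .annotation import GenomeAnnotation, GenomicBlock
from .probam_format import (
    FLAG_FORWARD,
    FLAG_REVERSE,
    FLAG_SECONDARY_FORWARD,
    FLAG_SECONDARY_REVERSE,
    FLAG_UNMAPPED,
    ProBAMFile,
    ProBAMRecord,
    provenance_comment,
)
from .psm_io import DEFAULT_DECOY_PREFIXES, PSMRecord, strip_decoy_prefix

log = logging.getLogger(__name__)

__version__ = "0.1.0"


def locate_in_protein(peptide: str, protein_sequence: str) -> List[Tuple[int, int]]:
    """All occurrences of ``peptide`` in ``protein_sequence``.

    Returns 1-based inclusive (aa_start, aa_end) pairs, leftmost first;
    overlapping occurrences are reported. Matching is exact — no I/L
    equivalence unless the caller normalizes beforehand.
    """
    if not peptide or not protein_sequence:
        return []
    out = []
    start = protein_sequence.find(peptide)
    while start != -1:
        out.append((start + 1, start + len(peptide)))
        start = protein_sequence.find(peptide, start + 1)
    return out


def translate_blocks(annotation: GenomeAnnotation, blocks: Sequence[GenomicBlock]) -> str:
    """Strand-aware conceptual translation of the bases under ``blocks``.

    Blocks are read in genomic order on '+', reversed and complemented
    on '-'; the standard genetic code (table 1) is used.
    """
    ordered = sorted(blocks, key=lambda b: b.start)
    nt = "".join(annotation.fetch(b.chrom, b.start, b.end) for b in ordered)
    if blocks[0].strand == "-":
        nt = str(Seq(nt).reverse_complement())
    return str(Seq(nt).translate())


def _blocks_to_cigar(blocks: Sequence[Tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def map_psm(
    psm: PSMRecord,
    annotation: GenomeAnnotation,
    proteins: Mapping[str, str],
    decoy_prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES,
) -> List[ProBAMRecord]:
    """Map one PSM to all of its genomic locations.

    One record is emitted per distinct location (chrom, blocks, strand)
    across all protein hits; the location with the smallest (chrom, pos)
    is primary, the rest secondary. If no location validates, a single
    unmapped (flag 4) record is returned so the identification is not
    silently lost.
    """
    query = psm.peptide[::-1] if psm.is_decoy else psm.peptide
    locations: Dict[Tuple[str, Tuple[Tuple[int, int], ...], str], List[GenomicBlock]] = {}

    for hit in psm.protein_hits:
        accession = strip_decoy_prefix(hit, decoy_prefixes) if psm.is_decoy else hit
        protein_seq = proteins.get(accession)
        tid = annotation.protein_index.get(accession)
        if protein_seq is None and tid is not None:
            # protein absent from the FASTA: derive it from the annotation
            protein_seq = str(
                Seq(annotation.coding_sequence(tid, trim_stop=True)).translate()
            )
        if protein_seq is None or tid is None:
            log.warning(
                "PSM %s: protein hit %s absent from %s; hit skipped",
                psm.spectrum_id,
                hit,
                "annotation" if protein_seq is not None else "FASTA and annotation",
            )
            continue
        for aa_start, aa_end in locate_in_protein(query, protein_seq):
            try:
                blocks = annotation.protein_to_genome(accession, aa_start, aa_end)
            except ValueError:
                continue
            if translate_blocks(annotation, blocks) != query:
                log.warning(
                    "PSM %s: encoding sequence at %s aa %d-%d inconsistent with "
                    "peptide; location discarded",
                    psm.spectrum_id,
                    accession,
                    aa_start,
                    aa_end,
                )
                continue
            key = (
                blocks[0].chrom,
                tuple(sorted((b.start, b.end) for b in blocks)),
                blocks[0].strand,
            )
            locations.setdefault(key, blocks)

    if not locations:
        return [_unmapped_record(psm)]

    ordered = sorted(locations.items(), key=lambda kv: (kv[0][0], kv[0][1][0][0]))
    records = []
    for idx, ((chrom, ivs, strand), _) in enumerate(ordered):
        mapped_strand = _flip(strand) if psm.is_decoy else strand
        if idx == 0:
            flag = FLAG_FORWARD if mapped_strand == "+" else FLAG_REVERSE
        else:
            flag = (
                FLAG_SECONDARY_FORWARD if mapped_strand == "+" else FLAG_SECONDARY_REVERSE
            )
        seq = "".join(annotation.fetch(chrom, s, e) for s, e in ivs)
        records.append(
            ProBAMRecord(
                qname=psm.spectrum_id,
                flag=flag,
                rname=chrom,
                pos=ivs[0][0] + 1,
                cigar=_blocks_to_cigar(ivs),
                seq=seq,
                peptide=psm.peptide,
                modifications=list(psm.modifications),
                score=psm.score,
                charge=psm.charge,
                nh=len(ordered),
                decoy=int(psm.is_decoy),
            )
        )
    return records


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _unmapped_record(psm: PSMRecord) -> ProBAMRecord:
    return ProBAMRecord(
        qname=psm.spectrum_id,
        flag=FLAG_UNMAPPED,
        peptide=psm.peptide,
        modifications=list(psm.modifications),
        score=psm.score,
        charge=psm.charge,
        nh=0,
        decoy=int(psm.is_decoy),
    )


def build_probam(
    psms: Sequence[PSMRecord],
    annotation: GenomeAnnotation,
    proteins: Mapping[str, str],
    psm_fdr: float = None,
    decoy_prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES,
) -> ProBAMFile:
    """Map a filtered PSM list into a complete proBAM file.

    The header's sequence dictionary comes from the annotation's genome;
    provenance (@PG/@CO) records the annotation scheme and the PSM FDR the
    input was filtered at.
    """
    file = ProBAMFile(sq=dict(annotation.chrom_lengths))
    file.pg_lines.append(f"@PG\tID:probam\tPN:probam\tVN:{__version__}")
    file.co_lines.append(provenance_comment(annotation.name, psm_fdr))
    n_mapped = n_unmapped = n_decoy = 0
    for psm in psms:
        records = map_psm(psm, annotation, proteins, decoy_prefixes)
        file.records.extend(records)
        if records[0].is_mapped:
            n_mapped += 1
        else:
            n_unmapped += 1
        n_decoy += int(psm.is_decoy)
    log.info(
        "mapped %d PSMs (%d unmapped, %d decoy) into %d records",
        n_mapped,
        n_unmapped,
        n_decoy,
        len(file.records),
    )
    return file
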