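"""Shared fixtures: generated references and hand-built toy annotations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import pytest

from probam.annotation import GenomeAnnotation, GenomicBlock, TranscriptModel
from probam.fixtures import Reference, make_reference
from probam.annotation import load_annotation


@dataclass
class LoadedReference:
    ref: Reference
    ann: GenomeAnnotation
    gtf: str
    fasta: str
    proteins: str


@pytest.fixture(scope="session")
def ref20(tmp_path_factory) -> LoadedReference:
    """The default 20-gene synthetic reference (seed 7), loaded from disk."""
    ref = make_reference(7, n_genes=20, isoform_rate=0.5)
    outdir = tmp_path_factory.mktemp("ref20")
    gtf, fasta, prot = ref.write(str(outdir))
    ann = load_annotation(gtf, fasta, name="schemeA")
    return LoadedReference(ref, ann, gtf, fasta, prot)


def build_toy_annotation(
    cds_seq: str,
    blocks,
    strand: str = "+",
    chrom: str = "chrT",
    chrom_len: int = 1000,
    gene_id: str = "G1",
    transcript_id: str = "T1",
    protein_id: str = "P1",
    extra_transcripts=(),
) -> GenomeAnnotation:
    """Build an in-memory single-gene annotation with a planted CDS.

    ``blocks`` are ascending (start, end) genomic intervals whose total
    length must equal len(cds_seq); the genome is 'A' background with the
    coding bases written in (reverse-complemented on '-').
    """
    from probam.fixtures import _revcomp

    total = sum(e - s for s, e in blocks)
    assert total == len(cds_seq)
    genome_arr = ["A"] * chrom_len
    tx_blocks = list(blocks) if strand == "+" else list(blocks)[::-1]
    offset = 0
    for s, e in tx_blocks:
        piece = cds_seq[offset:offset + (e - s)]
        offset += e - s
        genome_arr[s:e] = list(piece if strand == "+" else _revcomp(piece))
    genome: Dict[str, str] = {chrom: "".join(genome_arr)}

    gblocks = [GenomicBlock(chrom, s, e, strand) for s, e in tx_blocks]
    transcripts = {
        transcript_id: TranscriptModel(
            transcript_id, gene_id, strand, list(gblocks), list(gblocks), protein_id
        )
    }
    for tx in extra_transcripts:
        transcripts[tx.transcript_id] = tx
    return GenomeAnnotation(transcripts, {chrom: chrom_len}, genome, name="toy")
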