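"""Synthetic reference data with recorded ground truth.

Generates a fully self-consistent toy proteogenomics world: a genome
FASTA, a GTF with multi-exon genes on both strands (optionally with
alternative isoforms produced by exon skipping, the dominant source of
intra-gene shared peptides), a protein FASTA translated from the CDSs,
and tryptic PSM tables with reversed-sequence decoys. Every generated
peptide's true genomic location is recorded, so tests can compare mapper
and reannotation output against exact expectations.

Exon lengths are whole codons, which keeps exon skipping frame-preserving
and makes truth bookkeeping exact; real annotations are messier (see the
methods note for what this generator does not emulate).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq
from pyteomics import mass as pmass

from .psm_io import PSMRecord

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

OXIDATION_DELTA = 15.9949


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tryptic_peptides(
    sequence: str,
    min_length: int = 6,
    missed_cleavages: int = 0,
    proline_rule: bool = False,
) -> List[str]:
    """In-silico tryptic digest: cleave after K/R (optionally not before P)."""
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(sequence))
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            pep = sequence[cuts[i]:cuts[j]]
            if len(pep) >= min_length:
                peptides.append(pep)
    return peptides


@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    protein_id: str
    chrom: str
    strand: str
    cds: List[Tuple[int, int]]  # transcription order, 0-based half-open
    protein: str

    def base_positions(self) -> List[int]:
        """Genomic position of every CDS base, in transcription order."""
        out: List[int] = []
        for s, e in self.cds:
            out.extend(range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1))
        return out


@dataclass
class PeptideLocationTruth:
    protein_id: str
    transcript_id: str
    chrom: str
    strand: str
    aa_start: int
    aa_end: int
    blocks: Tuple[Tuple[int, int], ...]  # ascending genomic order


@dataclass
class FixtureTruth:
    """Ground truth recorded while generating a synthetic reference."""

    transcripts: Dict[str, TranscriptTruth] = field(default_factory=dict)
    proteins: Dict[str, str] = field(default_factory=dict)
    peptides: Dict[str, List[PeptideLocationTruth]] = field(default_factory=dict)
    gene_extents: Dict[str, Tuple[str, int, int]] = field(default_factory=dict)

    def target_peptides(self) -> List[str]:
        return sorted(self.peptides)

    def proteins_containing(self, peptide: str) -> List[str]:
        return sorted(pid for pid, seq in self.proteins.items() if peptide in seq)

    def gene_of_position(self, chrom: str, pos: int) -> Optional[str]:
        for gene, (c, lo, hi) in self.gene_extents.items():
            if c == chrom and lo <= pos < hi:
                return gene
        return None


@dataclass
class Reference:
    """A generated reference: genome, annotation text, proteins, truth."""

    genome: Dict[str, str]
    gtf_text: str
    protein_fasta_text: str
    truth: FixtureTruth
    name: str = "schemeA"

    def write(self, outdir: str) -> Tuple[str, str, str]:
        os.makedirs(outdir, exist_ok=True)
        fasta = os.path.join(outdir, "genome.fa")
        gtf = os.path.join(outdir, f"{self.name}.gtf")
        prot = os.path.join(outdir, "proteins.fa")
        with open(fasta, "w") as fh:
            for chrom in self.genome:
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        with open(gtf, "w") as fh:
            fh.write(self.gtf_text)
        with open(prot, "w") as fh:
            fh.write(self.protein_fasta_text)
        return gtf, fasta, prot


def _gtf_lines(
    chrom: str,
    strand: str,
    gene_id: str,
    tid: str,
    pid: str,
    blocks: Sequence[Tuple[int, int]],
) -> List[str]:
    lines = []
    for s, e in sorted(blocks):
        attrs = f'gene_id "{gene_id}"; transcript_id "{tid}"; protein_id "{pid}";'
        for feat in ("exon", "CDS"):
            lines.append(
                "\t".join(
                    [chrom, "probam_sim", feat, str(s + 1), str(e), ".", strand, ".", attrs]
                )
            )
    return lines


def _translate_codons(cds_seq: str) -> str:
    return str(Seq(cds_seq).translate())


def make_reference(
    seed: int,
    n_genes: int = 20,
    isoform_rate: float = 0.5,
) -> Reference:
    """Generate a synthetic genome, annotation, proteome and truth.

    Genes alternate strands across two chromosomes; each has 1-4 exons of
    10-30 whole codons separated by 40-200 nt introns. With probability
    ``isoform_rate`` a gene with ≥3 exons gains a second isoform that
    skips one internal exon, creating intra-gene shared peptides.
    Deterministic under ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be ≥ 1")
    if not 0.0 <= isoform_rate <= 1.0:
        raise ValueError("isoform_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = FixtureTruth()
    gtf_lines: List[str] = []
    fasta_entries: List[Tuple[str, str, str]] = []  # pid, tid, seq
    chrom_genes: Dict[str, List[dict]] = {"chr1": [], "chr2": []}

    for i in range(n_genes):
        gene_id = f"GENE{i + 1}"
        chrom = "chr1" if i < (n_genes + 1) // 2 else "chr2"
        strand = "+" if i % 2 == 0 else "-"
        if rng.random() < 0.15 and i != 0:
            n_exons = 1
        else:
            n_exons = int(rng.integers(2, 5))
        exon_lens = [3 * int(rng.integers(10, 31)) for _ in range(n_exons)]
        introns = [int(rng.integers(40, 201)) for _ in range(n_exons - 1)]
        total_codons = sum(exon_lens) // 3
        codon_idx = rng.integers(0, len(_SENSE_CODONS), size=total_codons - 1)
        cds_seq = "ATG" + "".join(_SENSE_CODONS[j] for j in codon_idx)
        chrom_genes[chrom].append(
            {
                "gene_id": gene_id,
                "strand": strand,
                "exon_lens": exon_lens,
                "introns": introns,
                "cds_seq": cds_seq,
                "skip_exon": (
                    1 + int(rng.integers(0, n_exons - 2))
                    if n_exons >= 3 and rng.random() < isoform_rate
                    else None
                ),
            }
        )

    genome: Dict[str, str] = {}
    for chrom, genes in chrom_genes.items():
        cursor = 0
        segments: List[Tuple[int, int, str]] = []  # start, end, bases (forward)
        for g in genes:
            cursor += int(rng.integers(100, 301))
            blocks: List[Tuple[int, int]] = []
            for j, length in enumerate(g["exon_lens"]):
                blocks.append((cursor, cursor + length))
                cursor += length
                if j < len(g["introns"]):
                    cursor += g["introns"][j]
            g["blocks"] = blocks  # ascending genomic order
            # transcription order
            tx_blocks = blocks if g["strand"] == "+" else blocks[::-1]
            offset = 0
            for s, e in tx_blocks:
                piece = g["cds_seq"][offset:offset + (e - s)]
                offset += e - s
                segments.append((s, e, piece if g["strand"] == "+" else _revcomp(piece)))
        cursor += int(rng.integers(100, 301))
        chrom_len = cursor
        arr = rng.integers(0, 4, size=chrom_len)
        seq = np.array(list("ACGT"))[arr]
        for s, e, piece in segments:
            seq[s:e] = list(piece)
        genome[chrom] = "".join(seq)

        for idx, g in enumerate(genes):
            gene_id = g["gene_id"]
            gnum = gene_id[4:]
            tid, pid = f"TX{gnum}", f"PROT{gnum}"
            tx_blocks = g["blocks"] if g["strand"] == "+" else g["blocks"][::-1]
            protein = _translate_codons(g["cds_seq"])
            tx = TranscriptTruth(tid, gene_id, pid, chrom, g["strand"], list(tx_blocks), protein)
            truth.transcripts[tid] = tx
            truth.proteins[pid] = protein
            gtf_lines.extend(_gtf_lines(chrom, g["strand"], gene_id, tid, pid, g["blocks"]))
            fasta_entries.append((pid, tid, protein))
            lo = min(s for s, _ in g["blocks"])
            hi = max(e for _, e in g["blocks"])
            truth.gene_extents[gene_id] = (chrom, lo, hi)
            if g["skip_exon"] is not None:
                skip = g["skip_exon"]  # index in transcription order
                iso_blocks = [b for j, b in enumerate(tx_blocks) if j != skip]
                drop_from = sum(e - s for s, e in tx_blocks[:skip]) // 3
                drop_len = (tx_blocks[skip][1] - tx_blocks[skip][0]) // 3
                protein2 = protein[:drop_from] + protein[drop_from + drop_len:]
                tid2, pid2 = f"TX{gnum}b", f"PROT{gnum}b"
                tx2 = TranscriptTruth(
                    tid2, gene_id, pid2, chrom, g["strand"], iso_blocks, protein2
                )
                truth.transcripts[tid2] = tx2
                truth.proteins[pid2] = protein2
                gtf_lines.extend(
                    _gtf_lines(chrom, g["strand"], gene_id, tid2, pid2, sorted(iso_blocks))
                )
                fasta_entries.append((pid2, tid2, protein2))

    _record_peptide_truth(truth)

    fasta_text = []
    for pid, tid, seq in fasta_entries:
        fasta_text.append(f">{pid} transcript:{tid}")
        for i in range(0, len(seq), 60):
            fasta_text.append(seq[i:i + 60])
    return Reference(
        genome=genome,
        gtf_text="\n".join(gtf_lines) + "\n",
        protein_fasta_text="\n".join(fasta_text) + "\n",
        truth=truth,
    )


def _record_peptide_truth(truth: FixtureTruth) -> None:
    """Digest every protein and record each peptide's true locations."""
    all_peptides = set()
    for protein in truth.proteins.values():
        all_peptides.update(tryptic_peptides(protein))
    for pep in sorted(all_peptides):
        locs: List[PeptideLocationTruth] = []
        seen_blocks = set()
        for tid in sorted(truth.transcripts):
            tx = truth.transcripts[tid]
            start = tx.protein.find(pep)
            while start != -1:
                aa_start, aa_end = start + 1, start + len(pep)
                positions = tx.base_positions()[3 * start:3 * aa_end]
                blocks = _runs(sorted(positions))
                key = (tx.chrom, blocks, tx.strand)
                if key not in seen_blocks:
                    seen_blocks.add(key)
                    locs.append(
                        PeptideLocationTruth(
                            tx.protein_id, tid, tx.chrom, tx.strand, aa_start, aa_end, blocks
                        )
                    )
                start = tx.protein.find(pep, start + 1)
        truth.peptides[pep] = locs


def _runs(sorted_positions: Sequence[int]) -> Tuple[Tuple[int, int], ...]:
    blocks = []
    run_start = prev = sorted_positions[0]
    for p in sorted_positions[1:]:
        if p != prev + 1:
            blocks.append((run_start, prev + 1))
            run_start = p
        prev = p
    blocks.append((run_start, prev + 1))
    return tuple(blocks)


def simulate_psms(
    truth: FixtureTruth,
    seed: int,
    n_psms: int = 1000,
    decoy_fraction: float = 0.1,
    score_separation: float = 3.0,
    mod_fraction: float = 0.1,
    run_name: str = "run1",
) -> List[PSMRecord]:
    """Simulate a PSM table from the fixture's tryptic peptide pool.

    Target scores are drawn from N(score_separation, 1) and decoy scores
    from N(0, 1); since FDR estimation depends only on rank, any monotone
    score would behave identically. Decoy peptides are reversed target
    peptides with ``rev_``-prefixed accessions. A fraction of PSMs carries
    a methionine-oxidation modification when the sequence permits.
    """
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = truth.target_peptides()
    if not pool:
        raise ValueError("fixture contains no digestible peptides of length ≥ 6")
    psms: List[PSMRecord] = []
    for i in range(n_psms):
        pep = pool[int(rng.integers(0, len(pool)))]
        hits = truth.proteins_containing(pep)
        is_decoy = bool(rng.random() < decoy_fraction)
        if is_decoy:
            sequence = pep[::-1]
            hits = [f"rev_{h}" for h in hits]
            score = float(rng.normal(0.0, 1.0))
        else:
            sequence = pep
            score = float(rng.normal(score_separation, 1.0))
        charge = 2 + int(rng.random() < 0.3)
        mods: List[Tuple[int, float]] = []
        if rng.random() < mod_fraction and "M" in sequence:
            positions = [j + 1 for j, aa in enumerate(sequence) if aa == "M"]
            mods.append((positions[int(rng.integers(0, len(positions)))], OXIDATION_DELTA))
        psms.append(
            PSMRecord(
                spectrum_id=f"{run_name}.{i + 1:05d}.{i + 1:05d}.{charge}",
                peptide=sequence,
                modifications=mods,
                charge=charge,
                score=score,
                protein_hits=hits,
                is_decoy=is_decoy,
            )
        )
    return psms


def write_pepxml(psms: Sequence[PSMRecord], path: str, score_name: str = "probam_score") -> None:
    """Write PSMs as a minimal pepXML (spectrum_query/search_hit subset)."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<msms_pipeline_analysis xmlns="http://regis-web.systemsbiology.net/pepXML"'
        ' summary_xml="probam.pep.xml">',
        ' <msms_run_summary base_name="probam" raw_data_type="raw" raw_data=".mzML">',
        '  <search_summary base_name="probam" search_engine="probam-sim"'
        ' precursor_mass_type="monoisotopic" fragment_mass_type="monoisotopic"/>',
    ]
    for i, psm in enumerate(psms, 1):
        delta_total = sum(d for _, d in psm.modifications)
        neutral = pmass.fast_mass(psm.peptide) + delta_total
        lines.append(
            f'  <spectrum_query spectrum="{psm.spectrum_id}" start_scan="{i}"'
            f' end_scan="{i}" precursor_neutral_mass="{neutral:.4f}"'
            f' assumed_charge="{psm.charge}" index="{i}">'
        )
        lines.append("   <search_result>")
        first, rest = psm.protein_hits[0], psm.protein_hits[1:]
        lines.append(
            f'    <search_hit hit_rank="1" peptide="{psm.peptide}" protein="{first}"'
            f' num_tot_proteins="{len(psm.protein_hits)}"'
            f' calc_neutral_pep_mass="{neutral:.4f}" massdiff="0.0"'
            ' num_matched_ions="0" tot_num_ions="0" num_missed_cleavages="0"'
            ' is_rejected="0">'
        )
        for acc in rest:
            lines.append(f'     <alternative_protein protein="{acc}"/>')
        if psm.modifications:
            lines.append("     <modification_info>")
            for pos, delta in psm.modifications:
                residue = psm.peptide[pos - 1]
                total = pmass.std_aa_mass[residue] + delta
                lines.append(
                    f'      <mod_aminoacid_mass position="{pos}" mass="{total:.4f}"/>'
                )
            lines.append("     </modification_info>")
        lines.append(f'     <search_score name="{score_name}" value="{psm.score!r}"/>')
        lines.append("    </search_hit>")
        lines.append("   </search_result>")
        lines.append("  </spectrum_query>")
    lines.append(" </msms_run_summary>")
    lines.append("</msms_pipeline_analysis>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class SchemeVariant:
    """An engineered alternative annotation scheme for reannotation tests.

    Relative to the generating scheme it (1) removes one gene entirely,
    (2) extends the first exon of one multi-exon gene 3 nt into its first
    intron (so junctions over that intron no longer match), and (3)
    extends one gene's CDS outward by whole bases that shift its reading
    frame. ``expected_drop_step`` predicts, from geometry alone, at which
    reannotation step a record is removed (0 = retained).
    """

    gtf_text: str
    name: str
    truth: FixtureTruth
    removed_gene: str
    junction_gene: str
    junction_old_intron: Tuple[str, int, int]
    frame_gene: str

    def write(self, outdir: str) -> str:
        os.makedirs(outdir, exist_ok=True)
        path = os.path.join(outdir, f"{self.name}.gtf")
        with open(path, "w") as fh:
            fh.write(self.gtf_text)
        return path

    def expected_drop_step(self, record) -> int:
        if not record.is_mapped:
            return 0
        gene = self.truth.gene_of_position(record.rname, record.pos - 1)
        if gene == self.removed_gene:
            return 1
        if gene == self.junction_gene:
            chrom, gs, ge = self.junction_old_intron
            blocks = record.blocks()
            for (s0, e0), (s1, _) in zip(blocks, blocks[1:]):
                if record.rname == chrom and (e0, s1) == (gs, ge):
                    return 2
            return 0
        if gene == self.frame_gene:
            return 3
        return 0


def make_scheme_b(reference: Reference, name: str = "schemeB") -> SchemeVariant:
    """Derive the engineered reannotation scheme from a generated reference.

    Genes are chosen deterministically among single-isoform genes: the
    first becomes the removed gene, the first plus-strand multi-exon one
    the junction-modified gene, and the next one the frame-shifted gene.
    """
    truth = reference.truth
    single_iso = [
        gid
        for gid in sorted(truth.gene_extents, key=lambda g: int(g[4:]))
        if sum(1 for tx in truth.transcripts.values() if tx.gene_id == gid) == 1
    ]
    junction_candidates = [
        gid
        for gid in single_iso
        if (tx := _single_tx(truth, gid)).strand == "+" and len(tx.cds) >= 2
    ]
    if not junction_candidates or len(single_iso) < 3:
        raise ValueError(
            "reference too small for a scheme variant: need ≥3 single-isoform "
            "genes including a plus-strand multi-exon one"
        )
    junction = junction_candidates[0]
    removed = next(g for g in single_iso if g != junction)
    frame = next(g for g in single_iso if g not in (removed, junction))

    jtx = _single_tx(truth, junction)
    sorted_blocks = sorted(jtx.cds)
    old_intron = (jtx.chrom, sorted_blocks[0][1], sorted_blocks[1][0])

    lines = []
    for line in reference.gtf_text.splitlines():
        fields = line.split("\t")
        attrs = fields[8]
        gid = attrs.split('gene_id "')[1].split('"')[0]
        if gid == removed:
            continue
        start, end = int(fields[3]), int(fields[4])
        if gid == junction:
            # extend first exon 3 nt into the first intron
            if end == sorted_blocks[0][1]:
                fields[4] = str(end + 3)
        elif gid == frame:
            ftx = _single_tx(truth, frame)
            fsorted = sorted(ftx.cds)
            if start == fsorted[0][0] + 1:
                fields[3] = str(start - 1)
            if end == fsorted[-1][1]:
                fields[4] = str(end + 2)
        lines.append("\t".join(fields))
    return SchemeVariant(
        gtf_text="\n".join(lines) + "\n",
        name=name,
        truth=truth,
        removed_gene=removed,
        junction_gene=junction,
        junction_old_intron=old_intron,
        frame_gene=frame,
    )


def _single_tx(truth: FixtureTruth, gene_id: str) -> TranscriptTruth:
    return next(tx for tx in truth.transcripts.values() if tx.gene_id == gene_id)
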