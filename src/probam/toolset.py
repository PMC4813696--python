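"""Genome-based analysis of proBAM files.

Everything here consumes genome-aligned PSM records and a
:class:`~probam.annotation.GenomeAnnotation`:

* peptide classification by genomic multiplicity and junction status;
* CDS coverage at gene, chromosome and genome level, with a one-proportion
  z-test for chromosome deviations and a resampling saturation curve;
* bipartite peptide↔feature graphs built from genomic overlap, parsimony
  protein/gene inference (greedy set cover after collapsing
  indistinguishable and discarding subsumed features) with group-level
  target-decoy FDR;
* spectral/peptide count tables (overall and feature-specific);
* three-step reannotation of records to a different annotation scheme;
* multi-study integration and two-step PSM rescue.

Decoy records (XD:i:1) ride along for FDR estimation but never contribute
to classification, coverage or counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from . import intervals
from .annotation import GenomeAnnotation, TranscriptModel
from .probam_format import ProBAMFile, merge_probam, provenance_comment
from .psm_io import PSMRecord, compute_psm_fdr

log = logging.getLogger(__name__)

# A peptide node: (sequence, is_decoy). Distinctness is by exact sequence;
# modifications distinguish PSMs, not peptides.
PepKey = Tuple[str, bool]


# ---------------------------------------------------------------------------
# peptide classification
# ---------------------------------------------------------------------------

@dataclass
class PeptideClass:
    peptide: str
    n_locations: int
    junction: bool
    exons_spanned: int


def classify_peptides(file: ProBAMFile) -> List[PeptideClass]:
    """One row per distinct target peptide sequence.

    ``n_locations`` counts distinct (chrom, blocks, strand) tuples over the
    peptide's records; ``junction`` is true when any location's CIGAR
    contains an N; ``exons_spanned`` is the M-segment count of the primary
    record.
    """
    per_pep: Dict[str, Dict] = {}
    for rec in file.mapped_records(include_decoys=False):
        info = per_pep.setdefault(
            rec.peptide, {"locs": set(), "junction": False, "spanned": 1}
        )
        info["locs"].add((rec.rname, tuple(rec.blocks()), rec.strand))
        if "N" in rec.cigar:
            info["junction"] = True
        if not rec.is_secondary:
            info["spanned"] = len(rec.blocks())
    return [
        PeptideClass(pep, len(info["locs"]), info["junction"], info["spanned"])
        for pep, info in sorted(per_pep.items())
    ]


# ---------------------------------------------------------------------------
# CDS coverage
# ---------------------------------------------------------------------------

def _covered_by_chrom(files: Sequence[ProBAMFile]) -> Dict[str, List[Tuple[int, int]]]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for f in files:
        for rec in f.mapped_records(include_decoys=False):
            by_chrom.setdefault(rec.rname, []).extend(rec.blocks())
    return {c: intervals.merge(iv) for c, iv in by_chrom.items()}


def _cds_union_by_chrom(annotation: GenomeAnnotation) -> Dict[str, List[Tuple[int, int]]]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for gene in annotation.genes:
        for b in annotation.gene_cds_union(gene):
            by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    return {c: intervals.merge(iv) for c, iv in by_chrom.items()}


def coverage(file: ProBAMFile, annotation: GenomeAnnotation, level: str = "gene"):
    """Fraction of CDS bases covered by target records.

    Returns a dict keyed by gene or chromosome, or a single float at
    ``level='genome'``. The denominator is always the union of CDS
    intervals of the annotation at the requested level.
    """
    covered = _covered_by_chrom([file])
    if level == "gene":
        out = {}
        for gene in sorted(annotation.genes):
            union = [(b.start, b.end) for b in annotation.gene_cds_union(gene)]
            chroms = {b.chrom for b in annotation.gene_cds_union(gene)}
            total = intervals.total_length(union)
            if total == 0:
                out[gene] = 0.0
                continue
            hit = sum(
                intervals.intersect_length(covered.get(c, []), union) for c in chroms
            )
            out[gene] = hit / total
        return out
    cds = _cds_union_by_chrom(annotation)
    if level == "chromosome":
        return {
            c: (
                intervals.intersect_length(covered.get(c, []), iv)
                / intervals.total_length(iv)
            )
            for c, iv in sorted(cds.items())
        }
    if level == "genome":
        total = sum(intervals.total_length(iv) for iv in cds.values())
        hit = sum(
            intervals.intersect_length(covered.get(c, []), iv) for c, iv in cds.items()
        )
        return hit / total if total else 0.0
    raise ValueError(f"unknown level {level!r}: expected gene, chromosome or genome")


def coverage_ztest(
    chrom_covered: int, chrom_total: int, genome_fraction: float
) -> Tuple[float, float]:
    """One-proportion z-test of a chromosome's coverage against the genome.

    Tests the per-base coverage fraction ``chrom_covered / chrom_total``
    against the genome-wide fraction; the p-value is one-sided for lower
    coverage (small p = chromosome covered less than expected).
    """
    if chrom_total <= 0:
        raise ValueError("chrom_total must be positive")
    if not 0.0 < genome_fraction < 1.0:
        raise ValueError("genome_fraction must lie strictly between 0 and 1")
    p_hat = chrom_covered / chrom_total
    z = (p_hat - genome_fraction) / np.sqrt(
        genome_fraction * (1.0 - genome_fraction) / chrom_total
    )
    return float(z), float(stats.norm.cdf(z))


def coverage_saturation(
    per_sample_files: Sequence[ProBAMFile],
    annotation: GenomeAnnotation,
    draws_per_size: int,
    seed: int,
) -> pd.DataFrame:
    """Genome CDS coverage of random sample subsets of every size.

    For each subset size k, ``draws_per_size`` random k-subsets are drawn
    without replacement and the union coverage computed, giving the
    saturation curve of coverage versus sample number. Reproducible under
    ``seed``.
    """
    if draws_per_size < 1:
        raise ValueError("draws_per_size must be ≥ 1")
    if not per_sample_files:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    cds = _cds_union_by_chrom(annotation)
    total = sum(intervals.total_length(iv) for iv in cds.values())
    per_file = [_covered_by_chrom([f]) for f in per_sample_files]
    rows = []
    n = len(per_sample_files)
    for k in range(1, n + 1):
        for draw in range(draws_per_size):
            idx = rng.choice(n, size=k, replace=False)
            merged: Dict[str, List[Tuple[int, int]]] = {}
            for i in idx:
                for c, iv in per_file[i].items():
                    merged.setdefault(c, []).extend(iv)
            hit = sum(
                intervals.intersect_length(iv, cds.get(c, []))
                for c, iv in merged.items()
            )
            rows.append((k, draw, hit / total if total else 0.0))
    return pd.DataFrame(rows, columns=["sample_size", "draw", "coverage"])


# ---------------------------------------------------------------------------
# bipartite graph and parsimony inference
# ---------------------------------------------------------------------------

@dataclass
class BipartiteGraph:
    """Peptide↔feature graph built from genomic overlap."""

    level: str
    peptide_features: Dict[PepKey, Set[str]] = field(default_factory=dict)
    feature_peptides: Dict[str, Set[PepKey]] = field(default_factory=dict)
    decoy_features: Set[str] = field(default_factory=set)

    def add_edge(self, pep: PepKey, feature: str, decoy_feature: bool) -> None:
        self.peptide_features.setdefault(pep, set()).add(feature)
        self.feature_peptides.setdefault(feature, set()).add(pep)
        if decoy_feature:
            self.decoy_features.add(feature)

    def add_peptide(self, pep: PepKey) -> None:
        self.peptide_features.setdefault(pep, set())


def _effective_strand(rec) -> str:
    """Strand of the encoding locus: decoys flip back to their forward twin."""
    if rec.decoy:
        return "+" if rec.strand == "-" else "-"
    return rec.strand


def _splice_consistent(blocks: Sequence[Tuple[int, int]], tx: TranscriptModel) -> bool:
    """True if the blocks lie in the transcript's CDS exons with every
    junction coinciding exactly with one of its introns."""
    cds = [(b.start, b.end) for b in tx.cds_sorted()]
    n = len(blocks)
    for i, (cs, ce) in enumerate(cds):
        if not (cs <= blocks[0][0] and blocks[0][1] <= ce):
            continue
        if n == 1:
            return True
        if blocks[0][1] != ce:
            continue
        ok = True
        for k in range(1, n):
            j = i + k
            if j >= len(cds) or blocks[k][0] != cds[j][0]:
                ok = False
                break
            if k < n - 1:
                if blocks[k][1] != cds[j][1]:
                    ok = False
                    break
            elif blocks[k][1] > cds[j][1]:
                ok = False
                break
        if ok:
            return True
    return False


def _in_frame(rec, tx: TranscriptModel, annotation: GenomeAnnotation) -> bool:
    """True if the record's bases, read in the transcript's frame,
    translate to the (forward-twin) peptide."""
    blocks = rec.blocks()
    first_base = blocks[0][0] if tx.strand == "+" else blocks[-1][1] - 1
    off = annotation.genome_offset_in_cds(tx.transcript_id, rec.rname, first_base)
    if off is None or off % 3 != 0:
        return False
    nt = rec.seq
    if tx.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    expected = rec.peptide[::-1] if rec.decoy else rec.peptide
    return str(Seq(nt).translate()) == expected


def build_bipartite(
    file: ProBAMFile, annotation: GenomeAnnotation, level: str = "gene"
) -> BipartiteGraph:
    """Connect peptides to proteins or genes by genomic overlap.

    An edge requires the peptide's blocks to be splice-consistent with a
    CDS of the feature (contained in its exons, junctions matching its
    introns exactly). Decoy peptides connect to decoy twins of features
    (``rev_``-prefixed, marked) so group-level FDR can be estimated.
    """
    if level not in ("protein", "gene"):
        raise ValueError(f"unknown level {level!r}: expected protein or gene")
    graph = BipartiteGraph(level=level)
    by_chrom = annotation.transcripts_by_chrom()
    for rec in file.mapped_records():
        pep: PepKey = (rec.peptide, bool(rec.decoy))
        graph.add_peptide(pep)
        strand = _effective_strand(rec)
        blocks = rec.blocks()
        for tx in by_chrom.get(rec.rname, []):
            if tx.strand != strand:
                continue
            if level == "protein" and tx.protein_id is None:
                continue
            if not _splice_consistent(blocks, tx):
                continue
            feature = tx.protein_id if level == "protein" else tx.gene_id
            if rec.decoy:
                feature = f"rev_{feature}"
            graph.add_edge(pep, feature, decoy_feature=bool(rec.decoy))
    return graph


@dataclass
class FeatureGroup:
    members: Tuple[str, ...]
    representative: str
    peptides: FrozenSet[PepKey]
    is_decoy: bool


@dataclass
class InferenceResult:
    level: str
    groups: List[FeatureGroup]
    subsumed: List[str]
    single_hit_groups: List[FeatureGroup]
    group_fdr: float
    cover_size: int  # greedy-cover cardinality before the min-2 filter

    def target_features(self) -> Set[str]:
        out: Set[str] = set()
        for g in self.groups:
            if not g.is_decoy:
                out.update(g.members)
        return out


def parsimony_infer(graph: BipartiteGraph, min_peptides: int = 2) -> InferenceResult:
    """Minimal protein/gene groups explaining all observed peptides.

    Features with identical peptide sets collapse into one
    (indistinguishable) group; features whose peptide set is a strict
    subset of another's are subsumed and discarded; a greedy set cover
    then selects groups by most unexplained peptides (ties broken by
    smallest representative id). Groups with fewer than ``min_peptides``
    distinct peptides are moved to ``single_hit_groups``. The group FDR
    is #all-decoy groups / #target groups among the surviving groups;
    mixed groups count as target (conservative).
    """
    by_pepset: Dict[FrozenSet[PepKey], List[str]] = {}
    for feature, peps in graph.feature_peptides.items():
        if peps:
            by_pepset.setdefault(frozenset(peps), []).append(feature)

    groups = [
        FeatureGroup(
            members=tuple(sorted(members)),
            representative=min(members),
            peptides=pepset,
            is_decoy=all(m in graph.decoy_features for m in members),
        )
        for pepset, members in by_pepset.items()
    ]

    subsumed: List[str] = []
    kept: List[FeatureGroup] = []
    for g in groups:
        if any(g.peptides < other.peptides for other in groups):
            subsumed.extend(g.members)
        else:
            kept.append(g)

    unexplained: Set[PepKey] = set().union(*(g.peptides for g in kept)) if kept else set()
    selected: List[FeatureGroup] = []
    candidates = sorted(kept, key=lambda g: g.representative)
    while unexplained:
        best = max(candidates, key=lambda g: (len(g.peptides & unexplained),))
        gain = len(best.peptides & unexplained)
        if gain == 0:
            break
        # max() keeps the first (lexicographically smallest representative) on ties
        selected.append(best)
        candidates.remove(best)
        unexplained -= best.peptides

    final = [g for g in selected if len(g.peptides) >= min_peptides]
    single_hit = [g for g in selected if len(g.peptides) < min_peptides]
    n_decoy = sum(1 for g in final if g.is_decoy)
    n_target = sum(1 for g in final if not g.is_decoy)
    group_fdr = min(1.0, n_decoy / max(1, n_target))
    return InferenceResult(
        level=graph.level,
        groups=final,
        subsumed=sorted(subsumed),
        single_hit_groups=single_hit,
        group_fdr=group_fdr,
        cover_size=len(selected),
    )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def count_tables(file: ProBAMFile, graph: BipartiteGraph) -> pd.DataFrame:
    """Overall and feature-specific spectral and peptide counts.

    The overall spectral count of a feature sums all PSMs whose peptide has
    an edge to it; the specific count sums only PSMs whose peptide's sole
    edge is to that feature. Peptide counts are analogous with distinct
    sequences. PSMs are tallied from primary records (one per PSM), so a
    PSM counts once per feature regardless of how many of the feature's
    isoform locations it hits, and counts stay additive when merged files
    contain the same spectrum identifiers. Decoys are excluded.
    """
    pep_spectra: Dict[str, int] = {}
    for rec in file.mapped_records(include_decoys=False):
        if not rec.is_secondary:
            pep_spectra[rec.peptide] = pep_spectra.get(rec.peptide, 0) + 1

    rows = []
    for feature in sorted(graph.feature_peptides):
        if feature in graph.decoy_features:
            continue
        overall_spec = specific_spec = overall_pep = specific_pep = 0
        for pep in graph.feature_peptides[feature]:
            seq, is_decoy = pep
            if is_decoy or seq not in pep_spectra:
                continue
            n_spec = pep_spectra[seq]
            overall_spec += n_spec
            overall_pep += 1
            if graph.peptide_features[pep] == {feature}:
                specific_spec += n_spec
                specific_pep += 1
        rows.append(
            (feature, overall_spec, specific_spec, overall_pep, specific_pep)
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "overall_spectral",
            "specific_spectral",
            "overall_peptide",
            "specific_peptide",
        ],
    ).set_index("feature")
    df.attrs["level"] = graph.level
    return df


# ---------------------------------------------------------------------------
# reannotation
# ---------------------------------------------------------------------------

@dataclass
class ReannotationResult:
    file: ProBAMFile
    retained_fraction: float
    dropped_by_step: Dict[int, List]

    def __iter__(self):
        return iter((self.file, self.retained_fraction))


def reannotate(file: ProBAMFile, new_annotation: GenomeAnnotation) -> ReannotationResult:
    """Re-express genome-aligned PSMs under a different annotation scheme.

    Three filtering steps, each applied to every mapped record:

    1. records with bases outside the new scheme's CDS union are removed;
    2. records inconsistent with its gene structures (a junction not
       matching any transcript's intron, or an M block outside that
       transcript's CDS exons) are removed;
    3. records out of frame (blocks that do not translate to the peptide
       in the transcript's reading frame) are removed.

    Decoys are filtered by the same geometry via their forward twins. No
    new identifications are introduced — the output records are a subset
    of the input. Unmapped records cannot be associated with any scheme
    and are dropped.
    """
    for chrom, length in file.sq.items():
        expected = new_annotation.chrom_lengths.get(chrom)
        if expected is not None and expected != length:
            raise ValueError(
                f"sequence {chrom!r} length mismatch between file ({length}) "
                f"and annotation genome ({expected}): different genome build?"
            )
    cds_union = _cds_union_by_chrom(new_annotation)
    by_chrom = new_annotation.transcripts_by_chrom()

    retained = []
    dropped: Dict[int, List] = {1: [], 2: [], 3: []}
    n_mapped = 0
    for rec in file.records:
        if not rec.is_mapped:
            continue
        n_mapped += 1
        blocks = rec.blocks()
        if not all(
            intervals.contains(cds_union.get(rec.rname, []), s, e) for s, e in blocks
        ):
            dropped[1].append(rec)
            continue
        strand = _effective_strand(rec)
        consistent = [
            tx
            for tx in by_chrom.get(rec.rname, [])
            if tx.strand == strand and _splice_consistent(blocks, tx)
        ]
        if not consistent:
            dropped[2].append(rec)
            continue
        if not any(_in_frame(rec, tx, new_annotation) for tx in consistent):
            dropped[3].append(rec)
            continue
        retained.append(rec)

    out = ProBAMFile(
        sq=dict(file.sq),
        pg_lines=list(file.pg_lines),
        co_lines=list(file.co_lines) + [provenance_comment(new_annotation.name, None)],
        records=retained,
    )
    fraction = len(retained) / n_mapped if n_mapped else 1.0
    return ReannotationResult(out, fraction, dropped)


# ---------------------------------------------------------------------------
# integration and rescue
# ---------------------------------------------------------------------------

def _per_spectrum_qvalues(file: ProBAMFile) -> Dict[str, float]:
    """Recompute PSM q-values from the XS/XD payloads of a proBAM file."""
    seen: Dict[str, PSMRecord] = {}
    for rec in file.records:
        if rec.qname in seen or rec.score is None:
            continue
        seen[rec.qname] = PSMRecord(
            spectrum_id=rec.qname,
            peptide=rec.peptide or "X",
            charge=rec.charge or 2,
            score=rec.score,
            protein_hits=["-"],
            is_decoy=bool(rec.decoy),
        )
    return {p.spectrum_id: p.qvalue for p in compute_psm_fdr(list(seen.values()))}


def refilter_by_psm_fdr(file: ProBAMFile, fdr: float) -> ProBAMFile:
    """Re-apply the PSM filter from the scores stored in the file."""
    qvalues = _per_spectrum_qvalues(file)
    records = [r for r in file.records if qvalues.get(r.qname, 1.0) <= fdr]
    return ProBAMFile(
        sq=dict(file.sq),
        pg_lines=list(file.pg_lines),
        co_lines=list(file.co_lines),
        records=records,
    )


@dataclass
class IntegrationResult:
    file: ProBAMFile
    protein_inference: InferenceResult
    gene_inference: InferenceResult
    combined_counts: Dict[str, pd.DataFrame]
    per_study_counts: List[Dict[str, pd.DataFrame]]
    fdr_report: Dict[str, float]


def integrate(
    files: Sequence[ProBAMFile],
    annotation: GenomeAnnotation,
    psm_fdr: float = 0.01,
) -> IntegrationResult:
    """Multi-study integration on the shared genomic coordinate system.

    Merges the studies' proBAM files, re-applies the PSM filter at
    ``psm_fdr`` from the stored scores (so a stricter threshold than any
    study's original one refines downstream FDRs), reannotates everything
    to one scheme, infers protein and gene groups with group-level FDRs,
    and produces per-study and combined count tables.
    """
    merged = merge_probam(files)
    filtered = refilter_by_psm_fdr(merged, psm_fdr)
    reann = reannotate(filtered, annotation)
    combined = reann.file

    graphs = {
        level: build_bipartite(combined, annotation, level)
        for level in ("protein", "gene")
    }
    protein_inf = parsimony_infer(graphs["protein"])
    gene_inf = parsimony_infer(graphs["gene"])
    combined_counts = {level: count_tables(combined, graphs[level]) for level in graphs}

    per_study_counts = []
    for f in files:
        study = reannotate(refilter_by_psm_fdr(f, psm_fdr), annotation).file
        per_study_counts.append(
            {
                level: count_tables(study, build_bipartite(study, annotation, level))
                for level in ("protein", "gene")
            }
        )

    n_spectra = len({r.qname for r in combined.records if not r.decoy})
    fdr_report = {
        "psm_fdr": psm_fdr,
        "n_spectra": n_spectra,
        "protein_group_fdr": protein_inf.group_fdr,
        "gene_group_fdr": gene_inf.group_fdr,
        "n_protein_groups": sum(1 for g in protein_inf.groups if not g.is_decoy),
        "n_gene_groups": sum(1 for g in gene_inf.groups if not g.is_decoy),
    }
    return IntegrationResult(
        file=combined,
        protein_inference=protein_inf,
        gene_inference=gene_inf,
        combined_counts=combined_counts,
        per_study_counts=per_study_counts,
        fdr_report=fdr_report,
    )


def rescue_psms(
    merged: ProBAMFile,
    confident: InferenceResult,
    strict_fdr: float,
    relaxed_fdr: float,
    annotation: GenomeAnnotation,
) -> ProBAMFile:
    """Two-step PSM rescue for confidently identified features.

    Keeps the strict-filter record set and adds back records with q-value
    in (strict, relaxed] whose peptides connect exclusively to features of
    the confident inference — relaxing the PSM threshold only where the
    protein or gene is already established.
    """
    if relaxed_fdr < strict_fdr:
        raise ValueError(
            f"relaxed_fdr ({relaxed_fdr}) must be ≥ strict_fdr ({strict_fdr})"
        )
    qvalues = _per_spectrum_qvalues(merged)
    graph = build_bipartite(merged, annotation, confident.level)
    confident_features = confident.target_features()

    keep: Set[str] = set()
    for rec in merged.records:
        q = qvalues.get(rec.qname, 1.0)
        if q <= strict_fdr:
            keep.add(rec.qname)
        elif q <= relaxed_fdr and rec.is_mapped:
            features = graph.peptide_features.get((rec.peptide, bool(rec.decoy)), set())
            if features and features <= confident_features:
                keep.add(rec.qname)

    return ProBAMFile(
        sq=dict(merged.sq),
        pg_lines=list(merged.pg_lines),
        co_lines=list(merged.co_lines)
        + [f"@CO\tproBAM:rescue strict={strict_fdr:g};relaxed={relaxed_fdr:g}"],
        records=[r for r in merged.records if r.qname in keep],
    )
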