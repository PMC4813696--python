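"""Peptide-spectrum match I/O and PSM-level target-decoy FDR.

PSMs arrive either as pepXML (read through pyteomics) or as a simple
versioned TSV dialect. Decoy status is inferred from accession prefixes
(``rev_`` / ``DECOY_`` by default). FDR estimation is the plain
decoy/target ratio with q-value monotonization; decoys that pass the
filter are deliberately retained, because downstream protein- and
gene-level FDRs are estimated from the decoy matches kept in the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

from pyteomics import pepxml
from pyteomics.mass import std_aa_mass

log = logging.getLogger(__name__)

DEFAULT_DECOY_PREFIXES: Tuple[str, ...] = ("rev_", "DECOY_")

TSV_HEADER = ["spectrum_id", "peptide", "modifications", "charge", "score", "proteins"]
TSV_VERSION_LINE = "# probam-psm-tsv v1"


@dataclass
class PSMRecord:
    """One spectrum-peptide match (top-ranked hit for its spectrum)."""

    spectrum_id: str
    peptide: str
    modifications: List[Tuple[int, float]] = field(default_factory=list)
    charge: int = 2
    score: float = 0.0
    protein_hits: List[str] = field(default_factory=list)
    is_decoy: bool = False
    qvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        if not self.protein_hits:
            raise ValueError(f"PSM {self.spectrum_id}: no protein hits")
        for pos, _ in self.modifications:
            if not 1 <= pos <= len(self.peptide):
                raise ValueError(
                    f"PSM {self.spectrum_id}: modification position {pos} "
                    f"outside peptide of length {len(self.peptide)}"
                )


def is_decoy_accession(accession: str, prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES) -> bool:
    return any(accession.startswith(p) for p in prefixes)


def strip_decoy_prefix(accession: str, prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES) -> str:
    for p in prefixes:
        if accession.startswith(p):
            return accession[len(p):]
    return accession


def format_modifications(mods: Sequence[Tuple[int, float]]) -> str:
    """Dialect encoding for the XM tag: ``pos:delta;...`` or ``-``."""
    if not mods:
        return "-"
    return ";".join(f"{pos}:{delta:g}" for pos, delta in mods)


def parse_modifications(text: str) -> List[Tuple[int, float]]:
    if text in ("-", "", "*"):
        return []
    out = []
    for item in text.split(";"):
        pos, delta = item.split(":")
        out.append((int(pos), float(delta)))
    return out


def read_psms(
    path: str,
    dialect: str = "tsv",
    decoy_prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES,
) -> List[PSMRecord]:
    """Read PSMs; one record per spectrum, rank-1 hits only."""
    if dialect == "tsv":
        return _read_tsv(path, decoy_prefixes)
    if dialect == "pepxml":
        return _read_pepxml(path, decoy_prefixes)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'pepxml')")


def _read_tsv(path: str, decoy_prefixes: Sequence[str]) -> List[PSMRecord]:
    records = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields != TSV_HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: bad header {fields!r}; expected {TSV_HEADER}"
                    )
                header = fields
                continue
            if len(fields) != len(TSV_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(TSV_HEADER)} columns")
            spectrum_id, peptide, mods, charge, score, proteins = fields
            hits = proteins.split(";")
            records.append(
                PSMRecord(
                    spectrum_id=spectrum_id,
                    peptide=peptide,
                    modifications=parse_modifications(mods),
                    charge=int(charge),
                    score=float(score),
                    protein_hits=hits,
                    is_decoy=all(is_decoy_accession(h, decoy_prefixes) for h in hits),
                )
            )
    return records


def _read_pepxml(path: str, decoy_prefixes: Sequence[str]) -> List[PSMRecord]:
    records = []
    with pepxml.read(path) as reader:
        for query in reader:
            hits = query.get("search_hit") or []
            top = [h for h in hits if h.get("hit_rank", 1) == 1]
            if not top:
                continue
            hit = top[0]
            peptide = hit["peptide"]
            accessions = [p["protein"] for p in hit["proteins"]]
            mods = []
            for mod in hit.get("modifications", []):
                pos = int(mod["position"])
                residue = peptide[pos - 1]
                delta = float(mod["mass"]) - std_aa_mass[residue]
                mods.append((pos, round(delta, 4)))
            scores = hit.get("search_score", {})
            score = float(next(iter(scores.values()))) if scores else 0.0
            records.append(
                PSMRecord(
                    spectrum_id=query["spectrum"],
                    peptide=peptide,
                    modifications=mods,
                    charge=int(query.get("assumed_charge", 2)),
                    score=score,
                    protein_hits=accessions,
                    is_decoy=all(is_decoy_accession(a, decoy_prefixes) for a in accessions),
                )
            )
    return records


def write_psms_tsv(psms: Iterable[PSMRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_VERSION_LINE + "\n")
        fh.write("\t".join(TSV_HEADER) + "\n")
        for psm in psms:
            fh.write(
                "\t".join(
                    [
                        psm.spectrum_id,
                        psm.peptide,
                        format_modifications(psm.modifications),
                        str(psm.charge),
                        repr(psm.score),
                        ";".join(psm.protein_hits),
                    ]
                )
                + "\n"
            )


def compute_psm_fdr(psms: Sequence[PSMRecord], higher_better: bool = True) -> List[PSMRecord]:
    """Assign q-values by the target-decoy ratio, best score first.

    At each score threshold FDR = #decoys / max(1, #targets) among records
    at or above it; the q-value is the running minimum of FDR walking from
    the worst score to the best (capped at 1). Ties sort decoys first,
    which makes the estimate conservative.
    """
    if not psms:
        return []
    key = (lambda p: (-p.score, not p.is_decoy)) if higher_better else (
        lambda p: (p.score, not p.is_decoy)
    )
    ranked = sorted(psms, key=key)
    n_decoy = n_target = 0
    fdrs = []
    for psm in ranked:
        if psm.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(1, n_target))
    qvalues = [0.0] * len(fdrs)
    running = 1.0
    for i in range(len(fdrs) - 1, -1, -1):
        running = min(running, fdrs[i])
        qvalues[i] = min(running, 1.0)
    return [replace(p, qvalue=q) for p, q in zip(ranked, qvalues)]


def filter_psms(psms: Sequence[PSMRecord], fdr: float) -> List[PSMRecord]:
    """Keep records (targets AND decoys) with q-value ≤ ``fdr``."""
    if not 0.0 <= fdr <= 1.0:
        raise ValueError(f"fdr must be in [0, 1], got {fdr}")
    for p in psms:
        if p.qvalue is None:
            raise ValueError(f"PSM {p.spectrum_id} has no q-value; run compute_psm_fdr first")
    return [p for p in psms if p.qvalue <= fdr]
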