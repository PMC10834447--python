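"""Input parsing: protein FASTA files and external domain-annotation TSVs.

Coordinates in every file this package reads or writes are 1-based and
inclusive, the convention of Pfam-style protein domain tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional

from Bio import SeqIO

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DOMAIN_KINDS = ("SIGNAL", "TM", "KINASE", "LRR")


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with species provenance."""

    id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.id}: sequence must be uppercase")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainCall:
    """A located domain (1-based inclusive residue coordinates)."""

    kind: str
    start: int
    end: int
    score: float = 0.0
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad span {self.start}..{self.end} (1-based inclusive)")

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str, species_id: Optional[str] = None) -> List[ProteinRecord]:
    """Read a protein FASTA; record ids are truncated at the first whitespace.

    ``species_id`` defaults to the file name without extension.
    """
    if species_id is None:
        species_id = os.path.splitext(os.path.basename(path))[0]
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append(
            ProteinRecord(id=rec.id, species_id=species_id, sequence=str(rec.seq).upper())
        )
    return records


def load_species_manifest(path: str) -> Dict[str, str]:
    """TSV of (fasta_path_or_species, species_id) overriding file-name species."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            key, species = line.rstrip("\n").split("\t")[:2]
            mapping[key] = species
    return mapping


def load_external_annotations(path: str) -> Dict[str, List[DomainCall]]:
    """Parse a domain-annotation TSV into per-protein calls.

    Expected columns: protein_id, kind, start, end, score (tab-separated,
    header row, 1-based inclusive coordinates).  These tables stand in for
    tmhmm / hmmer / SignalP / predict-phytolrr output and are treated
    identically to the built-in detectors downstream.
    """
    calls: Dict[str, List[DomainCall]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            pid, kind, start_s, end_s, score_s = fields[:5]
            if kind not in DOMAIN_KINDS:
                raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
            try:
                start, end, score = int(start_s), int(end_s), float(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start < 1 or start > end:
                raise ValueError(
                    f"{path}:{lineno}: bad span {start}..{end} (1-based inclusive)"
                )
            calls.setdefault(pid, []).append(
                DomainCall(kind=kind, start=start, end=end, score=score, source="external")
            )
    return calls
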