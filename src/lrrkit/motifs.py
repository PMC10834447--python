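"""Diagnostic short-motif scanners and juxtamembrane charge.

Island domains of immune LRR-RLPs carry the lysine motifs Kx5Y and Yx8KG
(involved in BAK1 co-receptor binding); the terminal LRR motif of the C3
region carries the QxxT/S loop required for SERK interaction; the TM helix
may carry chained GxxxG dimerisation motifs (SOBIR1 association); and the
end of the eJM region of LRR-RLPs is negatively charged.  All match
positions are 1-based; overlapping matches are all reported, since
presence rather than multiplicity is what matters downstream.

Scanners are written as explicit position loops (not regular expressions)
so the test suite can check them against an independent regex oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")


@dataclass
class MotifScanReport:
    protein_id: str
    kx5y_positions: List[int] = field(default_factory=list)
    yx8kg_positions: List[int] = field(default_factory=list)
    has_either_lysine: bool = False
    qxxts_positions: List[Tuple[int, Optional[str]]] = field(default_factory=list)
    has_tqxxx: bool = False
    gxxxg_positions: List[int] = field(default_factory=list)
    gxxxg_chain_max: int = 0
    ejm_net_charge: int = 0
    ejm_terminal_charge: int = 0


def scan_lysine_motifs(sequence: str) -> Tuple[List[int], List[int], bool]:
    """Find Kx5Y (K, any 5, Y) and Yx8KG (Y, any 8, K, G) match starts."""
    kx5y = [
        i + 1
        for i in range(len(sequence) - 6)
        if sequence[i] == "K" and sequence[i + 6] == "Y"
    ]
    yx8kg = [
        i + 1
        for i in range(len(sequence) - 10)
        if sequence[i] == "Y" and sequence[i + 9] == "K" and sequence[i + 10] == "G"
    ]
    return kx5y, yx8kg, bool(kx5y or yx8kg)


def scan_qxxts(sequence: str) -> Tuple[List[Tuple[int, Optional[str]]], bool]:
    """Find QxxT/S (Q, any 2, T or S) matches in a terminal-LRR sequence.

    Each match is reported with the residue immediately before the Q (None
    when the Q is at position 1).  ``has_tqxxx`` is True when any Q is
    directly preceded by a T, the weaker TQxxx variant seen in RLP23.
    """
    matches: List[Tuple[int, Optional[str]]] = []
    has_tqxxx = False
    for i, aa in enumerate(sequence):
        if aa != "Q":
            continue
        if i > 0 and sequence[i - 1] == "T":
            has_tqxxx = True
        if i + 3 < len(sequence) and sequence[i + 3] in ("T", "S"):
            matches.append((i + 1, sequence[i - 1] if i > 0 else None))
    return matches, has_tqxxx


def scan_gxxxg(sequence: str) -> Tuple[List[int], int]:
    """Find GxxxG matches and the longest period-4 chain.

    Consecutive motifs share their terminal G (GxxxGxxxG is a chain of
    two), so a run of k glycines spaced exactly 4 apart scores a chain of
    k - 1 GxxxG units.
    """
    positions = [
        i + 1
        for i in range(len(sequence) - 4)
        if sequence[i] == "G" and sequence[i + 4] == "G"
    ]
    g_pos = {i for i, aa in enumerate(sequence) if aa == "G"}
    chain_max = 0
    for p in sorted(g_pos):
        if p - 4 in g_pos:
            continue  # not the start of a period-4 run
        k = 1
        while p + 4 * k in g_pos:
            k += 1
        chain_max = max(chain_max, k - 1)
    return positions, chain_max


def charge(sequence: str) -> int:
    """Net charge as (#K + #R) - (#D + #E); histidine counts as neutral."""
    return sum(1 for aa in sequence if aa in POSITIVE) - sum(
        1 for aa in sequence if aa in NEGATIVE
    )


def ejm_charge(sequence: str, window: int = 10) -> Tuple[int, int]:
    """Net charge of an eJM region and of its last ``window`` residues."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if not sequence:
        return 0, 0
    return charge(sequence), charge(sequence[-window:])


def scan_report(protein_id: str, id_sequences: List[str], terminal_lrr_seq: str,
                tm_seq: str, ejm_seq: str, window: int = 10) -> MotifScanReport:
    """Run every scanner over one receptor's extracted regions."""
    report = MotifScanReport(protein_id)
    for seq in id_sequences:
        kx5y, yx8kg, _ = scan_lysine_motifs(seq)
        report.kx5y_positions.extend(kx5y)
        report.yx8kg_positions.extend(yx8kg)
    report.has_either_lysine = bool(report.kx5y_positions or report.yx8kg_positions)
    report.qxxts_positions, report.has_tqxxx = scan_qxxts(terminal_lrr_seq)
    report.gxxxg_positions, report.gxxxg_chain_max = scan_gxxxg(tm_seq)
    report.ejm_net_charge, report.ejm_terminal_charge = ejm_charge(ejm_seq, window)
    return report
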