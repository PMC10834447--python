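"""Receptor classification from sequence-derived or external domain calls.

Receptor-like kinases (RLKs) are proteins with 1-2 transmembrane helices
(TM) and a cytosolic kinase domain (KD); receptor-like proteins (RLPs)
carry 1-2 TMs but no KD; ectodomain-only proteins have neither TM nor KD.
The detectors in this module are deliberately simple, rule-based stand-ins
for the external predictors normally used for these annotations (tmhmm,
SignalP, hmmer/PF00069, predict-phytolrr): a Kyte-Doolittle sliding-window
scan for TMs and signal peptides, an ordered catalytic-landmark search for
kinase domains, and the plant LRR core pattern for LRR motifs.  Precomputed
annotations can be supplied instead via :func:`lrrkit.io.load_external_annotations`
and are treated identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple
import warnings

from .config import AnalysisConfig
from .io import DomainCall, ProteinRecord

# Kyte & Doolittle hydropathy; X (unknown residue) scores 0 and never
# matches a motif character class.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: residues counted as hydrophobic for signal-peptide runs
HYDROPHOBIC = frozenset("AILMFVC")

#: plant LRR core: hydrophobic at pattern positions 1,4,6,8,13 and a
#: turn-capable residue at position 11 (1-based within the pattern)
LRR_HYDRO = frozenset("LIVFM")
LRR_POLAR = frozenset("NTSC")
LRR_CORE_LEN = 13
LRR_CALL_LEN = 24


class ReceptorClass(str, Enum):
    RLK = "RLK"
    RLP = "RLP"
    ECTODOMAIN_ONLY = "ECTODOMAIN_ONLY"
    OTHER = "OTHER"


@dataclass
class ReceptorClassification:
    cls: ReceptorClass
    n_tm: int
    has_kd: bool
    ecto_span: Optional[Tuple[int, int]] = None
    endo_span: Optional[Tuple[int, int]] = None
    filtered_reason: Optional[str] = None


#: hydropathy in integer deci-units; threshold comparisons on window sums
#: are exact, so boundary windows (mean == threshold) are never lost to
#: floating-point accumulation order
KD_DECI = {aa: round(v * 10) for aa, v in KYTE_DOOLITTLE.items()}


def _hydropathy(sequence: str) -> List[float]:
    return [KYTE_DOOLITTLE[aa] for aa in sequence]


def detect_signal_peptide(sequence: str, config: Optional[AnalysisConfig] = None
                          ) -> Optional[Tuple[int, int]]:
    """Rule-based signal-peptide call (SignalP stand-in).

    A maximal run of hydrophobic residues that begins within the first 10
    residues, spans 7-15 residues, and has mean hydropathy >= 2.0 marks a
    signal peptide from residue 1 to the end of the run.  Returns a 1-based
    inclusive interval or None.
    """
    cfg = config or AnalysisConfig()
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    i = 0
    while i < n and i < cfg.sp_start_within:
        if sequence[i] in HYDROPHOBIC:
            j = i
            while j < n and sequence[j] in HYDROPHOBIC:
                j += 1
            run_len = j - i
            if cfg.sp_min_len <= run_len <= cfg.sp_max_len:
                mean = sum(KYTE_DOOLITTLE[aa] for aa in sequence[i:j]) / run_len
                if mean >= cfg.sp_threshold:
                    return (1, j)  # residue 1 .. end of run
            i = j
        else:
            i += 1
    return None


def detect_tm(sequence: str, window: int = 19, threshold: float = 1.6,
              mask: Optional[Tuple[int, int]] = None,
              config: Optional[AnalysisConfig] = None) -> List[DomainCall]:
    """Sliding-window hydropathy TM scan (tmhmm stand-in).

    Window means of Kyte-Doolittle hydropathy are computed at every window
    start; maximal runs of qualifying windows are merged into candidate
    spans (the union of the windows).  Spans shorter than 15 residues are
    dropped; spans longer than 35 residues are trimmed to their
    maximal-scoring 21-mer.  ``mask`` (1-based inclusive, typically a
    signal peptide) zeroes the hydropathy of the masked residues so they
    are never reported as a TM.
    """
    cfg = config or AnalysisConfig()
    if window % 2 == 0 or window < 7:
        raise ValueError("window must be odd and >= 7")
    n = len(sequence)
    if n < window:
        warnings.warn(f"sequence shorter than TM window ({n} < {window}); no scan")
        return []
    h = [KD_DECI[aa] for aa in sequence]
    if mask is not None:
        for p in range(mask[0] - 1, min(mask[1], n)):
            h[p] = 0
    # integer prefix sums for O(1), exact window sums
    pre = [0]
    for v in h:
        pre.append(pre[-1] + v)
    need = threshold * 10 * window  # deci-units
    ok = [pre[s + window] - pre[s] >= need for s in range(n - window + 1)]
    calls: List[DomainCall] = []
    s = 0
    while s < len(ok):
        if not ok[s]:
            s += 1
            continue
        e = s
        while e + 1 < len(ok) and ok[e + 1]:
            e += 1
        # union of qualifying windows, 0-based [s, e + window - 1]
        span_start, span_end = s, e + window - 1
        span_len = span_end - span_start + 1
        if span_len > cfg.tm_max_len:
            k = cfg.tm_trim_len
            best_s, best_val = span_start, -float("inf")
            for t in range(span_start, span_end - k + 2):
                val = pre[t + k] - pre[t]
                if val > best_val:
                    best_s, best_val = t, val
            span_start, span_end = best_s, best_s + k - 1
            span_len = k
        if span_len >= cfg.tm_min_len:
            score = (pre[span_end + 1] - pre[span_start]) / 10 / span_len
            calls.append(DomainCall("TM", span_start + 1, span_end + 1, score))
        s = e + 1
    return calls


def detect_kinase(sequence: str) -> Optional[DomainCall]:
    """Ordered catalytic-landmark kinase search (PF00069 stand-in).

    Requires, in order: the glycine-rich loop G-x-G-x-x-G, a catalytic
    lysine within 30 residues of the loop, the HRD motif, and the DFG
    motif, all within a 150-350-residue window.  The reported span runs
    from the glycine loop to 30 residues past DFG (clipped to the sequence
    end).  When several candidates exist the most compact one is kept.
    """
    n = len(sequence)
    best: Optional[Tuple[int, int, int]] = None  # (span_len, g_start, dfg_end)
    for g in range(n - 5):
        if not (sequence[g] == "G" and sequence[g + 2] == "G" and sequence[g + 5] == "G"):
            continue
        loop_end = g + 6
        k_pos = sequence.find("K", loop_end, loop_end + 30)
        if k_pos < 0:
            continue
        hrd = sequence.find("HRD", k_pos + 1)
        if hrd < 0:
            continue
        dfg = sequence.find("DFG", hrd + 3)
        if dfg < 0:
            continue
        dfg_end = dfg + 3  # one past DFG, 0-based
        span_len = dfg_end - g
        if not (150 <= span_len <= 350):
            continue
        if best is None or span_len < best[0]:
            best = (span_len, g, dfg_end)
    if best is None:
        return None
    _, g, dfg_end = best
    end = min(dfg_end + 30, n)  # 30 residues past DFG, clipped
    return DomainCall("KINASE", g + 1, end, score=1.0)


def _lrr_core_match(sequence: str, i: int) -> bool:
    """Does the LRR core pattern match at 0-based position ``i``?"""
    if i + LRR_CORE_LEN > len(sequence):
        return False
    s = sequence
    return (
        s[i] in LRR_HYDRO
        and s[i + 3] in LRR_HYDRO
        and s[i + 5] in LRR_HYDRO
        and s[i + 7] in LRR_HYDRO
        and s[i + 10] in LRR_POLAR
        and s[i + 12] in LRR_HYDRO
    )


def detect_lrr(sequence: str) -> List[DomainCall]:
    """Greedy non-overlapping plant-LRR motif scan (predict-phytolrr stand-in).

    Each match of the core pattern anchors a 24-residue call (clipped at
    the sequence end); scanning resumes past the call, so calls never
    overlap.
    """
    calls: List[DomainCall] = []
    n = len(sequence)
    i = 0
    while i <= n - LRR_CORE_LEN:
        if _lrr_core_match(sequence, i):
            end = min(i + LRR_CALL_LEN, n)
            calls.append(DomainCall("LRR", i + 1, end, score=1.0))
            i = i + LRR_CALL_LEN
        else:
            i += 1
    return calls


def annotate_protein(record: ProteinRecord,
                     config: Optional[AnalysisConfig] = None) -> List[DomainCall]:
    """Run all built-in detectors on one protein.

    The signal-peptide region (if any) is masked before the TM scan so it
    is never mistaken for a membrane helix.
    """
    cfg = config or AnalysisConfig()
    calls: List[DomainCall] = []
    sp = detect_signal_peptide(record.sequence, cfg)
    if sp is not None:
        calls.append(DomainCall("SIGNAL", sp[0], sp[1], score=1.0))
    calls.extend(detect_tm(record.sequence, cfg.tm_window, cfg.tm_threshold,
                           mask=sp, config=cfg))
    kd = detect_kinase(record.sequence)
    if kd is not None:
        calls.append(kd)
    calls.extend(detect_lrr(record.sequence))
    return calls


def _check_calls(record: ProteinRecord, calls: Sequence[DomainCall]) -> None:
    for c in calls:
        if c.end > record.length:
            raise ValueError(
                f"{record.id}: {c.kind} call {c.start}..{c.end} outside sequence "
                f"of length {record.length}"
            )


def classify(record: ProteinRecord, calls: Sequence[DomainCall],
             config: Optional[AnalysisConfig] = None) -> ReceptorClassification:
    """Derive the receptor class from a protein's domain calls.

    Proteins shorter than 150 residues are filtered; LRR-containing
    TM+kinase candidates additionally require 250 residues.  1-2 TMs with a
    KD -> RLK; 1-2 TMs without KD -> RLP; no TM, no KD, with LRR motifs ->
    ectodomain-only; everything else (including >2 TMs) -> OTHER.
    The result is independent of the order of ``calls``.
    """
    cfg = config or AnalysisConfig()
    _check_calls(record, calls)
    tms = sorted((c for c in calls if c.kind == "TM"), key=lambda c: c.start)
    n_tm = len(tms)
    has_kd = any(c.kind == "KINASE" for c in calls)
    n_lrr = sum(1 for c in calls if c.kind == "LRR")

    if record.length < cfg.min_len_other:
        return ReceptorClassification(ReceptorClass.OTHER, n_tm, has_kd,
                                      filtered_reason="min_length")
    is_lrr_rlk_candidate = has_kd and 1 <= n_tm <= 2 and n_lrr >= 1
    if is_lrr_rlk_candidate and record.length < cfg.min_len_lrr_rlk:
        return ReceptorClassification(ReceptorClass.OTHER, n_tm, has_kd,
                                      filtered_reason="min_length")

    if has_kd and 1 <= n_tm <= 2:
        cls = ReceptorClass.RLK
    elif not has_kd and 1 <= n_tm <= 2:
        cls = ReceptorClass.RLP
    elif not has_kd and n_tm == 0 and n_lrr >= 1:
        cls = ReceptorClass.ECTODOMAIN_ONLY
    else:
        return ReceptorClassification(ReceptorClass.OTHER, n_tm, has_kd)

    result = ReceptorClassification(cls, n_tm, has_kd)
    if cls in (ReceptorClass.RLK, ReceptorClass.RLP):
        result.ecto_span, result.endo_span = split_ecto_endo(record, calls, result)
    elif cls is ReceptorClass.ECTODOMAIN_ONLY:
        result.ecto_span = (1, record.length)
    return result


def split_ecto_endo(record: ProteinRecord, calls: Sequence[DomainCall],
                    cls: ReceptorClassification
                    ) -> Tuple[Optional[Tuple[int, int]], Optional[Tuple[int, int]]]:
    """Split a TM-anchored receptor into ecto- and endodomain stretches.

    Candidate stretches are the maximal TM-free segments of the sequence.
    For RLKs the endodomain is the stretch containing the kinase domain and
    the ectodomain is the LRR-richest remaining stretch; for RLPs the
    ectodomain is the LRR-richest stretch and the endodomain the longest of
    the rest.  Ties break toward the N-terminal stretch.
    """
    tms = sorted((c for c in calls if c.kind == "TM"), key=lambda c: c.start)
    if not tms:
        raise ValueError(f"{record.id}: cannot split without a TM")
    # maximal TM-free stretches (1-based inclusive)
    stretches: List[Tuple[int, int]] = []
    prev_end = 0
    for tm in tms:
        if tm.start - 1 >= prev_end + 1:
            stretches.append((prev_end + 1, tm.start - 1))
        prev_end = tm.end
    if prev_end < record.length:
        stretches.append((prev_end + 1, record.length))
    if not stretches:
        return None, None

    lrrs = [c for c in calls if c.kind == "LRR"]
    kd = next((c for c in calls if c.kind == "KINASE"), None)

    def n_lrr_in(span: Tuple[int, int]) -> int:
        return sum(1 for c in lrrs if c.start >= span[0] and c.end <= span[1])

    def overlaps(span: Tuple[int, int], call: DomainCall) -> bool:
        return not (call.end < span[0] or call.start > span[1])

    if kd is not None:
        endo = next((s for s in stretches if overlaps(s, kd)), None)
        rest = [s for s in stretches if s != endo]
        ecto = max(rest, key=lambda s: (n_lrr_in(s), -s[0]), default=None)
    else:
        ecto = max(stretches, key=lambda s: (n_lrr_in(s), -s[0]))
        rest = [s for s in stretches if s != ecto]
        endo = max(rest, key=lambda s: (s[1] - s[0], -s[0]), default=None)
    return ecto, endo
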