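"""LRR ectodomain architecture: regions, NL/ID gaps, ID+4LRR, C3/eJM/TM/cJM.

The ectodomain of an LRR receptor is a string of ~24-residue LRR motifs.
Motifs fewer than 13 residues apart are grouped into LRR-regions; the gaps
between regions are the interesting part: 15-29-residue gaps are N-loopout
(NL) candidates and 30-90-residue gaps are island-domain (ID) candidates.
Candidate gaps that still contain an LRR motif are screened out.  For each
surviving gap, n1 counts the LRR motifs N-terminal of it and n2 the motifs
C-terminal of it; an ID with exactly four motifs after it marks the
ID+4LRR architecture shared by immune LRR-RLPs and the developmental
LRR-RLK subgroup Xb.  The last four motifs form the C3 region; eJM/TM/cJM
are the juxtamembrane and membrane spans downstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

from .config import AnalysisConfig
from .io import DomainCall, ProteinRecord
from . import annotate

Span = Tuple[int, int]


@dataclass
class LRRRegion:
    start: int
    end: int
    motif_spans: List[Span]

    @property
    def n_motifs(self) -> int:
        return len(self.motif_spans)


@dataclass
class GapCall:
    start: int
    end: int
    gap_class: str              # "NL", "ID", or "NONE"
    sequence: str = ""
    n1: int = 0                 # LRR motifs N-terminal of the gap
    n2: int = 0                 # LRR motifs C-terminal of the gap
    passed_lrr_screen: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """C3 / eJM / TM / cJM spans and sequences (spans may be empty)."""

    c3_span: Span
    ejm_span: Optional[Span]
    tm_span: Span
    cjm_span: Optional[Span]
    c3_seq: str = ""
    ejm_seq: str = ""
    tm_seq: str = ""
    cjm_seq: str = ""


@dataclass
class ArchitectureProfile:
    protein_id: str
    motif_spans: List[Span]
    regions: List[LRRRegion]
    gaps: List[GapCall]
    id_plus_4lrr: bool = False
    region_set: Optional[RegionSet] = None


def group_regions(motif_spans: Sequence[Span], merge_lt: int = 13) -> List[LRRRegion]:
    """Group sorted, non-overlapping motif spans into LRR-regions.

    Adjacent motifs strictly fewer than ``merge_lt`` residues apart share a
    region; the inter-motif distance is the number of residues strictly
    between the two spans.
    """
    if not motif_spans:
        return []
    for (s1, e1), (s2, e2) in zip(motif_spans, motif_spans[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping motif spans {s1}..{e1} and {s2}..{e2}")
    regions: List[LRRRegion] = []
    current = [tuple(motif_spans[0])]
    for span in motif_spans[1:]:
        gap = span[0] - current[-1][1] - 1
        if gap < merge_lt:
            current.append(tuple(span))
        else:
            regions.append(LRRRegion(current[0][0], current[-1][1], current))
            current = [tuple(span)]
    regions.append(LRRRegion(current[0][0], current[-1][1], current))
    return regions


def call_gaps(regions: Sequence[LRRRegion],
              config: Optional[AnalysisConfig] = None,
              sequence: Optional[str] = None,
              seq_len: Optional[int] = None) -> List[GapCall]:
    """Call every inter-region gap and classify it by length.

    Lengths within ``nl_range`` are NL candidates, within ``id_range`` ID
    candidates, anything else NONE.  Gaps before the first or after the
    last motif are not candidates unless ``include_terminal_gaps`` is set.
    """
    cfg = config or AnalysisConfig()
    if not regions:
        raise ValueError("need at least one LRR region")

    def classify_len(length: int) -> str:
        if cfg.nl_range[0] <= length <= cfg.nl_range[1]:
            return "NL"
        if cfg.id_range[0] <= length <= cfg.id_range[1]:
            return "ID"
        return "NONE"

    def make(start: int, end: int) -> GapCall:
        seq = sequence[start - 1:end] if sequence else ""
        return GapCall(start, end, classify_len(end - start + 1), sequence=seq)

    gaps: List[GapCall] = []
    if cfg.include_terminal_gaps and regions[0].start > 1:
        gaps.append(make(1, regions[0].start - 1))
    for a, b in zip(regions, regions[1:]):
        if b.start - a.end > 1:
            gaps.append(make(a.end + 1, b.start - 1))
    if cfg.include_terminal_gaps and seq_len and regions[-1].end < seq_len:
        gaps.append(make(regions[-1].end + 1, seq_len))
    return gaps


def screen_gap(gap: GapCall,
               lrr_detector: Callable[[str], list] = annotate.detect_lrr) -> bool:
    """Keep a candidate gap only if no LRR motif is detected inside it."""
    keep = not lrr_detector(gap.sequence)
    gap.passed_lrr_screen = keep
    return keep


def locate_ids(profile: ArchitectureProfile,
               config: Optional[AnalysisConfig] = None) -> ArchitectureProfile:
    """Annotate gaps with n1/n2 motif counts and set the ID+4LRR flag.

    The flag is raised when any surviving ID has exactly ``id4_n2``
    (default 4) LRR motifs C-terminal of it (``id4_le`` relaxes this to
    "at most").
    """
    cfg = config or AnalysisConfig()
    total = len(profile.motif_spans)
    profile.id_plus_4lrr = False
    for gap in profile.gaps:
        gap.n1 = sum(1 for s, e in profile.motif_spans if e < gap.start)
        gap.n2 = total - gap.n1
        if gap.gap_class == "ID" and gap.passed_lrr_screen:
            hit = gap.n2 <= cfg.id4_n2 if cfg.id4_le else gap.n2 == cfg.id4_n2
            if hit:
                profile.id_plus_4lrr = True
    return profile


def extract_regions(record: ProteinRecord, profile: ArchitectureProfile,
                    tm_call: DomainCall,
                    kd_call: Optional[DomainCall] = None) -> RegionSet:
    """Extract C3 (last four LRR motifs), eJM, TM, and cJM spans.

    cJM runs from the TM to the kinase domain for RLKs and to the
    C-terminus for RLPs; eJM and cJM may be empty.
    """
    motifs = profile.motif_spans
    if len(motifs) < 4:
        raise ValueError(f"{record.id}: C3 undefined with {len(motifs)} LRR motifs")
    if tm_call.start <= motifs[-1][1]:
        raise ValueError(f"{record.id}: TM is not C-terminal of the LRR motifs")
    c3 = (motifs[-4][0], motifs[-1][1])
    ejm = (c3[1] + 1, tm_call.start - 1) if tm_call.start - 1 >= c3[1] + 1 else None
    tm = (tm_call.start, tm_call.end)
    cjm_end = (kd_call.start - 1) if kd_call is not None else record.length
    cjm = (tm_call.end + 1, cjm_end) if cjm_end >= tm_call.end + 1 else None

    def cut(span: Optional[Span]) -> str:
        return record.sequence[span[0] - 1:span[1]] if span else ""

    return RegionSet(c3, ejm, tm, cjm, cut(c3), cut(ejm), cut(tm), cut(cjm))


def build_profile(record: ProteinRecord, calls: Sequence[DomainCall],
                  cls=None, config: Optional[AnalysisConfig] = None
                  ) -> ArchitectureProfile:
    """Compose the full architecture analysis for one protein.

    Uses the LRR calls inside the ectodomain (all calls when no TM is
    present), groups them into regions, calls and screens gaps, locates
    IDs, and — when a single ectodomain-flanking TM exists and the protein
    has at least four motifs — extracts the C3/eJM/TM/cJM regions.
    """
    cfg = config or AnalysisConfig()
    ecto = getattr(cls, "ecto_span", None) if cls is not None else None
    lrrs = sorted((c for c in calls if c.kind == "LRR"), key=lambda c: c.start)
    if ecto is not None:
        lrrs = [c for c in lrrs if c.start >= ecto[0] and c.end <= ecto[1]]
    motif_spans = [(c.start, c.end) for c in lrrs]
    profile = ArchitectureProfile(record.id, motif_spans, [], [])
    if not motif_spans:
        return profile
    profile.regions = group_regions(motif_spans, cfg.merge_lt)
    profile.gaps = call_gaps(profile.regions, cfg, sequence=record.sequence,
                             seq_len=record.length)
    for gap in profile.gaps:
        if gap.gap_class in ("NL", "ID"):
            screen_gap(gap)
    locate_ids(profile, cfg)

    tms = sorted((c for c in calls if c.kind == "TM"), key=lambda c: c.start)
    kd = next((c for c in calls if c.kind == "KINASE"), None)
    tm_after = [t for t in tms if t.start > motif_spans[-1][1]]
    if len(motif_spans) >= 4 and tm_after:
        try:
            profile.region_set = extract_regions(record, profile, tm_after[0], kd)
        except ValueError:
            profile.region_set = None
    return profile
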