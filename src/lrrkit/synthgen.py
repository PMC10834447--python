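"""Seeded synthetic receptors, proteomes, lineage panels, and planted trees.

Every pipeline stage needs ground truth to be testable without the 350
public proteomes the real analysis used, so this module plants
architectures rather than evolving them: a receptor is assembled from a
signal peptide, tandem copies of a 24-residue LRR template, polar NL/ID
fillers that can never match the LRR core pattern, an eJM composed to hit
a target net charge, a hydrophobic TM carrying a requested GxxxG chain,
and (for RLKs) a kinase cassette whose catalytic landmarks are laid out so
the kinase detector recovers it exactly.  Each emitted sequence is
validated by running the annotate/arch/motifs pipeline on it at generation
time; generation fails loudly if the planted truth is not recovered.

All outputs are byte-for-byte reproducible from (spec, seed): randomness
flows exclusively through the supplied numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import annotate, arch, motifs
from .config import AnalysisConfig
from .evostats import GenomeFamilyCounts
from .io import ProteinRecord

# -- building blocks ---------------------------------------------------------

#: 24-residue LRR template matching the detector core (hydrophobic at
#: 1,4,6,8,13; N at 11) and free of Q/H/F/M/G/Y/W/C so that fillers and
#: motif planting stay unambiguous.
LRR_TEMPLATE = "LAELDLSVNKNAIPASAEASAEAS"

#: signal peptide: Met-Lys then a 10-leucine hydrophobic core
SIGNAL_PEPTIDE = "MKLLLLLLLLLL"

#: polar N-terminal cap; buffers the signal peptide from the first LRR
N_CAP = "QSSNNPPQSE"

#: hydrophobic TM backbone (23-mer, no G); GxxxG chains are written in
TM_BACKBONE = "ILLVILLVILLVILLVILLVILL"
#: 0-based positions receiving G for a chain of length c (c+1 glycines)
TM_G_POSITIONS = (2, 6, 10, 14)

#: residues allowed in NL/ID fillers: polar/charged, never hydrophobic,
#: never Y/G/H/F, so no LRR core, lysine motif, or kinase landmark can
#: arise by accident
FILLER_ALPHABET = "DEKNPQRST"
#: neutral filler for eJM/cJM padding (no charges either)
NEUTRAL_ALPHABET = "NQSTP"

QXXTS_MOTIFS = ("TQFDT", "GQFQT", "GQFYS", "GQFET")
KX5Y_INSERT = "KQSNTEY"
YX8KG_INSERT = "YQSNTEPQSKG"

EJM_TAIL_LEN = 8   # neutral tail so TM-flank absorption never eats charges

# average plant proteome amino-acid frequencies (order ACDEFGHIKLMNPQRSTVWY)
BACKGROUND_FREQS = {
    "A": 0.063, "C": 0.018, "D": 0.054, "E": 0.067, "F": 0.040, "G": 0.064,
    "H": 0.023, "I": 0.053, "K": 0.061, "L": 0.096, "M": 0.024, "N": 0.043,
    "P": 0.048, "Q": 0.035, "R": 0.054, "S": 0.091, "T": 0.051, "V": 0.069,
    "W": 0.012, "Y": 0.034,
}


@dataclass
class ReceptorSpec:
    cls: str = "RLP"                      # RLK | RLP | ECTODOMAIN_ONLY
    n_lrr_before_id: int = 2
    id_length: Optional[int] = 60
    n_lrr_after_id: int = 4
    nl_length: Optional[int] = None
    nl_after: int = 1                     # NL inserted after this many motifs
    gxxxg_chain: int = 0
    ejm_charge_target: int = 0
    has_signal_peptide: bool = False
    qxxts_motif: Optional[str] = None     # one of QXXTS_MOTIFS, or None
    plant_kx5y: bool = False
    plant_yx8kg: bool = False
    ejm_length: int = 24
    cjm_length: int = 18

    def __post_init__(self) -> None:
        if self.cls not in ("RLK", "RLP", "ECTODOMAIN_ONLY"):
            raise ValueError(f"unknown class {self.cls!r}")
        if self.id_length is not None and not (30 <= self.id_length <= 90):
            raise ValueError("id_length must be in [30, 90]")
        if self.nl_length is not None and not (15 <= self.nl_length <= 29):
            raise ValueError("nl_length must be in [15, 29]")
        if not (0 <= self.gxxxg_chain <= 3):
            raise ValueError("gxxxg_chain must be 0-3 for a 23-residue TM")
        if abs(self.ejm_charge_target) > self.ejm_length - EJM_TAIL_LEN - 2:
            raise ValueError("ejm_charge_target unreachable at this eJM length")
        if self.nl_length is not None and not (
            1 <= self.nl_after < self.n_lrr_before_id
        ):
            raise ValueError("nl_after must split the pre-ID motif block")
        if self.qxxts_motif is not None and self.qxxts_motif not in QXXTS_MOTIFS:
            raise ValueError(f"qxxts_motif must be one of {QXXTS_MOTIFS}")

    @property
    def n_lrr_total(self) -> int:
        return self.n_lrr_before_id + self.n_lrr_after_id


@dataclass
class GapTruth:
    start: int
    end: int
    length: int
    gap_class: str
    n1: int
    n2: int


@dataclass
class GroundTruth:
    protein_id: str
    cls: str
    motif_spans: List[Tuple[int, int]]
    gaps: List[GapTruth]
    id_plus_4lrr: bool
    sp_span: Optional[Tuple[int, int]]
    tm_span: Optional[Tuple[int, int]]          # planted TM backbone
    kd_span: Optional[Tuple[int, int]]
    gxxxg_chain: int
    ejm_net_charge: int
    has_kx5y: bool
    has_yx8kg: bool
    has_qxxts: bool
    has_tqxxx: bool


def _filler(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _make_id_filler(rng: np.random.Generator, length: int,
                    kx5y: bool, yx8kg: bool) -> str:
    inserts = []
    if kx5y:
        inserts.append(KX5Y_INSERT)
    if yx8kg:
        inserts.append(YX8KG_INSERT)
    needed = sum(len(s) for s in inserts)
    if needed > length:
        raise ValueError("ID too short for the requested lysine motifs")
    seq = _filler(rng, length - needed, FILLER_ALPHABET)
    # embed inserts at deterministic offsets spread through the filler
    for k, ins in enumerate(inserts):
        pos = (k + 1) * len(seq) // (len(inserts) + 1)
        seq = seq[:pos] + ins + seq[pos:]
    assert len(seq) == length
    return seq


def _make_ejm(rng: np.random.Generator, length: int, target: int) -> str:
    """Neutral pad + charged block + neutral tail, net charge == target."""
    block = ("K" if target > 0 else "E") * abs(target)
    pad = _filler(rng, length - EJM_TAIL_LEN - len(block), NEUTRAL_ALPHABET)
    tail = _filler(rng, EJM_TAIL_LEN, NEUTRAL_ALPHABET)
    return pad + block + tail


def _make_tm(chain: int) -> str:
    tm = list(TM_BACKBONE)
    for p in TM_G_POSITIONS[: chain + 1 if chain > 0 else 0]:
        tm[p] = "G"
    return "".join(tm)


def _make_kinase_cassette(rng: np.random.Generator) -> str:
    """Glycine loop, catalytic K, HRD, DFG, 30-residue tail; landmarks laid
    out so the detected span is exactly the cassette."""
    loop = "GEGSQG"
    seg1 = _filler(rng, 4, NEUTRAL_ALPHABET) + "K"       # K within 30 of loop
    seg2 = _filler(rng, 80, NEUTRAL_ALPHABET) + "HRD"
    seg3 = _filler(rng, 84, NEUTRAL_ALPHABET) + "DFG"
    tail = _filler(rng, 30, NEUTRAL_ALPHABET)
    cassette = loop + seg1 + seg2 + seg3 + tail
    span = len(loop + seg1 + seg2 + seg3)                # loop start .. DFG end
    assert 150 <= span <= 350
    return cassette


def _terminal_motif(spec: ReceptorSpec) -> str:
    """Last LRR motif copy, optionally carrying a planted QxxT/S block."""
    if spec.qxxts_motif is None:
        return LRR_TEMPLATE
    t = list(LRR_TEMPLATE)
    t[17:22] = list(spec.qxxts_motif)
    return "".join(t)


def make_receptor(spec: ReceptorSpec, rng: np.random.Generator,
                  protein_id: str = "synth",
                  config: Optional[AnalysisConfig] = None,
                  validate: bool = True) -> Tuple[str, GroundTruth]:
    """Assemble one receptor sequence and its machine-readable truth.

    Raises if the spec is unsatisfiable or if the pipeline run on the
    emitted sequence does not recover the planted architecture.
    """
    cfg = config or AnalysisConfig()
    parts: List[str] = []
    pos = 0  # 0-based running offset

    def emit(s: str) -> Tuple[int, int]:
        nonlocal pos
        parts.append(s)
        span = (pos + 1, pos + len(s))  # 1-based inclusive
        pos += len(s)
        return span

    sp_span = emit(SIGNAL_PEPTIDE)[0:2] if spec.has_signal_peptide else None
    emit(N_CAP)

    motif_spans: List[Tuple[int, int]] = []
    gaps: List[GapTruth] = []

    def emit_motifs(k: int, terminal_block: bool) -> None:
        for j in range(k):
            is_last = terminal_block and j == k - 1
            motif_spans.append(emit(_terminal_motif(spec) if is_last else LRR_TEMPLATE))

    # pre-ID motifs, with optional NL inside the block
    if spec.nl_length is not None:
        emit_motifs(spec.nl_after, terminal_block=False)
        nl_span = emit(_filler(rng, spec.nl_length, FILLER_ALPHABET))
        gaps.append(GapTruth(nl_span[0], nl_span[1], spec.nl_length, "NL", 0, 0))
        emit_motifs(spec.n_lrr_before_id - spec.nl_after,
                    terminal_block=(spec.id_length is None))
    else:
        emit_motifs(spec.n_lrr_before_id, terminal_block=(spec.id_length is None))

    if spec.id_length is not None:
        id_seq = _make_id_filler(rng, spec.id_length, spec.plant_kx5y, spec.plant_yx8kg)
        id_span = emit(id_seq)
        gaps.append(GapTruth(id_span[0], id_span[1], spec.id_length, "ID", 0, 0))
        emit_motifs(spec.n_lrr_after_id, terminal_block=True)
    elif spec.plant_kx5y or spec.plant_yx8kg:
        raise ValueError("lysine motifs are planted in the ID; spec has none")

    tm_span = kd_span = None
    if spec.cls in ("RLK", "RLP"):
        emit(_make_ejm(rng, spec.ejm_length, spec.ejm_charge_target))
        tm_span = emit(_make_tm(spec.gxxxg_chain))
        if spec.cls == "RLK":
            emit(_filler(rng, spec.cjm_length, NEUTRAL_ALPHABET))
            kd_span = emit(_make_kinase_cassette(rng))
        else:
            emit(_filler(rng, spec.cjm_length, NEUTRAL_ALPHABET))
    else:
        # ectodomain-only: polar tail, padded past the 150-residue filter
        tail = max(12, 160 - pos)
        emit(_filler(rng, tail, NEUTRAL_ALPHABET))

    sequence = "".join(parts)

    # fill gap n1/n2 and the ID+4LRR flag from the planted layout
    for g in gaps:
        g.n1 = sum(1 for s, e in motif_spans if e < g.start)
        g.n2 = len(motif_spans) - g.n1
    id4 = any(
        g.gap_class == "ID" and g.n2 == cfg.id4_n2 for g in gaps
    )
    truth = GroundTruth(
        protein_id=protein_id,
        cls=spec.cls,
        motif_spans=motif_spans,
        gaps=gaps,
        id_plus_4lrr=id4,
        sp_span=sp_span,
        tm_span=tm_span,
        kd_span=kd_span,
        gxxxg_chain=spec.gxxxg_chain,
        ejm_net_charge=spec.ejm_charge_target,
        has_kx5y=spec.plant_kx5y,
        has_yx8kg=spec.plant_yx8kg,
        has_qxxts=spec.qxxts_motif is not None,
        has_tqxxx=spec.qxxts_motif is not None and spec.qxxts_motif.startswith("T"),
    )
    if validate:
        _validate_receptor(sequence, truth, spec, cfg)
    return sequence, truth


def _validate_receptor(sequence: str, truth: GroundTruth, spec: ReceptorSpec,
                       cfg: AnalysisConfig) -> None:
    """Run the real pipeline on the emitted sequence and compare to truth."""
    record = ProteinRecord(truth.protein_id, "synthetic", sequence)
    calls = annotate.annotate_protein(record, cfg)
    cls = annotate.classify(record, calls, cfg)
    if cls.cls.value != truth.cls:
        raise AssertionError(
            f"{truth.protein_id}: planted {truth.cls}, pipeline says "
            f"{cls.cls.value} ({cls.filtered_reason})"
        )
    profile = arch.build_profile(record, calls, cls, cfg)
    if [tuple(s) for s in profile.motif_spans] != truth.motif_spans:
        raise AssertionError(f"{truth.protein_id}: LRR motif spans not recovered")
    observed = [
        (g.start, g.end, g.gap_class)
        for g in profile.gaps
        if g.gap_class in ("NL", "ID") and g.passed_lrr_screen
    ]
    expected = [(g.start, g.end, g.gap_class) for g in truth.gaps]
    if observed != expected:
        raise AssertionError(f"{truth.protein_id}: gap calls not recovered")
    if profile.id_plus_4lrr != truth.id_plus_4lrr:
        raise AssertionError(f"{truth.protein_id}: ID+4LRR flag not recovered")
    if truth.tm_span is not None and profile.region_set is not None:
        rs = profile.region_set
        _, chain = motifs.scan_gxxxg(rs.tm_seq)
        if chain != truth.gxxxg_chain:
            raise AssertionError(f"{truth.protein_id}: GxxxG chain not recovered")
        net, _ = motifs.ejm_charge(rs.ejm_seq, cfg.charge_window)
        if net != truth.ejm_net_charge:
            raise AssertionError(f"{truth.protein_id}: eJM charge not recovered")


def random_receptor_spec(rng: np.random.Generator,
                         cls: Optional[str] = None) -> ReceptorSpec:
    """Draw a realistic receptor spec for proteome simulation."""
    if cls is None:
        cls = str(rng.choice(["RLP", "RLK", "ECTODOMAIN_ONLY"]))
    with_id = bool(rng.random() < 0.7)
    n2 = int(rng.integers(2, 9))
    # gap-free receptors need enough motifs to clear the length filters
    n1 = int(rng.integers(2, 7)) if with_id else int(rng.integers(6, 13))
    spec = ReceptorSpec(
        cls=cls,
        n_lrr_before_id=n1,
        id_length=int(rng.integers(30, 91)) if with_id else None,
        n_lrr_after_id=n2 if with_id else 4,
        gxxxg_chain=int(rng.integers(0, 4)) if cls != "ECTODOMAIN_ONLY" else 0,
        ejm_charge_target=int(rng.integers(-6, 7)),
        has_signal_peptide=bool(rng.random() < 0.5),
        qxxts_motif=str(rng.choice(QXXTS_MOTIFS)) if rng.random() < 0.5 else None,
        plant_kx5y=bool(with_id and rng.random() < 0.5),
        plant_yx8kg=bool(with_id and rng.random() < 0.3),
    )
    return spec


def _background_protein(rng: np.random.Generator, cfg: AnalysisConfig) -> str:
    """Inert background protein: plant-like composition, no TM/KD/LRR.

    Rejection-samples until none of the detectors fire, so measured family
    percentages equal the planted ones exactly.
    """
    letters = list(BACKGROUND_FREQS)
    probs = np.array(list(BACKGROUND_FREQS.values()))
    probs = probs / probs.sum()
    for _ in range(200):
        length = int(rng.integers(150, 601))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        sp = annotate.detect_signal_peptide(seq, cfg)
        if annotate.detect_tm(seq, cfg.tm_window, cfg.tm_threshold, mask=sp,
                              config=cfg):
            continue
        if annotate.detect_kinase(seq) is not None:
            continue
        if annotate.detect_lrr(seq):
            continue
        return seq
    raise RuntimeError("could not sample an inert background protein")


@dataclass
class SpeciesSpec:
    species_id: str
    n_proteins: int = 1000
    family_percent: Dict[str, float] = field(
        default_factory=lambda: {"LRR-RLP": 1.0, "LRR-RLK": 2.0}
    )

    def __post_init__(self) -> None:
        if sum(self.family_percent.values()) > 100:
            raise ValueError("family percentages sum above 100")


FAMILY_CLASS = {"LRR-RLP": "RLP", "LRR-RLK": "RLK", "ECTO": "ECTODOMAIN_ONLY"}


def make_proteome(species: SpeciesSpec, rng: np.random.Generator,
                  config: Optional[AnalysisConfig] = None
                  ) -> Tuple[List[ProteinRecord], List[Dict]]:
    """Emit a synthetic proteome and its per-protein truth table.

    Exactly round(n * pct / 100) receptors are planted per family; the
    remaining proteins are inert background.
    """
    cfg = config or AnalysisConfig()
    records: List[ProteinRecord] = []
    truth_rows: List[Dict] = []
    counts = {
        fam: int(round(species.n_proteins * pct / 100.0))
        for fam, pct in species.family_percent.items()
    }
    idx = 0
    for fam in sorted(counts):
        for _ in range(counts[fam]):
            idx += 1
            pid = f"{species.species_id}_p{idx:05d}"
            spec = random_receptor_spec(rng, cls=FAMILY_CLASS[fam])
            seq, truth = make_receptor(spec, rng, protein_id=pid, config=cfg)
            records.append(ProteinRecord(pid, species.species_id, seq))
            truth_rows.append({
                "protein_id": pid, "family": fam, "cls": truth.cls,
                "n_lrr": len(truth.motif_spans),
                "n_gaps": len(truth.gaps),
                "id_plus_4lrr": truth.id_plus_4lrr,
                "gxxxg_chain": truth.gxxxg_chain,
                "ejm_net_charge": truth.ejm_net_charge,
                "has_kx5y": truth.has_kx5y,
                "has_yx8kg": truth.has_yx8kg,
                "has_qxxts": truth.has_qxxts,
            })
    n_background = species.n_proteins - sum(counts.values())
    for _ in range(n_background):
        idx += 1
        pid = f"{species.species_id}_p{idx:05d}"
        records.append(
            ProteinRecord(pid, species.species_id, _background_protein(rng, cfg))
        )
        truth_rows.append({
            "protein_id": pid, "family": "background", "cls": "OTHER",
            "n_lrr": 0, "n_gaps": 0, "id_plus_4lrr": False,
            "gxxxg_chain": 0, "ejm_net_charge": 0,
            "has_kx5y": False, "has_yx8kg": False, "has_qxxts": False,
        })
    return records, truth_rows


@dataclass
class PanelSpec:
    """Lineage panel with planted family percentages and deviation factors.

    ``lineages`` maps lineage name -> species ids (ordered); ``baselines``
    maps family -> lineage -> baseline percent; ``deviations`` maps
    (species_id, family) -> multiplicative factor (default 1).  With the
    default n_searched of 20,000 and baseline percents that are multiples
    of 0.05, all planted counts are integral and the realised expansion
    rates equal factor - 1 exactly.
    """

    lineages: Dict[str, List[str]]
    baselines: Dict[str, Dict[str, float]]
    deviations: Dict[Tuple[str, str], float] = field(default_factory=dict)
    n_searched: int = 20_000


def default_panel_spec() -> PanelSpec:
    """A small study-shaped panel: algal baselines through Tracheophytes."""
    lineages = {
        "Glaucophyta_Rhodophyta": [f"redalga_{i}" for i in range(1, 6)],
        "green_algae": [f"greenalga_{i}" for i in range(1, 6)],
        "Bryophytes": [f"bryophyte_{i}" for i in range(1, 6)],
        "Tracheophytes": [f"tracheophyte_{i}" for i in range(1, 8)],
    }
    baselines = {
        "LRR-RLK": {"Glaucophyta_Rhodophyta": 0.10, "green_algae": 0.50,
                    "Bryophytes": 1.00, "Tracheophytes": 1.50},
        "LRR-RLP": {"Glaucophyta_Rhodophyta": 0.05, "green_algae": 0.10,
                    "Bryophytes": 0.40, "Tracheophytes": 0.80},
        "NB-ARC": {"Glaucophyta_Rhodophyta": 0.05, "green_algae": 0.10,
                   "Bryophytes": 0.50, "Tracheophytes": 1.00},
    }
    deviations = {}
    for lineage, members in lineages.items():
        # symmetric factors keep the lineage median at the baseline
        factors = [0.5, 0.8, 1.0, 1.2, 2.0, 1.4, 0.6][: len(members)]
        for sp, f in zip(members, factors):
            for fam in baselines:
                deviations[(sp, fam)] = f
    return PanelSpec(lineages=lineages, baselines=baselines, deviations=deviations)


def make_lineage_panel(panel: PanelSpec, rng: np.random.Generator
                       ) -> Tuple[List[GenomeFamilyCounts], List[Dict]]:
    """Realise the panel as integer gene counts plus a truth table.

    Truth expansion rates are computed from the realised integer counts
    against the realised baseline-lineage median, so rounding is part of
    the recorded truth, not an unrecorded error.
    """
    counts_out: List[GenomeFamilyCounts] = []
    realised: Dict[str, Dict[str, int]] = {}
    for lineage, members in panel.lineages.items():
        if not members:
            raise ValueError(f"lineage {lineage!r} has no species")
        for sp in members:
            fam_counts = {}
            for fam, base in panel.baselines.items():
                pct = base[lineage] * panel.deviations.get((sp, fam), 1.0)
                fam_counts[fam] = int(round(pct / 100.0 * panel.n_searched))
            realised[sp] = fam_counts
            counts_out.append(GenomeFamilyCounts(sp, lineage, fam_counts,
                                                 panel.n_searched))
    truth_rows: List[Dict] = []
    lineage_names = list(panel.lineages)
    for baseline_lineage, target_lineage in zip(lineage_names, lineage_names[1:]):
        for fam in panel.baselines:
            base_pcts = [
                realised[sp][fam] / panel.n_searched * 100.0
                for sp in panel.lineages[baseline_lineage]
            ]
            med = float(np.median(base_pcts))
            for sp in panel.lineages[target_lineage]:
                pct = realised[sp][fam] / panel.n_searched * 100.0
                rate = (pct - med) / med if med > 0 else None
                truth_rows.append({
                    "species_id": sp, "family": fam,
                    "baseline_lineage": baseline_lineage,
                    "target_lineage": target_lineage,
                    "pct": pct, "baseline_median": med, "rate": rate,
                })
    return counts_out, truth_rows


def make_planted_tree(k_clusters: int, leaves_per_cluster: int,
                      d_within: float, d_between: float,
                      rng: np.random.Generator
                      ) -> Tuple[str, Dict[str, int]]:
    """Newick tree whose cophenetic distances are exactly ``d_within``
    inside planted clusters and ``d_between`` across them.

    Leaf order is shuffled by ``rng`` (deterministic per seed).  Returns
    the newick string and the truth partition leaf -> cluster index.
    """
    if not (0 < d_within < d_between):
        raise ValueError("require 0 < d_within < d_between")
    if k_clusters < 1 or leaves_per_cluster < 1:
        raise ValueError("need at least one cluster and one leaf per cluster")
    w = d_within / 2.0
    b = (d_between - d_within) / 2.0
    truth: Dict[str, int] = {}
    clades = []
    for c in range(k_clusters):
        # hyphens, not underscores: unquoted underscores are read as
        # spaces under the newick standard
        leaves = [f"c{c}-l{j}" for j in range(leaves_per_cluster)]
        rng.shuffle(leaves)
        for leaf in leaves:
            truth[leaf] = c
        inner = ",".join(f"{leaf}:{w:.6f}" for leaf in leaves)
        if k_clusters == 1:
            clades.append(inner)
        else:
            clades.append(f"({inner}):{b:.6f}")
    order = rng.permutation(k_clusters)
    newick = "(" + ",".join(clades[i] for i in order) + ");"
    return newick, truth
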