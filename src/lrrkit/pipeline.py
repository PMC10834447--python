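"""Stage orchestration, TSV emission, and run manifests.

Two composite runs are provided: ``run_annotate_arch_motifs`` takes FASTA
proteomes through classification, architecture parsing and motif scanning,
and ``run_evolution_report`` turns a family-count table plus lineage map
into expansion, correlation and test tables.  Every output is TSV (UTF-8,
header row, 1-based inclusive coordinates); a JSON manifest records the
inputs, the configuration snapshot, the seed and SHA-256 checksums of all
outputs, so a rerun with the same manifest is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import annotate, arch, motifs as motifs_mod
from .config import AnalysisConfig
from .evostats import (GenomeFamilyCounts, bh_fdr, correlate_with_family,
                       expansion_table, family_percentage)
from .io import DomainCall, ProteinRecord, load_external_annotations, read_fasta

log = logging.getLogger("lrrkit")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    inputs: List[str]
    config: dict
    seed: int
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add(self, path: str) -> None:
        self.outputs[os.path.basename(path)] = _sha256(path)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"inputs": self.inputs, "config": self.config, "seed": self.seed,
                 "outputs": self.outputs},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def analyse_protein(record: ProteinRecord,
                    calls: Optional[Sequence[DomainCall]] = None,
                    config: Optional[AnalysisConfig] = None):
    """Classify one protein and, when it is an LRR receptor, parse its
    architecture and scan its motifs.  Returns (classification, profile,
    report); the latter two may be None."""
    cfg = config or AnalysisConfig()
    if calls is None:
        calls = annotate.annotate_protein(record, cfg)
    cls = annotate.classify(record, calls, cfg)
    profile = None
    report = None
    if cls.cls is not annotate.ReceptorClass.OTHER:
        profile = arch.build_profile(record, calls, cls, cfg)
        id_seqs = [g.sequence for g in profile.gaps
                   if g.gap_class == "ID" and g.passed_lrr_screen]
        if profile.region_set is not None:
            rs = profile.region_set
            last_motif = profile.motif_spans[-1]
            terminal_seq = record.sequence[last_motif[0] - 1:last_motif[1]]
            report = motifs_mod.scan_report(
                record.id, id_seqs, terminal_seq, rs.tm_seq, rs.ejm_seq,
                cfg.charge_window,
            )
    return cls, profile, report


def run_annotate_arch_motifs(fasta_paths: Sequence[str], out_dir: str,
                             config: Optional[AnalysisConfig] = None,
                             domains_path: Optional[str] = None) -> RunManifest:
    """Annotate -> architecture -> motifs over one or more proteomes.

    Per-protein failures are logged and skipped; zero parseable records is
    an error.  Writes classification.tsv, architecture.tsv, gaps.tsv,
    motifs.tsv, id_regions.fasta and manifest.json under ``out_dir``.
    """
    cfg = config or AnalysisConfig()
    os.makedirs(out_dir, exist_ok=True)
    external = load_external_annotations(domains_path) if domains_path else {}
    cls_rows, arch_rows, gap_rows, motif_rows, id_fasta = [], [], [], [], []
    n_records = 0
    for path in fasta_paths:
        for record in read_fasta(path):
            n_records += 1
            try:
                calls = external.get(record.id) or annotate.annotate_protein(record, cfg)
                cls, profile, report = analyse_protein(record, calls, cfg)
            except Exception as exc:  # isolate per-protein failures
                log.warning("skipping %s: %s", record.id, exc)
                continue
            cls_rows.append({
                "protein_id": record.id, "species_id": record.species_id,
                "class": cls.cls.value, "n_tm": cls.n_tm, "has_kd": cls.has_kd,
                "ecto_start": cls.ecto_span[0] if cls.ecto_span else "",
                "ecto_end": cls.ecto_span[1] if cls.ecto_span else "",
                "endo_start": cls.endo_span[0] if cls.endo_span else "",
                "endo_end": cls.endo_span[1] if cls.endo_span else "",
                "filtered_reason": cls.filtered_reason or "",
            })
            if profile is not None:
                rs = profile.region_set
                arch_rows.append({
                    "protein_id": record.id,
                    "n_motifs": len(profile.motif_spans),
                    "n_regions": len(profile.regions),
                    "id_plus_4lrr": profile.id_plus_4lrr,
                    "c3_start": rs.c3_span[0] if rs else "",
                    "c3_end": rs.c3_span[1] if rs else "",
                    "tm_start": rs.tm_span[0] if rs else "",
                    "tm_end": rs.tm_span[1] if rs else "",
                })
                for g in profile.gaps:
                    gap_rows.append({
                        "protein_id": record.id, "start": g.start, "end": g.end,
                        "length": g.length, "gap_class": g.gap_class,
                        "n1": g.n1, "n2": g.n2,
                        "passed_lrr_screen": g.passed_lrr_screen,
                    })
                    if g.gap_class == "ID" and g.passed_lrr_screen:
                        id_fasta.append((f"{record.id}|ID|{g.start}-{g.end}",
                                         g.sequence))
            if report is not None:
                motif_rows.append({
                    "protein_id": record.id,
                    "kx5y": len(report.kx5y_positions),
                    "yx8kg": len(report.yx8kg_positions),
                    "has_either_lysine": report.has_either_lysine,
                    "qxxts": len(report.qxxts_positions),
                    "has_tqxxx": report.has_tqxxx,
                    "gxxxg_chain_max": report.gxxxg_chain_max,
                    "ejm_net_charge": report.ejm_net_charge,
                    "ejm_terminal_charge": report.ejm_terminal_charge,
                })
    if n_records == 0:
        raise ValueError("no parseable FASTA records in inputs")

    manifest = RunManifest(inputs=list(fasta_paths), config=cfg.to_dict(),
                           seed=cfg.seed)
    for name, rows, cols in (
        ("classification.tsv", cls_rows,
         ["protein_id", "species_id", "class", "n_tm", "has_kd", "ecto_start",
          "ecto_end", "endo_start", "endo_end", "filtered_reason"]),
        ("architecture.tsv", arch_rows,
         ["protein_id", "n_motifs", "n_regions", "id_plus_4lrr", "c3_start",
          "c3_end", "tm_start", "tm_end"]),
        ("gaps.tsv", gap_rows,
         ["protein_id", "start", "end", "length", "gap_class", "n1", "n2",
          "passed_lrr_screen"]),
        ("motifs.tsv", motif_rows,
         ["protein_id", "kx5y", "yx8kg", "has_either_lysine", "qxxts",
          "has_tqxxx", "gxxxg_chain_max", "ejm_net_charge",
          "ejm_terminal_charge"]),
    ):
        path = os.path.join(out_dir, name)
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        manifest.add(path)
    fasta_path = os.path.join(out_dir, "id_regions.fasta")
    with open(fasta_path, "w") as fh:
        for header, seq in id_fasta:
            fh.write(f">{header}\n{seq}\n")
    manifest.add(fasta_path)
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest


def load_counts_table(path: str) -> List[GenomeFamilyCounts]:
    """Counts TSV: species_id, lineage, family, count, n_searched."""
    df = pd.read_csv(path, sep="\t")
    out: List[GenomeFamilyCounts] = []
    for (sp, lineage, n), grp in df.groupby(["species_id", "lineage", "n_searched"]):
        out.append(GenomeFamilyCounts(
            str(sp), str(lineage),
            dict(zip(grp["family"], grp["count"].astype(int))), int(n),
        ))
    return out


def run_evolution_report(counts: Sequence[GenomeFamilyCounts],
                         lineage_pairs: Sequence[tuple], out_dir: str,
                         target_family: Optional[str] = None,
                         config: Optional[AnalysisConfig] = None) -> RunManifest:
    """Expansion rates for each (baseline, target) lineage pair, plus
    optional co-expansion correlations against ``target_family``."""
    cfg = config or AnalysisConfig()
    os.makedirs(out_dir, exist_ok=True)
    known = {g.species_id for g in counts}
    exp_rows = []
    for baseline, target in lineage_pairs:
        for rec in expansion_table(counts, baseline, target):
            exp_rows.append({
                "species_id": rec.species_id, "family": rec.family,
                "baseline_lineage": rec.baseline_lineage,
                "target_lineage": target, "pct": rec.pct,
                "baseline_median": rec.baseline_median,
                "rate": "" if rec.rate is None else rec.rate,
            })
    manifest = RunManifest(inputs=[], config=cfg.to_dict(), seed=cfg.seed)
    exp_path = os.path.join(out_dir, "expansion.tsv")
    pd.DataFrame(exp_rows).to_csv(exp_path, sep="\t", index=False)
    manifest.add(exp_path)

    if target_family is not None:
        table = pd.DataFrame({
            g.species_id: {
                fam: family_percentage(c, g.n_searched)
                for fam, c in g.counts.items()
            }
            for g in counts
        }).T
        corr_rows = [
            {"family": r.family, "target_family": r.target_family,
             "r": "" if r.r is None else r.r, "n": r.n, "strength": r.strength}
            for r in correlate_with_family(table, target_family, cfg)
        ]
        corr_path = os.path.join(out_dir, "correlation.tsv")
        pd.DataFrame(corr_rows).to_csv(corr_path, sep="\t", index=False)
        manifest.add(corr_path)

    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest
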