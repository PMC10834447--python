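"""Evolutionary statistics for receptor-family sizes.

Family sizes are expressed as percentages of the searched gene set
(count / n_searched x 100).  Lineage expansion uses the median family
percentage of a baseline lineage (median rather than mean, to resist
outlier genomes); the expansion rate of a species is
(pct - baseline_median) / baseline_median, so 0 means no expansion,
positive values expansion and negative values contraction.  Co-expansion
between families is summarised by Pearson r with strong (> 0.6) and
medium (0.3-0.6) classes.  Congruence between a family-fraction profile
and a phylogeny is tested with a Mantel permutation test (10,000
permutations by default, one-sided "greater" as in vegan); p-values are
corrected with Benjamini-Hochberg FDR, and 2x2 enrichments use the
two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig


@dataclass
class GenomeFamilyCounts:
    species_id: str
    lineage: str
    counts: Dict[str, int]
    n_searched: int

    def __post_init__(self) -> None:
        if self.n_searched <= 0:
            raise ValueError(f"{self.species_id}: n_searched must be positive")
        for fam, c in self.counts.items():
            if c > self.n_searched:
                raise ValueError(
                    f"{self.species_id}/{fam}: count {c} exceeds n_searched"
                )


@dataclass
class ExpansionRecord:
    species_id: str
    family: str
    baseline_lineage: str
    pct: float
    baseline_median: float
    rate: Optional[float]


@dataclass
class CorrelationRecord:
    family: str
    target_family: str
    r: Optional[float]
    n: int
    strength: str  # "strong", "medium", "weak/none", or "NA"


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    fdr_q: Optional[float] = None


@dataclass
class FisherResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


def family_percentage(count: int, n_searched: int) -> float:
    """Family size as percent of searched genes."""
    if n_searched <= 0:
        raise ValueError("n_searched must be positive")
    if count < 0 or count > n_searched:
        raise ValueError(f"count {count} outside [0, n_searched]")
    return count / n_searched * 100.0


def lineage_median(percents: Sequence[float], lineage: str = "") -> float:
    """Median family percentage over the species of a baseline lineage."""
    if len(percents) == 0:
        raise ValueError(f"empty baseline lineage {lineage!r}")
    return float(np.median(np.asarray(percents, dtype=float)))


def expansion_rate(pct: float, baseline_median: float) -> Optional[float]:
    """(pct - median) / median; None (not a blow-up) when the median is 0."""
    if baseline_median < 0:
        raise ValueError("baseline median must be non-negative")
    if baseline_median == 0:
        return None
    return (pct - baseline_median) / baseline_median


def expansion_table(counts: Sequence[GenomeFamilyCounts],
                    baseline_lineage: str, target_lineage: str,
                    families: Optional[Sequence[str]] = None
                    ) -> List[ExpansionRecord]:
    """Expansion rates of every target-lineage species against a baseline."""
    baseline = [g for g in counts if g.lineage == baseline_lineage]
    targets = [g for g in counts if g.lineage == target_lineage]
    if not baseline:
        raise ValueError(f"empty baseline lineage {baseline_lineage!r}")
    if families is None:
        families = sorted({f for g in counts for f in g.counts})
    records: List[ExpansionRecord] = []
    for fam in families:
        med = lineage_median(
            [family_percentage(g.counts.get(fam, 0), g.n_searched) for g in baseline],
            baseline_lineage,
        )
        for g in targets:
            pct = family_percentage(g.counts.get(fam, 0), g.n_searched)
            records.append(ExpansionRecord(
                g.species_id, fam, baseline_lineage, pct, med,
                expansion_rate(pct, med),
            ))
    return records


def _strength(r: float, cfg: AnalysisConfig) -> str:
    if r > cfg.r_strong:
        return "strong"
    if cfg.r_medium <= r <= cfg.r_strong:
        return "medium"
    return "weak/none"


def correlate_with_family(table: pd.DataFrame, target_family: str,
                          config: Optional[AnalysisConfig] = None
                          ) -> List[CorrelationRecord]:
    """Pearson r of every family column against ``target_family``.

    ``table`` is species x family percentages; each pair uses
    pairwise-complete genomes and requires at least three of them.
    Constant columns give an undefined r, flagged "NA".
    """
    cfg = config or AnalysisConfig()
    if target_family not in table.columns:
        raise KeyError(f"target family {target_family!r} not in table")
    records: List[CorrelationRecord] = []
    y_all = table[target_family]
    for fam in table.columns:
        if fam == target_family:
            continue
        pair = pd.concat([table[fam], y_all], axis=1).dropna()
        n = len(pair)
        if n < 3:
            raise ValueError(f"{fam}: fewer than 3 genomes with both values")
        x = pair.iloc[:, 0].to_numpy(float)
        y = pair.iloc[:, 1].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            records.append(CorrelationRecord(fam, target_family, None, n, "NA"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        records.append(CorrelationRecord(fam, target_family, r, n, _strength(r, cfg)))
    return records


def fractions_to_distance(values: Dict[str, float]) -> Tuple[List[str], np.ndarray]:
    """Absolute-difference distance matrix between per-species fractions."""
    species = [s for s, v in values.items() if v is not None and not math.isnan(v)]
    if len(species) < len(values):
        warnings.warn("species with missing values excluded from distance matrix")
    if len(species) < 2:
        raise ValueError("need at least two species with values")
    v = np.array([values[s] for s in species], dtype=float)
    return species, np.abs(v[:, None] - v[None, :])


def mantel(d1: np.ndarray, d2: np.ndarray, n_perm: int = 10_000,
           seed: int = 0, alternative: str = "greater") -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the strictly-upper-triangle
    entries; the null distribution is generated by simultaneous row/column
    permutation of ``d2``.  The one-sided p-value is
    (1 + #{r_perm >= r_obs}) / (1 + n_perm); ``alternative="two-sided"``
    compares absolute values.  Deterministic given ``seed``.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("distance matrices must be square and of equal shape")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test requires at least 4 labels")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    iu = np.triu_indices(n, k=1)

    def norm(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        s = np.sqrt((v ** 2).sum())
        if s == 0:
            raise ValueError("constant distance matrix; Mantel r undefined")
        return v / s

    x = norm(d1[iu])
    y = norm(d2[iu])
    r_obs = float(x @ y)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # permuted upper triangles, vectorised: d2[perm][:, perm][iu]
    rows = perms[:, iu[0]]
    cols = perms[:, iu[1]]
    perm_vecs = d2[rows, cols]
    pv = perm_vecs - perm_vecs.mean(axis=1, keepdims=True)
    denom = np.sqrt((pv ** 2).sum(axis=1))
    denom[denom == 0] = np.inf
    r_perm = (pv @ x) / denom
    if alternative == "greater":
        hits = int(np.sum(r_perm >= r_obs))
    elif alternative == "two-sided":
        hits = int(np.sum(np.abs(r_perm) >= abs(r_obs)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed)


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving by input index."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def fisher_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums the hypergeometric probabilities (margins fixed) of
    every table at most as probable as the observed one, with a relative
    tie tolerance of 1e-7.  The odds ratio is ad/bc, infinite when bc = 0
    and ad > 0, and NaN for the degenerate 0/0 case.
    """
    for v in (a, b, c, d):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    # hypergeometric pmf over the support, via log-gamma for stability
    from scipy.special import gammaln

    def log_comb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logp = (log_comb(r1, support) + log_comb(n - r1, c1 - support)
            - log_comb(n, c1))
    pmf = np.exp(logp - logp.max())
    pmf = pmf / pmf.sum()
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(((a, b), (c, d)), odds, p)
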