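# Methods

## Scope and model

`lrrkit` operationalises a comparative-genomics workflow for plant
cell-surface receptors. The objects of study are single-pass membrane
receptors whose extracellular face is a string of ~24-residue leucine-rich
repeats (LRRs): receptor-like kinases (RLKs, 1–2 transmembrane helices
plus a cytosolic kinase domain), receptor-like proteins (RLPs, 1–2 TMs,
no kinase), and ectodomain-only proteins. Two architectural insertions
between LRR motifs carry most of the signal: short N-loopouts (NLs,
15–29 residues) and longer island domains (IDs, 30–90 residues). The
ID+4LRR configuration — an island domain immediately preceding the last
four LRR motifs — is the hallmark shared by immune LRR-RLPs and the
developmental LRR-RLK subgroup Xb, and the short motifs the package
scans (QxxT/S in the terminal repeat, Kx5Y/Yx8KG in the ID, GxxxG chains
in the TM, a negatively charged eJM) mark the co-receptor interfaces
(SERK/BAK1 and SOBIR1 recruitment) that distinguish the two families.

The pipeline stages are independent and composable: annotate
(classification), arch (architecture parsing), motifs (scanners),
evostats (family-size statistics), treeclust (cophenetic network
clustering), synthgen (ground-truth generator), pipeline (orchestration
and manifests).

## Detector stand-ins

Production annotation of real proteomes uses external predictors
(tmhmm, SignalP, hmmer/PF00069, predict-phytolrr). `lrrkit` accepts
their output through the external-annotation TSV path and treats those
calls identically to its own. The built-in detectors are deliberately
simple rules chosen to be exactly testable:

- **TM**: sliding-window mean Kyte–Doolittle hydropathy (window 19,
  threshold 1.6), maximal runs of qualifying windows unioned into spans;
  spans under 15 residues are dropped, spans over 35 trimmed to the
  maximal-scoring 21-mer. Window sums are compared in integer deci-units
  so threshold ties never depend on floating-point summation order.
- **Signal peptide**: a maximal hydrophobic run (residues AILMFVC) of
  7–15 residues with mean hydropathy ≥ 2.0 beginning within the first 10
  residues marks residues 1..run-end; the region is masked (hydropathy 0)
  before the TM scan so it is never double-counted as a membrane helix.
- **Kinase domain**: ordered catalytic landmarks — G-x-G-x-x-G, a lysine
  within 30 residues, HRD, then DFG — inside a 150–350-residue window;
  the most compact candidate wins and the span extends 30 residues past
  DFG (clipped).
- **LRR motif**: the plant LRR core with hydrophobic {L,I,V,F,M} at
  pattern positions 1, 4, 6, 8, 13 and {N,T,S,C} at 11; greedy
  left-to-right, each match anchoring a 24-residue non-overlapping call.
  X scores 0 hydropathy and matches no motif class.

## Parameter defaults

All knobs live in `AnalysisConfig`; every value is recorded in the run
manifest. Defaults: region merge < 13 residues; NL range [15, 29]
(configurable — survey-style descriptions sometimes quote 10–29, but
with merging below 13 the 10–12 band is unreachable, so the executed
range is the default); ID range [30, 90]; ID+4LRR requires exactly
N2 = 4 motifs after the ID (`id4_le` relaxes to ≤ 4); length filters 250
(LRR-kinase candidates, applied to the untrimmed sequence) and 150
(all proteins); terminal eJM charge window 10 residues (the width of
"the end of the eJM" is not standardised; it is configurable); Pearson
strong/medium boundaries 0.6/0.3 with [0.3, 0.6] assigned to medium;
Mantel 10,000 permutations, one-sided "greater" (the vegan default;
two-sided by flag); cophenetic cutoff 0.2 substitutions/site, strict
inequality; charge counts only K/R as positive and D/E as negative
(histidine neutral).

Open design points were resolved as follows and are flagged in the
configuration rather than hidden: gaps flanking the first or last motif
are not NL/ID candidates by default (`include_terminal_gaps` switches
this on); for 2-TM receptors with tied LRR counts the N-terminal stretch
is taken as ectodomain; the cJM of RLKs ends at the residue before the
kinase domain (`cjm_mode`); any qualifying ID raises the ID+4LRR flag,
not only the most C-terminal one; Yx8KG strictly requires the trailing
glycine; co-expansion correlations use family percentages, not raw
counts.

## Statistics

Family size is count/searched × 100. Expansion rate is
(pct − baseline-lineage median)/median — the median resists outlier
genomes; a zero median propagates as not-available rather than dividing.
The Mantel statistic is the Pearson correlation of strictly-upper-triangle
entries, with the null built by simultaneous row/column permutation of
the second matrix and p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm); the
permutation stream is seeded, so results are reproducible.
Benjamini–Hochberg correction is delegated to statsmodels. The
two-sided Fisher p-value sums hypergeometric probabilities of all tables
(fixed margins) at most as probable as the observed one, with a 1e-7
relative tie tolerance; it is implemented over the full support via
log-gamma so the exhaustive small-table sweep is fast, and it is
cross-checked against both scipy and an exact integer-arithmetic
enumeration in the tests. The odds ratio is ad/bc, infinite when bc = 0
with ad > 0.

Tree clustering converts cophenetic distances d < 0.2 into edge weights
1 − d/cutoff (positive, bounded, cutoff-relative; plain 1 − d by flag —
the conversion only rescales weights and did not change any planted
partition we tested). Louvain runs single-shot with a fixed seed: the
igraph routine the field typically uses is run-to-run nondeterministic,
so determinism-by-seed is a deliberate strengthening. Isolated leaves
become singleton clusters and are counted in composition summaries.

## The synthetic generator

`synthgen` plants architectures; it does not simulate molecular
evolution (no indels, no domain shuffling, no substitution history
unless a noise rate is requested — the default suites are noiseless so
recovery can be asserted exactly). A receptor is a concatenation of an
optional signal peptide (MK + 10 leucines), a polar cap, tandem copies
of a fixed 24-residue LRR template that matches the detector core,
NL/ID fillers drawn from a polar alphabet (DEKNPQRST) that can never
match the LRR core, a lysine-motif insert when requested, an eJM
composed as neutral pad + charge block + 8-residue neutral tail (the
tail absorbs the TM detector's flank extension so the planted net charge
always survives region extraction), a 23-residue hydrophobic TM carrying
0–3 chained GxxxG units, and for RLKs a kinase cassette whose landmark
spacing makes the detected span the cassette exactly. Every emitted
sequence is validated by running the real pipeline at generation time.

Background proteome proteins are drawn from average plant amino-acid
frequencies and rejection-sampled until no detector fires, so planted
family percentages are exact by construction. Consequently, passing
round-trip suites demonstrates correctness of the pipeline logic on
unambiguous architectures — not robustness to the noisy, partially
degenerate repeats of real proteomes, where detector sensitivity is
governed by the external predictors feeding the annotation path.

The default lineage panel uses four lineages (Glaucophyta+Rhodophyta →
green algae → Bryophytes → Tracheophytes, mirroring the baseline
progression used for plant receptor families), 5–7 species each,
n_searched = 20,000, and baseline percentages that are multiples of
0.05% with one-decimal deviation factors, so all planted counts are
integers and recovered expansion rates are exact to machine precision.
Planted trees place k cluster nodes at branch length
(d_between − d_within)/2 from the root with leaves at d_within/2, making
within- and between-cluster cophenetic distances exactly d_within and
d_between.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to make
every check exhaustive or statistically stable: all 120 gap lengths; 300
planted receptors; 1,000 Mantel null replicates of 12 labels × 999
permutations; every 2×2 table with margins ≤ 30 (164,175 tables); 200
random trees of ≤ 12 leaves; 20 Louvain seeds; 10,000 random peptides;
120-protein proteomes for determinism runs. Dataset-scale headline
counts from real 350-proteome surveys are not reproducible at this scale
and are out of scope. Ties in TM trimming resolve to the leftmost
maximal window; region/stretch ties resolve N-terminal; all coordinates
are 1-based inclusive externally.

## Known limitations

- The stand-in detectors are rule-based and will not match
  tmhmm/SignalP/hmmer sensitivity on real sequences; the external
  annotation path is the fidelity escape hatch.
- Non-LRR ectodomain families (G-lectin, WAK, LysM, ...) are not
  assigned by profile search; family labels arrive via metadata.
- Alignment and tree inference are consumed, not produced: the package
  emits region FASTAs and reads newick.
- Cluster-count summaries depend on the input tree and cutoff; no claim
  is made about absolute cluster numbers on real data.
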