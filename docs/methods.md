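# Methods

## Problem and model

Bacterial proteins adapt to the compartment they function in. In marine
("salt-out") bacteria the cytoplasm is osmotically buffered while the
periplasm and the extracellular milieu are not, so exported proteins show a
gradient of adaptations — acidification (more Asp/Glu, fewer Arg/Lys/His,
lower isoelectric point), enrichment of polar (Ser, Thr, Asn) and aromatic
(Phe, Tyr, Trp) residues, and characteristic dipeptides (NP/PN) — that
grows from cytoplasmic through periplasmic to extracellular proteins.
`ayu` exploits this gradient to predict localization from sequence, which
matters because a large share of the extracellular proteome is exported by
signal-peptide-independent systems and is invisible to signal-peptide
predictors alone.

Each protein is a 466-vector: AAC(20) ‖ DPC(400) ‖ pQSO(20) ‖ pPAAC(20) ‖
pI(1) ‖ SLR(1) ‖ SP(4), with block offsets 0/20/420/440/460/461/462.

**Sequence-order descriptors.** For the canonical-residue subsequence
R_1..R_L:

* pQSO: τ_d = Σ_{i=1..L−d} d(R_i, R_{i+d})² for d = 1..20, emitted as
  x_d = w·τ_d / (1 + w·Σ_d' τ_d') with w = 0.1;
* pPAAC: Θ(a,b) = mean over three standardized propensity scales
  (hydrophobicity, hydrophilicity, residue mass) of (scale(b) − scale(a))²;
  θ_d = mean of Θ over all lag-d pairs; x_d = w·θ_d / (1 + w·Σ θ) with
  w = 0.05.

Both are "partial": the 20 composition slots of the classical descriptors
are dropped (they duplicate AAC) while the classical denominator is kept so
the coupling terms stay on their usual scale. Lags at or beyond the
sequence length are zero. Weights are the classical defaults.

**Physicochemical distance matrix.** The packaged default d(a,b) is the
Euclidean distance over the three standardized scales above, normalized to
a maximum of 1. This is a reconstruction in the spirit of the published
amino-acid physicochemical distances, not a reprint of the original table
(which is not available offline); the matrix is an injectable parameter of
`pqso`, so any 20×20 symmetric zero-diagonal table can be substituted and
the descriptor contract (oracle equivalence, zero for homopolymers) is
matrix-agnostic.

**Isoelectric point.** Composition-only Henderson–Hasselbalch model with
the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9,
E 4.1, C 8.5, Y 10.1), solved by bisection on [0, 14] to an interval of
1e-6 (net charge residual far below 1e-4). A learned pI predictor would
give values differing by up to ~0.5 pH units; since pI enters only as a
monotone feature, the classifier is insensitive to the calibration choice.

**Region log-ratio (SLR).** Proteins annotated with transmembrane-helix
(pH), beta-barrel (pB), signal (pS), outside (po) and inside (pi) residue
fractions get the amalgam log-ratio ln((pH + pB + ε)/(pS + po + pi + ε)),
ε = 1e-6 guarding empty amalgams (an unannotated protein scores
ln(1e-6) ≈ −13.8). Natural log; the ε guard and base are implementation
choices documented here because the amalgam is undefined at zero.

**Signal-peptide block.** Four probabilities (any, Sec/SPI, SPII, Tat) as
produced by an external predictor and carried through the annotation TSV.
When no annotation table is supplied, a crude fallback scores the best
8-residue mean Kyte–Doolittle hydropathy within the first 30 residues,
squashed through a logistic centered at 2.25; it is logged as NOT
equivalent to a trained predictor and sets the type probabilities to 0.

## Classifiers

Both modes use xgboost (`hist`, single thread, fixed seed — runs are
bit-reproducible) with early stopping on held-out log-loss (patience 20,
up to 500 trees, depth 6, learning rate 0.1, subsample 1.0 by default; a
3×3×2 grid over depth {4,6,8} × rate {0.05,0.1,0.3} × subsample {0.8,1.0}
is available through `grid_search_cv`, scored by k-category MCC over
homology-aware folds).

The ordinal decomposition trains L1 = P(exported) on all rows and
L2 = P(extracellular | exported) on the exported subset only. Because L2
is conditional, the chain rule P = (1−p1, p1(1−p2), p1·p2) recombines the
two outputs into a proper distribution with no clamping; the Frank–Hall
subtraction variant (which can go negative and needs renormalising) is
available for comparison. SMOTE (interpolation toward k = 5 same-class
nearest neighbours, all classes brought to the majority count, originals
kept verbatim) defaults to on for multiclass and off for ordinal.
Predictions whose top probability falls below τ = 0.5 are reported as
"unclassified" rather than forced into a class.

Scoring conventions: "unclassified" predictions are kept as an extra
confusion column — they count as false negatives for their true class and
never as false positives (a drop-rows policy is available). Gorodkin's R_K
is computed in covariance form from the confusion matrix and reduces
exactly to the binary MCC for K = 2; degenerate marginals return 0 by
convention, flagged.

## Dataset construction

* Global identity: Needleman–Wunsch with BLOSUM62, gap open 11 / extend 1;
  identity = identical aligned positions / alignment length; coverage =
  non-terminal-gap span of the shorter sequence / its length (the shorter
  sequence as denominator is a choice, configurable).
* Annotation propagation: a curated label transfers to a query only at
  ≥ 25% global identity AND with exactly equal ordered domain lists (same
  content and synteny). Identity is measured over the alignment length.
* Greedy clustering (dedup at 0.30/0.80, screening clusters at 0.70/0.95):
  sequences visited by descending length; each joins the first cluster
  whose founder it matches at both thresholds, else founds one. The
  reported representative is the member with the best reference-match
  identity when available, otherwise the longest member.
* Homology-aware partitioning: connected components of the ≥ 30%-identity
  graph are atomic; components are placed greedily (largest first) where
  their classes are relatively most under target, which yields exact
  stratification when the graph is edgeless and guarantees that no
  above-threshold pair ever crosses a fold boundary. A component larger
  than the largest fold triggers a warning recorded in the manifest.
* All-vs-all alignment is quadratic, so pairs sharing no 5-mer are skipped.
  At ≥ 25–30% identity over desk-scale lengths a passing pair essentially
  always shares a 5-mer; the exhaustive (prefilter-free) checker used in
  tests verifies the partition contract independently.

## Synthetic proteome generator

The generator produces the study conditions for training and evaluation
with no external data:

* class ratio 1:1:10 extracellular:periplasmic:cytoplasmic (multinomial,
  or exact counts on request);
* per-class mean compositions: a typical bacterial baseline with
  D/E/S/T/N/F/Y/W multiplied by (1+s) and R/K/H/V/I/L/M/C by (1−s), then
  renormalized; s = 0.5 extracellular, 0.25 periplasmic, 0 cytoplasmic.
  This realizes a mean absolute shift of ≈ 2.4 percentage points per
  affected letter (2.3–5.7 pp for the abundant ones; rare letters such as
  Trp or Cys cannot move that far multiplicatively from a ~1% base);
* per-protein composition ~ Dirichlet(300 × class mean), then residues
  i.i.d. The concentration 300 puts within-class per-letter spread
  (~1.5 pp) below the between-class shifts, so the configured effect sizes
  are recoverable at desk scale while per-protein variability remains
  substantial; at the realized sequence lengths the residue-sampling noise
  (~1.7 pp per letter) is of the same order, keeping the problem
  non-trivial;
* signal peptides on 90% of periplasmic and 60% of extracellular proteins
  (never on cytoplasmic ones): positively charged n-region, 8–12-residue
  hydrophobic h-region, small-residue c-region — enough structure for the
  hydrophobicity fallback to detect; annotation probabilities drawn near
  0.9 for carriers, exactly 0 otherwise;
* NP/PN dipeptide insertions at Poisson rates 3 / 2 / 0.2 per protein
  (extracellular / periplasmic / cytoplasmic);
* lengths log-normal (σ = 0.35) with medians 200 / 200 / 260, minimum 60;
* 5% of cytoplasmic proteins become inner-membrane decoys: 1–3 hydrophobic
  helices written into the sequence and annotated as transmembrane
  segments, mostly with a membrane GO flag.

What the generator does **not** emulate: phylogenetic structure and
real homology families (sequences are i.i.d. given their class, so the
homology graph of a generated proteome is nearly edgeless — the partition
machinery is exercised separately on planted-homolog fixtures), realistic
signal-peptide predictor score distributions (carriers vs non-carriers are
cleanly separated), domain architectures, taxon-specific composition, and
genuine secretion-system biology. Passing tests on generated data
therefore demonstrate that the pipeline recovers the statistical structure
it was told to plant — composition gradients, SP asymmetry, imbalance —
not field performance on real proteomes, which additionally depends on the
quality of the external signal-peptide/transmembrane annotations.

## Screening rules

A protein is a membrane protein when its transmembrane-helix plus
beta-barrel residues reach 5% of its length, except that a single helix
starting within the first 30 residues (a span where signal peptides are
routinely miscalled as helices) counts only with a membrane GO term. The
30-residue N-terminal window and the SP-positive threshold (any-SP
probability ≥ 0.5) are documented defaults. Expression ratios use
log2((metaT + ε)/(metaG + ε)) with ε = 1e-3 pseudo-abundance because real
recruitment tables contain zeros.

## Numerical and design notes

* Ambiguity letters (X, B, Z, U, O) are kept in records but excluded from
  descriptors: composition ignores them, dipeptide windows containing one
  are skipped, sequence-order terms use the canonical-only subsequence.
  For alignment, U→C and O→K (structural analogues) since BLOSUM62 lacks
  those columns.
* Multiplicative zero replacement: zeros → δ (default 1e-5), non-zeros
  scaled by (1 − z·δ). ILR uses the orthonormal pivot
  (sequential-binary-partition) basis by default; the basis is a parameter
  and the transform is an isometry between Aitchison and Euclidean
  geometry.
* Residue-economy properties use Akashi–Gojobori aerobic ATP costs and
  whole-residue elemental formulas (backbone included: Arg 4 N, Lys 2 N,
  Met/Cys 1 S); the cost table is swappable.
* Ties in grid search keep the first grid point in declaration order;
  greedy clustering breaks length ties lexicographically by id; every
  stochastic operation takes an explicit seed (default 42).
* Model persistence stores boosters plus a JSON manifest (mode, layout,
  hyperparameters, seed, threshold, version); loading reconstructs the
  sklearn wrappers around the boosters.
* Problem sizes: the benchmark pipeline runs 2,600 proteins (200/200/2,200)
  with a 70/15/15 homology-aware split — large enough for stable k-category
  MCC on the 390-protein test split while the all-vs-all identity stage
  stays in the minutes range on a single CPU. Per-class generator checks
  use 1,000 proteins per class.

## Known limitations

* The SP fallback heuristic is a hydrophobicity screen, not a trained
  predictor; predictions without an annotation table are correspondingly
  weaker and flagged in logs.
* The greedy clusterer is a simplified stand-in for CD-HIT/mmseqs2-style
  tools; it matches against cluster founders only.
* With ~30 minority-class proteins in a 15% test split, recall moves in
  steps of 1/30 ≈ 0.033; comparisons between training variants (e.g.
  SMOTE on vs off) at that granularity can swing by a few proteins across
  seeds. On generated data SMOTE's effect on extracellular recall is
  seed-dependent and can be negative by more than the ~0.02 seen on real
  curated data, while overall MCC is essentially unchanged.
* pI values use EMBOSS pKa constants; absolute values shift with the pKa
  set, orderings do not.
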