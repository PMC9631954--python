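# Methods

This note documents the models, the numerical choices and the synthetic
data underlying `epitopescan`, and what the tests do and do not establish.

## Scoring models

### Pocket-PSSM MHC-II predictor

A position-specific scoring matrix (PSSM) for an allele is a 9 × 20 table
of additive half-site preferences over the MHC-II binding core. A 9-mer
core scores the plain left-to-right sum of its nine addressed cells — the
summation order is part of the contract so that scores are bit-reproducible
across implementations. Peptides longer than 9 residues are scanned over
every 9-mer frame; the reported score is the best frame and ties resolve to
the leftmost frame (determinism). Scores are reported raw, with no
length normalization or cross-allele rescaling.

Pan-allele coverage uses pocket similarity. The groove is decomposed by a
`PocketDefinition`: an editable table of pockets, the core positions each
pocket contacts, and the pseudo-sequence positions that line it. The
default definition has five anchor pockets at core positions 1, 4, 6, 7
and 9 (non-anchor positions assigned to the nearest anchor pocket so the
whole core is covered) over a 15-residue pseudo-sequence split evenly.
Pocket similarity between two pseudo-sequences is the BLOSUM62 score over
the pocket's positions normalized by the geometric mean of the two
self-scores, clipped to [0, 1] — symmetric, equal to 1 on identity, and
comparable across pockets of different sizes.

Virtual matrices are assembled per pocket in one of two modes:

- `nearest` (default): each pocket's matrix rows are copied from the single
  most similar library entry (ties to the first library entry);
- `blend`: rows are averaged over all entries with per-pocket similarity
  weights normalized to sum to 1.

Both modes reproduce a library entry cell-for-cell when the target
pseudo-sequence matches it exactly; this passthrough is asserted in the
test suite. `nearest` is the default because it preserves measured columns
verbatim instead of smoothing them.

### MHC-I affinity regressor

Binding affinities span five orders of magnitude, so regression is done on
the standard log-transform y = 1 − ln(IC50 nM)/ln(50000), clamped to
[0, 1]; the inverse is IC50 = 50000^(1−y). Peptides are encoded one-hot by
default (20 indicators per residue, alphabetical order ACDEFGHIKLMNPQRSTVWY
— the single residue-order convention shared with the PSSM module).
BLOSUM62-row encoding and arbitrary per-residue descriptor tables loaded
from CSV (for NLF/OETMAP-style schemes) are available; one-hot is adequate
for this model family and is what the defaults use.

The network is a single hidden layer of 32 rectified units trained with
adam (learning rate 0.01, minibatches of 64, L2 penalty 0.01, tolerance
1e-6 with a 50-iteration patience, at most 500 iterations, fixed seed).
These values were chosen for desk-scale determinism and are all
configurable via `TrainConfig`. Two of them matter: small minibatches are
what lets adam actually reach the optimum of this (essentially linear)
problem within the iteration budget, and the L2 penalty keeps predictions
tame on peptides far from the training distribution — without it a
degenerate constant-target training set yields visibly non-constant
predictions on unseen peptides.

One model is trained per (allele, peptide length) pair; there is no
pan-allele extrapolation. Models persist via joblib with a format-version
field; loading a mismatched version fails loudly rather than guessing.
Pearson r is computed in y-space (the nM scale would let a handful of weak
binders dominate); AUC labels true IC50 < 500 nM as positive, ranks lower
predicted IC50 as more positive, and uses midranks for ties, making it
invariant under strictly monotone transforms of the predictions.

## Selection

`rank` assigns within-(sequence, allele) ordinals, best score first, ties
broken by position then peptide (total order, hence deterministic). The
rank cutoff is an absolute integer per sequence per allele. `score` keeps
records at or beyond an absolute cutoff — a record exactly at 500 nM counts
as a binder, the conventional reading. `global` compares each record with
an allele-specific empirical quantile computed on a reference set, with
linear interpolation between order statistics (one pinned rule, again for
determinism); "level t" always means "top fraction t" regardless of the
predictor's score direction. Computing the cutoff per allele keeps
high-scoring alleles from flooding the selection.

Promiscuity groups identical (sequence, position, peptide) rows across
alleles after thresholding, keeps groups seen in at least `min_alleles`
alleles (inclusive), sorts by allele count then best score then position,
and optionally caps rows per sequence after sorting so one long protein
cannot dominate.

Cluster detection slides a window (default 25 residues, suited to ~20-mer
synthesis regions) over binder start positions; any window containing at
least `min_binders` (default 3) distinct starts seeds a region, adjacent
seeds merge, and each merged region is reported from its first binder
start to its last binder end. Because peptide ends can stretch a region
into its neighbour, extents that touch are merged again — emitted clusters
never overlap. Clusters are ranked by density = binders / residues.

## Conservation

Conservation is ungapped window identity: the best fraction of matching
positions over all same-length windows of the subject. Peptides are short
(15-mers) and the downstream filter is a simple identity fraction, so
gapped alignment would add parameters without changing decisions; a
subject shorter than the peptide scores 0 with a warning. The ">x%"
filter is strictly greater — at 0.67 on 15-mers, 11/15 passes and 10/15
does not. Shared-core matching declares two peptides equivalent when they
share an exact substring of at least 9 residues (the class-II register
length); similarity-weighted cores are deliberately out of scope.

## Pipeline

The pipeline is config-driven (INI sections `[prediction]`, `[selection]`,
`[output]`; unknown keys rejected; omitted keys take documented defaults;
the effective configuration is echoed into the output directory).
Parallelism is per protein, matching the per-protein CSV saving; each
protein's file is written as soon as it completes, an existing file is
skipped unless `overwrite` is set (the resume contract), and the
promiscuity and cluster tables are computed from the saved files
afterwards — so outputs are byte-identical across thread counts and across
any interrupt/resume interleaving. Floats are serialized at full round-trip
precision and parsed with pandas' round-trip parser for the same reason.

## Synthetic data

The generators in `epitopescan.synthetic` make every stage testable
without downloads; all are pure functions of their arguments including the
seed.

- `random_proteins`: uniform-residue sequences (no compositional bias,
  hence no claim about real proteome statistics).
- `synthetic_pssm`: N(0, 0.3²) background cells plus a +5.0 bonus for one
  designated residue at each anchor position (default anchors {2, 9}),
  mimicking anchor-driven binding motifs.
- `synthetic_affinity_set`: random 9-mers scored by the planted matrix,
  min-max scaled into y using the matrix's *analytic* score envelope
  (sum of per-position minima/maxima — closed-form endpoints make the
  y = 0 and y = 1 cases exactly testable), Gaussian noise added in y-space
  (keeping IC50 positive by construction), then mapped to nM. Peptides are
  binder-enriched: each anchor carries its designated residue with
  probability 0.35, as real affinity training sets are strongly enriched
  for binders — a uniform-random 9-mer is almost never a binder, and a
  training set without binders supports neither regression nor the 500 nM
  classification. At zero noise the set is an exact deterministic image of
  the matrix, which is what lets the recovery experiment separate model
  error from data noise.
- `planted_binder_sequence`: binder records densely tiling known regions,
  for plant-and-recover cluster tests.

Parameter-recovery conditions used by the acceptance tests: 2000 training /
500 held-out peptides, noise σ = 0.05 in y, fixed seed. Under these
conditions the held-out Pearson r is ≈ 0.93–0.95 (noise-imposed ceiling
≈ 0.97) and AUC ≈ 0.98; with σ = 0 the fit reaches r ≈ 0.999. Passing these
tests shows the estimator recovers a planted additive ground truth through
the full encode→fit→persist→predict path; it does not certify accuracy on
real measured affinities, where targets are not additive in residues and
noise is not Gaussian.

## Known limitations

- The bundled pocket library is synthetic: it exercises the virtual-matrix
  machinery and the pipeline end-to-end but carries no measured binding
  specificity. Real use requires a measured matrix library in the
  documented directory format.
- No class-I processing terms (proteasomal cleavage, TAP transport) and no
  eluted-ligand likelihoods; scores are binding-affinity-style only.
- Conservation is ungapped; distant homologs with indels inside a peptide
  are under-scored.
- The MHC-I model is strictly per-allele; alleles without training data
  are not imputed.
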