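# epitopescan

Integrated MHC binding prediction and T-cell epitope selection, from a
single antigen to a whole proteome.

Presentation of short peptides on MHC molecules is the gating step of the
adaptive immune response, and predicting which peptides a given HLA allele
will bind is the core computation of vaccine design, immuno-diagnostics and
immunogenicity screening. `epitopescan` bundles two built-in predictors
behind one interface, the selection machinery that turns raw scores into a
short candidate list, and a config-driven pipeline that scales the whole
thing to proteomes.

## What it computes

**MHC-II pocket-PSSM predictor** (`mhc2_pssm`). A 9-mer core *c* is scored
against an allele's position-specific scoring matrix *M* (9 × 20) by

&nbsp;&nbsp;&nbsp;&nbsp;S(c) = Σᵢ₌₁⁹ M[i, cᵢ]

and a longer peptide takes the maximum over its 9-mer frames. Alleles
without a measured matrix are covered pan-style: the binding groove is
split into pockets (default: anchor pockets at core positions 1, 4, 6, 7,
9), each pocket borrows the matrix columns of the library allele whose
pocket pseudo-sequence is most similar under BLOSUM62 (or a
similarity-weighted blend), and the borrowed columns assemble a *virtual*
matrix. An allele whose pseudo-sequence matches a library entry reproduces
that entry exactly.

**MHC-I affinity regressor** (`mhc1_mlp`). Peptides are one-hot encoded
(BLOSUM62 rows and CSV descriptor tables are also available) and a small
multilayer perceptron is fit per allele to the log-transformed affinity

&nbsp;&nbsp;&nbsp;&nbsp;y = 1 − ln(IC50)/ln(50000), clamped to [0, 1],

so 1 nM ↦ 1 and the 50 μM non-binder ceiling ↦ 0. Models persist with
joblib and reload bit-for-bit. Evaluation uses Pearson *r* in y-space and
ROC AUC at the conventional 500 nM binder threshold.

**Selection.** Three threshold strategies — within-protein `rank`, absolute
`score` (≤ 500 nM counts as a binder), and allele-specific `global`
quantile cutoffs computed on a reference set so whole-proteome scans are
judged against a standard scale. On top of these: *promiscuous binders*
(peptides above the cutoff in ≥ n alleles, ranked by allele count and best
score, with an optional per-protein cap) and *epitope-density clusters*
(regions with many binder starts per unit length, the regions worth
synthesizing as ~20-mers).

**Conservation.** Ungapped window identity of each peptide against homolog
proteomes, a strict ">x% identity" filter, and shared-core matching: two
peptides sharing an exact ≥ 9-residue substring almost certainly present
the same MHC-II register.

Adapters for the external netMHCpan / netMHCIIpan / MHCflurry tools have
reserved registry names but are not bundled.

## Worked example

Train and evaluate an MHC-I model on a synthetic affinity set whose ground
truth is a planted scoring matrix (`examples/02_train_mhc1_model.py`):

```
trained on 2000 9-mers for HLA-A*02:01
held-out Pearson r : 0.954
held-out ROC AUC   : 0.988 (positives = true IC50 < 500 nM)
reloaded model predictions identical: True
```

The Pearson r is computed between predicted and observed affinities in the
transformed y-space on 500 held-out peptides; 0.95 against data with noise
σ = 0.05 means the network essentially recovered the planted matrix. The
AUC says binders (< 500 nM) are almost perfectly separated from
non-binders, and the reloaded-model line demonstrates the persistence
contract.

Match predicted peptides against published cross-reactive SARS-CoV-2
epitopes (`examples/05_conservation_matching.py`):

```
6/9 published cross-reactive epitopes are hit by the predicted peptide pool:

  PSGTWLTYTGAIKLD  ->  GTWLTYTGAIKLDDK
  SFIEDLLFNKVTLAD  ->  FIEDLLFNKVTLADA, DLLFNKVTLADAGFI
  YEQYIKWPWYIWLGF  ->  -
  ...
```

Each `->` line is a shared ≥ 9-residue core between an experimentally
confirmed epitope (Mateus et al. 2020) and a peptide selected purely by
prediction.

The other example scripts cover MHC-II scanning with virtual matrices
(`01`), promiscuous-binder selection (`03`) and cluster detection (`04`).

## Command line

```bash
epitopescan predict -c run.conf    # config-driven pipeline
epitopescan predict --test         # self-test on packaged synthetic proteins
epitopescan train -i train.csv -o models
epitopescan quantiles -i reference.fasta -o qtable.csv
epitopescan clusters -d results -o clusters.csv
epitopescan conserve -q peptides.csv -s homologs.fasta -o conserved.csv
```

The pipeline reads FASTA or GenBank (CDS translations), saves one CSV per
protein as it completes, resumes interrupted runs without overwriting, runs
proteins in parallel (`threads`), and finishes by writing the
promiscuous-binder and cluster tables. Settings omitted from the config
file take documented defaults.

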