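"""Synthetic data generators: random proteomes, planted-anchor matrices,
noisy affinity training sets and planted binder clusters.

Every generator is a pure function of its arguments including the seed, so
tests and experiments are reproducible bit-for-bit. The affinity generator
produces (peptide, IC50) pairs whose ground truth is a known PSSM: the
matrix score is min-max scaled into the y = 1 - ln(ic50)/ln(50000) target
space using the matrix's analytic score envelope, Gaussian noise is added in
y-space (keeping IC50 positive by construction), and the result is mapped
back to nM. At zero noise the set is an exact deterministic image of the
matrix, so model-recovery experiments can separate model error from data
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AMINO_ACIDS, BindingRecord, ProteinRecord
from .mhc1_mlp import MAX_IC50, TrainingExample
from .mhc2_pssm import PSSM

ANCHOR_BONUS_DEFAULT = 5.0
BACKGROUND_SD_DEFAULT = 0.3
#: probability that a training peptide carries the designated residue at an
#: anchor position; real affinity training sets are strongly binder-enriched,
#: and uniform-random peptides would be almost all non-binders
ENRICH_PROB_DEFAULT = 0.35


def random_proteins(
    n: int, length_range: tuple[int, int], seed: int
) -> list[ProteinRecord]:
    """Uniform-residue random proteins with unique ids, deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, L))
        out.append(ProteinRecord(id=f"synth{i + 1:04d}", sequence=seq,
                                 description="synthetic random protein"))
    return out


@dataclass
class SyntheticPSSM:
    """A planted-anchor matrix plus the ground truth needed for assertions."""

    pssm: PSSM
    anchor_residues: dict  # core position (1-based) -> designated residue


def synthetic_pssm(
    seed: int,
    anchor_positions: set[int] = frozenset({2, 9}),
    anchor_bonus: float = ANCHOR_BONUS_DEFAULT,
    background_sd: float = BACKGROUND_SD_DEFAULT,
    allele: str = "HLA-DRB1*01:01",
) -> SyntheticPSSM:
    """Matrix of small Gaussian background noise with one favoured residue
    per anchor position receiving ``+anchor_bonus``."""
    if not set(anchor_positions) <= set(range(1, 10)):
        raise ValueError("anchor positions must be within 1..9")
    rng = np.random.default_rng(seed)
    scores = rng.normal(0.0, background_sd, (9, 20))
    anchors = {}
    for p in sorted(anchor_positions):
        r = int(rng.integers(0, 20))
        scores[p - 1, r] += anchor_bonus
        anchors[p] = AMINO_ACIDS[r]
    return SyntheticPSSM(PSSM(allele, scores), anchors)


def synthetic_affinity_set(
    spssm: SyntheticPSSM,
    n: int,
    noise_sd: float,
    seed: int,
    enrich_prob: float = ENRICH_PROB_DEFAULT,
) -> list[TrainingExample]:
    """Noisy (peptide, IC50) pairs whose ground truth is the planted matrix.

    Peptides are random 9-mers, binder-enriched: each anchor position carries
    its designated residue with probability *enrich_prob* (independently),
    other positions are uniform. True y is the min-max scaled matrix score
    (analytic envelope); observed y = clamp(true + N(0, noise_sd)); IC50 =
    50000**(1 - observed y).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = spssm.pssm.scores
    peps = rng.integers(0, 20, (n, 9))
    for p, res in spssm.anchor_residues.items():
        plant = rng.random(n) < enrich_prob
        peps[plant, p - 1] = AMINO_ACIDS.index(res)
    raw = m[np.arange(9)[None, :], peps].sum(axis=1)
    lo, hi = spssm.pssm.score_range()
    y_true = (raw - lo) / (hi - lo)
    y_obs = np.clip(y_true + rng.normal(0.0, noise_sd, n), 0.0, 1.0)
    # keep ic50 strictly positive/finite at the y=1 endpoint
    ic50 = MAX_IC50 ** (1.0 - y_obs)
    return [
        TrainingExample("".join(AMINO_ACIDS[j] for j in row), float(v))
        for row, v in zip(peps, ic50)
    ]


def planted_binder_sequence(
    length: int,
    regions: list[tuple[int, int]],
    kmer_length: int = 15,
    seed: int = 0,
) -> tuple[ProteinRecord, list[BindingRecord]]:
    """A random protein plus ground-truth binders densely tiling *regions*.

    Binder starts occupy every position of each (start, end) region (1-based
    inclusive, non-overlapping, within the sequence) and appear nowhere else.
    """
    for a, b in regions:
        if not (1 <= a <= b <= length):
            raise ValueError(f"region ({a}, {b}) outside [1, {length}]")
    for (a1, b1), (a2, b2) in zip(sorted(regions), sorted(regions)[1:]):
        if a2 <= b1:
            raise ValueError(f"overlapping regions ({a1},{b1}) and ({a2},{b2})")
    rec = random_proteins(1, (length, length), seed)[0]
    rec.id = f"planted{seed:04d}"
    binders = []
    max_start = length - kmer_length + 1
    for a, b in sorted(regions):
        for pos in range(a, min(b, max_start) + 1):
            binders.append(
                BindingRecord(
                    peptide=rec.sequence[pos - 1 : pos - 1 + kmer_length],
                    pos=pos, sequence_id=rec.id, allele="HLA-DRB1*01:01",
                    score=1.0,
                )
            )
    return rec, binders
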