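"""Pocket-matrix MHC-II binding predictor.

A 9-mer core is scored by summing one matrix cell per position
(``score = sum_i M[i, core_i]``); longer peptides are scanned over all 9-mer
frames and the best frame wins. Alleles without a library matrix are covered
pan-style: the binding groove is decomposed into pockets, each pocket's
specificity is borrowed from the library allele whose pocket pseudo-sequence
is most similar (or blended across the library, similarity-weighted), and the
borrowed columns are assembled into a *virtual* matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    BindingRecord,
    Predictor,
    PredictorInfo,
    normalize_allele,
    register_predictor,
)

logger = logging.getLogger(__name__)

CORE_LENGTH = 9


@dataclass
class PSSM:
    """9 × 20 additive score matrix for one MHC-II allele.

    Rows are core positions 1..9, columns the residues in alphabetical
    order (ACDEFGHIKLMNPQRSTVWY). Higher scores mean stronger binding.
    """

    allele: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (CORE_LENGTH, 20):
            raise ValueError(
                f"PSSM for {self.allele}: expected shape (9, 20), "
                f"got {self.scores.shape}"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError(f"PSSM for {self.allele}: non-finite cells")

    # analytic score envelope (used by the synthetic-affinity generator)
    def score_range(self) -> tuple[float, float]:
        return float(self.scores.min(axis=1).sum()), float(
            self.scores.max(axis=1).sum()
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# allele: {self.allele}\n")
            df = pd.DataFrame(
                self.scores, index=range(1, 10), columns=list(AMINO_ACIDS)
            )
            df.index.name = "pos"
            df.to_csv(fh)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PSSM":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# allele:"):
                raise ValueError(f"{path}: missing '# allele:' header line")
            allele = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, index_col=0, float_precision="round_trip")
        return cls(allele, df[list(AMINO_ACIDS)].to_numpy())


def score_core(pssm: PSSM, core: str) -> float:
    """Additive matrix score of a 9-mer core."""
    if len(core) != CORE_LENGTH:
        raise ValueError(f"core must be 9 residues, got {len(core)}")
    total = 0.0
    scores = pssm.scores
    for i, a in enumerate(core):
        j = AA_INDEX.get(a)
        if j is None:
            raise ValueError(f"non-canonical residue {a!r} in core")
        # left-to-right accumulation: the score is defined as the plain
        # sequential sum of the 9 addressed cells
        total += scores[i, j]
    return float(total)


def score_peptide(pssm: PSSM, peptide: str) -> tuple[float, int]:
    """Best 9-mer frame score in a peptide and its 1-based frame offset.

    Ties go to the leftmost maximizing frame (determinism).
    """
    if len(peptide) < CORE_LENGTH:
        raise ValueError(
            f"peptide must be at least {CORE_LENGTH} residues, got "
            f"{len(peptide)}"
        )
    best, best_start = -np.inf, 1
    for i in range(len(peptide) - CORE_LENGTH + 1):
        s = score_core(pssm, peptide[i : i + CORE_LENGTH])
        if s > best:
            best, best_start = s, i + 1
    return best, best_start


# ---------------------------------------------------------------------------
# Pocket library and virtual matrices

@dataclass(frozen=True)
class PocketDefinition:
    """Decomposition of the binding groove into pockets.

    Each pocket is (label, core positions covered [1-based], indices into the
    pseudo-sequence [0-based]). Every core position 1..9 must be covered.
    """

    pockets: tuple  # of (label, tuple of core positions, tuple of indices)

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.pockets]
        if len(set(labels)) != len(labels):
            raise ValueError("pocket labels must be unique")
        covered = {c for _, cps, _ in self.pockets for c in cps}
        missing = set(range(1, 10)) - covered
        if missing:
            raise ValueError(f"core positions not covered by any pocket: {missing}")

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.pockets]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"pocket": lab,
             "core_positions": ";".join(map(str, cps)),
             "pseudo_indices": ";".join(map(str, idx))}
            for lab, cps, idx in self.pockets
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PocketDefinition":
        df = pd.read_csv(path, dtype=str)
        pockets = tuple(
            (r["pocket"],
             tuple(int(x) for x in r["core_positions"].split(";")),
             tuple(int(x) for x in r["pseudo_indices"].split(";")))
            for _, r in df.iterrows()
        )
        return cls(pockets)


def default_pocket_definition(pseudo_length: int = 15) -> PocketDefinition:
    """Five anchor pockets covering core positions 1, 4, 6, 7 and 9.

    Non-anchor core positions are assigned to their nearest anchor pocket so
    the whole core is covered; the pseudo-sequence is split evenly.
    """
    anchors = [1, 4, 6, 7, 9]
    coverage = {1: (1, 2), 4: (3, 4, 5), 6: (6,), 7: (7, 8), 9: (9,)}
    per = pseudo_length // len(anchors)
    if per * len(anchors) != pseudo_length:
        raise ValueError("pseudo_length must be divisible by 5")
    pockets = tuple(
        (f"p{a}", coverage[a], tuple(range(i * per, (i + 1) * per)))
        for i, a in enumerate(anchors)
    )
    return PocketDefinition(pockets)


def _blosum62_matrix() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    return np.array(
        [[float(mat[a, b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS]
    )


@dataclass
class PocketLibrary:
    """Library alleles' matrices + pseudo-sequences, for virtual synthesis.

    ``entries`` hold (allele, pseudo-sequence, PSSM) for the alleles with
    measured matrices; ``extra_pseudo`` maps further alleles (no matrix) to
    their pseudo-sequences so they can be covered virtually.
    """

    entries: list  # of (allele, pseudo, PSSM)
    pocket_def: PocketDefinition
    similarity_matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    extra_pseudo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("pocket library needs at least one entry")
        lengths = {len(p) for _, p, _ in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"pseudo-sequences of mixed lengths: {sorted(lengths)}")
        alleles = [a for a, _, _ in self.entries]
        if len(set(alleles)) != len(alleles):
            raise ValueError("duplicate library alleles")

    @property
    def pseudo_length(self) -> int:
        return len(self.entries[0][1])

    @property
    def alleles(self) -> list[str]:
        return [a for a, _, _ in self.entries]

    def pseudo_for(self, allele: str) -> str | None:
        for a, p, _ in self.entries:
            if a == allele:
                return p
        return self.extra_pseudo.get(allele)

    # -- plain-text persistence (directory of CSVs) --
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.pocket_def.to_csv(d / "pockets.csv")
        rows = [{"allele": a, "pseudo_sequence": p} for a, p, _ in self.entries]
        rows += [{"allele": a, "pseudo_sequence": p}
                 for a, p in self.extra_pseudo.items()]
        pd.DataFrame(rows).to_csv(d / "pseudo_sequences.csv", index=False)
        for a, _, pssm in self.entries:
            pssm.to_csv(d / (allele_filename(a) + ".csv"))

    @classmethod
    def load(cls, directory: str | Path) -> "PocketLibrary":
        d = Path(directory)
        pocket_def = PocketDefinition.from_csv(d / "pockets.csv")
        pseudo = pd.read_csv(d / "pseudo_sequences.csv")
        pseudo_map = dict(zip(pseudo["allele"], pseudo["pseudo_sequence"]))
        entries, extra = [], {}
        matrix_files = {f: PSSM.from_csv(f) for f in sorted(d.glob("*.csv"))
                        if f.name not in ("pockets.csv", "pseudo_sequences.csv")}
        by_allele = {m.allele: m for m in matrix_files.values()}
        for allele, ps in pseudo_map.items():
            if allele in by_allele:
                entries.append((allele, ps, by_allele[allele]))
            else:
                extra[allele] = ps
        return cls(entries, pocket_def, extra_pseudo=extra)


def allele_filename(allele: str) -> str:
    """Filesystem-safe allele name ('*' and ':' replaced by '_')."""
    return allele.replace("*", "_").replace(":", "_")


def pocket_similarity(
    pseudo_a: str, pseudo_b: str, library: PocketLibrary
) -> np.ndarray:
    """Per-pocket similarity of two pseudo-sequences, each in [0, 1].

    For each pocket, the substitution-matrix score over the pocket's
    pseudo-sequence positions is normalized by the geometric mean of the two
    self-scores (so sim(a, a) = 1 and the measure is symmetric), then clipped
    to [0, 1].
    """
    L = library.pseudo_length
    if len(pseudo_a) != L or len(pseudo_b) != L:
        raise ValueError(
            f"pseudo-sequence length mismatch: library {L}, "
            f"got {len(pseudo_a)} and {len(pseudo_b)}"
        )
    S = library.similarity_matrix
    ia = np.array([AA_INDEX[c] for c in pseudo_a])
    ib = np.array([AA_INDEX[c] for c in pseudo_b])
    sims = []
    for _, _, idx in library.pocket_def.pockets:
        idx = np.asarray(idx)
        sab = S[ia[idx], ib[idx]].sum()
        saa = S[ia[idx], ia[idx]].sum()
        sbb = S[ib[idx], ib[idx]].sum()
        sims.append(np.clip(sab / np.sqrt(saa * sbb), 0.0, 1.0))
    return np.array(sims)


def build_virtual_pssm(
    target_allele: str,
    target_pseudo: str,
    library: PocketLibrary,
    mode: str = "nearest",
) -> PSSM:
    """Synthesize a matrix for an uncovered allele from pocket similarity.

    ``mode="nearest"`` copies each pocket's columns from the single most
    similar library entry (ties to the first entry); ``mode="blend"``
    averages entries with per-pocket similarity weights normalized to sum
    to 1. An exact pseudo-sequence match reproduces that entry's matrix
    cell-for-cell.
    """
    if mode not in ("nearest", "blend"):
        raise ValueError(f"mode must be 'nearest' or 'blend', got {mode!r}")
    for allele, pseudo, pssm in library.entries:
        if pseudo == target_pseudo:
            return PSSM(target_allele, pssm.scores.copy())
    sims = np.array(
        [pocket_similarity(target_pseudo, p, library) for _, p, _ in library.entries]
    )  # shape (n_entries, n_pockets)
    scores = np.zeros((CORE_LENGTH, 20))
    for j, (_, core_positions, _) in enumerate(library.pocket_def.pockets):
        rows = np.asarray(core_positions) - 1
        if mode == "nearest":
            e = int(np.argmax(sims[:, j]))
            scores[rows] = library.entries[e][2].scores[rows]
        else:
            w = sims[:, j]
            total = w.sum()
            w = np.full(len(w), 1.0 / len(w)) if total == 0 else w / total
            for e, we in enumerate(w):
                scores[rows] += we * library.entries[e][2].scores[rows]
    return PSSM(target_allele, scores)


# ---------------------------------------------------------------------------
# Predictor

class Mhc2PssmPredictor(Predictor):
    """MHC-II predictor over a pocket library; default peptide length 15."""

    name = "mhc2_pssm"

    def __init__(
        self,
        library: PocketLibrary,
        mode: str = "nearest",
        peptide_length: int = 15,
    ):
        self.library = library
        self.mode = mode
        self._peptide_length = peptide_length
        self._cache: dict[str, PSSM] = {}

    @property
    def peptide_length(self) -> int:
        return self._peptide_length

    def info(self) -> PredictorInfo:
        alleles = tuple(
            sorted(set(self.library.alleles) | set(self.library.extra_pseudo))
        )
        return PredictorInfo(
            name=self.name,
            score_kind="arbitrary",
            better="higher",
            supported_lengths=frozenset(range(9, 31)),
            supported_alleles=alleles,
        )

    def matrix_for(self, allele: str, pseudo: str | None = None) -> PSSM:
        allele = normalize_allele(allele)
        if allele in self._cache:
            return self._cache[allele]
        for a, _, pssm in self.library.entries:
            if a == allele:
                self._cache[allele] = pssm
                return pssm
        pseudo = pseudo or self.library.pseudo_for(allele)
        if pseudo is None:
            raise ValueError(
                f"no matrix or pseudo-sequence known for allele {allele!r}"
            )
        pssm = build_virtual_pssm(allele, pseudo, self.library, self.mode)
        self._cache[allele] = pssm
        return pssm

    def predict_peptides(self, peptides, allele) -> list[BindingRecord]:
        allele = normalize_allele(allele)
        pssm = self.matrix_for(allele)
        out = []
        for pep in peptides:
            score, _ = score_peptide(pssm, pep)
            out.append(
                BindingRecord(peptide=pep, pos=1, sequence_id="", allele=allele,
                              score=score)
            )
        return out


register_predictor("mhc2_pssm", Mhc2PssmPredictor)
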