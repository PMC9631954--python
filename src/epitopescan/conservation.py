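"""Peptide conservation against homologous proteomes, and shared-core
matching between peptide sets.

Conservation here is ungapped window identity: a peptide's identity against a
subject protein is the best fraction of matching positions over all
same-length windows of the subject. Peptides are short enough (typically
15-mers) that gapped alignment adds little and would blur the simple
">x% identity" filter.

Two peptides "share a core" when they have an exact common substring of at
least 9 residues — the length of the MHC-II binding register — which is the
practical signature that two overlapping 15-mers present the same epitope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ProteinRecord


@dataclass
class ConservationRow:
    peptide: str
    best_identity: float
    best_subject: str
    per_subject: dict  # subject id -> identity fraction


def peptide_identity(peptide: str, subject_sequence: str) -> float:
    """Best ungapped identity of *peptide* over all windows of *subject*.

    Returns matches/len(peptide) for the best-matching same-length window;
    0.0 when the subject is shorter than the peptide.
    """
    if not peptide:
        raise ValueError("empty peptide")
    k, L = len(peptide), len(subject_sequence)
    if L < k:
        return 0.0
    pep = np.frombuffer(peptide.encode(), dtype=np.uint8)
    sub = np.frombuffer(subject_sequence.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(sub, k)
    matches = (windows == pep).sum(axis=1)
    return float(matches.max()) / k


def best_identity(
    peptide: str, subjects: list[ProteinRecord]
) -> ConservationRow:
    """Per-subject max identity; best over subjects (ties to first subject)."""
    if not subjects:
        raise ValueError("need at least one subject")
    per = {s.id: peptide_identity(peptide, s.sequence) for s in subjects}
    if all(len(s.sequence) < len(peptide) for s in subjects):
        warnings.warn(
            f"all subjects shorter than peptide {peptide!r}; identity 0",
            stacklevel=2,
        )
    best_subject = max(subjects, key=lambda s: per[s.id]).id
    return ConservationRow(
        peptide=peptide, best_identity=per[best_subject],
        best_subject=best_subject, per_subject=per,
    )


def conservation_table(
    peptides: list[str], subjects: list[ProteinRecord]
) -> list[ConservationRow]:
    return [best_identity(p, subjects) for p in peptides]


def filter_conserved(
    rows: list[ConservationRow], min_identity: float
) -> list[ConservationRow]:
    """Keep rows strictly above *min_identity*, sorted best first.

    Strict inequality matches the usual ">x% identity" phrasing: for 15-mers
    a 0.67 cutoff keeps 11/15 and drops 10/15.
    """
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    kept = [r for r in rows if r.best_identity > min_identity]
    kept.sort(key=lambda r: -r.best_identity)
    return kept


def shares_core(a: str, b: str, min_core: int = 9) -> bool:
    """True iff *a* and *b* have an exact common substring >= *min_core*."""
    if min_core < 1:
        raise ValueError("min_core must be >= 1")
    if len(a) < min_core or len(b) < min_core:
        return False
    # any shared substring of length >= min_core contains one of exactly
    # min_core, so checking fixed-length substrings is sufficient
    subs = {a[i : i + min_core] for i in range(len(a) - min_core + 1)}
    return any(b[i : i + min_core] in subs for i in range(len(b) - min_core + 1))


def match_shared_core(
    queries: list[str], pool: list[str], min_core: int = 9
) -> dict:
    """Map each query peptide to the pool peptides sharing a core with it.

    Hit lists preserve pool order and may be empty.
    """
    return {
        q: [p for p in pool if shares_core(q, p, min_core)] for q in queries
    }
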