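"""Binder selection: thresholds, promiscuity across alleles, and clustering.

Three threshold strategies reduce raw predictions to binders:

``rank``
    keep the top *n* peptides per sequence per allele (within-protein ranking);
``score``
    keep peptides beating a single score cutoff (e.g. IC50 <= 500 nM) —
    records exactly at the cutoff count as binders;
``global``
    keep peptides beating an allele-specific quantile cutoff precomputed on a
    reference sequence set, so selection is against a standard scale rather
    than within-protein rank. Computing the cutoff per allele stops
    high-scoring alleles from dominating the result.

Promiscuous binders are peptides above the cutoff in at least ``min_alleles``
alleles — more likely to be immunogenic across a target population.
Binder-density clusters ("epitope density") locate sequence regions packed
with binder starts, ranked by binders per unit length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BindingRecord


@dataclass(frozen=True)
class ThresholdSpec:
    """How to turn scores into a binder set.

    ``value`` means: max rank for ``rank``; a score cutoff in predictor units
    for ``score``; a top-fraction t in (0, 1) for ``global``. ``better``
    states the predictor's score direction.
    """

    method: str  # "rank" | "score" | "global"
    value: float
    better: str = "higher"  # or "lower"

    def __post_init__(self) -> None:
        if self.method not in ("rank", "score", "global"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.better not in ("lower", "higher"):
            raise ValueError(f"better must be 'lower' or 'higher'")
        if self.method == "rank" and self.value < 1:
            raise ValueError("rank cutoff must be >= 1")
        if self.method == "global" and not (0 < self.value < 1):
            raise ValueError("global level must be in (0, 1)")


@dataclass
class QuantileTable:
    """Per-allele score cutoffs at top-fraction levels, from a reference set."""

    table: dict  # allele -> {level: score}
    better: str = "higher"
    source: str = ""
    reference: str = ""

    def cutoff(self, allele: str, level: float) -> float:
        if allele not in self.table:
            raise KeyError(
                f"allele {allele!r} not in quantile table "
                f"(has: {sorted(self.table)})"
            )
        levels = self.table[allele]
        if level in levels:
            return levels[level]
        # interpolate between tabulated levels if needed
        ks = sorted(levels)
        if level < ks[0] or level > ks[-1]:
            raise KeyError(
                f"level {level} outside tabulated range [{ks[0]}, {ks[-1]}] "
                f"for {allele!r}"
            )
        return float(np.interp(level, ks, [levels[k] for k in ks]))

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"allele": a, "level": lv, "score": s}
            for a, levels in sorted(self.table.items())
            for lv, s in sorted(levels.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, better: str = "higher") -> "QuantileTable":
        df = pd.read_csv(path)
        table: dict = {}
        for _, r in df.iterrows():
            table.setdefault(str(r["allele"]), {})[float(r["level"])] = float(
                r["score"]
            )
        return cls(table, better=better)


@dataclass
class PromiscuityRow:
    peptide: str
    sequence_id: str
    pos: int
    allele_count: int
    best_score: float
    alleles: list


@dataclass
class Cluster:
    sequence_id: str
    start: int  # 1-based inclusive
    end: int
    n_binders: int

    @property
    def density(self) -> float:
        return self.n_binders / (self.end - self.start + 1)


def _score_key(better: str):
    return (lambda s: -s) if better == "higher" else (lambda s: s)


def rank_records(records: list[BindingRecord], better: str = "higher"
                 ) -> list[BindingRecord]:
    """Fill ``rank`` within each (sequence_id, allele) group; 1 = best.

    Tied scores get consecutive ordinals, resolved by position then peptide
    (deterministic).
    """
    key = _score_key(better)
    groups: dict[tuple, list[BindingRecord]] = {}
    for r in records:
        groups.setdefault((r.sequence_id, r.allele), []).append(r)
    for grp in groups.values():
        grp.sort(key=lambda r: (key(r.score), r.pos, r.peptide))
        for i, r in enumerate(grp, 1):
            r.rank = i
    return records


def select_binders(
    records: list[BindingRecord],
    spec: ThresholdSpec,
    qtable: QuantileTable | None = None,
) -> list[BindingRecord]:
    """Subset of *records* passing the threshold; input order preserved."""
    if spec.method == "rank":
        ranked = rank_records(list(records), spec.better)
        return [r for r in ranked if r.rank is not None and r.rank <= spec.value]
    if spec.method == "score":
        if spec.better == "lower":
            return [r for r in records if r.score <= spec.value]
        return [r for r in records if r.score >= spec.value]
    # global
    if qtable is None:
        raise ValueError("global threshold requires a quantile table")
    cutoffs = {}
    for r in records:
        if r.allele not in cutoffs:
            cutoffs[r.allele] = qtable.cutoff(r.allele, spec.value)
    if spec.better == "lower":
        return [r for r in records if r.score <= cutoffs[r.allele]]
    return [r for r in records if r.score >= cutoffs[r.allele]]


def compute_quantile_table(
    reference_records: list[BindingRecord],
    levels: list[float],
    better: str = "higher",
    source: str = "",
    reference: str = "",
) -> QuantileTable:
    """Empirical per-allele cutoffs so that "level t" means "top fraction t".

    For better=higher the cutoff at t is the (1 - t) quantile of the allele's
    reference scores; for better=lower it is the t quantile. Linear
    interpolation between order statistics.
    """
    for t in levels:
        if not (0 < t < 1):
            raise ValueError(f"levels must be in (0, 1), got {t}")
    by_allele: dict[str, list[float]] = {}
    for r in reference_records:
        by_allele.setdefault(r.allele, []).append(r.score)
    table: dict = {}
    for allele, scores in by_allele.items():
        if not scores:
            warnings.warn(f"no reference scores for {allele}; omitted",
                          stacklevel=2)
            continue
        if len(scores) < 20:
            warnings.warn(
                f"only {len(scores)} reference scores for {allele}; "
                "quantiles will be coarse", stacklevel=2,
            )
        arr = np.asarray(scores)
        table[allele] = {
            t: float(np.quantile(arr, (1 - t) if better == "higher" else t))
            for t in levels
        }
    return QuantileTable(table, better=better, source=source, reference=reference)


def promiscuous_binders(
    records: list[BindingRecord],
    spec: ThresholdSpec,
    qtable: QuantileTable | None = None,
    min_alleles: int = 1,
    cap_per_sequence: int | None = None,
) -> list[PromiscuityRow]:
    """Peptides above the cutoff in at least *min_alleles* alleles.

    Rows are sorted by allele count (descending), then best score (best
    first), then position; ``cap_per_sequence`` truncates each sequence's
    rows after sorting, preventing long proteins from dominating.
    """
    if min_alleles < 1:
        raise ValueError("min_alleles must be >= 1")
    selected = select_binders(records, spec, qtable)
    groups: dict[tuple, list[BindingRecord]] = {}
    for r in selected:
        groups.setdefault((r.sequence_id, r.pos, r.peptide), []).append(r)
    key = _score_key(spec.better)
    rows = []
    for (seq_id, pos, pep), grp in groups.items():
        alleles = [r.allele for r in grp]
        if len(alleles) < min_alleles:
            continue
        best = min((r.score for r in grp), key=key)
        rows.append(
            PromiscuityRow(peptide=pep, sequence_id=seq_id, pos=pos,
                           allele_count=len(alleles), best_score=best,
                           alleles=sorted(alleles))
        )
    rows.sort(key=lambda r: (-r.allele_count, key(r.best_score), r.pos,
                             r.peptide))
    if cap_per_sequence is not None:
        kept, counts = [], {}
        for r in rows:
            c = counts.get(r.sequence_id, 0)
            if c < cap_per_sequence:
                kept.append(r)
                counts[r.sequence_id] = c + 1
        rows = kept
    return rows


def detect_clusters(
    binders: list[BindingRecord],
    window: int = 25,
    min_binders: int = 3,
) -> list[Cluster]:
    """Find regions of high binder density in one sequence.

    A window of ``window`` residues slides over binder start positions;
    windows holding at least ``min_binders`` distinct binder starts seed
    regions, overlapping or adjacent seeds merge, and each merged region is
    reported spanning its first binder start to its last binder end. Output
    is sorted by density (binders per residue) descending.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not binders:
        return []
    seq_ids = {r.sequence_id for r in binders}
    if len(seq_ids) > 1:
        raise ValueError(
            f"detect_clusters expects one sequence, got {sorted(seq_ids)}"
        )
    seq_id = seq_ids.pop()
    distinct = {(r.pos, r.peptide) for r in binders}
    starts = sorted({p for p, _ in distinct})
    # seed windows: anchor at each binder start, count starts within reach
    seeds = []
    for w in starts:
        lo, hi = w, w + window - 1
        n = sum(1 for s in starts if lo <= s <= hi)
        if n >= min_binders:
            seeds.append((lo, hi))
    if not seeds:
        return []
    # merge overlapping/adjacent seed windows
    merged = [list(seeds[0])]
    for lo, hi in seeds[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    extents = []  # (start, end, member set)
    for lo, hi in merged:
        members = {(p, pep) for p, pep in distinct if lo <= p <= hi}
        if not members:
            continue
        first = min(p for p, _ in members)
        last = max(p + len(pep) - 1 for p, pep in members)
        extents.append([first, last, members])
    # peptide ends can stretch an extent into the next region: keep merging
    extents.sort(key=lambda e: e[0])
    joined = [extents[0]]
    for start, end, members in extents[1:]:
        if start <= joined[-1][1]:
            joined[-1][1] = max(joined[-1][1], end)
            joined[-1][2] |= members
        else:
            joined.append([start, end, members])
    clusters = [
        Cluster(sequence_id=seq_id, start=s, end=e, n_binders=len(m))
        for s, e, m in joined
    ]
    clusters.sort(key=lambda c: (-c.density, c.start))
    return clusters


def promiscuity_to_frame(rows: list[PromiscuityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"peptide": r.peptide, "sequence_id": r.sequence_id, "pos": r.pos,
          "allele_count": r.allele_count, "best_score": r.best_score,
          "alleles": ";".join(r.alleles)} for r in rows],
        columns=["peptide", "sequence_id", "pos", "allele_count",
                 "best_score", "alleles"],
    )


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sequence_id": c.sequence_id, "start": c.start, "end": c.end,
          "n_binders": c.n_binders, "density": c.density} for c in clusters],
        columns=["sequence_id", "start", "end", "n_binders", "density"],
    )
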