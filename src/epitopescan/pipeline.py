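"""The config-driven prediction pipeline.

Scales from one antigen to a proteome: every input protein is k-merized,
scored across all requested alleles, ranked within the protein and saved to
its own CSV as soon as it completes (so an interrupted run resumes without
recomputing or overwriting finished proteins). Proteins are independent, so
parallelism is per protein and the outputs are identical for any thread
count. After prediction, the promiscuous-binder table and per-sequence
binder-density clusters are computed from the saved files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from joblib import Parallel, delayed

from .core import BindingRecord, Predictor, ProteinRecord, get_predictor
from .datasets import builtin_library, resolve_alleles
from .fileio import (
    RunConfig,
    protein_csv_path,
    read_protein_csv,
    read_proteins,
    write_effective_config,
    write_protein_csv,
)
from .mhc2_pssm import PocketLibrary
from .selection import (
    QuantileTable,
    ThresholdSpec,
    clusters_to_frame,
    detect_clusters,
    promiscuity_to_frame,
    promiscuous_binders,
    rank_records,
    select_binders,
)

logger = logging.getLogger(__name__)


@dataclass
class RunSummary:
    output_dir: str
    proteins_done: int = 0
    proteins_skipped: int = 0
    proteins_failed: int = 0
    n_promiscuous: int = 0
    n_clusters: int = 0
    failures: list = field(default_factory=list)


def predictor_from_config(config: RunConfig) -> Predictor:
    if config.predictor == "mhc2_pssm":
        library = (PocketLibrary.load(config.library_dir)
                   if config.library_dir else builtin_library())
        return get_predictor("mhc2_pssm", {
            "library": library, "peptide_length": config.kmer_length,
        })
    if config.predictor == "mhc1_mlp":
        return get_predictor("mhc1_mlp", {
            "model_dir": config.model_dir,
            "peptide_length": config.kmer_length,
        })
    return get_predictor(config.predictor, {})


def _predict_one(
    predictor: Predictor, record: ProteinRecord, alleles, k: int
) -> list[BindingRecord]:
    records = predictor.predict_sequences([record], alleles, k=k)
    return rank_records(records, predictor.info().better)


def run_pipeline(
    config: RunConfig, proteins: list[ProteinRecord] | None = None
) -> RunSummary:
    """Run prediction + selection per *config*; returns a summary.

    *proteins* overrides ``config.input_paths`` (used by the built-in test
    run and by callers who already hold parsed records).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_effective_config(config, outdir / "effective_config.conf")

    if proteins is None:
        proteins = []
        for path in config.input_paths:
            proteins.extend(read_proteins(path))
    if not proteins:
        raise ValueError("no input proteins (set input= or pass records)")

    predictor = predictor_from_config(config)
    alleles = resolve_alleles(config.alleles)
    summary = RunSummary(output_dir=str(outdir))

    todo = []
    for rec in proteins:
        if protein_csv_path(outdir, rec.id).exists() and not config.overwrite:
            summary.proteins_skipped += 1
        else:
            todo.append(rec)

    def _worker(rec: ProteinRecord):
        try:
            return rec.id, _predict_one(predictor, rec, alleles,
                                        config.kmer_length), None
        except Exception as e:  # logged per protein; the run continues
            return rec.id, None, str(e)

    results = Parallel(n_jobs=config.threads, backend="loky")(
        delayed(_worker)(rec) for rec in todo
    ) if config.threads > 1 else [_worker(rec) for rec in todo]

    for seq_id, records, err in results:
        if err is not None:
            logger.error("prediction failed for %s: %s", seq_id, err)
            summary.proteins_failed += 1
            summary.failures.append((seq_id, err))
            continue
        write_protein_csv(records, outdir, sequence_id=seq_id, overwrite=True)
        summary.proteins_done += 1

    if summary.proteins_failed and not (
        summary.proteins_done or summary.proteins_skipped
    ):
        raise RuntimeError(
            "all proteins failed; first error: " + summary.failures[0][1]
        )

    # selection over everything present in the output directory
    info = predictor.info()
    spec = ThresholdSpec(config.threshold_method, config.threshold_value,
                         better=info.better)
    qtable = None
    if config.threshold_method == "global":
        if not config.quantile_table:
            raise ValueError("global threshold requires quantile_table=")
        qtable = QuantileTable.from_csv(config.quantile_table,
                                        better=info.better)

    all_records: list[BindingRecord] = []
    for rec in proteins:
        if protein_csv_path(outdir, rec.id).exists():
            all_records.extend(read_protein_csv(outdir, rec.id))

    rows = promiscuous_binders(
        all_records, spec, qtable, min_alleles=config.min_alleles,
        cap_per_sequence=config.cap_per_sequence,
    )
    promiscuity_to_frame(rows).to_csv(outdir / "promiscuous.csv", index=False)
    summary.n_promiscuous = len(rows)

    selected = select_binders(all_records, spec, qtable)
    by_seq: dict[str, list[BindingRecord]] = {}
    for r in selected:
        by_seq.setdefault(r.sequence_id, []).append(r)
    clusters = []
    for seq_id in sorted(by_seq):
        clusters.extend(
            detect_clusters(by_seq[seq_id], window=config.cluster_window,
                            min_binders=config.cluster_min_binders)
        )
    clusters_to_frame(clusters).to_csv(outdir / "clusters.csv", index=False)
    summary.n_clusters = len(clusters)
    return summary


def run_builtin_test(output_dir: str = "synthetic_test") -> RunSummary:
    """Exercise the whole pipeline on packaged synthetic sample proteins."""
    from .datasets import sample_proteins

    config = RunConfig(output_dir=output_dir, overwrite=True,
                       threshold_method="rank", threshold_value=5,
                       min_alleles=2)
    return run_pipeline(config, proteins=sample_proteins())


# ---------------------------------------------------------------------------
# Track export for external plotting

@dataclass
class TrackSet:
    """Per-sequence visualization coordinates: one track per allele (or per
    method), each a list of (start, end, score) binder blocks."""

    sequence_id: str
    length: int
    tracks: list  # of (label, [(start, end, score), ...])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sequence_id": self.sequence_id, "length": self.length,
            "tracks": [
                {"label": lab, "blocks": [list(b) for b in blocks]}
                for lab, blocks in self.tracks
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_tracks(
    records: list[BindingRecord],
    selection: list[BindingRecord],
    sequence_id: str,
    length: int | None = None,
    by: str = "allele",
) -> TrackSet:
    """Arrange selected binders of one sequence into plot-ready tracks."""
    records = [r for r in records if r.sequence_id == sequence_id]
    chosen = {(r.pos, r.peptide, r.allele) for r in selection
              if r.sequence_id == sequence_id}
    if length is None:
        length = max((r.pos + len(r.peptide) - 1 for r in records), default=0)
    labels = sorted({getattr(r, by) for r in records})
    tracks = []
    for lab in labels:
        blocks = sorted(
            (r.pos, r.pos + len(r.peptide) - 1, r.score)
            for r in records
            if getattr(r, by) == lab and (r.pos, r.peptide, r.allele) in chosen
        )
        for s, e, _ in blocks:
            assert 1 <= s <= e <= length
        tracks.append((lab, blocks))
    return TrackSet(sequence_id=sequence_id, length=length, tracks=tracks)


def track_overlap(a: TrackSet, b: TrackSet) -> int:
    """Residue positions covered by blocks in both track sets (>= 0)."""
    def covered(ts: TrackSet) -> set[int]:
        out: set[int] = set()
        for _, blocks in ts.tracks:
            for s, e, _ in blocks:
                out.update(range(s, e + 1))
        return out

    return len(covered(a) & covered(b))
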