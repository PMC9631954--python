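"""File formats: FASTA / GenBank input, per-protein CSV results, quantile
tables and INI run configuration."""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .core import BindingRecord, ProteinRecord

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["peptide", "pos", "sequence_id", "allele", "score", "rank"]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA; id = first header token, sequence uppercased."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.strip() and not line.startswith(">"):
                break
            if line.startswith(">") and len(line.strip()) == 1:
                raise ValueError(f"{path}:{i}: empty FASTA header")
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(),
                          description=rec.description)
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            desc = r.description if r.description.startswith(r.id) else (
                f"{r.id} {r.description}".strip()
            )
            fh.write(f">{desc}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def read_genbank_cds(path: str | Path) -> list[ProteinRecord]:
    """One protein per CDS feature carrying a translation.

    id preference: locus_tag, then protein_id; CDS without a translation are
    skipped with a logged count.
    """
    records, skipped = [], 0
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            translation = quals.get("translation", [None])[0]
            if not translation:
                skipped += 1
                continue
            tag = quals.get("locus_tag", quals.get("protein_id", ["?"]))[0]
            desc = quals.get("product", [""])[0]
            records.append(
                ProteinRecord(id=tag, sequence=translation, description=desc)
            )
    if skipped:
        logger.info("skipped %d CDS features without a translation", skipped)
    if not records:
        raise ValueError(f"{path}: no translated CDS features found")
    return records


def read_proteins(path: str | Path) -> list[ProteinRecord]:
    """Dispatch on extension: GenBank (.gb/.gbk/.gbff) or FASTA otherwise."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return read_genbank_cds(path)
    return read_fasta(path)


# ---------------------------------------------------------------------------
# Per-protein result CSVs

def records_to_frame(records: list[BindingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"peptide": r.peptide, "pos": r.pos, "sequence_id": r.sequence_id,
          "allele": r.allele, "score": r.score,
          "rank": "" if r.rank is None else r.rank} for r in records],
        columns=CSV_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[BindingRecord]:
    out = []
    for row in df.itertuples(index=False):
        rank = getattr(row, "rank")
        rank = None if (pd.isna(rank) or rank == "") else int(rank)
        out.append(
            BindingRecord(peptide=str(row.peptide), pos=int(row.pos),
                          sequence_id=str(row.sequence_id),
                          allele=str(row.allele), score=float(row.score),
                          rank=rank)
        )
    return out


def protein_csv_path(directory: str | Path, sequence_id: str) -> Path:
    return Path(directory) / f"{sequence_id}.csv"


def write_protein_csv(
    records: list[BindingRecord], directory: str | Path,
    sequence_id: str | None = None, overwrite: bool = True,
) -> Path:
    """Write one sequence's records to ``<sequence_id>.csv``.

    Floats are serialized at repr precision so a read-back is value-identical
    (and resumed runs are byte-identical). Refuses to clobber an existing
    file unless *overwrite* — the resume contract.
    """
    ids = {r.sequence_id for r in records}
    if sequence_id is None:
        if len(ids) != 1:
            raise ValueError(f"records span multiple sequences: {sorted(ids)}")
        sequence_id = ids.pop()
    elif ids and ids != {sequence_id}:
        raise ValueError(f"records do not all belong to {sequence_id!r}")
    path = protein_csv_path(directory, sequence_id)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite is not set")
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False, float_format=None)
    return path


def read_protein_csv(directory: str | Path, sequence_id: str
                     ) -> list[BindingRecord]:
    path = protein_csv_path(directory, sequence_id)
    # round_trip parsing keeps scores bit-identical to what was written
    df = pd.read_csv(path, dtype={"peptide": str},
                     float_precision="round_trip")
    return frame_to_records(df)


# ---------------------------------------------------------------------------
# Run configuration (INI)

_DEFAULTS = {
    "prediction": {
        "predictor": "mhc2_pssm",
        "input": "",            # comma-separated FASTA/GenBank paths
        "alleles": "mhc2_dr_small",
        "kmer_length": "15",
        "threads": "1",
        "library_dir": "",      # empty = built-in synthetic library
        "model_dir": "models",
    },
    "selection": {
        "threshold_method": "rank",
        "threshold_value": "5",
        "min_alleles": "3",
        "cap_per_sequence": "",
        "quantile_table": "",
        "cluster_window": "25",
        "cluster_min_binders": "3",
    },
    "output": {
        "output_dir": "results",
        "overwrite": "no",
    },
}


@dataclass
class RunConfig:
    predictor: str = "mhc2_pssm"
    input_paths: list = field(default_factory=list)
    alleles: str | list = "mhc2_dr_small"
    kmer_length: int = 15
    threads: int = 1
    library_dir: str = ""
    model_dir: str = "models"
    threshold_method: str = "rank"
    threshold_value: float = 5.0
    min_alleles: int = 3
    cap_per_sequence: int | None = None
    quantile_table: str = ""
    cluster_window: int = 25
    cluster_min_binders: int = 3
    output_dir: str = "results"
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError(f"threads must be >= 1, got {self.threads}")
        if self.kmer_length < 1:
            raise ValueError("kmer_length must be >= 1")


def read_config(path: str | Path) -> RunConfig:
    """Parse an INI run configuration, applying documented defaults.

    Unknown sections or keys are rejected by name, so typos fail loudly
    rather than silently falling back to a default.
    """
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    merged = {s: dict(v) for s, v in _DEFAULTS.items()}
    for section in parser.sections():
        if section not in _DEFAULTS:
            raise ValueError(f"{path}: unknown config section [{section}]")
        for key, value in parser.items(section):
            if key not in _DEFAULTS[section]:
                raise ValueError(
                    f"{path}: unknown key {key!r} in section [{section}]"
                )
            merged[section][key] = value

    def _int(section, key, minimum=None):
        raw = merged[section][key]
        try:
            v = int(raw)
        except ValueError:
            raise ValueError(f"{path}: key {key!r} must be an integer, "
                             f"got {raw!r}") from None
        if minimum is not None and v < minimum:
            raise ValueError(f"{path}: key {key!r} must be >= {minimum}")
        return v

    cap = merged["selection"]["cap_per_sequence"].strip()
    return RunConfig(
        predictor=merged["prediction"]["predictor"],
        input_paths=[p.strip() for p in
                     merged["prediction"]["input"].split(",") if p.strip()],
        alleles=merged["prediction"]["alleles"],
        kmer_length=_int("prediction", "kmer_length", 1),
        threads=_int("prediction", "threads", 1),
        library_dir=merged["prediction"]["library_dir"],
        model_dir=merged["prediction"]["model_dir"],
        threshold_method=merged["selection"]["threshold_method"],
        threshold_value=float(merged["selection"]["threshold_value"]),
        min_alleles=_int("selection", "min_alleles", 1),
        cap_per_sequence=int(cap) if cap else None,
        quantile_table=merged["selection"]["quantile_table"],
        cluster_window=_int("selection", "cluster_window", 1),
        cluster_min_binders=_int("selection", "cluster_min_binders", 1),
        output_dir=merged["output"]["output_dir"],
        overwrite=parser.getboolean(
            "output", "overwrite",
            fallback=_DEFAULTS["output"]["overwrite"] == "yes",
        ),
    )


def write_effective_config(config: RunConfig, path: str | Path) -> None:
    """Echo the effective settings so a run records what it used."""
    parser = configparser.ConfigParser()
    parser["prediction"] = {
        "predictor": config.predictor,
        "input": ",".join(config.input_paths),
        "alleles": (config.alleles if isinstance(config.alleles, str)
                    else ",".join(config.alleles)),
        "kmer_length": str(config.kmer_length),
        "threads": str(config.threads),
        "library_dir": config.library_dir,
        "model_dir": config.model_dir,
    }
    parser["selection"] = {
        "threshold_method": config.threshold_method,
        "threshold_value": repr(config.threshold_value),
        "min_alleles": str(config.min_alleles),
        "cap_per_sequence": ("" if config.cap_per_sequence is None
                             else str(config.cap_per_sequence)),
        "quantile_table": config.quantile_table,
        "cluster_window": str(config.cluster_window),
        "cluster_min_binders": str(config.cluster_min_binders),
    }
    parser["output"] = {
        "output_dir": config.output_dir,
        "overwrite": "yes" if config.overwrite else "no",
    }
    with open(path, "w") as fh:
        parser.write(fh)
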