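"""Shared domain types, peptide generation and the predictor registry.

Everything downstream speaks :class:`BindingRecord` — one peptide × allele
prediction row — so that matrix-score predictors (arbitrary units, higher is
better) and affinity predictors (IC50 nM, lower is better) can be selected,
ranked and reported through the same machinery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
"""Canonical residue order used by every encoder and matrix in the package."""

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residues accepted in input protein sequences ('X' = unknown; peptides
#: containing it are skipped by predictors rather than scored)
VALID_RESIDUES = set(AMINO_ACIDS) | {"X"}


class EpitopeScanError(Exception):
    """Base class for errors raised by this package."""


class UnknownPredictorError(EpitopeScanError):
    pass


class NotBundledError(EpitopeScanError):
    """An external prediction tool whose adapter is not shipped here."""


@dataclass
class ProteinRecord:
    """A protein sequence with a stable identifier.

    ``id`` is the locus tag / first FASTA header token; ``sequence`` is
    restricted to the 20 canonical residues plus 'X'.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence, 1) if c in bad)
            raise ValueError(
                f"protein {self.id!r}: invalid residue {self.sequence[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BindingRecord:
    """One peptide × allele prediction.

    ``pos`` is the 1-based start of the peptide within its parent sequence.
    ``rank`` is the within-sequence, per-allele ordinal (1 = best) and is
    unset (None) until :func:`epitopescan.selection.rank_records` fills it.
    """

    peptide: str
    pos: int
    sequence_id: str
    allele: str
    score: float
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class PredictorInfo:
    """Static description of a predictor's score semantics."""

    name: str
    score_kind: str  # "affinity_nM" | "arbitrary"
    better: str  # "lower" | "higher"
    supported_lengths: frozenset[int] = frozenset()
    supported_alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.score_kind == "affinity_nM" and self.better != "lower":
            raise ValueError("affinity_nM scores imply better='lower'")


def make_kmers(sequence: str, k: int, step: int = 1) -> list[tuple[int, str]]:
    """Every window of length *k* at stride *step*, with 1-based starts.

    Returns ``floor((L - k)/step) + 1`` windows when ``L >= k``, else none.
    Residues outside the accepted alphabet are rejected; 'X' is allowed here
    (predictors skip peptides containing it).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    seq = sequence.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        pos = next(i for i, c in enumerate(seq, 1) if c in bad)
        raise ValueError(f"invalid residue {seq[pos - 1]!r} at position {pos}")
    return [(i + 1, seq[i : i + k]) for i in range(0, len(seq) - k + 1, step)]


# ---------------------------------------------------------------------------
# Allele name normalization

# genes with a trailing digit must sort before their prefix (DRB1 before B)
_GENES = (
    "DRB1", "DRB3", "DRB4", "DRB5", "DQA1", "DQB1", "DPA1", "DPB1", "DRA",
    "A", "B", "C", "E", "F", "G",
)

_ALLELE_RE = re.compile(
    r"^(?:HLA)?[-_ ]?(" + "|".join(_GENES) + r")[-_* ]?(\d{2})[:_.]?(\d{2,3})$",
    re.IGNORECASE,
)


def normalize_allele(raw: str) -> str:
    """Canonicalize an HLA allele name to ``HLA-A*01:01`` style.

    Accepts underscore, no-separator and lowercase dialects (upstream tools
    disagree on naming). Idempotent on its own output.
    """
    if not raw or not raw.strip():
        raise ValueError("empty allele name")
    m = _ALLELE_RE.match(raw.strip())
    if m is None:
        raise ValueError(f"cannot parse allele name: {raw!r}")
    gene, group, protein = m.group(1).upper(), m.group(2), m.group(3)
    return f"HLA-{gene}*{group}:{protein}"


# ---------------------------------------------------------------------------
# Predictor registry

class Predictor:
    """Abstract prediction method.

    Concrete predictors implement :meth:`info` and :meth:`predict_peptides`;
    :meth:`predict_sequences` is shared plumbing that k-merizes each protein,
    skips windows containing 'X', and tags records with positions.
    """

    def info(self) -> PredictorInfo:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_peptides(
        self, peptides: Sequence[str], allele: str
    ) -> list[BindingRecord]:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def peptide_length(self) -> int:
        raise NotImplementedError

    def predict_sequences(
        self,
        records: Iterable[ProteinRecord],
        alleles: Sequence[str],
        k: int | None = None,
        step: int = 1,
    ) -> list[BindingRecord]:
        """Score every k-mer of every protein against every allele."""
        k = k or self.peptide_length
        out: list[BindingRecord] = []
        for rec in records:
            kmers = [(p, pep) for p, pep in make_kmers(rec.sequence, k, step)
                     if "X" not in pep]
            if not kmers:
                continue
            positions = [p for p, _ in kmers]
            peptides = [pep for _, pep in kmers]
            for allele in alleles:
                scored = self.predict_peptides(peptides, allele)
                for pos, r in zip(positions, scored):
                    r.pos = pos
                    r.sequence_id = rec.id
                out.extend(scored)
        return out


_REGISTRY: dict[str, Callable[..., Predictor]] = {}

#: external tools with a reserved adapter slot but no bundled wrapper
RESERVED_EXTERNAL = ("netmhcpan", "netmhciipan", "mhcflurry")


def register_predictor(name: str, factory: Callable[..., Predictor]) -> None:
    _REGISTRY[name] = factory


def registered_predictors() -> list[str]:
    return sorted(_REGISTRY) + list(RESERVED_EXTERNAL)


def get_predictor(name: str, options: Mapping | None = None) -> Predictor:
    """Look up a predictor by registry name and construct it.

    ``options`` are passed through to the predictor factory (e.g. a PSSM
    library for ``mhc2_pssm``, a model directory for ``mhc1_mlp``).
    """
    options = dict(options or {})
    if name in RESERVED_EXTERNAL:
        raise NotBundledError(
            f"{name!r} is an external tool; no adapter is bundled with this "
            "package. Install and wrap it separately."
        )
    if name not in _REGISTRY:
        raise UnknownPredictorError(
            f"unknown predictor {name!r}; registered: "
            + ", ".join(registered_predictors())
        )
    return _REGISTRY[name](**options)
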