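"""Numeric peptide encodings for the MHC-I affinity regressor.

One-hot is the default scheme (adequate in practice for this model family);
BLOSUM62 rows are available as a substitution-profile encoding, and arbitrary
per-residue descriptor tables (e.g. NLF- or OETMAP-style coefficients) can be
loaded from CSV via :func:`table_scheme`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .core import AMINO_ACIDS


@dataclass(frozen=True)
class EncodingScheme:
    """Maps each canonical residue to a fixed-width numeric vector."""

    name: str
    table: dict  # residue -> tuple of floats
    width: int

    def __post_init__(self) -> None:
        for aa in AMINO_ACIDS:
            if aa not in self.table:
                raise ValueError(f"scheme {self.name!r}: missing residue {aa!r}")
            if len(self.table[aa]) != self.width:
                raise ValueError(
                    f"scheme {self.name!r}: residue {aa!r} has width "
                    f"{len(self.table[aa])}, expected {self.width}"
                )


def onehot_scheme() -> EncodingScheme:
    """20-dimensional indicator encoding, alphabetical residue order."""
    table = {}
    for i, aa in enumerate(AMINO_ACIDS):
        v = [0.0] * 20
        v[i] = 1.0
        table[aa] = tuple(v)
    return EncodingScheme("onehot", table, 20)


def blosum62_scheme() -> EncodingScheme:
    """Each residue encoded as its BLOSUM62 substitution row (20 values)."""
    mat = substitution_matrices.load("BLOSUM62")
    table = {
        a: tuple(float(mat[a, b]) for b in AMINO_ACIDS) for a in AMINO_ACIDS
    }
    return EncodingScheme("blosum62", table, 20)


def table_scheme(path: str | Path, name: str = "table") -> EncodingScheme:
    """Load a per-residue descriptor table from CSV.

    First column: residue letter; remaining columns: numeric descriptors.
    """
    df = pd.read_csv(path)
    residues = df.iloc[:, 0].astype(str).str.upper()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    table = {r: tuple(row) for r, row in zip(residues, values)}
    return EncodingScheme(name, table, values.shape[1])


_BUILTIN = {"onehot": onehot_scheme, "blosum62": blosum62_scheme}


def get_scheme(name: str) -> EncodingScheme:
    if name not in _BUILTIN:
        raise ValueError(
            f"unknown encoding scheme {name!r}; built-in: {sorted(_BUILTIN)}"
        )
    return _BUILTIN[name]()


def encode_peptide(peptide: str, scheme: EncodingScheme) -> np.ndarray:
    """Flat vector of length ``len(peptide) * scheme.width``, residue order
    preserved."""
    out = np.empty(len(peptide) * scheme.width)
    for i, aa in enumerate(peptide):
        if aa not in scheme.table:
            raise ValueError(
                f"residue {aa!r} at position {i + 1} not in scheme "
                f"{scheme.name!r}"
            )
        out[i * scheme.width : (i + 1) * scheme.width] = scheme.table[aa]
    return out


def encode_set(peptides: list[str], scheme: EncodingScheme) -> np.ndarray:
    """Row-wise encoding of equal-length peptides; row i == peptides[i]."""
    lengths = {len(p) for p in peptides}
    if len(lengths) > 1:
        a, b = sorted(lengths)[:2]
        raise ValueError(f"peptides of mixed lengths (found {a} and {b})")
    if not peptides:
        return np.empty((0, scheme.width))
    n_cols = len(peptides[0]) * scheme.width
    out = np.empty((len(peptides), n_cols))
    for i, p in enumerate(peptides):
        out[i] = encode_peptide(p, scheme)
    return out
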