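"""Bundled small datasets: allele presets, a synthetic pocket library for
MHC-II prediction out of the box, synthetic sample proteins for the built-in
test run, and the published SARS-CoV-2 cross-reactive CD4+ epitope set of
Mateus et al. (2020, Science) used by the conservation example.

The pocket library and sample proteins are synthetic (seeded generators, not
measured binding data); they exist so the full pipeline runs and can be
tested without external downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mhc2_pssm import PocketLibrary, default_pocket_definition
from .synthetic import random_proteins, synthetic_pssm

#: small illustrative allele panels; population-scale panels are a user input
ALLELE_PRESETS = {
    "mhc1_small": [
        "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01",
        "HLA-B*07:02", "HLA-B*08:01",
    ],
    "mhc2_dr_small": [
        "HLA-DRB1*01:01", "HLA-DRB1*03:01", "HLA-DRB1*04:01",
        "HLA-DRB1*07:01",
    ],
    "mhc2_dr_extended": [
        "HLA-DRB1*01:01", "HLA-DRB1*03:01", "HLA-DRB1*04:01",
        "HLA-DRB1*07:01", "HLA-DRB1*08:01", "HLA-DRB1*11:01",
        "HLA-DRB1*13:01", "HLA-DRB1*15:01",
    ],
}

_LIBRARY_ALLELES = ALLELE_PRESETS["mhc2_dr_small"]
_VIRTUAL_ALLELES = [
    "HLA-DRB1*08:01", "HLA-DRB1*11:01", "HLA-DRB1*13:01", "HLA-DRB1*15:01",
]
_PSEUDO_LENGTH = 15
_LIBRARY_SEED = 20210224


def builtin_library() -> PocketLibrary:
    """Deterministic synthetic pocket library: 4 DR alleles with matrices,
    4 more covered only by pseudo-sequence (scored via virtual matrices)."""
    from .core import AMINO_ACIDS
    import numpy as np

    rng = np.random.default_rng(_LIBRARY_SEED)
    entries = []
    anchor_sets = [{2, 9}, {1, 9}, {2, 6}, {4, 9}]
    for i, allele in enumerate(_LIBRARY_ALLELES):
        pseudo = "".join(AMINO_ACIDS[j]
                         for j in rng.integers(0, 20, _PSEUDO_LENGTH))
        sp = synthetic_pssm(
            seed=_LIBRARY_SEED + i + 1, anchor_positions=anchor_sets[i],
            allele=allele,
        )
        entries.append((allele, pseudo, sp.pssm))
    extra = {}
    for allele in _VIRTUAL_ALLELES:
        # virtual alleles: a library pseudo-sequence with a few mutations
        base = list(entries[len(extra) % len(entries)][1])
        for pos in rng.integers(0, _PSEUDO_LENGTH, 3):
            base[pos] = AMINO_ACIDS[int(rng.integers(0, 20))]
        extra[allele] = "".join(base)
    return PocketLibrary(
        entries, default_pocket_definition(_PSEUDO_LENGTH), extra_pseudo=extra
    )


def sample_proteins(n: int = 5, seed: int = 1234) -> list:
    """Synthetic sample proteins for the built-in pipeline test run."""
    recs = random_proteins(n, (120, 300), seed)
    for i, r in enumerate(recs, 1):
        r.id = f"sample{i:02d}"
        r.description = "synthetic sample protein"
    return recs


def crossreactive_epitopes() -> pd.DataFrame:
    """SARS-CoV-2 cross-reactive CD4+ epitopes (Mateus et al. 2020) with the
    predicted 15-mers that hit them; 'hits' is ';'-separated, empty = none."""
    with resources.files("epitopescan.data").joinpath(
        "sarscov2_crossreactive.csv"
    ).open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    return df


def crossreactive_query_pool() -> tuple[list[str], list[str]]:
    """The query epitopes and the distinct predicted-peptide pool, in order."""
    df = crossreactive_epitopes()
    queries = df["query"].tolist()
    pool: list[str] = []
    for h in df["hits"]:
        for p in str(h).split(";"):
            if p and p not in pool:
                pool.append(p)
    return queries, pool


def resolve_alleles(spec: str | list) -> list[str]:
    """Resolve an explicit allele list or a preset name."""
    from .core import normalize_allele

    if isinstance(spec, str):
        if spec in ALLELE_PRESETS:
            return list(ALLELE_PRESETS[spec])
        parts = [p.strip() for p in spec.split(",") if p.strip()]
        if not parts:
            raise ValueError("empty allele specification")
        return [normalize_allele(p) for p in parts]
    return [normalize_allele(a) for a in spec]
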