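"""Select promiscuous binders — peptides predicted to bind in several
alleles — from raw predictions.

Scores a small synthetic proteome across four HLA-DR alleles, keeps the
top-ranked peptides per protein per allele, and groups identical peptides
across alleles. A peptide above the cutoff in several alleles is more
likely to be immunogenic across a diverse population.
"""

from epitopescan import ThresholdSpec, get_predictor, promiscuous_binders
from epitopescan.datasets import ALLELE_PRESETS, builtin_library
from epitopescan.synthetic import random_proteins

proteins = random_proteins(4, (120, 200), seed=7)
predictor = get_predictor("mhc2_pssm", {"library": builtin_library()})
records = predictor.predict_sequences(proteins, ALLELE_PRESETS["mhc2_dr_small"])

rows = promiscuous_binders(
    records,
    ThresholdSpec("rank", 30, better="higher"),
    min_alleles=2,
    cap_per_sequence=5,
)

print(f"{len(records)} raw scores -> {len(rows)} promiscuous binders "
      "(top-30 per allele, >= 2 alleles)")
print("\npeptide          protein    pos  alleles  best score")
for r in rows[:8]:
    print(f"{r.peptide}  {r.sequence_id}  {r.pos:4d}  {r.allele_count:7d}"
          f"  {r.best_score:8.2f}")
print("\nRows are sorted by allele count, then best score; "
      "cap_per_sequence stops long proteins dominating the list.")
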