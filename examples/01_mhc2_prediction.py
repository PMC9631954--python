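"""Score an antigen's 15-mers against HLA-DR alleles with the pocket-PSSM
predictor.

Builds a small random antigen, scores every 15-mer window in two alleles
(one with a library matrix, one covered via a virtual matrix synthesized
from pocket similarity), and prints the top-ranked peptides. Higher matrix
scores mean stronger predicted MHC-II binding; rank 1 is the best peptide
in the protein for that allele.
"""

from epitopescan import get_predictor, rank_records
from epitopescan.datasets import builtin_library
from epitopescan.synthetic import random_proteins

antigen = random_proteins(1, (160, 160), seed=42)[0]
predictor = get_predictor("mhc2_pssm", {"library": builtin_library()})

alleles = ["HLA-DRB1*01:01", "HLA-DRB1*15:01"]  # library / virtual
records = predictor.predict_sequences([antigen], alleles)
rank_records(records, better="higher")

print(f"antigen {antigen.id}: {len(antigen)} residues, "
      f"{len(records)} peptide x allele scores")
for allele in alleles:
    best = sorted((r for r in records if r.allele == allele),
                  key=lambda r: r.rank)[:3]
    print(f"\ntop 3 peptides for {allele}:")
    for r in best:
        print(f"  rank {r.rank}: {r.peptide} at {r.pos}  score {r.score:.2f}")
print("\nEach score sums one matrix cell per core position; the best "
      "9-mer frame inside the 15-mer is reported.")
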