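"""Conservation filtering and shared-core matching on the published
SARS-CoV-2 cross-reactive epitope set.

Cross-reactive T-cell epitopes (Mateus et al. 2020) are compared with the
predicted 15-mer pool bundled with the package: two peptides that share an
exact >= 9-residue substring most likely present the same MHC-II binding
core, so a 'hit' means the prediction found the experimentally confirmed
epitope. Conservation is ungapped window identity against a homolog.
"""

from epitopescan import match_shared_core, peptide_identity
from epitopescan.datasets import crossreactive_query_pool

queries, pool = crossreactive_query_pool()
hits = match_shared_core(queries, pool, min_core=9)

n_hit = sum(1 for q in queries if hits[q])
print(f"{n_hit}/{len(queries)} published cross-reactive epitopes are hit "
      "by the predicted peptide pool:\n")
for q in queries:
    shown = ", ".join(hits[q]) if hits[q] else "-"
    print(f"  {q}  ->  {shown}")

core, hit = "GTWLTYTGAIKLD", "GTWLTYTGAIKLDDK"
ident = peptide_identity(core, hit)
print(f"\nExample: the shared 13-mer core {core} sits verbatim inside "
      f"{hit} (window identity {ident:.2f}), so both peptides present the "
      "same MHC-II register.")
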