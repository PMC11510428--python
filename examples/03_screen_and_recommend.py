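"""Score the packaged 40 recommended molecules with QED/SA and re-rank
them by PageRank centrality on the similarity graph.

QED is the geometric mean of eight desirability-transformed descriptors
(0 = undruglike, 1 = ideal).  The SA score rates synthesis difficulty on
1–10 (sa_raw: 1 = easiest; sa_ease = 11 − sa_raw reports the opposite
orientation).  PageRank favours molecules central to the similarity
network — structurally representative candidates.
"""

from azogen import generate_corpus
from azogen.data import table2
from azogen.recommend import adjacency, feature_matrix, pagerank
from azogen.screen import build_fragment_table, score_molecules, shortlist

fixture = table2()
smiles = list(dict.fromkeys(fixture["smiles"]))  # unique, order kept
models = {s: m for s, m in zip(fixture["smiles"], fixture["model"])}

reference = generate_corpus(n=1000, seed=11, motif_fraction=0.05)
table = build_fragment_table(reference)
cards = score_molecules(smiles, table, [models[s] for s in smiles])

top_qed, tally = shortlist(cards, "qed", 10)
print("top 10 by QED (score, model, SMILES):")
for c in top_qed:
    print(f"  {c.qed:.3f}  {c.source_model:9s}  {c.canonical_smiles}")
print("per-model tally:", tally)

fm = feature_matrix(smiles, radius=2, n_bits=256)
ranking = pagerank(adjacency(fm))
print(f"\nPageRank over {ranking.scores.size} molecules "
      f"(converged in {ranking.iterations} iterations); top 5:")
for smi, score in ranking.top_k(5):
    print(f"  {score:.5f}  {smi}")
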