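"""Generate a synthetic SMILES corpus and train the BPE tokenizer.

The corpus emulates two training sets: a broad pretraining set of small
organic molecules and its QM7b-like subset (≤7 heavy atoms over
C/N/O/S/Cl) used for fine-tuning.  A requested fraction of molecules
carries the acyclic N–N photoswitch motif.
"""

from azogen import generate_corpus, qm7b_like_subset, train_bpe
from azogen.chem import has_bonded_nn, parse_smiles

corpus = generate_corpus(n=2000, seed=7, motif_fraction=0.05)
subset = qm7b_like_subset(corpus)
n_motif = sum(has_bonded_nn(parse_smiles(s)) for s in corpus.smiles())

print(f"pretraining corpus : {len(corpus)} unique molecules")
print(f"  with N–N motif   : {n_motif} ({100 * n_motif / len(corpus):.1f}%, target 5%)")
print(f"fine-tune subset   : {len(subset)} molecules (≤7 heavy atoms, C/N/O/S/Cl)")

tok = train_bpe(corpus)  # default: 72-symbol alphabet + 1000 merges
print(f"tokenizer size     : {tok.size} (72 base symbols + {len(tok.merges)} merges)")
example = corpus.smiles()[0]
print(f"example            : {example!r} -> {tok.tokenize(example)}")
# The tokenizer size is the printed vocabulary count; BOS/EOS/PAD are
# tracked separately.  Round-trips are exact: decode(encode(s)) == s.
assert tok.decode(tok.encode(example)) == example
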