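"""Build the distinguishable-domain vocabulary from positive annotations.

An InterPro accession enters the vocabulary when strictly more than five
positive proteins carry it; proteins are then encoded as binary presence
vectors over the vocabulary.  The planted hallmark accessions (RRM-like)
should dominate the support ranking.
"""

from spliceid import SyntheticSpec, build_vocabulary, encode_domains, generate_dataset

pos, neg = generate_dataset(SyntheticSpec(seed=1))
vocab = build_vocabulary(pos, min_support_exclusive=5)

print(f"vocabulary of {len(vocab)} accessions (support > 5 among {len(pos)} positives)")
print("accession   support")
for acc, support in vocab.entries:
    print(f"{acc}  {support:7d}")

vec = encode_domains(pos[0], vocab)
print(f"\n{pos[0].id} encodes as {vec.astype(int).tolist()}")
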