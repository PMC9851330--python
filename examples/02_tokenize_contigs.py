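"""Turn contigs into fixed-length protein-token sentences.

Each contig is read gene by gene; every protein gets the token of the
cluster representative it aligns best to, and the token list is framed as
[CLS] t1 ... tn [SEP] [PAD]... at length 300.
"""

from phalife.synthetic import SyntheticSpec, generate_universe
from phalife.tokenizer import PrecomputedProteins, tokenize_contigs
from phalife.vocabulary import (build_similarity_graph, build_vocabulary,
                                markov_cluster)

universe = generate_universe(SyntheticSpec(seed=7))
vocab = build_vocabulary(
    markov_cluster(build_similarity_graph(universe.alignment_edges())))

contigs = dict(list(universe.genomes.items())[:2])
sentences = tokenize_contigs(contigs, vocab,
                             PrecomputedProteins(universe.protein_calls()),
                             universe.query_hit_edges())
for cid, s in sentences.items():
    head = " ".join(map(str, s.token_ids[:12]))
    print(f"{cid}: {s.n_content} genes -> sentence of length "
          f"{len(s.token_ids)} | first ids: {head} ...")
# Token 2 is [CLS], 3 is [SEP], 0 is [PAD]; ids >= 5 are protein clusters.
# The sentence is always exactly 300 long regardless of gene count.
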