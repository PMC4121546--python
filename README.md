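# litgraph

Turn a corpus of article abstracts into a weighted entity network and
query it: distance-weighted entity co-occurrence, frequency-scaled PMI
aggregation, cosine-similarity statements, fuzzy boolean querying with
ranked article provenance, a path-based related-article index, and a
random-walk evaluation framework grounded in MeSH-style tree-code
similarity.

## Layout

| module | responsibility |
|---|---|
| `litgraph.corpus_io` | Medline XML / plain-text readers, sentence segmentation, corpus statistics |
| `litgraph.mention_extraction` | pluggable entity extraction (gazetteer, chunker, external TSV annotations) |
| `litgraph.cooc_extraction` | per-document distance-weighted co-occurrence statements |
| `litgraph.kb_builder` | corpus-wide knowledge base: fPMI co-occurrence layer + cosine similarity layer |
| `litgraph.kb_index` | term / statement / provenance matrices and the lemmatised full-text lookup |
| `litgraph.query_engine` | fuzzy boolean query parsing and evaluation, ranked statement/source expansion |
| `litgraph.pub_graph` | entity graphs, graph statistics, path-based related-article index |
| `litgraph.eval_sim` | tree-code taxonomy similarity, heuristic random walks, measure battery, index comparison |
| `litgraph.fixtures` | worked-example constants and seeded synthetic corpora / taxonomies / graphs |

## CLI

```bash
# knowledge base + indices from a plain-text directory or Medline XML file
litgraph build corpus_dir/ --dictionary terms.txt --out-dir kb_out/

# fuzzy boolean query against the saved indices
litgraph query "parkinsonism AND (mrpi OR magnetic resonance parkinsonism index)" \
    --indices kb_out/indices.json --top-terms 5 --top-statements 7 --format json

# corpus statistics, related-article index, walk measure report
litgraph stats corpus_dir/ --dictionary terms.txt --out stats.tsv
litgraph related kb_out/kb.tsv --out related.tsv
litgraph walks kb_out/kb.tsv mesh_ascii.txt --seed 1 --out measures.tsv

# seeded synthetic fixtures
litgraph fixtures make --spec spec.json --seed 7 --out-dir fixtures_out/
```

## Notes on key conventions

* Co-occurrence kernel: mention pairs at sentence distance `d <= 3`
  contribute `1/(d+1)`; both the window and the kernel are configurable
  (`CoocParams`).
* fPMI distributions are per-pair / per-term score sums divided by the
  total basic-statement count; weights are normalised by the
  nearest-rank 95th percentile of the positive scores and clipped to 1.
* Similarity layer keeps cosine values `>= 0.25`, computed over full
  co-occurrence context vectors.
* Fuzzy query logic uses min / max / `1-x`; statement degrees are the
  arithmetic mean of the two member-term degrees; source degrees are
  max-normalised weighted sums.
* Related-article index: max over entity paths of at most 3 edges of the
  product of edge weights, pruned below 0.1.
* Walk batches are bit-reproducible: the per-combination RNG is derived
  from `(seed, heuristic, length, radius)`.
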