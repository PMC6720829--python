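# tipin

Protein complex identification from dynamic **t**emporal-**i**nterval
**p**rotein **i**nteraction **n**etworks.

Given a scored static protein-protein interaction (PPI) network, a
time-course gene expression matrix, a protein subcellular-localization
table and GO annotations, `tipin`:

1. min-max normalizes each gene's expression profile and thresholds it
   (active threshold `phi`) into per-time-point activity states;
2. builds a temporal network per time point (edges between co-active
   proteins, keeping the static reliability score) and merges consecutive
   temporal networks into all `T*(T+1)/2` temporal-interval networks,
   scoring each surviving edge by its minimum over the interval;
3. grows protein clusters in every interval network by seed expansion: a
   candidate joins only if the tentative cluster stays jointly colocalized
   (shares a subcellular category), stays jointly coexpressed (windowed
   mean of the product of normalized profiles ≥ `gamma`), and the candidate
   is GO-semantically similar to its reliably-linked cluster members in at
   least two of the three ontologies (CC/MF/BP);
4. deduplicates clusters across intervals into a catalog with interval
   provenance, and scores catalogs against a reference with a full metric
   suite (precision/recall/f-measure, Frac, MMR, Sn/PPV/Acc,
   FAM = Frac + Acc + MMR, exact-match count #PM, hypergeometric
   enrichment).

A synthetic-bundle generator (`tipin.synthetic`) plants ground-truth
complexes with consistent network, expression, localization and ontology
signals, so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic bundle with planted complexes
tipin simulate --seed 1 --out bundle/

# construct all temporal-interval networks (one TSV per interval)
tipin build --ppi bundle/network.tsv --expr bundle/expression.tsv \
    --phi 0.5 --out nets/

# identify complexes end to end
tipin identify --ppi bundle/network.tsv --expr bundle/expression.tsv \
    --loc bundle/localization.tsv --obo bundle/ontology.obo \
    --gaf bundle/annotations.gaf --config config.yaml --out pred.txt

# score a prediction against a reference catalog
tipin evaluate --pred pred.txt --ref bundle/complexes.txt

# enrichment (over-expression) score
tipin enrich --pred pred.txt --obo bundle/ontology.obo \
    --gaf bundle/annotations.gaf --background proteins.txt
```

`config.yaml` may set any of: `r`, `sigma`, `omega`, `theta`, `gamma`,
`phi`, `min_size`, `jq_denominator` (`window`|`T`), `strict_localization`,
`dedup` (`exact`|`none`), `exclude_evidence`, `n_cycles`.

**Note on `gamma`** (joint-coexpression threshold): it has no published
reference value. The shipped default is 0.01; scan it for your data.

## Package layout

| module | contents |
| --- | --- |
| `tipin.io_formats` | readers/writers: edge lists, expression TSV, localization table, complex lists, OBO 1.2, GAF 2.x |
| `tipin.dynnet` | weighted static network, normalization, activity, temporal and interval networks |
| `tipin.conditions` | joint colocalization, joint coexpression, GO semantic similarity, expanding-cluster rule |
| `tipin.identify` | seed-expansion identification and catalog assembly |
| `tipin.evaluation` | matching metrics and enrichment analysis |
| `tipin.synthetic` | synthetic bundles with planted ground truth |
| `tipin.cli` | `tipin` command group |
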