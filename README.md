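# mccsp

Rank chain pathways from a genetic variant to a disease outcome through a
gene-expression network.

Most GWAS hits sit in noncoding regions, and their effect on disease is
thought to propagate through gene expression: a variant perturbs one gene,
the perturbation travels along the regulatory network, and eventually reaches
the clinical outcome. Given (a) a known directed acyclic network whose single
source is the variant (e.g. APOE ε4 carrier status) and single sink is the
disease (e.g. Alzheimer's disease), and (b) a samples × nodes data matrix
(genotype 0/1, expression continuous, disease 0/1), `mccsp` answers: *which
chain pathways variant → gene → … → disease carry the largest effect?*

## Method

Each directed edge *i → j* is given a nonnegative connection strength
*r<sub>ij</sub>*, estimated with one of six dependence measures:

| name       | measure                                                        |
|------------|----------------------------------------------------------------|
| `pearson`  | &#124;Pearson product-moment correlation&#124;                  |
| `spearman` | &#124;Spearman rank correlation&#124; (mid-ranks for ties)      |
| `distance` | empirical distance correlation *R<sub>n</sub>*                  |
| `mi`       | kernel-density plug-in mutual information (Gaussian kernels)    |
| `mic`      | maximal information coefficient (approximate MINE grid search)  |
| `mcc`      | maximal correlation coefficient sup<sub>φ₁,φ₂</sub> ρ(φ₁(X), φ₂(Y)), estimated by alternating conditional expectations (ACE) |

The effect of a chain pathway is the product of its edge strengths,
*r<sub>X,M₁</sub> · r<sub>M₁,M₂</sub> · … · r<sub>M_k,Y</sub>*. With the
transform *r′<sub>ij</sub> = log(1/r<sub>ij</sub>)* the largest-effect chains
become the smallest-weight source→sink paths, which are found with a
K-shortest-paths deviation (Yen) search whose shortest-path subroutine
relaxes edges in topological order (so raw mutual information above 1, i.e.
negative weights, is handled on DAGs). Each returned pathway gets a
**pathway importance score** PIS = effect / *q₅₀*, where *q₅₀* is the median
effect over all Q source→sink pathways; PIS > 1 marks an above-median chain.

The MCC is attractive here because it degenerates to |Pearson| when the
relationship is linear but keeps its full value under arbitrary invertible
transformations — quadratic, cosine or arcuate edges that make Pearson
collapse to ≈ 0 leave the MCC near the designed strength. The bundled
benchmark quantifies exactly this: a 56-node / 82-edge DAG with 4 planted
high-effect pathways (edge strengths U(0.75, 1) versus background U(0, 0.25)),
structural-equation data with standardised nodes, and subsample replicates
scored by whether the top-4 pathways are recovered in exact order
("all-right") or as a set ("range-right").

## Worked example

```sh
python examples/rank_pathways.py
```

```
5 of 6 pathways (q50 = 0.0689):
  1. APOEg->APOEe->GRIN2A->CAPN2->MAPT->AD  effect=0.1613  PIS=2.341
  2. APOEg->APOEe->GRIN2A->NOS1->AD  effect=0.149  PIS=2.163
  3. APOEg->APOEe->CACNA1C->CAPN2->MAPT->AD  effect=0.06995  PIS=1.015
  4. APOEg->APOEe->CACNA1C->NOS1->AD  effect=0.06785  PIS=0.9847
  5. APOEg->APOEe->GRIN2A->MAPK1->CASP3->AD  effect=0.06223  PIS=0.9032
```

The fixture is a six-pathway fan from genotype through expression nodes to
disease; the two chains whose PIS clearly exceeds 1 are the ones worth
taking forward. `examples/compare_estimators.py` shows the six measures side
by side on a linear versus a cosine edge, and `examples/run_benchmark.py`
runs a small benchmark in which Pearson misranks the planted pathways while
MCC keeps finding them.

The same pipeline is scriptable from a shell:

```sh
mccsp rank --network net.tsv --data expr.csv --source APOEg --sink AD \
      --method mcc --K 5 --out ranking.tsv
mccsp simulate --config scenario.yaml --out table.tsv
```

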