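# icra — InterCriteria analysis for pairwise comparison of criteria

`icra` implements InterCriteria analysis (ICrA), a multi-criterion
decision-making method that compares criteria pairwise through the
orderings they induce on a common set of objects. Its motivating use case
is comparing docking scoring functions: given tables of docking outputs
(best docking score, lowest pose RMSD, RMSD of the best-scored pose, score
of the lowest-RMSD pose) for a set of protein–ligand complexes, ICrA tells
you which scoring functions rank the complexes alike — and hence could be
used interchangeably — and which disagree and could complement each other
in consensus docking. The method applies unchanged to any objects ×
criteria evaluation table.

## The method

The input is an index matrix [O, C, e]: m objects, n criteria, and real
evaluations e_{O_i,C_k}. For each pair of criteria (C_k, C_l), every one
of the m(m−1)/2 unordered object pairs is compared under the relation
R = ">": the counter S^μ_{k,l} is incremented when the two criteria order
the objects the same way, S^ν_{k,l} when they order them oppositely.
Normalising gives the intuitionistic fuzzy pair

    μ_{C_k,C_l} = 2 S^μ / (m(m−1)),   ν_{C_k,C_l} = 2 S^ν / (m(m−1)),

the *degrees of agreement and disagreement*, with μ + ν ≤ 1 and
uncertainty π = 1 − μ − ν absorbing ties. On tie-free data
μ − ν equals Kendall's τ_a, so μ = (1 + τ_a)/2. Against thresholds
α > β the pair is classified as *positive consonance* (μ ≥ α, ν ≤ β),
*negative consonance* (μ ≤ β, ν ≥ α), or *dissonance*; the "thirds" scale
(α ≈ 2/3, β ≈ 1/3) additionally separates an *uncertainty* class
(μ + ν < α). Threshold sweeps with β = 1 − α quantify how sensitive the
conclusions are to the choice of (α, β).

The package also bundles:

- the published 15-pair × 4-block table of degrees of agreement for the
  five MOE scoring functions (London dG, ASE, Affinity dG, Alpha HB,
  GBVI/WSA dG) and an experimental −logK column, as a fixture;
- a Gaussian-copula generator of synthetic docking-output tables with
  controllable pairwise concordance (expected μ = ½ + arcsin(ρ)/π);
- Pearson-correlation juxtaposition (μ and r side by side per pair).

## Worked example

Sweep the packaged agreement table over the five standard (α, β) settings:

```sh
icra sweep --fixture --out-dir sweep_out
cat sweep_out/per_block.csv
```

```
alpha/beta,BestDS,BestRMSD,RMSD_BestDS,DS_BestRMSD
0.75/0.25,0,8,0,0
0.7/0.3,1,10,0,1
0.67/0.33,1,10,5,1
0.65/0.35,2,10,7,1
0.6/0.4,5,10,11,4
```

Each cell counts the criteria pairs (out of 15, including the five pairs
with the experimental affinity column) in positive consonance for one
docking output at one threshold setting. BestRMSD — the lowest pose RMSD —
is the output on which the scoring functions agree most: 8 of 10
scoring-function pairs are already in positive consonance at the strict
0.75/0.25 setting and all 10 from 0.70/0.30 on. The other outputs only
develop consonant pairs as the thresholds relax. `sweep_out/per_pair.csv`
contains the dual view: per criteria pair, in how many of the four docking
outputs it is positive — the Alpha HB–London dG row reads 1, 3, 4, 4, 4,
i.e. at the thirds thresholds this pair agrees in all four outputs.

The same analysis on your own data:

```sh
icra run BestDS.csv BestRMSD.csv --alpha 0.75 --alpha 0.67 --out-dir out
```

reads each CSV (header row = criteria labels, first column = object
labels), computes all pairwise ⟨μ, ν⟩, and writes `mu.csv`, `nu.csv`,
`labels.csv` (one classification column per scheme), `juxtaposition.csv`
(μ, ν and Pearson r per pair) and `triangle_points.csv` (coordinates in
the intuitionistic triangle). Synthetic inputs with a known concordance
structure come from `icra synth --m 195 --seed 1 --out-dir blocks`.

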