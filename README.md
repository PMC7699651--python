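# mlcascade

Cascading-failure analysis of multilayer molecular networks: a simulator,
analytics and analytical percolation theory for coupled gene-regulatory /
protein-protein-interaction / metabolic systems.

## The problem

A cell's robustness is not a property of any single interaction network.
Perturbing a transcription factor silences its target genes; the proteins
those genes encode drop out of the interactome; proteins disconnected from
the main body of the interactome stop functioning and take their own
protein-coding genes with them; and metabolites lose the enzymatic support
that sustains them.  `mlcascade` models this as a three-layer network:

* a **directed gene regulatory network** (GRN), regulator → target;
* an **undirected protein-protein interaction network** (PPI), where a
  protein is functional only inside the largest connected component (LCC);
* an **undirected metabolic network**, where a metabolite with `k_s`
  protein supports fails once `ceil(f_P2M * k_s)` of them are lost, and
  must likewise sit in the metabolic LCC.

Genes and proteins are linked by a partial one-to-one interdependency
matching (gene ↔ protein product); proteins support metabolites through a
many-to-many map.  The package is written for systems biologists who want
to rank genes by their network influence, compare real wiring against
degree-preserving null models, or predict functional-layer sizes
analytically instead of simulating.

## What it computes

**Cascade simulation.** Removing a seed gene set (or a random `1 − p`
fraction) triggers alternating GRN/PPI failure rounds until a fixed point,
then a single metabolic update.  The final functional fractions
`f_S^G, f_S^P, f_S^M` quantify the damage; `1 − f_S^P` for a single-gene
perturbation is that gene's **influence score**.

**Analytical theory.** From the joint GRN degree distribution
`P(k_in, k_out)`, layer generating functions `G(x), H(x) = G'(x)/G'(1)` and
equivalent coupling strengths `q_G, q_P, q_Meta`, the theory iterates

```
ψ'_n = p · (1 − q_G · (1 − h_PPI(φ'_{n−1})))
φ'_n = 1 − q_P · (1 − h_Gene(ψ'_n) · p)
```

to its fixed point, where `h_Gene` captures survival of the initial
removal, of regulation loss (`p^(k_in+1)`) and of regulatory isolation, and
`h_PPI(p) = 1 − G_PPI(p·x_c + 1 − p)` with `x_c = H_PPI(p·x_c + 1 − p)` is
the giant-component factor.  A binomial support-failure stage with
threshold `ceil(f_P2M·k_s)` then yields `f_S^M`.

**Analytics and null models.** Tie-aware precision–recall / average
precision (APS) for gene prioritization, hypergeometric and
degree-matched-null overlap tests, targeted-vs-random metabolic damage with
one-sided Mann–Whitney p-values, and degree-preserving neutral /
assortative / disassortative rewiring within and between layers.

## Worked example

Generate a synthetic three-layer Erdős–Rényi benchmark, simulate the
cascade over a grid of surviving fractions `p`, and compare with theory:

```sh
mlcascade synth er --ng 1000 --np 1000 --nm 250 --seed 1 --out bench
printf 'g12\n' > seeds.txt
mlcascade cascade run --net bench/bundle.yaml --seeds seeds.txt --out single.json
# f_S^G=0.98 f_S^P=0.982 f_S^M=0.976
mlcascade cascade curve --net bench/bundle.yaml --p-grid 0.1:1.0:0.1 \
    --reps 10 --isolate-rule per_round --seed 3 --out sim.tsv
# R = {'gene': 0.21958, 'ppi': 0.32708, 'met': 0.51528}
mlcascade theory curve --net bench/bundle.yaml --p-grid 0.1:1.0:0.1 --out theory.tsv
mlcascade theory compare --sim sim.tsv --theory theory.tsv
# pearson_r = 0.999378
```

The single-gene run shows that perturbing `g12` leaves 98% of genes
functional — the 2% loss is dominated by the baseline regulatory isolates
that are non-functional in any case.  The robustness integrals `R = ∫ f_S dp`
summarize each layer's resilience to random gene removal (the metabolic
layer, buffered by redundant supports, is the most robust here), and the
Pearson correlation of 0.9994 between the 30 simulated and predicted
(layer, p) values shows the generating-function theory tracking the
simulation closely.  The same comparison is available in one step via
`mlcascade theory benchmark`.

From Python, the same objects are available directly:

```python
from mlcascade import toy_fixture, PerturbationConfig, run_cascade

net = toy_fixture("T1")                       # 4 genes, 5 proteins, 3 metabolites
res = run_cascade(net, PerturbationConfig(seeds=frozenset({"g1"})))
res.f_s_ppi            # 0.2 — only one protein survives
res.rounds[0]["genes"] # ['g1', 'g2', 'g3', 'g4']
```

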