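# Methods

## The multilayer model

The system couples three layers. The gene regulatory network (GRN) is a
directed graph of regulator → target edges. The protein-protein interaction
(PPI) and metabolic layers are undirected. Two interlayer structures close
the loop: a partial one-to-one gene ↔ protein matching (interdependency:
failure of either endpoint fails the other) and a many-to-many
protein → metabolite support map. Metabolites exert no feedback on
proteins or genes — enzyme-level feedback loops are deliberately outside
the model.

Node ids are strings; layers may reuse raw ids, in which case the bundle
loader prefixes them (`G:`, `P:`, `M:`) so interlayer references stay
unambiguous. Undirected edges are stored as unordered pairs; self-loops are
dropped and duplicates collapsed at load time, with logged counts. Isolated
nodes can be declared through optional per-layer node-list files.

## The cascade

A perturbation removes a seed gene set, or a uniformly random `1 − p`
fraction. One round then consists of:

1. **GRN step.** Targets regulated by the newly failed genes fail (all of
   them, or an independent Bernoulli(`f`) subset per failing-gene edge when
   the redundancy parameter `f < 1`). Genes left with zero in+out degree in
   the surviving regulatory graph fail as regulatory isolates.
2. Proteins paired with the newly failed genes fail.
3. **PPI step.** Surviving proteins outside the largest connected
   component(s) fail. When several components tie for the maximum size, all
   of them count as functional — the inclusive rule avoids arbitrary
   id-ordering artifacts.
4. Genes paired with the newly failed proteins fail and seed the next
   round.

Rounds repeat to a fixed point; each full pass shares one round index,
which is what the second-round failure counts report. The metabolic update
runs once after convergence (metabolites have no feedback, so a single
application is equivalent to per-round application and cheaper): a
metabolite with `k_s > 0` supports fails when its failed supports reach
`ceil(f_P2M · k_s)`; metabolites with no supports can fail only through the
metabolic largest-component rule. At `p = 1` with no seeds, the baseline
state already excludes regulatory isolates, non-LCC proteins and non-LCC
metabolites.

### Propagation policies

Two choices are deliberately exposed rather than hard-wired:

* `grn_propagation`: under the default `one_hop`, only genes failed by the
  perturbation itself or by protein loss propagate to their regulatory
  targets; `recursive` lets target failures chain within a round. The
  default matches the analytical treatment, where survival of regulation
  loss is `p^(k_in+1)` — one hop from the removed set.
* `isolate_rule`: under the default `initial`, the regulatory-isolation
  rule applies in the first round only, reading isolation as part of the
  initial loss of regulatory context; `per_round` re-applies it after every
  round, which is the process the analytical recursion describes (the
  functional-gene factor is re-derived at every stage). The two policies
  agree on every cascade that terminates in one round; theory-validation
  runs use `per_round`.

Two consequences are worth knowing. Monotonicity in the seed set holds
under cause-independent propagation (`recursive` + `per_round`) but can
fail under `one_hop`: a gene killed as a regulatory target does not
propagate further, while the same gene killed via protein loss does, so a
larger perturbation can occasionally leave more nodes functional.
Similarly, only the `per_round` policy leaves a converged state that is a
true fixed point of the baseline dynamics.

### Controls and sensitivity knobs

* **Uncoupled control** removes the perturbed genes' proteins from the
  isolated PPI directly (one LCC application, no iteration).
* **Merged control** contracts each gene-protein pair into one node of the
  undirected union of GRN and PPI edges and measures the LCC fraction
  after seed deletion.
* **Coupling dilution** (`coupling_retention = r`) severs a uniform `1 − r`
  fraction of interdependency links before the run. Seed genes always
  transmit failure to their own protein, so `r = 0` reproduces the
  uncoupled process exactly for the same perturbed proteins — without this
  convention the zero-retention limit would be a null perturbation rather
  than the uncoupled control.
* **Link noise** adds/removes a bounded fraction of intra-layer edges.

## Analytical theory

All predictions derive from degree distributions. For the GRN the joint
pmf `P(k_in, k_out)` enters through

* `r_S(p) = Σ P(k_in, k_out) p^(k_in+1)` — the fraction surviving the
  removal and the loss of regulation;
* binomial thinning of both margins at rate `r_S` (independence of in- and
  out-degree is assumed at this step; empirical joints are accepted as
  input so the user can quantify the approximation);
* `f_S^G = r_S (1 − P^(r_S)(0,0))` — isolates of the remaining network are
  non-functional — and its conditional form
  `h_Gene(p) = r_S/p · (1 − P^(r_S)(0,0))`.

For the undirected layers, site-percolation generating functions give the
giant-component factor `h(p) = 1 − G(p·x_c + 1 − p)` with
`x_c = H(p·x_c + 1 − p)`. The fixed point is iterated from `x = 0`, which
converges monotonically to the smallest root (`x = 1` always solves the
equation and corresponds to no giant component); an analytic criticality
check (`p·H'(1) ≤ 1`) returns exactly zero in the subcritical regime, and a
bisection fallback guards slow near-critical convergence. Tolerance is
1e−12 with at most 1e5 iterations.

The coupled recursion alternates the two layers with equivalent coupling
strengths `q_G` (genes depending on proteins) and `q_P` (proteins depending
on genes):

```
ψ'_1 = p
φ'_n = 1 − q_P (1 − h_Gene(ψ'_n) · p)
ψ'_{n+1} = p (1 − q_G (1 − h_PPI(φ'_n)))
```

Note the factor `p` (not `ψ'_n`) in the protein-damage term: proteins whose
gene partner failed because of the protein's own death must not be counted
as fresh damage. Convergence is declared on `|ψ'_{n+1} − ψ'_n| < 1e−9`
within 1e4 stages; the functional fractions are `f_S^G = ψ'_m h_Gene(ψ'_m)`
and `f_S^P = φ'_m h_PPI(φ'_m)`.

The metabolic stage computes the probability that a supported metabolite
loses at least `ceil(f_P2M k_s)` supports,

```
ω = q_Meta · Σ_{k_s ≥ 1} P_D(k_s | k_s ≥ 1) · Σ_{l = ceil(f_P2M k_s)}^{k_s} C(k_s, l) (1 − φ_m)^l φ_m^{k_s − l},
```

with `q_Meta` the fraction of metabolites having any support. Summing over
the distribution conditioned on `k_s ≥ 1` keeps unsupported metabolites out
of the support-failure channel (they remain subject to the LCC rule);
including the `k_s = 0` term in the raw sum would wrongly fail a `q_Meta
P_D(0)` fraction even with no protein damage. Then `r_Meta = 1 − ω` and
`f_S^M = r_Meta (1 − G_Meta(r_Meta x_c + 1 − r_Meta))`.

### Coupling strengths

`naive` coupling strengths are participation fractions: the fraction of
genes with a paired protein, of proteins with a paired gene, and of
metabolites with at least one support. `calibrated` strengths minimize the
squared deviation between predicted and supplied simulated curves (11×11
grid search, then Nelder-Mead). Calibration against the protein curve
alone under-identifies `q_G`; supplying the gene-layer curve as well is
recommended and is what the package's own tests do.

### Accuracy

On three-layer ER benchmarks the theory is essentially exact in the
decoupled and fully coupled regimes away from the transition (deviations
~0.002, within Monte-Carlo error). At partial coupling (`q ≈ 0.8`) the
annealed random-coupling treatment carries a small systematic bias at
intermediate `p`: the quenched one-to-one matching of the simulation is
~1-2% more robust than predicted (a surviving gene's partner protein is
self-correlated across rounds, so incremental coupling damage is smaller
than the annealed recomputation assumes), and the bias does not shrink
with network size. The Pearson correlation between theory and simulation
over all layers and `p` values on the default benchmark is ≈ 0.9996; the
pointwise deviation peaks around 0.02 near mid-`p`. A practical corollary:
curve calibration absorbs this bias into `q_G`, which is why calibrated
`q_G` lands well below the generative value on simulated data even though
the estimator is exactly consistent on model-generated curves. The
parameter-recovery acceptance test records this honestly and fails on the
`q_G` component.

## Synthetic data

`generate_er_multilayer` draws a directed ER regulatory layer (in- and
out-degrees independently Poisson, matching the thinning step's
independence assumption), undirected ER protein and metabolic layers, a
uniform random one-to-one gene-protein matching covering `q_G·n_G` genes
and `q_P·n_P` proteins (reconciled to the smaller count), and per-metabolite
Poisson(`c_s`) supports attached to distinct uniform proteins. Support
degree 0 is kept — it exercises the `q_Meta` pathway. The canonical
benchmark is `n_G = n_P = 5000`, `n_M = 1000`, `c_G = 2`, `c_P = 8`,
`c_M = 4`, `q_G = q_P = 0.8`, `c_s = 3`; all generators are reproducible
from a single seed through named substreams.

What the generator does *not* emulate: degree heterogeneity (real
regulatory and interactome degree distributions are heavy-tailed),
in/out-degree correlations within the GRN, degree-degree correlations
within and between layers, and biologically structured (non-random)
interlayer wiring. Passing tests on these benchmarks therefore validate
the machinery and the theory's internal consistency under its own
assumptions — not the biological conclusions one would draw on real
networks, where those unmodeled correlations are exactly what the rewiring
null models are for.

Two fixed fixtures (`T1`, `T2`) are small enough to trace by hand; `T2`
adds a gene-protein pair that turns a protein disconnection into a genuine
second-round regulatory failure. Planted gene sets provide ground truth
for prioritization tests (`high_coupling`: top out-degree × paired-protein
degree) and for targeted-damage tests (genes whose proteins support chosen
metabolites).

## Analytics conventions

* **APS** is the step-wise average precision — the mean of the precision at
  each positive hit — averaged over random permutations within tied score
  groups (100 by default). Note that the expected APS of a random ranking
  exceeds the positive base rate at finite list length, since a hit counts
  in its own precision.
* Empirical p-values use the +1 correction,
  `p = (1 + #{null ≥ observed}) / (n + 1)`.
* Degree matching bins sorted degree values greedily so each bin spans at
  least 30 distinct values (short trailing bins merge backward); matching
  uses GRN total degree by default, with out-degree as an option.
* Mann-Whitney tests use exact enumeration for tie-free samples up to
  n = 8 and the tie-corrected normal approximation otherwise.
* Robustness integrals `R = ∫ f_S dp` are trapezoidal on the evaluated
  grid.

## Rewiring null models

Undirected layers randomize by repeated two-edge swaps (`n_steps` counts
attempted swaps, default 10×|E|): neutral picks one of the two
re-pairings uniformly; assortative joins the highest-degree of the four
endpoints with the next highest; disassortative joins highest with lowest.
Degree ties break by node id for determinism; swaps creating self-loops or
multi-edges are rejected, so every degree sequence is preserved exactly.
The directed GRN randomizes by exchanging whole out-neighborhoods of gene
pairs — both marginals are preserved while the joint (k_in, k_out) changes
— accepting only moves in the requested correlation direction (the sign of
`(k_in_u − k_in_v)(k_out_u − k_out_v)` decides in O(1)). Interlayer maps
re-match uniformly (neutral) or by degree-sorted ranks
(assortative/disassortative), keeping each side's participation multiset
fixed. One degenerate case is worth noting: some tiny degree profiles
admit a unique digraph realization in which every correlation-improving
out-neighborhood exchange would create a self-loop, so the assortative
fixed point is not always the unconstrained rank-pairing optimum.

## Problem sizes used by the test suite

The acceptance checks run at sizes chosen to keep the full suite
comfortably under a minute of compute while leaving Monte-Carlo error well
below the asserted margins: the theory-vs-simulation benchmark at the
canonical 5000/5000/1000 size with 30 replicates; decoupling checks on 100
ER instances of 60+60+15 nodes; parameter recovery on a 3000/3000/600
network with 10-replicate curves; prioritization on 50 instances of
250+250+60 nodes; targeted damage on a 400/400/100 network with 300
realizations per arm. These are the package's own validation conventions.

## Known limitations

* The theory treats interlayer coupling as annealed and random; see
  *Accuracy* above for the quantified consequences.
* In/out-degree correlations of the regulatory layer are accepted in the
  empirical joint pmf but the thinning step assumes independence.
* Edge weights, confidence scores and metabolite→protein feedback are out
  of scope.
* The cascade's LCC criterion makes single-protein removals nearly
  indistinguishable in the uncoupled control on dense interactomes; the
  uncoupled influence score is correspondingly coarse.
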