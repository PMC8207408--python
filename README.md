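# trophinet

Structural analysis of binary consumer–resource (bipartite) networks, built
around the question of what shapes the diet structure of a species-rich
predator assemblage: if predator body size alone governed diet breadth,
small species' diets would be subsets of large species' diets and the
network would be **nested**; if habitat-linked specialization governed it,
the network would split into semi-isolated **modules**. The package was
written for community ecologists analyzing interaction matrices such as the
62-snake × 26-resource trophic network of a Central Amazonian snake
community (archived on Dryad, doi:10.5061/dryad.f1vhhmgvt), but every
routine is generic over any binary incidence matrix.

## What it computes

Given an incidence matrix `A` (`A_ij = 1` when consumer *i* feeds on
resource *j*, `F = Σ A_ij` links, `k_i`/`d_j` consumer/resource degrees):

- **Connectance** `C = F/(nm)` and degree-distribution descriptors.
- **Nestedness (NODF)**: for each pair of rows with strictly decreasing
  positive totals `k_i > k_j > 0`, the paired term is
  `100·|row_i ∩ row_j|/k_j` (zero on ties); likewise over columns; NODF is
  the mean over all `n(n−1)/2 + m(m−1)/2` pairs, in [0, 100].
- **Bipartite modularity (Barber's Q_B)**:
  `Q = (1/F) Σ_ij (A_ij − k_i d_j/F)·δ(g_i, h_j)` over a joint module
  assignment of consumers (`g`) and resources (`h`), optimized by simulated
  annealing with a greedy polish; an exhaustive set-partition oracle covers
  networks with ≤ 12 nodes.
- **Null-model significance**: the probabilistic null that fills cell
  (i, j) with probability `(k_i/m + d_j/n)/2` (expected fill equals `F`
  exactly); Monte-Carlo p-values use the add-one correction and each
  metric's *relative* value `(obs − null mean)/null mean` is reported.
- **Species-removal statistics**: jackknife contributions
  `ΔN_i = N − N_i`, targeted group removals against random same-size
  removals, and a main-vs-secondary resource sensitivity comparison.
- **Guild–module association**: module × lifestyle contingency tables,
  margin-preserving randomization tests, and Bray–Curtis dissimilarity
  `BC(a,b) = Σ|c_a − c_b| / Σ(c_a + c_b)` between module compositions.
- **Regressions**: OLS of degree and of `ΔN_i` on log10 body mass.
- **Synthetic generators** with planted nested, modular, or
  modular-plus-connector structure for testing every stage end to end.

## Worked example

```python
import trophinet as tn

net, traits = tn.generate_combined(tn.GeneratorConfig(seed=1))
print(tn.summarize(net))
part = tn.optimize_modules(net, seed=1)
print(f"Q = {part.Q:.3f}   modules = {part.n_modules}")
conn = [s for s in net.consumers if traits.family_of(s) == "ConnectorFam"]
gr = tn.group_removal_test(net, conn, n_reps=999, seed=1)
print(f"NODF without connectors = {gr.observed_n:.2f} ({gr.pct_change:+.1f}%), "
      f"p = {gr.p_value:.3f}")
reg = tn.trait_degree_regression(net, traits)
print(f"degree ~ log10(mass): slope = {reg.slope:.2f},  R^2 = {reg.r_squared:.2f}")
```

prints (seed 1):

```
{'S': 67, 'R': 26, 'links': 199, 'SD': 2.97, 'C': 0.114, 'N': 13.111}
Q = 0.495   modules = 6
NODF without connectors = 9.44 (-28.0%), p = 0.001
degree ~ log10(mass): slope = 1.33,  R^2 = 0.33
```

Read: the synthetic community of 67 consumers and 26 resources has ~11% of
possible links realized and a mean diet breadth of ~3 resources. The
annealer finds the six planted modules (Q ≈ 0.50). Removing the five
large-bodied connector species degrades nestedness far more than removing
five random species (p = 0.001) — the hub role that large generalist
predators play in the real community — and diet breadth rises with body
mass (slope 1.33 per log10 gram).

The same analyses run from the shell: `trophinet simulate`, `trophinet
analyze --edges ... --traits ... --seed 1`, plus per-stage subcommands
(`nulls`, `removal`, `guilds`, `sensitivity`, `report`).

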