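# netentropy

**Signalling entropy of expression-weighted random walks on interaction
networks.**

`netentropy` is for systems biologists who want to quantify how *promiscuous*
the signalling of a single transcriptomic sample is, given a protein–protein
interaction (PPI) network — and to understand why that quantity rises in
cancer. Each sample defines a random walk on the network via the mass-action
principle: two interacting proteins are more likely to actually interact when
both are highly expressed. The walk's entropy rate is a single number per
sample that discriminates tumour from normal tissue, and its behaviour under
perturbations depends dramatically on whether the network's degree
distribution is scale-free or Poisson.

## The model

Given an undirected connected network with adjacency $A$ and a strictly
positive expression profile $E$ over its nodes, the sample-specific
stochastic matrix is

$$p_{ij} = \frac{A_{ij} E_j}{\sum_k A_{ik} E_k}$$

This walk satisfies detailed balance ($\pi_i p_{ij} = \pi_j p_{ji}$), so its
stationary distribution is available in closed form,

$$\pi_i = \frac{E_i \, x_{T,i}}{\sum_k E_k \, x_{T,k}}, \qquad
x_{T,i} = \sum_j A_{ij} E_j ,$$

and the **signalling entropy rate** is the $\pi$-weighted mean of the local
(per-node) transition entropies:

$$SR = \sum_i \pi_i \, LS_i, \qquad
LS_i = -\sum_j p_{ij} \log p_{ij} \le \log k_i .$$

The topological ceiling is $maxSR = \log \lambda$ with $\lambda$ the dominant
adjacency eigenvalue, attained by the maximal-entropy walk
$p_{ij} = A_{ij} v_j / (\lambda v_i)$. Because the uniform-expression
configuration ($LS_i = \log k_i$ everywhere) is *not* the global maximum,
perturbing a single node can either raise or lower $SR$ — and which happens
is governed by the node's degree and the network's topology. The analytic
perturbation engine, cohort analyses (Wilcoxon/AUC group contrasts, per-gene
differentials vs degree, hub-skew tests) and the degree-rank-matched
Erdős–Rényi control are all built on these closed forms.

## Worked example

```python
import numpy as np
import networkx as nx
import netentropy as ne

tri = ne.Network.from_networkx(nx.complete_graph(["a", "b", "c"]))
res = ne.SignalingEntropy(tri, np.array([1.0, 1.0, 2.0])).fit()
print(res.summary())
```

```
Signalling entropy: mass-action random walk
==============================================
sample:            sample
nodes (V):         3
edges:             3
mean degree <k>:   2.0000
entropy rate SR:   0.659167 nats
max SR (log lam):  0.693147 nats
SR / maxSR:        0.9510
top local entropy rates (pi_i * LS_i):
  c                k=    2  LSR=0.277259
  a                k=    2  LSR=0.190954
  b                k=    2  LSR=0.190954
```

The doubly expressed node `c` draws 40% of the stationary mass
($\pi = (0.3, 0.3, 0.4)$); the rate 0.659 nats sits below the triangle's
ceiling $\log 2 \approx 0.693$ because biasing the walk towards `c` costs
entropy.

A full synthetic study from the shell:

```bash
netentropy simulate --topology BA --nodes 2000 --rho 0.3 --seed 1 --out sim
netentropy compare-groups --network sim/network.tsv --expr sim/expression.tsv \
    --groups sim/groups.tsv --permutation-seed 1 --out cmp
netentropy er-control --network sim/network.tsv --expr sim/expression.tsv \
    --groups sim/groups.tsv --seed 2 --out er
```

`compare-groups` prints the group contrast (on the default fixture:
one-tailed Wilcoxon p ≈ 1.5e-05, AUC ≈ 0.74, Spearman(dE, k) ≈ 0.37) and
`er-control` shows the same expression transported to a degree-rank-matched
ER graph discriminating strictly worse (AUC ≈ 0.65) — the entropy-rate
increase needs the scale-free topology.

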