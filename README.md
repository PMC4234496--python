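# egonet-modules

Subnetwork biomarker discovery for case/control expression studies.  Given an
undirected molecular interaction network (e.g. a protein–protein interaction
map), a gene-by-sample expression matrix and a binary phenotype, the package
finds **ego-network modules** — a focal gene plus its network neighbourhood,
grown outward by snowball sampling — whose members' expression *collectively*
classifies the phenotype, even when no member is differentially expressed on
its own.

## Method

For every gene with degree ≥ 2 (the *ego*), the level-k ego-network is the
ego plus all genes within graph distance k.  Growth proceeds level by level;
each level's gene set is scored by stratified cross-validated classification
accuracy (SVM by default; KNN and random forests are available), and growth
stops at the first accuracy drop.  The retained module score is

* S_i — cross-validated accuracy of module i's genes,

tested against a label-permutation null, p = (1 + #{null ≥ S_i})/(B + 1).
Within each module, node importance V_ij is a random forest's out-of-bag
permutation importance: the mean increase in OOB misclassification when gene
j's values are permuted.  Genes are ranked globally by

* M_j = Σ_i S_i · V_ij  over the retained modules,

so hub genes that sit in many predictive neighbourhoods accumulate rank.  A
two-tailed Welch t-test with Benjamini–Hochberg correction annotates each
gene as differentially expressed or not.  See `docs/methods.md` for details
and design rationale.

## Worked example

```python
import networkx as nx, numpy as np, pandas as pd
from egonet import EgoNet

# a 4-clique A-B-C-D carrying the signal, plus an inert pendant path D-E-F
net = nx.Graph([("A","B"),("B","C"),("C","D"),("D","A"),("A","C"),("B","D"),
                ("D","E"),("E","F")])
rng = np.random.default_rng(5)
X = pd.DataFrame(rng.standard_normal((60, 6)), columns=list("ABCDEF"))
y = (X["A"] + X["B"] + X["C"] > 0).astype(int).to_numpy()

model = EgoNet(network=net, score_cutoff=0.6, n_permutations=99,
               importance_trees=200, random_state=0).fit(X, y)
for m in model.modules_:
    print(m.ego, m.level, sorted(m.members), round(m.score, 3), round(m.p_value, 3))
print(model.ranking_.head(4).to_string(index=False))
```

prints

```
A 1 ['A', 'B', 'C', 'D'] 0.883 0.01
B 1 ['A', 'B', 'C', 'D'] 0.883 0.01
C 1 ['A', 'B', 'C', 'D'] 0.883 0.01
D 1 ['A', 'B', 'C', 'D', 'E'] 0.85 0.01
E 2 ['A', 'B', 'C', 'D', 'E', 'F'] 0.85 0.01
gene        M  de_flag   de_fdr
   C 0.485300     True 0.000213
   B 0.301756     True 0.000634
   A 0.210243     True 0.004521
   D 0.048969    False 0.271933
```

Every ego inside the clique recovers the same four-gene module at level 1
with cross-validated accuracy ≈ 0.88 and the smallest attainable p-value at
B = 99 (0.01); the three genes driving the phenotype dominate the M ranking,
while the inert genes D, E, F contribute little.  The same pipeline runs from
the shell on TSV inputs:

```bash
egonet run --network net.tsv --expr expr.tsv --labels labels.tsv \
           --classifier svm --cutoff 0.9 --permutations 1000 --seed 0 --out results/
egonet simulate --mode table1 --sims 100 --nodes 500 --samples 100 --seed 0 --out sim/
```

`egonet run` writes `modules.tsv` (ego, level, score, p-value, members) and
`ranking.tsv` (gene, M, DE flag, DE FDR); identical options and seed give
byte-identical outputs.

## Synthetic benchmark

`egonet.simulate` plants a known module: a scale-free network (500 nodes by
default), standard-normal expression (100 samples), a true ego of degree
5–20 whose level-1 ego-network drives the outcome through 80% of its members,
linearly (Y = Σ X_i) or cubically (Y = Σ X_i³), dichotomised at 0.  The
recovery studies measure how often the top-ranked discovered modules match
the planted one (Jaccard ≥ 0.5) and compare classifiers and the greedy
aggregated-Z baseline (`egonet simulate --mode comparison`).

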