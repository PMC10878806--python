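# bowtienet

Bow-tie analysis of multi-stance online recommendation networks.

`bowtienet` is a research pipeline for directed social networks in which
pages hold one of three stances on a contested topic (here: anti-, pro-
and neutral-vaccination Facebook pages) and a directed edge `u -> v`
means "page u recommends page v to all its members".  It answers three
questions about such networks: how the information-flow roles of pages
differ between stance groups, whether those roles are stable over time
and statistically significant, and whether they help predict how each
page's audience (its *fan count*) changes between two snapshots.

## The model at its core

The **bow-tie decomposition** of a directed graph `G = (V, A)` singles
out the largest strongly connected component `S` and classifies every
node by its reachability relation to it:

```
SCC         = S
IN          = { v ∈ V−S : S reachable from v }          "listeners"
OUT         = { v ∈ V−S : v reachable from S }          "creators"
TUBES       = reachable from IN and reaching OUT, bypassing S
INTENDRILS  = reachable from IN, not reaching OUT
OUTTENDRILS = not reachable from IN, reaching OUT
OTHERS      = the rest
```

These seven sets are disjoint and cover `V`.  The *recursive*
decomposition applies the same classification inside each community of a
node partition (stance groups, or flow-based communities detected with
Infomap), ignoring cross-community edges, which exposes the local role a
page plays inside its own discursive community.

On top of the decomposition the package provides:

* degree-preserving null models (directed configuration model,
  directed edge swaps) and empirical p-values for component sizes;
* a per-page feature set — fan count `f_i`, weighted in-/out-degree
  `k_i^in = Σ_j A_ji` (edge weight = product of endpoint fan counts),
  same-stance and same-community strength shares, weighted PageRank and
  betweenness, and the two reduced bow-tie roles — feeding a
  cross-validated prediction harness (logistic classification of
  expansion, SVR/RFR regression of the fan-count change `Δf_i`, and
  CC / mutual-information / SFFS feature assessment);
* an agent-based SIR information-cascade simulator in which information
  travels *against* recommendation edges, with within-group
  (same-stance) and across-group (neutral) influence accounting per
  information piece and per seeding page;
* a synthetic-data generator that plants known bow-tie roles per stance
  group, heavy-tailed fan counts, target reciprocity and a
  fan-count-change law, so every stage is testable end to end.

## Worked example

The 12-node worked toy ships with the package and exercises all seven
roles:

```python
import bowtienet as bn

pair = bn.worked_toy()                 # two validated snapshots
roles = bn.decompose(pair.early)
st = bn.descriptive_stats(pair.early)
print({r: sorted(v) for r, v in roles.role_sets().items() if v})
print(f"{st.n_nodes} nodes, {st.n_edges} edges, "
      f"reciprocity {st.reciprocity_pct:.1f}%")
```

prints

```
{'SCC': ['a', 'b', 'c'], 'IN': ['d', 'e'], 'OUT': ['f', 'g'],
 'TUBES': ['h'], 'INTENDRILS': ['i'], 'OUTTENDRILS': ['j'],
 'OTHERS': ['k', 'l']}
12 nodes, 14 edges, reciprocity 14.3%
```

Pages `a,b,c` form the mutually-reachable core (information
"magnifiers"); `f,g` are only reached *from* the core, so their content
flows back into it (information "creators"); `d,e` only reach the core
("listeners").  In the later snapshot the new edge `g -> c` pulls the
OUT pages into the core, and whole-graph role stability over the eight
non-neutral pages drops to 55.6% — the package prints exactly these
numbers in `tests/test_synthetic.py` and the example above.

The same calls run on any loaded dataset:

```bash
bowtienet synth --seed 3 --out synthetic/   # generate a study dataset
bowtienet stats synthetic/edges_feb.csv synthetic/nodes.csv
bowtienet decompose synthetic/edges_feb.csv synthetic/nodes.csv \
    --partition polarity
bowtienet stability synthetic/ --partition polarity
```

## Data

The loader reads CSV snapshots: a node table `id,polarity,fan_feb,fan_oct`
(polarity codes `r` = anti, `b` = pro, `g` = neutral) and one edge list
`source,target` per snapshot.  The published two-snapshot vaccination-views
dataset (1326 pages, February and October 2019) can be fetched from its
public deposit (https://github.com/YuetingH/BT_Vaccination_Views,
archived at https://zenodo.org/records/10513913) and mapped onto this
dialect under `data/deposited/`; the repository itself ships no third-party data, and
`tests/test_acceptance.py::test_deposited_dataset_descriptives`
validates the mapped files against the published descriptive statistics
when they are present.

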