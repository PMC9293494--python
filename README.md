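# herbnetpharm

An offline, fully testable network-pharmacology pipeline for herbal
medicines, built around the analysis of Cassiae semen (the seed of
*Cassia obtusifolia* / *Cassia tora*, a classical Chinese herb for eye
disease) against cataracts. Herbal medicines act through many compounds
hitting many protein targets at once; network pharmacology makes that
tractable by screening compounds for drug-like properties, wiring
compounds to their protein targets, projecting targets onto a
protein–protein interaction (PPI) network, and asking which proteins and
pathways sit at the centre of the resulting graph.

The usual workflow leans on web databases (TCMSP, GeneCards, OMIM,
Bisogenet, DAVID) and GUI tools (Cytoscape plugins such as CytoNCA and
MCODE). This package reimplements the computational core as a library +
CLI that runs entirely from local files — or from a seeded synthetic-data
generator with planted ground truth, so every stage is verifiable.

## What the pipeline computes

1. **ADME activity screen.** A compound is *active* when its oral
   bioavailability and drug-likeness clear the standard thresholds,
   OB ≥ 30 % and DL ≥ 0.18.
2. **Networks.** The bipartite compound–target network; PPI subnetworks
   induced on the disease gene list and on the compound targets
   (seed-only induction, isolated nodes dropped); their merged network
   with per-node provenance (compound / disease / shared); and the exact
   compound ∩ disease shared-target set.
3. **Key-target screen.** Six centralities per node — degree (DC),
   closeness (CC, component-restricted), betweenness (BC, Brandes,
   unnormalized with each unordered pair counted once), eigenvector
   (EC, L2-normalized principal eigenvector), local average connectivity
   (LAC = 2·e(N(v))/|N(v)|) and network centrality
   (NC(v) = Σ_{u∈N(v)} ECC(u,v) with
   ECC(u,v) = |N(u)∩N(v)| / min(d_u−1, d_v−1)). A node is a **key
   target** when it strictly exceeds the network-wide mean on *all six*
   metrics; the **central network** is the subgraph induced on the key
   targets.
4. **Dense modules.** MCODE-style detection: nodes weighted by
   k × density of the highest k-core of their closed neighbourhood,
   greedy seeded expansion with a vertex-weight percentage (default
   0.2), haircut pruning, and the cluster score = density × size. A
   6-node module with all edges but one (density 14/15) scores 5.60.
5. **Enrichment.** Hypergeometric over-representation of the key
   targets against GMT term collections (optionally DAVID's EASE
   variant), Benjamini–Hochberg adjustment on demand, selection at raw
   p < 0.05, and top-10 (GO-style) / top-20 (pathway-style) reporting.
6. **qPCR fold change.** The 2^−ΔΔCt statistic for the validation arm.

## Worked example

```python
import herbnetpharm as hp

# the packaged Cassiae semen compound table (13 compounds)
records = hp.load_cassiae_semen_compounds()
active, report = hp.filter_active_compounds(records)
print(len(active))                      # 13  (all pass OB >= 30, DL >= 0.18)

# the module score that anchors the dense-module stage:
import itertools
nodes = list("ABCDEF")
edges = [e for e in itertools.combinations(nodes, 2) if e != ("A", "B")]
g = hp.InteractionGraph(nodes=nodes, edges=edges)   # K6 minus one edge
m = hp.module_score(g, set(nodes))
print(m.density, m.score)               # 0.9333333333333333 5.6

# a full synthetic study, end to end:
rep = hp.run_pipeline({"output_dir": "out", "seed": 42, "simulation": {}}, quiet=True)
print(rep["adme"]["n_active"])          # 14 of 40 simulated compounds active
print(rep["networks"]["merged"])        # {'n_nodes': 62, 'n_edges': 93, 'provenance': ...}
print(rep["modules"]["top_score"])      # 5.6   (the planted near-clique module)
print(rep["key_targets"]["count"])      # 4
```

The same pipeline runs from the shell:

```sh
herbnetpharm simulate --seed 42 --out simdir/
herbnetpharm run --config study.yaml --seed 42
herbnetpharm mcode --graph disease_ppi.sif --out modules.json
```

Every number in `report.json` is deterministic given the config and
seed; running twice produces a byte-identical report.

## Layout

- `src/herbnetpharm/io.py` — records, TSV/edge-list/SIF/GraphML/GMT readers and writers
- `src/herbnetpharm/adme.py` — OB/DL activity screen
- `src/herbnetpharm/network.py` — bipartite, induced and merged networks
- `src/herbnetpharm/centrality.py` — six metrics + key-target screen
- `src/herbnetpharm/mcode.py` — dense-module detection and cluster score
- `src/herbnetpharm/enrichment.py` — over-representation, BH, 2^−ΔΔCt
- `src/herbnetpharm/simulate.py` — seeded generators with planted ground truth
- `src/herbnetpharm/pipeline.py`, `cli.py` — orchestration and the `herbnetpharm` command

See `docs/methods.md` for the modelling choices and their rationale.
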