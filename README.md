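# regforest

Prize-collecting Steiner forest inference of transcriptional regulatory
networks, with 3D confocal nucleus quantification.

## The problem

When cells change state over time — for example fibroblasts de-differentiating
under sustained mechanical confinement — two waves of transcription are often
visible in time-course RNA-seq: an *early* wave of up-regulated genes, and a
much larger *late* wave that includes the eventual cell-state markers.  The
question is which early-wave transcription factors drive the late wave, given
that some critical intermediates (scaffolds, co-activators) may show no
expression change at all.

`regforest` answers this with network optimization over a two-layer
interactome:

* **protein layer** — proteins connected by protein–protein interaction (PPI)
  edges with STRING-style confidence scores;
* **rna layer** — transcripts reachable only through directed TF→target
  regulon edges collected from TF-target databases.

Genes up-regulated early (BH-adjusted p < 0.01, log2FC > 0) put prizes
`p(v) = β·log2FC` on their protein nodes; genes up-regulated late prize their
rna nodes.  Every edge has a cost: `c(e) = max(1 − confidence, 0.01)` for PPI
edges, a constant (default 0.5) for regulatory edges.  The
**prize-collecting Steiner forest** (PCSF) problem then selects a forest of
node-disjoint trees minimizing

```
Σ_{e ∈ forest} c(e)  +  Σ_{v ∉ forest} p(v)  +  ω · (number of trees)
```

— pay for the edges you use, forfeit the prizes you leave out, pay ω to open
each tree.  Zero-prize nodes enter a tree only when they connect prized nodes
cheaply: these Steiner nodes are exactly the silent intermediates.  The
induced interactome subgraph on the forest's nodes is the inferred regulatory
network; *transcriptional regulators* are its protein nodes with at least one
direct regulatory edge to an rna node, ranked by the mean of two dense ranks —
early log2 fold change and number of in-network targets up-regulated late.

Two solvers are provided: a brute-force exact oracle for instances up to 15
nodes (`solve_exact`) and a deterministic Goemans–Williamson-style
primal–dual heuristic with strong pruning (`solve_pcsf`) for realistic sizes.

A companion `imaging` module implements the matching microscopy readout:
per-plane dual-Otsu segmentation of DAPI-stained nuclei, watershed splitting
at a 10 µm nominal diameter, centroid linking across z-planes (1 µm
threshold), a 100 µm³ volume filter, per-nucleus volume-normalized
intensities, high-marker fractions (e.g. mean intensity > 300), per-nucleus
channel correlations, colocalized-volume ratios and spheroid projected areas.
Seeded synthetic-data generators (`synthetic`) produce interactomes with a
planted key regulator, matched DE tables, and confocal stacks with ground
truth, so the whole pipeline is testable offline.

## Worked example

```python
from regforest.synthetic import gen_planted_scenario
from regforest.model import RegulatorInference

scenario = gen_planted_scenario(seed=0)          # 100 proteins, 8 TFs, planted Tf07
model = RegulatorInference.from_tables(
    scenario.tables["ppi"], scenario.tables["regulons"],
    scenario.de_early, scenario.de_late)
results = model.fit()
print(results.summary())
```

prints

```
Prize-Collecting Steiner Forest regulator inference
=======================================================
Interactome: 100 protein nodes, 73 rna nodes, 197 PPI edges, 114 regulatory edges
Prizes:      28 positive (beta=1, fdr_max=0.01)
Forest:      1 trees, 29 nodes, objective 13.3520 (omega=1)
Network:     29 nodes, 33 edges, 4 regulators

rank  gene         early_lfc up_targets composite
   1  TF07             3.000         17       1.0
   2  TF01             1.314          5       2.5
   3  TF02             1.284          7       2.5
   4  TF00             0.597          2       4.0
```

The planted regulator Tf07 (early log2FC 3.0, 17 of its targets up-regulated
late) ranks first; the decoy TFs with weaker fold changes and sparser late
regulons rank behind it.  The forest's 29 nodes include zero-prize Steiner
proteins that connect the prized nodes.  `results.focal_analysis("TF07")`
lists the regulators that physically interact with the top hit and their
shared late-wave targets; `results.save(outdir)` writes the forest, the
network (GraphML + TSV) and the ranking table.

The same pipeline is available from the shell:

```sh
regforest simulate planted-regulator --seed 0 --outdir fixtures/
regforest infer --ppi fixtures/ppi.tsv --regulons fixtures/regulons.tsv \
    --de-early fixtures/de_early.tsv --de-late fixtures/de_late.tsv \
    --outdir out/
regforest simulate confocal --seed 0 --outdir stack/
regforest segment --stack stack/stack.tif --sidecar stack/stack.yaml --outdir nuclei/
```

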