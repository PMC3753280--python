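# junctiongraph

Predict the helical topology of RNA 3- and 4-way junctions from secondary
structure and model it as a scaled planar tree graph.

The pipeline has two stages. First, each n-way junction parsed from a
secondary structure is classified by a pair of random forests: one predicts
the coaxial-stacking configuration (e.g. `H1H2`, or `H1H4+H2H3` for 4-way
junctions), the other the junction family (`A/B/C` for 3-way; `H, cH, cL,
cK, pi, cW, psi, cX, X` for 4-way). Second, the predicted topology is turned
into a tree graph with 2n+1 vertices (two per helix plus a centroid) and 2n
edges, scaled by empirical distance parameters: coaxial-stack gap
`2.75*L + 3.91` Å for `L` intervening nucleotides, helix edge length
`2.87*(b-1)` Å for `b` base pairs, and lateral distances of 20.48 / 19.95 /
21.17 Å for parallel / perpendicular / diagonal arrangements of unstacked
helices. Solved 3D structures can be translated into the same representation
and compared to model graphs with RMSD (SVD superposition, proper rotations
only) and MaxAngle (maximum angle between corresponding helix edges).

## Layout

| Module | Role |
| --- | --- |
| `junctiongraph.secondary` | dot-bracket / CT parsing, pseudoknot removal, helix and junction decomposition |
| `junctiongraph.classify` | feature extraction, random-forest training, prediction, LOOCV, dataset TSV I/O |
| `junctiongraph.builder` | scaling parameters and scaled tree-graph construction from a topology |
| `junctiongraph.translate` | PDB/mmCIF reading, base-pair vertex construction, structure-to-graph translation, WC-pair detection |
| `junctiongraph.compare` | Kabsch superposition, RMSD, MaxAngle |
| `junctiongraph.synthetic` | ideal helix generator and composed junction fixtures with known ground-truth graphs |
| `junctiongraph.cli` / `config` | command-line entry points and run configuration |

## CLI

Installed as `junctiongraph` (or `python -m junctiongraph.cli`):

```sh
# decompose a secondary structure into junctions
junctiongraph parse input.db

# train / evaluate the topology classifier on a labeled TSV dataset
junctiongraph train data.tsv --seed 1 --out model.joblib
junctiongraph loocv data.tsv --seed 1

# predict topology, build a scaled model graph, translate a solved structure
junctiongraph predict model.joblib input.db
junctiongraph build input.db --stacks H1H2 --family A --out graph.json --pdb-out graph.pdb
junctiongraph pdb2graph native.pdb --pairs pairs.tsv --out native.json

# score two graphs / run the whole pipeline
junctiongraph compare native.json graph.json
junctiongraph run input.db --model model.joblib --native native.pdb --out report.json
```

Secondary-structure input is two-line dot-bracket (optional `>` header) or
CT format (`.ct`). Graphs are written as JSON and as pseudo-PDB (one
HETATM per vertex, CONECT per edge) for visualization. An optional
`key=value` config file can override the seed and any scaling parameter
(`junctiongraph build ... --config run.cfg`).

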