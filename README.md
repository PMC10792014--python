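# phylofam

A toolkit for gene-family macroevolution analyses on a fixed species tree:

- **treeio** — Newick parsing/serialisation (internal labels, branch
  lengths, NHX annotations), validated binary species trees, and the
  leaf-name → species mapping convention used throughout.
- **simulate** — birth–death gene-family simulation along a species tree
  with per-edge rate overrides and a full ground-truth event log; synthetic
  pairwise-similarity matrices (BLAST outfmt-6-like TSV); NNI topology
  perturbation for bootstrap-replicate stand-ins.
- **clustering** — homology-group delineation as connected components of a
  similarity graph at graduated P-value thresholds, cluster merge
  thresholds (bottleneck path P-values), nested threshold ladders, majority
  -vote component annotation, and a toy 2-D force layout.
- **reconcile** — weighted duplication–loss parsimony reconciliation via
  LCA mapping (S/D labels, per-species-edge loss placement), polytomy
  resolution, optimal rooting by exhaustive branch enumeration, NHX export.
- **complements** — ancestral gene copy numbers at every species-tree node,
  orthogroup delineation by cutting at duplication nodes, presence/absence
  matrices, and per-node duplication bursts.
- **support** — Transfer Bootstrap Expectation and Felsenstein bootstrap
  proportion from replicate trees, with traffic-light classification.
- **filters** — candidate curation rules: N-terminal cysteine-motif classes
  (CC/CXC/CX3C/XC), transmembrane-domain count range filter, and advisory
  length/signal-peptide flags.
- **pipeline / cli** — end-to-end orchestration with a single seed, flat
  config files, and a checksummed JSON manifest.

Everything is exercisable offline: the simulator provides families with
known histories, and the test suite checks each inference component against
independent brute-force oracles (exhaustive history enumeration, union-find
sweeps, set-arithmetic transfer distances).

## Command line

```sh
# simulate 5 families on the bundled 12-taxon chordate tree
phylofam simulate --families 5 --dup-rate 0.5 --loss-rate 0.2 --seed 42 --out out/

# homology groups at a threshold ladder (strictest first)
phylofam cluster --pairs out/pairs.tsv --thresholds 1e-35,1e-15,1e-6 --out out/

# duplication-loss reconciliation (leaf names encode species as "<sp>_<gene>")
phylofam reconcile --gene-trees out/families.nwk --sep "_" --out out/

# ancestral complements, presence matrix, duplication bursts
phylofam complements --gene-trees out/families.nwk --out out/

# branch supports from replicate trees
phylofam support --ref ref.nwk --reps boots.nwk --out out/

# motif classification + TM filtering of candidate sequences
phylofam motifs --fasta candidates.fa --annotations predictions.tsv --out out/

# everything from one config file
phylofam run --config run.cfg
```

A config file is flat `key = value` text, e.g.

```
out_dir   = out/
seed      = 42
stages    = simulate,cluster,reconcile,complements,support
n_families = 5
dup_rate  = 0.5
loss_rate = 0.2
thresholds = 1e-35,1e-15,1e-6
```

`phylofam validate-config --config run.cfg` reports problems without
running anything. Every run writes `manifest.json` with per-stage derived
seeds and SHA-256 checksums of all outputs; identical config + seed gives
byte-identical outputs.

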