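# connectocore

Topological characterization of weighted directed connectomes: global graph
statistics with degree-preserving rewired null models, multiscale community
detection with consensus clustering, hub / rich-club analysis, three-node
motif census, and persistent-homology cavity detection — plus synthetic
connectome generators so the entire pipeline is testable offline.

## What's inside

| Module | Purpose |
| --- | --- |
| `connectocore.io` | Labeled CSV/TSV matrix + coordinate loading, pairwise-complete node filtering (missing ≠ zero), log weight-to-length transform, symmetrization |
| `connectocore.synthetic` | Geometric (distance-decaying) and modular generators, exact fixture graphs |
| `connectocore.nulls` | Maslov–Sneppen double-edge-swap rewiring, seeded ensembles, empirical p-values |
| `connectocore.global_topology` | Strengths, reciprocity, assortativity, Fagiolo clustering, characteristic path length, small-world indices (γ, λ, σ) |
| `connectocore.communities` | Directed-modularity Louvain, Lancichinetti–Fortunato consensus, NMI, resolution sweeps with scale selection |
| `connectocore.hubs` | Participation coefficients, cross-resolution rank profiles, out/in strength ratios, rich-club curves with per-k significance |
| `connectocore.motifs` | 13-class triad census (induced or partial), exhaustive class enumeration, null significance spectrum |
| `connectocore.homology` | Clique-complex edge filtration, GF(2) persistence with representative cycles, cavity significance vs nulls |
| `connectocore.pipeline` | One-command orchestration with a master seed and a JSON summary bundle |

## CLI

```bash
# generate a synthetic connectome and analyze it
connectocore synth --n 55 --density 0.62 --seed 1 --out synth.csv
connectocore metrics synth.csv --nulls 200 --seed 0
connectocore communities synth.csv --runs 100 --seed 0 --out-dir comm/
connectocore hubs synth.csv --nulls 200 --seed 0 --out-dir hubs/
connectocore motifs synth.csv --nulls 100 --seed 0 --out motifs.csv
connectocore homology synth.csv --nulls 100 --seed 0 --out-dir homology/

# full pipeline from a JSON config
python - <<'EOF'
from connectocore import AnalysisConfig
AnalysisConfig(weights_path="synth.csv", n_nulls_global=200,
               louvain_runs=100, seed=1).to_json("cfg.json")
EOF
connectocore run --config cfg.json --out report/
```

The pipeline report contains `summary.json` (densities, reciprocity,
assortativity, clustering, path length, γ/λ/σ, selected community scales,
rich-club regime, motif spectrum, cavity table) and per-stage CSVs.

## Conventions

- Matrix orientation: rows = source areas, columns = target areas.
- Missing entries (`NA`, empty cell) mean "not tested" and are distinct from
  a literal 0 ("tested, absent"); `pairwise_complete=True` drops untested nodes.
- Weight-to-length: `-ln(w / w_max)`, so the strongest edge has length 0.
- Motif class IDs 1–13 follow the Brain Connectivity Toolbox ordering,
  reconstructed algorithmically from sorted degree-pair labels (class 9 is
  the reciprocal chain, class 13 the fully reciprocal triangle).
- Rich-club filter keeps nodes with total degree > k (pass `keep_geq` to flip).
- Persistence uses the 2-element field on the flag complex of the
  max-symmetrized graph, with both edge-rank and metric filtration values.
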