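# hgdti

Hierarchical heterogeneous graph convolutional networks for drug-target
interaction prediction. The package integrates four entity types (drugs,
diseases, genes, proteins) connected by nine binary relations, propagates
information through homogeneous GCN branches, per-entity embedding layers,
direct and indirect bipartite heterogeneous GCNs, and a relational GCN whose
last layer retains per-relation embeddings; inner products of the final
MLP-aggregated embeddings score candidate interactions.

Everything runs on plain numpy/scipy: gradients come from a small built-in
reverse-mode autodiff engine (`hgdti.autodiff`), optimized with Adam, fully
deterministic for a fixed seed.

## Layout

| module | contents |
| --- | --- |
| `hgdti.similarity` | Jaccard substructure similarity, hierarchical disease semantic similarity, matrix binarization |
| `hgdti.network` | entity catalogs, typed association matrices, normalized adjacencies, bipartite blocks, bundle I/O |
| `hgdti.model` | the full propagation architecture, parameter init/census, checkpoints |
| `hgdti.training` | composite multi-relation loss, masking, the Adam training loop |
| `hgdti.evaluation` | k-fold CV with balanced negative sampling, AUC/AUPR/F1 metrics, repositioning ranking, ablation runner |
| `hgdti.synthetic` | seeded generator of networks with planted low-rank structure (plus disease DAGs and drug fingerprints) |
| `hgdti.cli` | the `hgdti` command line |

## CLI

```bash
# generate a synthetic bundle (the no-download testbed)
hgdti simulate --out scratch/bundle --seed 7 --preset high_signal

# similarity matrices from substructure tokens and a disease hierarchy
hgdti similarity --substructures scratch/bundle/drug_substructures.tsv \
    --dag scratch/bundle/disease_dag.tsv --term-map scratch/bundle/disease_terms.tsv \
    --target-density 0.05 --out scratch/sim

# train / cross-validate / ablate / rank / sweep
hgdti train    --bundle scratch/bundle --out scratch/run  --epochs 300 --lr 1e-3 --embed-dim 64
hgdti evaluate --bundle scratch/bundle --out scratch/eval --epochs 300 --lr 1e-3 --embed-dim 64 -k 5
hgdti ablate   --bundle scratch/bundle --out scratch/abl  --epochs 300 --lr 1e-3 --embed-dim 64 -k 2
hgdti rank     --bundle scratch/bundle --out scratch/rank --disease di0003 --epochs 300 --lr 1e-3 --embed-dim 64
hgdti sweep    --bundle scratch/bundle --out scratch/swp  --betas 0.03,0.05,0.1,0.5,1.0 --epochs 100 --lr 1e-3 --embed-dim 32 -k 2
```

A YAML run config (`--config run.yaml`) with `model:`, `train:` and
`synthetic:` sections mirrors the dataclass fields and is schema-checked;
CLI flags override it. Every output directory receives a `run_config.yaml`
recording the resolved configuration and seed.

Model defaults follow the reference settings (embedding width 256, MLP
256/128/64, 2000 epochs, Adam at 1e-4, loss weight beta 0.05). The examples
above use the desk-scale settings (width 64, 300 epochs, lr 1e-3) that the
test suite exercises; at small fixture sizes large learning rates can
collapse the all-ReLU stack, so stay at or below 1e-3.

## Notes

- Held-out positives are masked from the supervision targets **and** from
  every adjacency operator (bipartite blocks, RGCN neighbor means) before
  training, so evaluation never leaks test edges into message passing.
- Ablation variants (`no_protein`, `no_gene`, `no_indirect`) are pure
  configuration on the same code path.
- Disease self-similarity is 0.5 under the literal similarity formula; the
  `reconciled` mode rescales so identical diseases score 1.
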