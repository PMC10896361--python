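# dnaclr

Species-aware DNA embeddings by curriculum contrastive learning, with the
classical tetranucleotide-frequency baselines and a full metagenomics
evaluation stack — for researchers who need to group anonymous DNA fragments
by species when no reference genome exists.

## The problem and the method

Metagenome assemblies and long-read datasets contain fragments from many
unknown species. Binning them requires an embedding under which fragments of
the same species cluster. The classical signal is genome composition:
**TNF**, the 256-dim frequency vector of overlapping 4-mers, and **TNF-K**,
its 103-dim projection through a linear kernel that removes the redundancy
imposed by DNA characteristics (reverse-complement strand symmetry, 3-mer
overlap consistency, unit sum).

`dnaclr` trains an embedding instead of prescribing one. Two non-overlapping
fragments of the same genome form a positive pair (x_i, x_i+); a transformer
encoder f over k-mer tokens is trained so positives attract and the other
2B−2 fragments in the batch repel, with each negative x_j weighted by its
hardness:

    α_ij = exp(s(f(x_i), f(x_j))/τ) / [ (1/(2B−2)) Σ_{k≠i,i+} exp(s(f(x_i), f(x_k))/τ) ]

(Weighted SimCLR; s = cosine similarity, τ = 0.05, α_ii+ = 1). A second
training phase makes anchors harder by **manifold instance mixup**: hidden
states of two anchors are mixed at a random encoder layer,
h_i^m = λ_i g_m(x_i) + (1−λ_i) g_m(x̂_i) with λ_i ~ Beta(α, α), and the
model is trained against the correspondingly mixed virtual label over the
batch's positives. The two phases form a curriculum (**C²LR**); i-Mix
(mixing at the input layer) and single-loss schedules are available as
ablation arms.

Any embedding — learned, TNF, or TNF-K — is evaluated by:

- **clustering**: K-means with the true species count, scored by ARI;
- **binning**: iterative density clustering (modified K-medoid) with a
  learned distance threshold, scored by the number of species recovered at
  F1 over 0.5 (banded up to 1.0);
- **few-shot classification**: logistic-regression probe with 1–20 labeled
  examples per species, scored by macro F1.

A seeded synthetic-community generator (order-3 Markov chains per species
with a divergence knob, abundance skew, read noise) makes the whole pipeline
runnable end-to-end on a laptop. See `docs/methods.md` for assumptions,
defaults, and limitations.

## Worked example

```python
import numpy as np
from dnaclr import (easy_community_config, make_community, kmeans_ari_mean,
                    modified_kmedoid, species_recovery)
from dnaclr.baselines import tnf_matrix
from dnaclr.io import EmbeddingMatrix

com = make_community(easy_community_config(fragments_per_species=30))
X = tnf_matrix([f.seq for f in com.fragments])
labels = list(com.truth["species"])
print("TNF K-means ARI:", round(kmeans_ari_mean(X, labels), 3))

emb = EmbeddingMatrix(ids=[f.id for f in com.fragments], rows=X, source="tnf")
result = modified_kmedoid(emb)
rec = species_recovery(result, com.truth)
print("bins:", len(result.bins), "species identified:", rec.n_identified)
```

Output:

```
TNF K-means ARI: 1.0
bins: 10 species identified: 10
```

On this high-divergence community every species has a distinct 4-mer
composition, so raw TNF clusters perfectly (ARI 1.0) and the density binner
recovers all 10 species, each at F1 in [0.9, 1.0]. The shipped *hard*
community (`hard_community_config()`) lowers the divergence until TNF fails
(5-shot macro F1 < 0.5); there, contrastive training demonstrably improves
K-means ARI over an untrained encoder — that experiment runs in
`tests/test_acceptance.py`.

Training is a statsmodels-style model/results pair:

```python
from dnaclr import C2LRModel, EncoderConfig, TrainConfig
from dnaclr.pairs import build_pairs

pairs = build_pairs(com.genomes, 320, 1000, np.random.default_rng(0))
model = C2LRModel(pairs[:300], pairs[300:],
                  EncoderConfig(n_layers=2, hidden_dim=32, n_heads=1,
                                max_tokens=250, dropout_rate=0.0),
                  TrainConfig.desk(seed=1), schedule="c2lr")
results = model.fit()
print(results.summary())          # schedule, losses, best checkpoint
embeddings = results.embed([f.seq for f in com.fragments])
```

The same operations are exposed on the command line: `dnaclr synth`,
`make-pairs`, `train`, `embed`, `eval-cluster`, `eval-bin`, `eval-fewshot`,
and `ablate` (each accepts `--seed` and writes a run manifest next to its
outputs).

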