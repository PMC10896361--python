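"""Synthetic multi-species genome communities.

Each species is an order-r Markov chain over {A,C,G,T} (default r=3, so the
4-mer composition is the species fingerprint — the same signal TNF reads).
Species chains are perturbations of a shared base chain; the ``divergence``
knob interpolates each transition row between the base chain (0 = species
indistinguishable) and an independent random chain (1 = maximally distinct),
controlling how separable species are by composition. Communities add
log-normal abundance skew and optional read noise (substitutions and short
indels), emulating imbalanced long-read metagenome samples.

Two shipped presets bound the difficulty range used in tests:
``easy_community_config`` (high divergence — descriptive TNF features
separate species) and ``hard_community_config`` (low divergence — TNF is
weak and learned embeddings can demonstrate gains).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import SeqRecord

BASES = "ACGT"


@dataclass(frozen=True)
class SpeciesModel:
    """Order-r Markov chain over ACGT for one species."""

    species_id: str
    transition: np.ndarray   # (4^order, 4); rows sum to 1
    order: int
    gc_bias: float = 0.0
    divergence: float = 0.0  # knob value used to draw this model

    def __post_init__(self):
        t = np.asarray(self.transition, float)
        if t.shape != (4 ** self.order, 4):
            raise ConfigError(f"transition must be ({4 ** self.order}, 4)")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("transition rows must sum to 1")


def _apply_gc_bias(rows: np.ndarray, gc_bias: float) -> np.ndarray:
    if gc_bias == 0.0:
        return rows
    tilt = np.exp(gc_bias * np.array([0.0, 1.0, 1.0, 0.0]))  # favor C, G
    rows = rows * tilt
    return rows / rows.sum(axis=1, keepdims=True)


def make_species_models(n: int, order: int = 3, divergence: float = 0.3,
                        rng: Optional[np.random.Generator] = None,
                        gc_bias: float = 0.0) -> list[SpeciesModel]:
    """Draw n species chains as convex perturbations of one shared base chain.

    Each species row is (1−w)·base + w·noise with w = divergence and noise a
    fresh Dirichlet(1,1,1,1) draw, so divergence=0 gives identical models and
    larger values monotonically increase inter-species distance.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ConfigError("divergence must be in [0, 1]")
    rng = rng or np.random.default_rng()
    n_ctx = 4 ** order
    base = rng.dirichlet(np.full(4, 3.0), size=n_ctx)
    models = []
    for s in range(n):
        noise = rng.dirichlet(np.ones(4), size=n_ctx)
        rows = (1.0 - divergence) * base + divergence * noise
        rows = _apply_gc_bias(rows, gc_bias)
        models.append(SpeciesModel(species_id=f"sp{s}", transition=rows,
                                   order=order, gc_bias=gc_bias,
                                   divergence=divergence))
    return models


def stationary_kmer_distribution(model: SpeciesModel) -> dict[str, float]:
    """Analytic stationary law of (order+1)-mers for the species chain."""
    r = model.order
    n_ctx = 4 ** r
    # context chain: ctx -> (ctx drop-first + next base)
    P = np.zeros((n_ctx, n_ctx))
    for ctx in range(n_ctx):
        tail = (ctx % (4 ** (r - 1))) * 4 if r > 0 else 0
        for b in range(4):
            P[ctx, tail + b] += model.transition[ctx, b]
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    kmers = ["".join(p) for p in product(BASES, repeat=r + 1)]
    out = {}
    for ctx in range(n_ctx):
        ctx_str = "".join(BASES[(ctx // 4 ** (r - 1 - j)) % 4] for j in range(r))
        for b in range(4):
            out[ctx_str + BASES[b]] = pi[ctx] * model.transition[ctx, b]
    return {k: float(out.get(k, 0.0)) for k in kmers}


def sample_genome(model: SpeciesModel, length: int,
                  rng: np.random.Generator) -> SeqRecord:
    """Sample one genome of `length` bases from the species chain."""
    r = model.order
    if length < r + 1:
        raise ConfigError(f"length must be >= order+1 = {r + 1}")
    cum = np.cumsum(model.transition, axis=1)
    # start from a uniformly random context
    ctx_digits = rng.integers(0, 4, size=r) if r > 0 else np.empty(0, int)
    ctx = 0
    for d in ctx_digits:
        ctx = ctx * 4 + int(d)
    out = list(ctx_digits)
    u = rng.random(length - r)
    mod = 4 ** (r - 1) if r > 0 else 1
    for i in range(length - r):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        out.append(b)
        ctx = (ctx % mod) * 4 + b if r > 0 else 0
    seq = "".join(BASES[b] for b in out)
    return SeqRecord(id=f"{model.species_id}_genome", seq=seq,
                     species_id=model.species_id, genome_id=model.species_id)


def corrupt_read(seq: str, error_rate: float, rng: np.random.Generator,
                 sub_frac: float = 0.8, indel_ext: float = 0.3) -> str:
    """Introduce sequencing-like noise: per-base errors at `error_rate`,
    split 80% substitutions / 10% insertions / 10% deletions, with
    geometric(1−indel_ext) indel lengths."""
    if error_rate == 0.0:
        return seq
    out = []
    i = 0
    other = {b: [c for c in BASES if c != b] for b in BASES}
    while i < len(seq):
        if rng.random() < error_rate:
            u = rng.random()
            if u < sub_frac:  # substitution
                out.append(other[seq[i]][rng.integers(3)])
                i += 1
            elif u < sub_frac + (1 - sub_frac) / 2:  # insertion
                n_ins = 1 + rng.geometric(1.0 - indel_ext) - 1
                out.extend(BASES[rng.integers(4)] for _ in range(n_ins))
            else:  # deletion
                n_del = 1 + rng.geometric(1.0 - indel_ext) - 1
                i += max(1, n_del)
        else:
            out.append(seq[i])
            i += 1
    return "".join(out) if out else seq[:1]


@dataclass(frozen=True)
class CommunityConfig:
    n_species: int = 10
    genome_length: int = 20_000
    fragments_per_species: int = 50   # mean count; exact when abundance_sigma=0
    fragment_length: int = 500
    abundance_sigma: float = 0.0      # log-normal abundance skew (0 = balanced)
    error_rate: float = 0.0
    markov_order: int = 3
    divergence: float = 0.3
    gc_bias: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_species, self.genome_length, self.fragment_length,
               self.fragments_per_species) < 1:
            raise ConfigError("community sizes must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.fragment_length > self.genome_length:
            raise ConfigError("fragment_length exceeds genome_length")


@dataclass
class Community:
    genomes: list[SeqRecord]
    fragments: list[SeqRecord]
    truth: pd.DataFrame  # columns: id, species
    config: CommunityConfig


def make_community(config: CommunityConfig) -> Community:
    """Generate genomes, fragments, and a truth table for one community."""
    rng = np.random.default_rng(config.seed)
    models = make_species_models(config.n_species, config.markov_order,
                                 config.divergence, rng, config.gc_bias)
    genomes = [sample_genome(m, config.genome_length, rng) for m in models]

    total = config.fragments_per_species * config.n_species
    if config.abundance_sigma > 0:
        w = rng.lognormal(0.0, config.abundance_sigma, config.n_species)
        counts = np.maximum(1, np.round(total * w / w.sum()).astype(int))
    else:
        counts = np.full(config.n_species, config.fragments_per_species)

    fragments, rows = [], []
    for genome, count in zip(genomes, counts):
        max_start = len(genome.seq) - config.fragment_length
        starts = rng.integers(0, max_start + 1, size=count)
        for j, s in enumerate(starts):
            frag = genome.seq[s: s + config.fragment_length]
            frag = corrupt_read(frag, config.error_rate, rng)
            fid = f"{genome.species_id}_f{j}"
            fragments.append(SeqRecord(id=fid, seq=frag,
                                       species_id=genome.species_id,
                                       genome_id=genome.species_id))
            rows.append({"id": fid, "species": genome.species_id})
    truth = pd.DataFrame(rows, columns=["id", "species"])
    return Community(genomes=genomes, fragments=fragments, truth=truth,
                     config=config)


# ---------------------------------------------------------------------------
# Shipped fixtures (divergence presets bracket TNF separability; see docs)


def easy_community_config(**overrides) -> CommunityConfig:
    """Strong composition signal: TNF features separate species."""
    base = dict(n_species=10, genome_length=20_000, fragments_per_species=100,
                fragment_length=1000, divergence=0.9, seed=2024)
    base.update(overrides)
    return CommunityConfig(**base)


def hard_community_config(**overrides) -> CommunityConfig:
    """Weak composition signal: TNF features do not separate species
    (few-shot TNF probes stay below chance-plus-margin), yet enough signal
    remains at this fragment length for contrastive training to find."""
    base = dict(n_species=10, genome_length=20_000, fragments_per_species=100,
                fragment_length=1000, divergence=0.12, seed=2024)
    base.update(overrides)
    return CommunityConfig(**base)
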