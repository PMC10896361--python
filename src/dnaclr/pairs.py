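"""Contrastive pair construction.

A positive pair is two non-overlapping fragments drawn from the same genome;
the contrastive objective treats them as "same species". Alternative positive
strategies (mutation, dropout, reverse complement) are provided for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ConfigError, DnaclrError
from .io import SeqRecord, reverse_complement

STRATEGY_NAMES = ("same_genome", "mutate", "dropout", "double")


class PairSkip(DnaclrError):
    """Genome unusable for pair extraction (too short / too many Ns); skip it."""


@dataclass(frozen=True)
class PairStrategy:
    """How the positive of a pair is produced.

    same_genome: second non-overlapping fragment from the same genome (default).
    mutate:      same fragment after random swap/delete edits at `mutation_rate`.
    dropout:     identical fragment; the two views come from two stochastic
                 encoder passes (dropout on), handled by the trainer.
    double:      reverse complement of the fragment.
    """

    name: str = "same_genome"
    mutation_rate: float = 0.05

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise ConfigError(f"unknown pair strategy {self.name!r}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SequencePair:
    """An anchor/positive fragment pair sharing a genome of origin."""

    anchor: SeqRecord
    positive: SeqRecord
    genome_id: str
    anchor_interval: Optional[tuple[int, int]] = None  # 0-based half-open
    positive_interval: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.anchor_interval is not None and self.positive_interval is not None:
            a, b = sorted([self.anchor_interval, self.positive_interval])
            if a[1] > b[0]:
                raise ValueError(
                    f"pair on {self.genome_id}: intervals {a} and {b} overlap"
                )


def _frac_n(seq: str) -> float:
    return seq.count("N") / len(seq)


def extract_pair(
    genome: SeqRecord,
    fragment_length: int,
    rng: np.random.Generator,
    max_n_frac: float = 0.10,
    max_retries: int = 10,
) -> SequencePair:
    """Draw two disjoint fragments of `fragment_length` uniformly from a genome.

    Placement is uniform over all disjoint ordered placements (sorted-offset
    construction). Fragments with more than `max_n_frac` Ns are re-drawn up to
    `max_retries` times. Raises PairSkip when the genome is too short or no
    acceptable draw is found.
    """
    L = fragment_length
    G = len(genome.seq)
    if G < 2 * L:
        raise PairSkip(
            f"genome {genome.id}: length {G} < 2 x fragment_length {L}"
        )
    for _ in range(max_retries):
        u1, u2 = np.sort(rng.integers(0, G - 2 * L + 1, size=2))
        s1, s2 = int(u1), int(u2) + L
        iv1, iv2 = (s1, s1 + L), (s2, s2 + L)
        if rng.random() < 0.5:  # anchor/positive roles are exchangeable
            iv1, iv2 = iv2, iv1
        a_seq = genome.seq[iv1[0]: iv1[1]]
        p_seq = genome.seq[iv2[0]: iv2[1]]
        if _frac_n(a_seq) > max_n_frac or _frac_n(p_seq) > max_n_frac:
            continue
        gid = genome.genome_id or genome.id
        return SequencePair(
            anchor=SeqRecord(id=f"{genome.id}:{iv1[0]}-{iv1[1]}", seq=a_seq,
                             species_id=genome.species_id, genome_id=gid),
            positive=SeqRecord(id=f"{genome.id}:{iv2[0]}-{iv2[1]}", seq=p_seq,
                               species_id=genome.species_id, genome_id=gid),
            genome_id=gid,
            anchor_interval=iv1,
            positive_interval=iv2,
        )
    raise PairSkip(f"genome {genome.id}: no fragment with <= {max_n_frac:.0%} Ns")


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply round(rate * len) edits: adjacent swaps and single-base deletions,
    the budget split evenly (deletions get the floor half)."""
    L = len(seq)
    n_edits = int(round(rate * L))
    if n_edits == 0:
        return seq
    n_del = n_edits // 2
    n_swap = n_edits - n_del
    chars = list(seq)
    if n_swap > 0:
        swap_pos = rng.choice(L - 1, size=n_swap, replace=False)
        for i in swap_pos:
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
    if n_del > 0:
        del_pos = np.sort(rng.choice(len(chars), size=n_del, replace=False))[::-1]
        for i in del_pos:
            del chars[int(i)]
    return "".join(chars)


def make_positive(
    seq: SeqRecord, strategy: PairStrategy, rng: np.random.Generator
) -> SeqRecord:
    """Produce the positive view of `seq` under an ablation strategy."""
    if strategy.name == "double":
        out = reverse_complement(seq.seq)
    elif strategy.name == "mutate":
        out = mutate_sequence(seq.seq, strategy.mutation_rate, rng)
    elif strategy.name == "dropout":
        out = seq.seq  # the two views come from stochastic encoder passes
    else:
        raise ConfigError(
            f"make_positive expects strategy in {{mutate, dropout, double}}, "
            f"got {strategy.name!r}"
        )
    return SeqRecord(id=f"{seq.id}|{strategy.name}", seq=out,
                     species_id=seq.species_id, genome_id=seq.genome_id)


def build_pairs(
    genomes: list[SeqRecord],
    n_pairs: int,
    fragment_length: int,
    rng: np.random.Generator,
    strategy: PairStrategy = PairStrategy(),
) -> list[SequencePair]:
    """Draw `n_pairs` pairs, allocated round-robin across usable genomes."""
    pairs: list[SequencePair] = []
    usable = list(genomes)
    while len(pairs) < n_pairs and usable:
        next_round = []
        for g in usable:
            if len(pairs) >= n_pairs:
                break
            try:
                pair = extract_pair(g, fragment_length, rng)
            except PairSkip:
                continue
            if strategy.name != "same_genome":
                pos = make_positive(pair.anchor, strategy, rng)
                pair = SequencePair(anchor=pair.anchor, positive=pos,
                                    genome_id=pair.genome_id)
            pairs.append(pair)
            next_round.append(g)
        usable = next_round
    return pairs
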