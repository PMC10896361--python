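"""A small transformer encoder producing fixed-size DNA embeddings.

Sequences are tokenized into non-overlapping k-mers (default k=4), passed
through pre-norm transformer blocks, and mean-pooled over the last hidden
states (masked mean when padding is present) to give the embedding f(x).

The forward pass is exposed in split form — ``forward_to_layer`` (g_m) and
``forward_from_layer`` (f_m) with f = f_m ∘ g_m — so hidden states at any
eligible layer m can be intercepted and mixed by the manifold-mixup
objective. Layer 0 means "immediately after the token/position embedding",
which lets input-level instance mixup be expressed as mixing at layer 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, embedding, gelu, layer_norm, softmax_last
from .exceptions import ConfigError, DegenerateInputError, InputError

PAD_ID = 0
UNK_ID = 1
N_SPECIALS = 2


@dataclass(frozen=True)
class EncoderConfig:
    k: int = 4
    n_layers: int = 4
    hidden_dim: int = 128
    n_heads: int = 4
    max_tokens: int = 512
    dropout_rate: float = 0.1
    ffn_mult: int = 4
    eligible_layers: Optional[tuple[int, ...]] = None  # default: all layers

    def __post_init__(self):
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.hidden_dim % self.n_heads:
            raise ConfigError("hidden_dim must be divisible by n_heads")

    @property
    def vocab_size(self) -> int:
        return 4 ** self.k + N_SPECIALS

    @property
    def layer_set(self) -> tuple[int, ...]:
        """Eligible mixing layers S; m=0 is the token-embedding output."""
        if self.eligible_layers is not None:
            return tuple(self.eligible_layers)
        return tuple(range(self.n_layers))


def _kmer_index(k: int) -> dict[str, int]:
    return {"".join(p): i + N_SPECIALS
            for i, p in enumerate(product("ACGT", repeat=k))}


_KMER_CACHE: dict[int, dict[str, int]] = {}


def tokenize(seq: str, config: EncoderConfig) -> np.ndarray:
    """Non-overlapping k-mer token ids; k-mers containing N map to UNK;
    the trailing remainder (< k bases) is dropped; truncated at max_tokens."""
    k = config.k
    table = _KMER_CACHE.setdefault(k, _kmer_index(k))
    ids = [table.get(seq[i: i + k], UNK_ID)
           for i in range(0, len(seq) - k + 1, k)]
    ids = ids[: config.max_tokens]
    if not ids:
        raise DegenerateInputError(f"sequence of length {len(seq)} yields no tokens")
    return np.asarray(ids, dtype=np.int64)


@dataclass
class HiddenState:
    """Per-token activations intercepted at layer `layer_index` (g_m output)."""

    values: Tensor          # (B, T, D)
    mask: np.ndarray        # (B, T) 1.0 for real tokens
    layer_index: int


class TransformerEncoder:
    """Pre-norm transformer over k-mer tokens with masked mean pooling."""

    def __init__(self, config: EncoderConfig, seed: int = 0,
                 params: Optional[dict[str, Tensor]] = None):
        self.config = config
        if params is not None:
            self.params = params
        else:
            self.params = self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        c = self.config
        D, F = c.hidden_dim, c.hidden_dim * c.ffn_mult

        def w(*shape, scale=0.02):
            return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        p = {"tok_emb": w(c.vocab_size, D), "pos_emb": w(c.max_tokens, D),
             "lnf_g": ones(D), "lnf_b": zeros(D)}
        for i in range(c.n_layers):
            p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"] = ones(D), zeros(D)
            p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"] = ones(D), zeros(D)
            for name in ("wq", "wk", "wv", "wo"):
                p[f"l{i}.{name}"] = w(D, D)
                p[f"l{i}.b{name[1]}"] = zeros(D)
            p[f"l{i}.w1"], p[f"l{i}.b1"] = w(D, F), zeros(F)
            p[f"l{i}.w2"], p[f"l{i}.b2"] = w(F, D), zeros(D)
        return p

    # -- internals ---------------------------------------------------------
    def _dropout(self, x: Tensor, training: bool,
                 rng: Optional[np.random.Generator]) -> Tensor:
        p = self.config.dropout_rate
        if not training or p <= 0.0:
            return x
        if rng is None:
            raise InputError("training-mode forward needs an rng for dropout")
        keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
        return x * keep

    def _attention(self, x: Tensor, i: int, mask: np.ndarray,
                   training: bool, rng) -> Tensor:
        c, p = self.config, self.params
        B, T, D = x.shape
        H, hd = c.n_heads, c.hidden_dim // c.n_heads

        def split(t):  # (B,T,D) -> (B,H,T,hd)
            return t.reshape(B, T, H, hd).swapaxes(1, 2)

        q = split(x @ p[f"l{i}.wq"] + p[f"l{i}.bq"])
        k = split(x @ p[f"l{i}.wk"] + p[f"l{i}.bk"])
        v = split(x @ p[f"l{i}.wv"] + p[f"l{i}.bv"])
        scores = (q @ k.T) * (1.0 / np.sqrt(hd))       # (B,H,T,T)
        neg = (1.0 - mask)[:, None, None, :] * -1e9    # mask out PAD keys
        attn = softmax_last(scores + neg)
        attn = self._dropout(attn, training, rng)
        out = (attn @ v).swapaxes(1, 2).reshape(B, T, D)
        return out @ p[f"l{i}.wo"] + p[f"l{i}.bo"]

    def _block(self, x: Tensor, i: int, mask: np.ndarray,
               training: bool, rng) -> Tensor:
        p = self.params
        h = layer_norm(x, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
        x = x + self._dropout(self._attention(h, i, mask, training, rng),
                              training, rng)
        h = layer_norm(x, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
        h = gelu(h @ p[f"l{i}.w1"] + p[f"l{i}.b1"]) @ p[f"l{i}.w2"] + p[f"l{i}.b2"]
        return x + self._dropout(h, training, rng)

    @staticmethod
    def _pad(token_lists: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        T = max(len(t) for t in token_lists)
        ids = np.full((len(token_lists), T), PAD_ID, dtype=np.int64)
        mask = np.zeros((len(token_lists), T))
        for b, t in enumerate(token_lists):
            ids[b, : len(t)] = t
            mask[b, : len(t)] = 1.0
        return ids, mask

    # -- split forward (f = f_m ∘ g_m) --------------------------------------
    def forward_to_layer(self, token_lists: Sequence[np.ndarray], m: int,
                         training: bool = False, rng=None) -> HiddenState:
        """g_m: embed tokens and run the first m transformer blocks."""
        c = self.config
        # 0 (token-embedding output) and n_layers (pooling only) are always
        # valid split points; anything else must be in the eligible set S
        if m not in set(c.layer_set) | {0, c.n_layers}:
            raise InputError(f"layer {m} not in eligible set {c.layer_set}")
        for t in token_lists:
            if t.size == 0:
                raise DegenerateInputError("empty token list")
            if t.max() >= c.vocab_size:
                raise InputError(f"token id {t.max()} out of vocabulary")
        ids, mask = self._pad(token_lists)
        x = embedding(self.params["tok_emb"], ids)
        x = x + embedding(self.params["pos_emb"], np.arange(ids.shape[1]))
        x = self._dropout(x, training, rng)
        for i in range(m):
            x = self._block(x, i, mask, training, rng)
        return HiddenState(values=x, mask=mask, layer_index=m)

    def forward_from_layer(self, h: HiddenState, m: int,
                           training: bool = False, rng=None) -> Tensor:
        """f_m: run blocks m..n_layers-1, final layer norm, masked mean-pool."""
        if m != h.layer_index:
            raise InputError(f"hidden state is at layer {h.layer_index}, not {m}")
        x, mask = h.values, h.mask
        for i in range(m, self.config.n_layers):
            x = self._block(x, i, mask, training, rng)
        x = layer_norm(x, self.params["lnf_g"], self.params["lnf_b"])
        denom = mask.sum(axis=1, keepdims=True)
        return (x * mask[:, :, None]).sum(axis=1) * (1.0 / denom)

    def forward(self, token_lists: Sequence[np.ndarray],
                training: bool = False, rng=None) -> Tensor:
        """f(x): full pass; mean pooling of the last hidden states. (B, D)."""
        return self.forward_from_layer(
            self.forward_to_layer(token_lists, 0, training, rng), 0,
            training, rng)

    # -- convenience ---------------------------------------------------------
    def embed_sequences(self, seqs: Sequence[str], batch_size: int = 64,
                        training: bool = False, rng=None) -> np.ndarray:
        """Deterministic (eval-mode by default) embeddings for raw sequences."""
        from .autodiff import free_graph

        rows = []
        for start in range(0, len(seqs), batch_size):
            chunk = seqs[start: start + batch_size]
            toks = [tokenize(s, self.config) for s in chunk]
            out = self.forward(toks, training=training, rng=rng)
            rows.append(out.data)
            free_graph(out)
        return np.vstack(rows)

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "TransformerEncoder":
        with np.load(path) as npz:
            cfg = json.loads(bytes(npz["__config__"]).decode())
            if cfg.get("eligible_layers") is not None:
                cfg["eligible_layers"] = tuple(cfg["eligible_layers"])
            config = EncoderConfig(**cfg)
            params = {k: Tensor(npz[k], requires_grad=True)
                      for k in npz.files if k != "__config__"}
        return cls(config, params=params)

    def clone(self) -> "TransformerEncoder":
        params = {k: Tensor(v.data.copy(), requires_grad=True)
                  for k, v in self.params.items()}
        return TransformerEncoder(self.config, params=params)
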