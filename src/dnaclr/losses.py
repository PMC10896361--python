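"""Contrastive objectives: Weighted SimCLR, MI-Mix, and i-Mix.

All losses operate on a batch of B positive pairs. Weighted SimCLR treats the
other 2B−2 samples in the batch as negatives and reweights each negative by
exp(s/τ) normalized to mean 1 over the negative set, so hard negatives (close
to the anchor) count more; the anchor's own positive keeps weight 1. The
batch loss averages the per-anchor loss over both directions (x_i and x_i+
each serve as anchor).

MI-Mix mixes the hidden states of two anchors at a random encoder layer with
per-anchor Beta(α,α) weights and trains the mixed anchor against a
correspondingly mixed virtual label. Its contrast set is restricted to the B
positives {f(x_k+)}, with the negative-weight normalizer averaging over the
B−1 indices k ≠ i. i-Mix is the same construction with the mixing applied at
the input (token-embedding) layer.

Functions accept numpy arrays or autodiff Tensors; they return a Tensor whose
``.item()`` is the loss value and through which gradients flow.

Numerical note: the weighted softmax is stabilized by subtracting the
(detached) per-row max logit before exponentiation; both the weights and the
loss are invariant to this shift, so the stabilization is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, l2_normalize
from .exceptions import BatchSizeError, InputError

DEFAULT_TEMPERATURE = 0.05
DEFAULT_BETA_ALPHA = 1.0


@dataclass(frozen=True)
class LossConfig:
    temperature: float = DEFAULT_TEMPERATURE
    beta_alpha: float = DEFAULT_BETA_ALPHA

    def __post_init__(self):
        if self.temperature <= 0:
            raise InputError("temperature must be > 0")
        if self.beta_alpha <= 0:
            raise InputError("beta_alpha must be > 0")


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; raises on zero vectors."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise InputError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def one_hot(b: int, i: int) -> np.ndarray:
    v = np.zeros(b)
    v[i] = 1.0
    return v


def validate_virtual_label(v: np.ndarray, atol: float = 1e-9) -> None:
    v = np.asarray(v, float)
    if np.any(v < -atol) or abs(v.sum() - 1.0) > atol:
        raise InputError("virtual label must be non-negative and sum to 1")


def mix_labels(v_i: np.ndarray, v_hat: np.ndarray, lam: float) -> np.ndarray:
    """v_mix = λ v_i + (1−λ) v_hat for one-hot virtual labels."""
    v_i, v_hat = np.asarray(v_i, float), np.asarray(v_hat, float)
    for v in (v_i, v_hat):
        if not (np.isin(v, (0.0, 1.0)).all() and v.sum() == 1.0):
            raise InputError("mix_labels expects one-hot inputs")
    return lam * v_i + (1.0 - lam) * v_hat


def mixed_label_matrix(lambdas: np.ndarray, permutation: np.ndarray) -> np.ndarray:
    """(B, B) matrix whose i-th row is λ_i e_i + (1−λ_i) e_{perm(i)}."""
    b = len(lambdas)
    eye = np.eye(b)
    return lambdas[:, None] * eye + (1.0 - lambdas)[:, None] * eye[permutation]


def mix_hidden(g_i, g_hat, lam):
    """Elementwise convex combination λ g_i + (1−λ) g_hat of hidden states.

    `lam` may be a scalar or a per-anchor vector (broadcast over trailing
    token/feature axes).
    """
    g_i = g_i if isinstance(g_i, Tensor) else Tensor(g_i)
    g_hat = g_hat if isinstance(g_hat, Tensor) else Tensor(g_hat)
    if g_i.shape != g_hat.shape:
        raise InputError(f"shape mismatch {g_i.shape} vs {g_hat.shape}")
    lam = np.asarray(lam, float)
    if lam.ndim == 1:
        lam = lam.reshape((-1,) + (1,) * (len(g_i.shape) - 1))
    return g_i * lam + g_hat * (1.0 - lam)


# ---------------------------------------------------------------------------
# Weighted SimCLR (both-direction batch loss over 2B anchors)


def _as_tensor(z) -> Tensor:
    return z if isinstance(z, Tensor) else Tensor(z)


def _weighted_simclr_all_losses(z_anchor, z_pos, tau: float) -> Tensor:
    """(2B,) per-anchor Weighted SimCLR losses; rows 0..B-1 use x_i as the
    anchor, rows B..2B-1 use x_i+ (roles exchanged)."""
    za, zp = _as_tensor(z_anchor), _as_tensor(z_pos)
    b = za.shape[0]
    if b < 2:
        raise BatchSizeError("Weighted SimCLR needs B >= 2 (no negatives)")
    if zp.shape != za.shape:
        raise InputError("anchor/positive shape mismatch")
    z = l2_normalize(concat([za, zp], axis=0))        # (2B, D)
    logits = (z @ z.T) * (1.0 / tau)                  # (2B, 2B)
    n = 2 * b
    eye = np.eye(n)
    partner = np.roll(eye, b, axis=1)                 # 1 at (i, i+B mod 2B)
    negmask = 1.0 - eye - partner
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    e = (logits - shift).exp()
    neg_mean = (e * negmask).sum(axis=1, keepdims=True) * (1.0 / (n - 2))
    alpha = e / neg_mean
    weights = alpha * negmask + partner               # α_{ii+} = 1, diag 0
    denom = (weights * e).sum(axis=1)                 # Σ_{j≠i} α_ij exp(s_ij/τ)
    log_pos = ((logits - shift) * partner).sum(axis=1)
    return -(log_pos - denom.log())


def weighted_simclr_anchor_loss(i: int, z_anchor, z_pos,
                                tau: float = DEFAULT_TEMPERATURE) -> float:
    """ℓ(f(x_i), v_i) for anchor i (0..2B-1; i >= B addresses x_{i−B}+)."""
    losses = _weighted_simclr_all_losses(z_anchor, z_pos, tau)
    return float(losses.data[i])


def weighted_simclr_batch_loss(z_anchor, z_pos,
                               tau: float = DEFAULT_TEMPERATURE) -> Tensor:
    """L = (1/2B) Σ_i [ℓ(f(x_i), v_i) + ℓ(f(x_i+), v_i)]."""
    return _weighted_simclr_all_losses(z_anchor, z_pos, tau).mean()


def simclr_negative_weights(i: int, z_all: np.ndarray,
                            tau: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Weights α_ij over the 2B batch positions for anchor i.

    Entry at the positive partner is 1 (by convention), at i itself 0, and at
    each of the 2B−2 negatives exp(s_ij/τ) normalized to mean 1.
    """
    z_all = np.asarray(z_all, float)
    n = z_all.shape[0]
    if n < 4 or n % 2:
        raise BatchSizeError("need 2B embeddings with B >= 2")
    b = n // 2
    zn = z_all / np.linalg.norm(z_all, axis=1, keepdims=True)
    s = zn @ zn[i] / tau
    s = s - s.max()
    e = np.exp(s)
    partner = (i + b) % n
    negs = [j for j in range(n) if j not in (i, partner)]
    w = np.zeros(n)
    w[negs] = e[negs] / e[negs].mean()
    w[partner] = 1.0
    return w


# ---------------------------------------------------------------------------
# MI-Mix / i-Mix


def _mimix_all_losses(z_mixed, z_pos, v_mix: np.ndarray, tau: float) -> Tensor:
    zm, zp = _as_tensor(z_mixed), _as_tensor(z_pos)
    b = zm.shape[0]
    if b < 2:
        raise BatchSizeError("MI-Mix needs B >= 2 (no negatives)")
    if zp.shape[0] != b:
        raise InputError("mixed-anchor/positive batch size mismatch")
    v_mix = np.asarray(v_mix, float)
    if v_mix.shape != (b, b):
        raise InputError(f"v_mix must be ({b}, {b})")
    logits = (l2_normalize(zm) @ l2_normalize(zp).T) * (1.0 / tau)  # (B, B)
    eye = np.eye(b)
    negmask = 1.0 - eye
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    e = (logits - shift).exp()
    neg_mean = (e * negmask).sum(axis=1, keepdims=True) * (1.0 / (b - 1))
    alpha = e / neg_mean
    weights = alpha * negmask + eye                   # α_{ii+} = 1
    denom = (weights * e).sum(axis=1)                 # Σ_{j=1..B} α_ij+ exp(·)
    logp = (logits - shift) - denom.log().reshape(b, 1)
    return -(Tensor(v_mix) * logp).sum(axis=1)


def mimix_anchor_loss(i: int, z_mixed, z_pos, v_mix: np.ndarray,
                      tau: float = DEFAULT_TEMPERATURE) -> float:
    """ℓ̂(f_m(h_i^m), v_i^mix): cross-entropy of the weighted softmax over the
    B positives against the mixed virtual label."""
    return float(_mimix_all_losses(z_mixed, z_pos, v_mix, tau).data[i])


def mimix_batch_loss(z_mixed, z_pos, v_mix: np.ndarray,
                     tau: float = DEFAULT_TEMPERATURE) -> Tensor:
    """L̂ = (1/B) Σ_i ℓ̂(f_m(h_i^m), v_i^mix)."""
    return _mimix_all_losses(z_mixed, z_pos, v_mix, tau).mean()


def mimix_negative_weights(i: int, z_mixed: np.ndarray, z_pos: np.ndarray,
                           tau: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Weights α_ij+ over the B positives for mixed anchor i (α_ii+ = 1)."""
    zm = np.asarray(z_mixed, float)
    zp = np.asarray(z_pos, float)
    b = zp.shape[0]
    if b < 2:
        raise BatchSizeError("need B >= 2")
    zi = zm[i] / np.linalg.norm(zm[i])
    zpn = zp / np.linalg.norm(zp, axis=1, keepdims=True)
    s = zpn @ zi / tau
    s = s - s.max()
    e = np.exp(s)
    negs = [j for j in range(b) if j != i]
    w = np.empty(b)
    w[negs] = e[negs] / e[negs].mean()
    w[i] = 1.0
    return w


def imix_batch_loss(z_mixed_input, z_pos, v_mix: np.ndarray,
                    tau: float = DEFAULT_TEMPERATURE) -> Tensor:
    """i-Mix: instance mixup at the input layer. Under the layer convention
    used here (layer 0 = token-embedding output) this is MI-Mix with m = 0,
    so the loss computation is identical."""
    return mimix_batch_loss(z_mixed_input, z_pos, v_mix, tau)
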