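"""Independent brute-force oracles shared by the test modules.

These implementations form full similarity/contingency tables and evaluate
every term of the definitions literally; they share no code with the package.
"""

import numpy as np


def oracle_weighted_simclr(za, zp, tau):
    """Per-anchor weighted-softmax losses over all 2B anchors."""
    Z = np.vstack([za, zp])
    n = len(Z)
    b = n // 2
    Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    s = Zn @ Zn.T
    per_anchor = []
    for i in range(n):
        partner = (i + b) % n
        negs = [k for k in range(n) if k not in (i, partner)]
        norm = np.mean([np.exp(s[i, k] / tau) for k in negs])

        def alpha(j):
            return 1.0 if j == partner else np.exp(s[i, j] / tau) / norm

        denom = sum(alpha(j) * np.exp(s[i, j] / tau)
                    for j in range(n) if j != i)
        per_anchor.append(-np.log(np.exp(s[i, partner] / tau) / denom))
    return per_anchor


def oracle_nt_xent(za, zp, tau):
    """Standard NT-Xent (all weights equal to one)."""
    Z = np.vstack([za, zp])
    n = len(Z)
    b = n // 2
    Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    s = Zn @ Zn.T
    total = 0.0
    for i in range(n):
        partner = (i + b) % n
        denom = sum(np.exp(s[i, j] / tau) for j in range(n) if j != i)
        total += -np.log(np.exp(s[i, partner] / tau) / denom)
    return total / n


def oracle_mimix(zm, zp, lambdas, perm, tau):
    """Mixed-anchor loss over the positive-only contrast set."""
    b = len(zp)
    zmn = zm / np.linalg.norm(zm, axis=1, keepdims=True)
    zpn = zp / np.linalg.norm(zp, axis=1, keepdims=True)
    s = zmn @ zpn.T
    eye = np.eye(b)
    vmix = lambdas[:, None] * eye + (1 - lambdas)[:, None] * eye[perm]
    total = 0.0
    for i in range(b):
        norm = np.mean([np.exp(s[i, k] / tau) for k in range(b) if k != i])

        def alpha(j):
            return 1.0 if j == i else np.exp(s[i, j] / tau) / norm

        denom = sum(alpha(j) * np.exp(s[i, j] / tau) for j in range(b))
        total += -sum(vmix[i, n] * np.log(np.exp(s[i, n] / tau) / denom)
                      for n in range(b))
    return total / b


def textbook_ari(a, b):
    """ARI from the contingency-table formula."""
    from math import comb

    a, b = list(a), list(b)
    cats_a, cats_b = sorted(set(a)), sorted(set(b))
    n = len(a)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for x, y in zip(a, b):
        table[cats_a.index(x), cats_b.index(y)] += 1
    sum_comb = sum(comb(int(nij), 2) for nij in table.reshape(-1))
    sum_a = sum(comb(int(ni), 2) for ni in table.sum(axis=1))
    sum_b = sum(comb(int(nj), 2) for nj in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return (sum_comb - expected) / (max_index - expected)
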