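"""Shared fixtures: small stacks, occurrence sets and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import nichedyn as nd


@pytest.fixture(scope="session")
def small_stack():
    return nd.make_env_stack(16, 16, 3, [1.0, 1.0, 1.0], noise_scale=0.05,
                             seed=42)


@pytest.fixture(scope="session")
def noshift_scenario():
    """Identical niches in both ranges; dense sampling."""
    return nd.make_invasion_scenario({
        "seed": 3, "n_rows": 32, "n_cols": 32,
        "n_native": 300, "n_invaded": 400})


@pytest.fixture(scope="session")
def shift_scenario():
    """Invaded niche displaced far outside the native occupied envelope."""
    return nd.make_invasion_scenario({
        "seed": 3, "n_rows": 32, "n_cols": 32,
        "n_native": 300, "n_invaded": 400,
        "native_breadth": [0.08] * 4,
        "native_centre_cell": (26, 26), "invaded_centre_cell": (5, 5)})


# ---------------------------------------------------------------- oracles

def schoener_d_oracle(z1, z2, mask=None):
    """Direct formula evaluation over explicit Python loops."""
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    if mask is None:
        mask = np.ones_like(z1, dtype=bool)
    s1 = sum(z1[i, j] for i in range(z1.shape[0]) for j in range(z1.shape[1])
             if mask[i, j])
    s2 = sum(z2[i, j] for i in range(z1.shape[0]) for j in range(z1.shape[1])
             if mask[i, j])
    total = 0.0
    for i in range(z1.shape[0]):
        for j in range(z1.shape[1]):
            if mask[i, j]:
                total += abs(z1[i, j] / s1 - z2[i, j] / s2)
    return 1.0 - 0.5 * total


def kde_oracle(scores, bounds, R, bw):
    """Per-cell double loop over points and grid cells."""
    scores = np.atleast_2d(np.asarray(scores, float))
    hx, hy = bw
    out = np.zeros((R, R))
    cx = [bounds[0][0] + (i + 0.5) * (bounds[0][1] - bounds[0][0]) / R
          for i in range(R)]
    cy = [bounds[1][0] + (j + 0.5) * (bounds[1][1] - bounds[1][0]) / R
          for j in range(R)]
    for i in range(R):
        for j in range(R):
            acc = 0.0
            for (sx, sy) in scores:
                acc += np.exp(-0.5 * ((cx[i] - sx) / hx) ** 2) * \
                       np.exp(-0.5 * ((cy[j] - sy) / hy) ** 2)
            out[i, j] = acc / (len(scores) * 2 * np.pi * hx * hy)
    return out


def auc_oracle(scores, labels):
    """Pair-counting Mann-Whitney AUC with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def max_sss_oracle(scores, labels):
    """Scan every candidate midpoint; return (threshold, best sens+spec)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    uniq = np.unique(scores)
    best_t, best_v = None, -np.inf
    for t in 0.5 * (uniq[:-1] + uniq[1:]):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / labels.sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        if sens + spec > best_v + 1e-12:
            best_t, best_v = t, sens + spec
    return best_t, best_v
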