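import numpy as np
import pytest

import rimpipe as rp


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic noise-free phantom reused by read-only tests."""
    cfg = rp.PhantomConfig(n_rim_pos=4, n_rim_neg=10, n_artefacts=2, seed=7)
    vs, gt = rp.generate_phantom(cfg)
    return cfg, vs, gt


@pytest.fixture(scope="session")
def noisy_phantom():
    cfg = rp.PhantomConfig(n_rim_pos=3, n_rim_neg=8, n_artefacts=1,
                           noise_sd=2.0, bias_field_amplitude=0.2, seed=11)
    vs, gt = rp.generate_phantom(cfg)
    return cfg, vs, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def flood_fill_components(mask):
    """Independent BFS flood-fill oracle for 6-connected components."""
    mask = np.asarray(mask).astype(bool)
    visited = np.zeros_like(mask)
    comps = []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
               (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for start in np.argwhere(mask):
        start = tuple(start)
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = []
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                if all(0 <= q[i] < mask.shape[i] for i in range(3)) \
                        and mask[q] and not visited[q]:
                    visited[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


def brute_force_auc(scores, labels):
    """Pairwise-comparison ROC AUC with ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s_pos in pos:
        for s_neg in neg:
            if s_pos > s_neg:
                total += 1.0
            elif s_pos == s_neg:
                total += 0.5
    return total / (len(pos) * len(neg))
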