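import numpy as np
import pytest

import protovol as pv


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest useful encoder: fast enough for per-test builds."""
    return pv.EncoderSpec(arch="tiny3d", channels=(3, 4), embedding_dim=8,
                          input_shape=(4, 8, 8))


@pytest.fixture(scope="session")
def tiny_synth_cfg():
    return pv.SyntheticConfig(n_patients=24, exams_per_patient=1,
                              volume_shape=(4, 8, 8), lesion_contrast=3.0,
                              lesion_radius_voxels=2.0, seed=7)


@pytest.fixture(scope="session")
def tiny_pool(tiny_synth_cfg):
    return pv.simulate_dataset(tiny_synth_cfg)


def naive_ge2e_loss(E: np.ndarray, w: float = 1.0, b: float = 0.0,
                    self_exclusion: bool = False) -> float:
    """Independent triple-loop evaluation of the GE2E loss formula.

    L = sum_ij [ -S_ji,i + log sum_k exp(S_ji,k) ] with
    S_ji,k = w*cos(f_ij, C_k) + b. Written with explicit loops and plain
    cosine arithmetic so it shares nothing with the vectorised path.
    """
    n, m, _ = E.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            f = E[i, j]
            sims = []
            for k in range(n):
                if self_exclusion and k == i:
                    members = [E[k, jj] for jj in range(m) if jj != j]
                else:
                    members = [E[k, jj] for jj in range(m)]
                c = sum(members) / len(members)
                cos = float(np.dot(f, c) / (np.linalg.norm(f) * np.linalg.norm(c)))
                sims.append(w * cos + b)
            total += -sims[i] + float(np.log(sum(np.exp(s) for s in sims)))
    return total


def pairwise_auc(scores, labels) -> float:
    """Brute-force O(n^2) Mann-Whitney AUC with 0.5 tie credit."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
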