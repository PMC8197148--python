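"""Shared fixtures: synthetic datasets, feature tables, and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from histostack import SyntheticConfig, generate_dataset, scan_dataset
from histostack.fusion import build_table


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(n_per_class=12, seed=7)


@pytest.fixture(scope="session")
def small_root(tmp_path_factory, small_cfg):
    root = tmp_path_factory.mktemp("synth_small")
    generate_dataset(small_cfg, root)
    return root


@pytest.fixture(scope="session")
def small_manifest(small_root):
    return scan_dataset(small_root)


@pytest.fixture(scope="session")
def small_table(small_manifest):
    """24-patch fused feature table (all four families, 782 columns)."""
    return build_table(small_manifest)


@pytest.fixture(scope="session")
def small_haralick_table(small_table):
    """Cheap 14-column projection for learner-heavy tests."""
    return small_table.restrict(["HARALICK"])


@pytest.fixture(scope="session")
def default_cfg():
    """The default study conditions: 200 patches per class, seed 1."""
    return SyntheticConfig(n_per_class=200, seed=1)


@pytest.fixture(scope="session")
def default_root(tmp_path_factory, default_cfg):
    root = tmp_path_factory.mktemp("synth_default")
    generate_dataset(default_cfg, root)
    return root


@pytest.fixture(scope="session")
def default_table(default_root):
    """Full 400 x 782 feature table under the default study conditions."""
    return build_table(scan_dataset(default_root))


def brute_force_haralick(P, base: float = 2.0) -> list[float]:
    """Independent loop-based evaluation of the 14 Haralick statistics.

    Written against the textbook formulas with explicit Python loops; shares
    no code with histostack.glcm.  Output order matches the package's fixed
    ordering.
    """
    L = len(P)
    P = [[float(P[i][j]) for j in range(L)] for i in range(L)]
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mux = sum(i * px[i] for i in range(L))
    muy = sum(j * py[j] for j in range(L))
    sx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(L)))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(L)))

    def ent(ps):
        return -sum(p * math.log(p, base) for p in ps if p > 0)

    asm = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * P[i][j] for i in range(L) for j in range(L))
    if sx > 0 and sy > 0:
        corr = (sum(i * j * P[i][j] for i in range(L) for j in range(L)) - mux * muy) / (sx * sy)
    else:
        corr = 0.0
    variance = sum((i - mux) ** 2 * P[i][j] for i in range(L) for j in range(L))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]
    sum_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_ent = ent(p_sum)
    entropy = ent([P[i][j] for i in range(L) for j in range(L)])
    dmean = sum(k * p_diff[k] for k in range(L))
    diff_var = sum((k - dmean) ** 2 * p_diff[k] for k in range(L))
    diff_ent = ent(p_diff)

    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        P[i][j] * math.log(px[i] * py[j], base)
        for i in range(L)
        for j in range(L)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log(px[i] * py[j], base)
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - base ** (-2.0 * (hxy2 - entropy))))

    nzx = [i for i in range(L) if px[i] > 0]
    nzy = [j for j in range(L) if py[j] > 0]
    if len(nzx) < 2 or len(nzy) < 2:
        mcc = 0.0
    else:
        Q = [
            [
                sum(P[a][k] * P[b][k] / (px[a] * py[k]) for k in nzy)
                for b in nzx
            ]
            for a in nzx
        ]
        eig = sorted(np.real(np.linalg.eigvals(np.array(Q))))
        mcc = math.sqrt(max(eig[-2], 0.0))

    return [
        corr, variance, idm, sum_avg, sum_var, sum_ent, entropy,
        imc2, mcc, diff_var, diff_ent, imc1, asm, contrast,
    ]


@pytest.fixture(scope="session")
def haralick_oracle():
    return brute_force_haralick


def random_symmetric_glcm(rng: np.random.Generator, size: int, sparsity: float = 0.3) -> np.ndarray:
    """A random normalized symmetric co-occurrence matrix with some zero cells."""
    M = rng.random((size, size))
    M[rng.random((size, size)) < sparsity] = 0.0
    M = M + M.T
    if M.sum() == 0:
        M[0, 0] = 1.0
    return M / M.sum()
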