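"""Shared fixtures: small synthetic screens and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import lsq_linear, minimize

import tilescan as ts


@pytest.fixture(scope="session")
def small_sim() -> ts.SimScreen:
    """A compact screen (8 genes) for fast integration tests."""
    return ts.simulate_screen(
        ts.SimConfig(n_genes=8, protein_length_range=(300, 500), seed=11)
    )


@pytest.fixture(scope="session")
def small_scores(small_sim) -> ts.ScreenScores:
    scores = ts.score_screen(small_sim.counts, small_sim.library)
    filtered, _ = ts.filter_guides(scores, drop={"tttt"})
    return filtered


@pytest.fixture()
def toy_count_matrix() -> ts.CountMatrix:
    counts = pd.DataFrame(
        {
            "A_r1_initial": [100, 100, 100],
            "A_r1_final": [100, 200, 0],
            "A_r2_initial": [100, 100, 100],
            "A_r2_final": [100, 200, 0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="guide_id"),
    )
    samples = pd.DataFrame(
        {
            "sample": ["A_r1_initial", "A_r1_final", "A_r2_initial", "A_r2_final"],
            "cell_line": ["A", "A", "A", "A"],
            "replicate": [1, 1, 2, 2],
            "timepoint": ["initial", "final", "initial", "final"],
        }
    ).set_index("sample")
    return ts.CountMatrix(counts=counts, samples=samples)


def fused_lasso_oracle(y, lambda0, lambda1):
    """Independent exact solver via the Fenchel dual: a box-constrained
    least-squares problem solved by scipy's BVLS."""
    y = np.asarray(y, float)
    n = len(y)
    B = np.zeros((n + max(n - 1, 0), n))
    for i in range(n):
        B[i, i] = lambda0
    for i in range(n - 1):
        B[n + i, i + 1] = lambda1
        B[n + i, i] = -lambda1
    res = lsq_linear(B.T, y, bounds=(-1, 1), tol=1e-15, max_iter=5000, method="bvls")
    return y - B.T @ res.x


def transformed_oracle(y, cfg):
    """Independent dense minimization of the transformed objective:
    |t| smoothed as sqrt(t^2+eps^2) with eps-continuation, analytic
    gradients, L-BFGS-B from two starts."""
    y = np.asarray(y, float)
    n = len(y)

    def make(eps):
        def fg(x):
            r = x - y
            val = 0.5 * np.dot(r, r)
            grad = r.copy()
            for vec, lam, a, is_diff in (
                (x, cfg.lambda0, cfg.a0, False),
                (np.diff(x), cfg.lambda1, cfg.a1, True),
            ):
                s = np.sqrt(vec * vec + eps * eps)
                if a < 1e-12:
                    val += lam * np.sum(s)
                    g = lam * vec / s
                else:
                    val += lam * np.sum((1.0 - np.exp(-a * s)) / a)
                    g = lam * np.exp(-a * s) * vec / s
                if is_diff:
                    grad[1:] += g
                    grad[:-1] -= g
                else:
                    grad += g
            return val, grad

        return fg

    best = None
    for start in (y.copy(), np.zeros(n)):
        x0 = start
        for eps in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8, 1e-9):
            res = minimize(
                make(eps), x0, jac=True, method="L-BFGS-B",
                options=dict(maxiter=5000, ftol=1e-16, gtol=1e-14),
            )
            x0 = res.x
        if best is None or res.fun < best[0]:
            best = (res.fun, x0)
    return best[1]


def random_convex_config(rng) -> ts.SolverConfig:
    """A random config satisfying the convexity gate (budget split evenly)."""
    l0 = rng.uniform(0, 0.5)
    l1 = rng.uniform(0, 2.0)
    a0 = min(rng.uniform(0, 2), 0.45 / max(l0, 1e-9))
    a1 = min(rng.uniform(0, 2), 0.45 / (4 * max(l1, 1e-9)))
    return ts.SolverConfig(lambda0=l0, lambda1=l1, a0=a0, a1=a1)
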