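"""Independent oracles for the test suite.

Closed-form Gaussian information quantities (from covariance matrices,
solving the stationary covariance of linear systems with the discrete
Lyapunov equation) and exact plug-in estimates on discrete joints.  These
never call the package's estimators.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

LN2 = float(np.log(2.0))


# -- Gaussian closed forms ----------------------------------------------


def _logdet(cov: np.ndarray, idx: list[int]) -> float:
    if not idx:
        return 0.0
    return float(np.linalg.slogdet(cov[np.ix_(idx, idx)])[1])


def gauss_mi(cov: np.ndarray, ia: list[int], ib: list[int]) -> float:
    """I(A;B) in bits for jointly Gaussian blocks of a covariance matrix."""
    return 0.5 * (_logdet(cov, ia) + _logdet(cov, ib) - _logdet(cov, ia + ib)) / LN2


def gauss_cmi(cov: np.ndarray, ia: list[int], ib: list[int], ic: list[int]) -> float:
    """I(A;B|C) in bits."""
    return (
        0.5
        * (
            _logdet(cov, ia + ic)
            + _logdet(cov, ib + ic)
            - _logdet(cov, ic)
            - _logdet(cov, ia + ib + ic)
        )
        / LN2
    )


def random_covariance(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Random well-conditioned SPD covariance matrix."""
    a = rng.normal(size=(dim, dim))
    cov = a @ a.T + dim * np.eye(dim)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def pulse_community_cov(
    a: float, c: float, b: float, sigma: float = 1.0, n_siblings: int = 7
) -> np.ndarray:
    """Exact stationary covariance of (x_t, x_{t+1}, C_t) for the shared-pulse
    community model: private AR(1) cores plus an iid common pulse entering
    the observation at weights (c, b) for lags (0, 1)."""
    v_r = sigma**2 / (1.0 - a * a)
    s = np.empty((3, 3))
    s[0, 0] = s[1, 1] = v_r + c * c + b * b
    s[2, 2] = v_r / n_siblings + c * c + b * b
    s[0, 1] = s[1, 0] = a * v_r + c * b
    s[0, 2] = s[2, 0] = c * c + b * b
    s[1, 2] = s[2, 1] = c * b
    return s


def drive_community_cov(
    a: float,
    coupling: float,
    persistence: float,
    shared_sd: float = 1.0,
    sigma: float = 1.0,
    n_siblings: int = 7,
) -> np.ndarray:
    """Exact stationary covariance of (x_t, x_{t+1}, C_t) for the persistent
    shared-drive community model, via the discrete Lyapunov equation for the
    filtered drive (H, h) subsystem."""
    A = np.array([[a, 1.0], [0.0, persistence]])
    B = np.array([[0.0], [shared_sd]])
    su = solve_discrete_lyapunov(A, B @ B.T)
    v_h, c_hh = su[0, 0], su[0, 1]
    v_p = sigma**2 / (1.0 - a * a)
    c_h_next = a * v_h + c_hh  # Cov(H_t, H_{t+1})
    g = coupling
    s = np.empty((3, 3))
    s[0, 0] = s[1, 1] = g * g * v_h + v_p
    s[0, 1] = s[1, 0] = g * g * c_h_next + a * v_p
    s[0, 2] = s[2, 0] = g * g * v_h
    s[1, 2] = s[2, 1] = g * g * c_h_next
    s[2, 2] = g * g * v_h + v_p / n_siblings
    return s


# -- discrete plug-in ---------------------------------------------------


def plugin_mi(joint: np.ndarray) -> float:
    """Exact I(X;Y) in bits from a joint pmf table."""
    p = np.asarray(joint, dtype=float)
    p = p / p.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def plugin_cmi(joint3: np.ndarray) -> float:
    """Exact I(X;Y|Z) in bits from a 3-way joint pmf table (x, y, z axes)."""
    p = np.asarray(joint3, dtype=float)
    p = p / p.sum()
    pz = p.sum(axis=(0, 1))
    pxz = p.sum(axis=1)
    pyz = p.sum(axis=0)
    total = 0.0
    for i, j, k in zip(*np.nonzero(p)):
        total += p[i, j, k] * np.log2(
            p[i, j, k] * pz[k] / (pxz[i, k] * pyz[j, k])
        )
    return float(total)


def empirical_joint(x: np.ndarray, y: np.ndarray, levels: int) -> np.ndarray:
    """Empirical joint pmf of two integer-coded samples."""
    joint = np.zeros((levels, levels))
    np.add.at(joint, (x, y), 1.0)
    return joint / joint.sum()
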