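"""Gaussian Markov random field primitives for first-order random walks.

A first-order random walk (RW1) prior on a latent monthly field
``omega_1..omega_T`` penalises squared successive differences:

    pi(omega | tau) ∝ tau^((T-1)/2) * exp(-tau/2 * sum_t (omega_t - omega_{t-1})^2)

The quadratic form is ``omega' Q omega`` with the intrinsic (rank T-1)
structure matrix Q returned by :func:`rw1_structure`.  The prior is improper
in the direction of the constant vector; identifiability against an intercept
is restored by the sum-to-zero constraint, handled throughout the package by
working in the orthonormal basis of the sum-zero subspace returned by
:func:`sum_to_zero_basis`.
"""

from __future__ import annotations

import numpy as np


def rw1_structure(T: int) -> np.ndarray:
    """Structure matrix Q = D'D of a first-order random walk of length ``T``.

    Q is tridiagonal with diagonal (1, 2, ..., 2, 1) and off-diagonal -1,
    has rank T-1 and row sums 0, and satisfies
    ``x' Q x = sum_t (x_t - x_{t-1})^2`` for any vector x.
    """
    if T < 2:
        raise ValueError(f"RW1 structure needs T >= 2, got T={T}")
    D = np.diff(np.eye(T), axis=0)  # (T-1, T) first-difference matrix
    return D.T @ D


def sum_to_zero_basis(T: int) -> np.ndarray:
    """Orthonormal basis (T x (T-1)) of the subspace {x : sum(x) = 0}.

    Columns are Helmert contrasts: column k has k leading entries
    ``1/sqrt(k(k+1))`` followed by ``-k/sqrt(k(k+1))``.  The construction is
    closed-form and therefore bit-reproducible across platforms.  For any
    coefficient vector u, ``B @ u`` sums to zero exactly, and ``B' B = I``.
    """
    if T < 2:
        raise ValueError(f"sum-to-zero basis needs T >= 2, got T={T}")
    B = np.zeros((T, T - 1))
    for k in range(1, T):
        s = np.sqrt(k * (k + 1.0))
        B[:k, k - 1] = 1.0 / s
        B[k, k - 1] = -k / s
    return B


def constrained_rw1_draw(T: int, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a sum-to-zero RW1 field: cumulative Gaussian increments, centred.

    The centred cumulative sum of N(0, 1/tau) increments has exactly the law
    of the intrinsic RW1 field conditioned on summing to zero (the anchoring
    of the walk only perturbs the precision in a direction that the centring
    projection removes).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    inc = rng.normal(0.0, 1.0 / np.sqrt(tau), size=T)
    walk = np.cumsum(inc)
    return walk - walk.mean()
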