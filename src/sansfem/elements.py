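"""Tensor-product Lagrange quadrilateral elements and Gauss quadrature.

Reference element is the bi-unit square [-1, 1]^2.  Nodes of an order-``k``
element sit on an equispaced (k+1) x (k+1) lattice, numbered row-major with
the eta index slowest.  Shape functions are products of 1-D Lagrange
polynomials; everything is evaluated once per (order, rule) pair and cached.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def lagrange_1d(order: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and derivatives of 1-D Lagrange basis on equispaced nodes in [-1, 1].

    Returns ``(N, dN)`` each of shape ``(len(x), order + 1)``.
    """
    nodes = np.linspace(-1.0, 1.0, order + 1)
    x = np.asarray(x, dtype=float)
    n = order + 1
    N = np.ones((x.size, n))
    dN = np.zeros((x.size, n))
    for i in range(n):
        # product form; derivative by logarithmic differentiation per term
        others = [j for j in range(n) if j != i]
        denom = np.prod(nodes[i] - nodes[others])
        N[:, i] = np.prod(x[:, None] - nodes[others], axis=1) / denom
        d = np.zeros(x.size)
        for j in others:
            rest = [m for m in others if m != j]
            d += np.prod(x[:, None] - nodes[rest], axis=1) if rest else 1.0
        dN[:, i] = d / denom
    return N, dN


@lru_cache(maxsize=None)
def quad_rule(npts: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """1-D Gauss-Legendre rule with ``npts`` points on [-1, 1]."""
    x, w = np.polynomial.legendre.leggauss(npts)
    return tuple(x), tuple(w)


@lru_cache(maxsize=None)
def tabulate(order: int, npts_1d: int):
    """Tabulate shape functions on a tensor Gauss rule.

    Returns ``(N, dN_dxi, dN_deta, w)`` with shapes
    ``(ngp, nn)``, ``(ngp, nn)``, ``(ngp, nn)``, ``(ngp,)`` where
    ``ngp = npts_1d**2`` and ``nn = (order + 1)**2``.
    """
    gx, gw = quad_rule(npts_1d)
    gx = np.asarray(gx)
    gw = np.asarray(gw)
    N1, dN1 = lagrange_1d(order, gx)
    nn1 = order + 1
    ngp = npts_1d * npts_1d
    nn = nn1 * nn1
    N = np.empty((ngp, nn))
    dNx = np.empty((ngp, nn))
    dNe = np.empty((ngp, nn))
    w = np.empty(ngp)
    g = 0
    for b in range(npts_1d):      # eta slow
        for a in range(npts_1d):  # xi fast
            for j in range(nn1):
                for i in range(nn1):
                    idx = j * nn1 + i
                    N[g, idx] = N1[a, i] * N1[b, j]
                    dNx[g, idx] = dN1[a, i] * N1[b, j]
                    dNe[g, idx] = N1[a, i] * dN1[b, j]
            w[g] = gw[a] * gw[b]
            g += 1
    return N, dNx, dNe, w


@lru_cache(maxsize=None)
def tabulate_edge(order: int, npts_1d: int):
    """1-D boundary-edge tabulation: ``(N, dN, w)`` on ``npts_1d`` Gauss points."""
    gx, gw = quad_rule(npts_1d)
    N1, dN1 = lagrange_1d(order, np.asarray(gx))
    return N1, dN1, np.asarray(gw)
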