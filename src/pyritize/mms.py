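"""Solver verification by the method of manufactured solutions.

A smooth sulfate/sulfide pair with compatible boundary data is chosen,
the residual of the governing operators applied to it is added back as
a source term, and the solver must then recover the manufactured pair.
Two checks are reported:

1. a fixed-mesh second-order finite-difference discretization of the
   same operators, refined over several uniform meshes, whose L2 error
   must shrink at the expected order (~2);
2. the production adaptive collocation solver, whose max-norm error at
   tight tolerance must be small (~1e-8 in practice).

The manufactured pair used by default is polynomial with exactly zero
gradient at the bottom of the domain, so the production boundary
conditions apply unchanged:

    Σ*(ζ) = 1 − c_s u²(3 − 2u),    u = ζ/ζ_cap
    η*(ζ) = c_h u²(1 − u)² + η0
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp
from scipy.linalg import solve_banded

from .params import NonDimensionalParams
from .profiles import oc_gradient

__all__ = ["manufactured_pair", "fd_solve_sulfate", "verify_mms"]


def manufactured_pair(p: NonDimensionalParams, zeta_cap: float = 5.0,
                      c_s: float = 0.6, c_h: float = 0.8):
    """Manufactured (Σ*, η*) and their first/second derivatives."""
    L = zeta_cap

    def sigma(z):
        u = z / L
        return 1.0 - c_s * u**2 * (3.0 - 2.0 * u)

    def dsigma(z):
        u = z / L
        return -c_s * 6.0 * u * (1.0 - u) / L

    def d2sigma(z):
        u = z / L
        return -c_s * 6.0 * (1.0 - 2.0 * u) / L**2

    def eta(z):
        u = z / L
        return c_h * u**2 * (1.0 - u) ** 2 + p.eta0

    def deta(z):
        u = z / L
        return c_h * 2.0 * u * (1.0 - u) * (1.0 - 2.0 * u) / L

    def d2eta(z):
        u = z / L
        return c_h * 2.0 * (1.0 - 6.0 * u + 6.0 * u**2) / L**2

    return (sigma, dsigma, d2sigma), (eta, deta, d2eta)


def _sulfate_source(p: NonDimensionalParams, funcs):
    """q(ζ) such that Da* Σ*'' − Σ*' + Γ' MΣ(Σ*) + q = 0."""
    sigma, dsigma, d2sigma = funcs

    def q(z):
        s = sigma(z)
        monod = s / (p.kappa_sigma + s)
        dgam = oc_gradient(p.gamma0, p.da_star, p.a, z)
        return -(p.da_star * d2sigma(z) - dsigma(z) + dgam * monod)

    return q


def fd_solve_sulfate(
    p: NonDimensionalParams,
    source,
    n: int,
    zeta_cap: float = 5.0,
    sigma_top: float = 1.0,
    newton_tol: float = 1.0e-12,
    max_iter: int = 50,
):
    """Fixed uniform-mesh FD solve of the (forced) sulfate operator.

    Central differences for both derivatives; the zero-gradient bottom
    boundary uses the standard ghost-node reflection.  Newton iteration
    with an analytic tridiagonal Jacobian.
    """
    z = np.linspace(0.0, zeta_cap, n)
    h = z[1] - z[0]
    dgam = oc_gradient(p.gamma0, p.da_star, p.a, z)
    q = source(z) if callable(source) else np.asarray(source)
    s = np.linspace(sigma_top, sigma_top, n)  # flat start

    def monod(v):
        vc = np.maximum(v, 0.0)
        return vc / (p.kappa_sigma + vc), np.where(
            v > 0.0, p.kappa_sigma / (p.kappa_sigma + vc) ** 2, 0.0
        )

    for _ in range(max_iter):
        m, dm = monod(s)
        F = np.zeros(n)
        # interior
        F[1:-1] = (
            p.da_star * (s[:-2] - 2.0 * s[1:-1] + s[2:]) / h**2
            - (s[2:] - s[:-2]) / (2.0 * h)
            + dgam[1:-1] * m[1:-1]
            + q[1:-1]
        )
        F[0] = s[0] - sigma_top
        # ghost reflection: s[n] = s[n-2] for zero gradient
        F[-1] = (
            p.da_star * 2.0 * (s[-2] - s[-1]) / h**2
            + dgam[-1] * m[-1]
            + q[-1]
        )
        if np.max(np.abs(F)) < newton_tol:
            break
        # tridiagonal Jacobian in banded form
        ab = np.zeros((3, n))
        ab[0, 2:] = p.da_star / h**2 - 1.0 / (2.0 * h)  # superdiag
        ab[1, 1:-1] = -2.0 * p.da_star / h**2 + dgam[1:-1] * dm[1:-1]
        ab[2, :-2] = p.da_star / h**2 + 1.0 / (2.0 * h)  # subdiag
        ab[1, 0] = 1.0
        ab[0, 1] = 0.0
        ab[1, -1] = -2.0 * p.da_star / h**2 + dgam[-1] * dm[-1]
        ab[2, -2] = 2.0 * p.da_star / h**2
        ds = solve_banded((1, 1), ab, -F)
        s = s + ds
    return z, s


def verify_mms(
    p: NonDimensionalParams | None = None,
    mesh_sizes=(41, 81, 161, 321),
    zeta_cap: float = 5.0,
    collocation_tol: float = 1.0e-9,
) -> dict:
    """Convergence report for the manufactured problem.

    Returns mesh spacings, L2 errors, observed orders between levels,
    and the collocation solver's max-norm error.  Raises no exception;
    callers assert on the reported numbers.
    """
    p = p or NonDimensionalParams(gamma0=3.0, da_star=2.0, psi0=0.0)
    funcs_s, funcs_h = manufactured_pair(p, zeta_cap)
    q = _sulfate_source(p, funcs_s)

    hs, errors = [], []
    for n in mesh_sizes:
        z, s = fd_solve_sulfate(p, q, n, zeta_cap)
        exact = funcs_s[0](z)
        hs.append(z[1] - z[0])
        errors.append(float(np.sqrt(np.trapezoid((s - exact) ** 2, z))))
    orders = [
        float(np.log(errors[i - 1] / errors[i]) / np.log(hs[i - 1] / hs[i]))
        for i in range(1, len(errors))
    ]

    # collocation consistency on the same forced problem
    def fun(z, y):
        s, ds = y
        sc = np.maximum(s, 0.0)
        monod = sc / (p.kappa_sigma + sc)
        dgam = oc_gradient(p.gamma0, p.da_star, p.a, z)
        return np.vstack([ds, (ds - dgam * monod - q(z)) / p.da_star])

    def bc(ya, yb):
        return np.array([ya[0] - 1.0, yb[1]])

    mesh = np.linspace(0.0, zeta_cap, 101)
    guess = np.vstack([np.ones_like(mesh), np.zeros_like(mesh)])
    sol = solve_bvp(fun, bc, mesh, guess, tol=collocation_tol, max_nodes=100_000)
    zf = np.linspace(0.0, zeta_cap, 1001)
    colloc_err = float(np.max(np.abs(sol.sol(zf)[0] - funcs_s[0](zf))))

    return {
        "h": hs,
        "l2_errors": errors,
        "observed_orders": orders,
        "collocation_max_error": colloc_err,
        "collocation_converged": sol.status == 0,
    }
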