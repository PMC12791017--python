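"""Steady-state reaction--transport solver for the sulfidic anoxic zone.

Solves the coupled nonlinear two-point boundary-value problem for the
two isotopologues (32S, 34S) of porewater sulfate and sulfide on the
non-dimensional depth interval ζ ∈ [0, ζ_cap] (default cap 5), then
integrates the pyrite isotopologue source terms and locates the base
of the pyrite formation zone, ζmax.

Non-dimensional species:

* ``Σ``  porewater sulfate / seawater sulfate (1 at the interface),
* ``η``  porewater sulfide / seawater sulfate,
* ``Γ``  organic carbon, ``Ψ`` reactive iron (closed-form power laws),
* ``Π``  pyrite, integrated from dΠ/dζ = −dΨ/dζ · η/(κ_η + η).

Microbial sulfate reduction consumes sulfate at the rate the OC
gradient dictates, throttled by a Monod term in Σ, and partitions the
rate between isotopologues with the equilibrium fractionation factor
α34; sulfide is consumed by Fe_HR with a Monod term in η and no
isotopic fractionation.  Upper boundary: fixed seawater values.  Lower
boundary: zero gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, solve_bvp

from .params import NonDimensionalParams, delta_from_ratio
from .profiles import default_zeta_grid, fe_gradient, oc_gradient

__all__ = [
    "SolverOptions",
    "SolverError",
    "ProfileSolution",
    "solve_bulk",
    "solve_isotopologues",
    "solve_profile",
    "integrate_pyrite",
    "find_zeta_max",
    "delta_curves",
    "msr_rate",
]

#: magnitudes below this are treated as exactly zero inside Monod terms
CLIP = 1.0e-10


@dataclass
class SolverOptions:
    """Numerical knobs for the collocation solve."""

    zeta_cap: float = 5.0
    n_eval: int = 400  # output grid size
    n_initial_mesh: int = 61
    grid_stretch: float = 3.0
    tol: float = 1.0e-7
    max_nodes: int = 200_000
    beta: float = 5.0e-4  # dΠ/dζ threshold defining ζmax
    max_attempts: int = 5
    seed: int = 0

    @property
    def undershoot_tol(self) -> float:
        """Largest tolerated negative concentration (ties to solver tol)."""
        return max(100.0 * self.tol, CLIP)


class SolverError(RuntimeError):
    """Non-convergence or an unphysical converged state."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class ProfileSolution:
    """Converged non-dimensional profiles for one parameter set."""

    params: NonDimensionalParams
    zeta: np.ndarray
    sigma: np.ndarray
    sigma32: np.ndarray
    sigma34: np.ndarray
    eta: np.ndarray
    eta32: np.ndarray
    eta34: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    pi: np.ndarray
    pi32: np.ndarray
    pi34: np.ndarray
    dpi_dzeta: np.ndarray
    d34s_sulfate: np.ndarray
    d34s_sulfide: np.ndarray
    d34s_pyrite: np.ndarray
    zeta_max: float
    delta_pyrite: float
    dsigma_dzeta0: float = np.nan  # surface gradients from the collocation
    deta_dzeta0: float = np.nan
    diagnostics: dict = field(default_factory=dict)

    @property
    def d34s_pyrite_buried(self) -> float:
        """δ34S of cumulative pyrite at the formation-zone base, permil."""
        if self.zeta_max <= 0.0 or self.pi[-1] <= 0.0:
            return np.nan
        return float(
            np.interp(self.zeta_max, self.zeta, self.d34s_pyrite)
        )

    def pi_integral(self, upto: float | None = None) -> float:
        """∫ Π dζ over [0, upto] (default: ζmax)."""
        upto = self.zeta_max if upto is None else upto
        mask = self.zeta <= upto
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.pi[mask], self.zeta[mask]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (zeta, species, value)."""
        cols = {
            "sigma": self.sigma,
            "sigma32": self.sigma32,
            "sigma34": self.sigma34,
            "eta": self.eta,
            "eta32": self.eta32,
            "eta34": self.eta34,
            "gamma": self.gamma,
            "psi": self.psi,
            "pi": self.pi,
            "pi32": self.pi32,
            "pi34": self.pi34,
            "d34s_sulfate": self.d34s_sulfate,
            "d34s_sulfide": self.d34s_sulfide,
            "d34s_pyrite": self.d34s_pyrite,
        }
        frames = [
            pd.DataFrame({"zeta": self.zeta, "species": name, "value": values})
            for name, values in cols.items()
        ]
        return pd.concat(frames, ignore_index=True)


def _clip(x):
    """Zero-floor with the dead band |x| < CLIP treated as zero."""
    return np.where(x > CLIP, x, 0.0)


def msr_rate(p: NonDimensionalParams, zeta, sigma):
    """Non-dimensional MSR rate density: −dΓ/dζ · Σ/(κ_Σ + Σ)."""
    sc = _clip(np.asarray(sigma, dtype=float))
    dgam = oc_gradient(p.gamma0, p.da_star, p.a, zeta)
    return -dgam * sc / (p.kappa_sigma + sc)


def _bulk_rhs(p: NonDimensionalParams):
    def fun(zeta, y):
        sigma, dsigma, eta, deta = y
        sc = _clip(sigma)
        ec = _clip(eta)
        msig = sc / (p.kappa_sigma + sc)
        meta = ec / (p.kappa_eta + ec)
        dgam = oc_gradient(p.gamma0, p.da_star, p.a, zeta)
        dpsi = fe_gradient(p.psi0, p.da_star, p.chi, p.b, zeta)
        d2sigma = (dsigma - dgam * msig) / p.da_star
        d2eta = (deta + dgam * msig - dpsi * meta) / (p.delta * p.da_star)
        return np.vstack([dsigma, d2sigma, deta, d2eta])

    return fun


def _bulk_bc(p: NonDimensionalParams):
    def bc(ya, yb):
        return np.array([ya[0] - 1.0, ya[2] - p.eta0, yb[1], yb[3]])

    return bc


def _iso_rhs(p: NonDimensionalParams):
    alpha = p.alpha34

    def fun(zeta, y):
        s32, ds32, s34, ds34, h32, dh32, h34, dh34 = y
        s32c, s34c = _clip(s32), _clip(s34)
        h32c, h34c = _clip(h32), _clip(h34)
        sigma = s32c + s34c
        eta = h32c + h34c
        msig = sigma / (p.kappa_sigma + sigma)
        meta = eta / (p.kappa_eta + eta)
        # isotopologue partitioning of the MSR rate
        denom_s = alpha * s34c + s32c
        safe_s = np.where(denom_s > 0.0, denom_s, 1.0)
        f32 = np.where(denom_s > 0.0, s32c / safe_s, 0.5)
        f34 = np.where(denom_s > 0.0, alpha * s34c / safe_s, 0.5)
        # pyritization draws on sulfide with no fractionation
        safe_h = np.where(eta > 0.0, eta, 1.0)
        g32 = np.where(eta > 0.0, h32c / safe_h, 0.5)
        g34 = np.where(eta > 0.0, h34c / safe_h, 0.5)
        dgam = oc_gradient(p.gamma0, p.da_star, p.a, zeta)
        dpsi = fe_gradient(p.psi0, p.da_star, p.chi, p.b, zeta)
        d2s32 = (ds32 - dgam * f32 * msig) / p.da_star
        d2s34 = (ds34 - dgam * f34 * msig) / p.da_star
        d2h32 = (dh32 + dgam * f32 * msig - dpsi * g32 * meta) / (
            p.delta * p.da_star
        )
        d2h34 = (dh34 + dgam * f34 * msig - dpsi * g34 * meta) / (
            p.delta * p.da_star
        )
        return np.vstack([ds32, d2s32, ds34, d2s34, dh32, d2h32, dh34, d2h34])

    return fun


def _iso_boundary_values(p: NonDimensionalParams):
    s32_0 = 1.0 / (1.0 + p.r34_sigma0)
    s34_0 = p.r34_sigma0 / (1.0 + p.r34_sigma0)
    h32_0 = p.eta0 / (1.0 + p.r34_eta0)
    h34_0 = p.eta0 * p.r34_eta0 / (1.0 + p.r34_eta0)
    return s32_0, s34_0, h32_0, h34_0


def _iso_bc(p: NonDimensionalParams):
    s32_0, s34_0, h32_0, h34_0 = _iso_boundary_values(p)

    def bc(ya, yb):
        return np.array(
            [
                ya[0] - s32_0,
                ya[2] - s34_0,
                ya[4] - h32_0,
                ya[6] - h34_0,
                yb[1],
                yb[3],
                yb[5],
                yb[7],
            ]
        )

    return bc


def _bulk_guess(p: NonDimensionalParams, mesh: np.ndarray, rng=None):
    """Heuristic starting iterate: Rayleigh-style sulfate drawdown and a
    sulfide profile from instantaneous local balance (production minus
    saturated consumption), optionally jittered for restarts."""
    zc = mesh[-1]
    drawdown = min(0.95, p.gamma0 / (p.gamma0 + 1.0 + p.da_star))
    sigma = 1.0 - drawdown * (mesh / zc)
    gamma = p.gamma0 * (p.a / (p.a + p.da_star * mesh)) ** p.a
    psi = p.psi0 * (p.b / (p.b + p.chi * p.da_star * mesh)) ** p.b
    eta = np.maximum(p.eta0 + (p.gamma0 - gamma) - (p.psi0 - psi), 1.0e-6)
    eta = np.minimum(eta, 5.0)
    if rng is not None:
        sigma = np.clip(sigma * rng.uniform(0.5, 1.2), 1.0e-6, 1.0)
        eta = eta * rng.uniform(0.2, 3.0)
        sigma[0], eta[0] = 1.0, max(p.eta0, 1.0e-6)
    dsigma = np.gradient(sigma, mesh)
    deta = np.gradient(eta, mesh)
    return np.vstack([sigma, dsigma, eta, deta])


def _run_bvp(fun, bc, mesh, guess, opts: SolverOptions, label: str):
    rng = np.random.default_rng(opts.seed)
    last_err = None
    for attempt in range(opts.max_attempts):
        y0 = guess if attempt == 0 else None
        if y0 is None:
            y0 = guess * rng.uniform(0.5, 1.5, size=(guess.shape[0], 1))
            y0[:, 0] = guess[:, 0]  # keep the surface boundary values
        try:
            sol = solve_bvp(
                fun, bc, mesh, y0, tol=opts.tol, max_nodes=opts.max_nodes
            )
        except Exception as exc:  # singular Jacobian etc.
            last_err = str(exc)
            continue
        if sol.status == 0:
            return sol, attempt + 1
        last_err = sol.message
    raise SolverError(
        f"{label} solve failed after {opts.max_attempts} attempts: {last_err}",
        {"residual": None, "message": last_err},
    )


def solve_bulk(
    p: NonDimensionalParams, options: SolverOptions | None = None
):
    """Solve the bulk (isotope-summed) sulfate/sulfide BVP.

    Returns the scipy BVP result; state vector (Σ, Σ', η, η').
    """
    opts = options or SolverOptions()
    mesh = default_zeta_grid(opts.n_initial_mesh, opts.zeta_cap, opts.grid_stretch)
    guess = _bulk_guess(p, mesh)
    sol, attempts = _run_bvp(
        _bulk_rhs(p), _bulk_bc(p), mesh, guess, opts, "bulk"
    )
    _check_positive(sol, (0, 2), opts, "bulk")
    sol.attempts = attempts
    return sol


def solve_isotopologues(
    p: NonDimensionalParams,
    bulk_sol,
    options: SolverOptions | None = None,
):
    """Solve the four-isotopologue BVP, seeded from the bulk solution."""
    opts = options or SolverOptions()
    mesh = bulk_sol.x
    s32_0, s34_0, h32_0, h34_0 = _iso_boundary_values(p)
    x32s = s32_0  # seawater 32-fraction of sulfate
    x34s = s34_0
    if p.eta0 > 0.0:
        x32h, x34h = h32_0 / p.eta0, h34_0 / p.eta0
    else:
        x32h, x34h = x32s, x34s
    yb = bulk_sol.y if np.array_equal(bulk_sol.x, mesh) else bulk_sol.sol(mesh)
    guess = np.vstack(
        [
            yb[0] * x32s,
            yb[1] * x32s,
            yb[0] * x34s,
            yb[1] * x34s,
            yb[2] * x32h,
            yb[3] * x32h,
            yb[2] * x34h,
            yb[3] * x34h,
        ]
    )
    sol, attempts = _run_bvp(
        _iso_rhs(p), _iso_bc(p), mesh, guess, opts, "isotopologue"
    )
    _check_positive(sol, (0, 2, 4, 6), opts, "isotopologue")
    sol.attempts = attempts
    return sol


def _check_positive(sol, rows, opts: SolverOptions, label: str):
    worst = min(float(sol.y[r].min()) for r in rows)
    if worst < -opts.undershoot_tol:
        raise SolverError(
            f"{label} solve produced negative concentrations ({worst:.3e})",
            {"min_value": worst, "residual": float(sol.rms_residuals.max())},
        )


def integrate_pyrite(p: NonDimensionalParams, zeta, eta32, eta34):
    """Cumulative pyrite isotopologues from the sulfide solution.

    dΠ/dζ = −dΨ/dζ · η/(κ_η+η), split by the instantaneous sulfide
    isotopologue fractions; Π(0) = 0.
    """
    zeta = np.asarray(zeta, dtype=float)
    h32c, h34c = _clip(np.asarray(eta32)), _clip(np.asarray(eta34))
    eta = h32c + h34c
    meta = eta / (p.kappa_eta + eta)
    safe = np.where(eta > 0.0, eta, 1.0)
    g32 = np.where(eta > 0.0, h32c / safe, 0.5)
    g34 = np.where(eta > 0.0, h34c / safe, 0.5)
    dpsi = fe_gradient(p.psi0, p.da_star, p.chi, p.b, zeta)
    dpi = -dpsi * meta
    pi32 = cumulative_trapezoid(dpi * g32, zeta, initial=0.0)
    pi34 = cumulative_trapezoid(dpi * g34, zeta, initial=0.0)
    return pi32 + pi34, pi32, pi34, dpi


def find_zeta_max(zeta, dpi_dzeta, beta: float = 5.0e-4) -> float:
    """Base of the pyrite formation zone.

    The first depth, below the rate maximum, at which dΠ/dζ falls to
    or below the threshold β; the domain cap if it never does, and 0
    if the rate never exceeds β at all (no appreciable formation).
    """
    zeta = np.asarray(zeta, dtype=float)
    dpi = np.asarray(dpi_dzeta, dtype=float)
    if zeta.size == 0:
        raise ValueError("empty profile")
    if beta <= 0.0:
        raise ValueError("beta must be positive")
    if dpi.max() <= beta:
        return 0.0
    imax = int(np.argmax(dpi))
    below = np.nonzero(dpi[imax:] <= beta)[0]
    if below.size == 0:
        return float(zeta[-1])
    return float(zeta[imax + below[0]])


def delta_curves(sol32, sol34, floor: float = 1.0e-300):
    """δ34S (permil VCDT) from an isotopologue pair; NaN where empty."""
    s32 = np.asarray(sol32, dtype=float)
    s34 = np.asarray(sol34, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s32 > floor, s34 / np.where(s32 > floor, s32, 1.0), np.nan)
    return delta_from_ratio(ratio)


def solve_profile(
    p: NonDimensionalParams,
    options: SolverOptions | None = None,
) -> ProfileSolution:
    """Full solve: bulk, isotopologues, pyrite integration, ζmax, deltas."""
    opts = options or SolverOptions()
    bulk = solve_bulk(p, opts)
    iso = solve_isotopologues(p, bulk, opts)

    zeta = default_zeta_grid(opts.n_eval, opts.zeta_cap, opts.grid_stretch)
    y = iso.sol(zeta)
    s32, s34 = _clip(y[0]), _clip(y[2])
    h32, h34 = _clip(y[4]), _clip(y[6])
    sigma = s32 + s34
    eta = h32 + h34
    gamma = p.gamma0 * (p.a / (p.a + p.da_star * zeta)) ** p.a
    psi = p.psi0 * (p.b / (p.b + p.chi * p.da_star * zeta)) ** p.b
    pi, pi32, pi34, dpi = integrate_pyrite(p, zeta, h32, h34)
    zmax = find_zeta_max(zeta, dpi, opts.beta)

    d34_sulfate = delta_curves(s32, s34)
    d34_sulfide = delta_curves(h32, h34)
    d34_pyrite = delta_curves(pi32, pi34)

    if zmax > 0.0 and np.interp(zmax, zeta, pi) > 0.0:
        d34_buried = float(np.interp(zmax, zeta, d34_pyrite))
        delta_pyrite = p.d34s_sulfate_sw - d34_buried
    else:
        delta_pyrite = np.nan

    y0 = iso.sol(0.0)
    dsigma0 = float(y0[1] + y0[3])
    deta0 = float(y0[5] + y0[7])

    bulk_on_grid = bulk.sol(zeta)
    sum_err_sigma = _relative_mismatch(sigma, _clip(bulk_on_grid[0]))
    sum_err_eta = _relative_mismatch(eta, _clip(bulk_on_grid[2]))

    diagnostics = {
        "bulk_residual": float(bulk.rms_residuals.max()),
        "iso_residual": float(iso.rms_residuals.max()),
        "bulk_nodes": int(bulk.x.size),
        "iso_nodes": int(iso.x.size),
        "bulk_attempts": bulk.attempts,
        "iso_attempts": iso.attempts,
        "isotopologue_sum_error_sigma": sum_err_sigma,
        "isotopologue_sum_error_eta": sum_err_eta,
    }
    return ProfileSolution(
        params=p,
        zeta=zeta,
        sigma=sigma,
        sigma32=s32,
        sigma34=s34,
        eta=eta,
        eta32=h32,
        eta34=h34,
        gamma=gamma,
        psi=psi,
        pi=pi,
        pi32=pi32,
        pi34=pi34,
        dpi_dzeta=dpi,
        d34s_sulfate=d34_sulfate,
        d34s_sulfide=d34_sulfide,
        d34s_pyrite=d34_pyrite,
        zeta_max=zmax,
        delta_pyrite=delta_pyrite,
        dsigma_dzeta0=dsigma0,
        deta_dzeta0=deta0,
        diagnostics=diagnostics,
    )


def _relative_mismatch(a: np.ndarray, b: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1.0e-12)
    return float(np.max(np.abs(a - b)) / scale)


def flux_balance(p: NonDimensionalParams, sol: ProfileSolution) -> dict:
    """Sulfur bookkeeping over the solved column.

    Integrated MSR production plus the advected boundary inflow must
    equal diffusive sulfide efflux at the surface plus advective
    sulfide burial at the bottom plus pyrite burial.  Returns the
    individual terms and the relative closure error.
    """
    zeta = sol.zeta
    production = float(np.trapezoid(msr_rate(p, zeta, sol.sigma), zeta))
    # upward diffusive sulfide loss across the interface
    efflux = p.delta * p.da_star * sol.deta_dzeta0
    burial_eta = float(sol.eta[-1])
    burial_pi = float(sol.pi[-1])
    supplied = production + p.eta0
    removed = efflux + burial_eta + burial_pi
    scale = max(abs(supplied), 1.0e-12)
    return {
        "production": production,
        "sulfide_efflux": efflux,
        "sulfide_burial": burial_eta,
        "pyrite_burial": burial_pi,
        "closure_error": abs(supplied - removed) / scale,
    }
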