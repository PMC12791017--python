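"""Re-dimensionalization of solutions into burial quantities and misfits.

Converts non-dimensional profiles back to wt%/mM depth profiles, then
to per-pixel pyrite inventories (mol FeS2), burial fluxes
(mol FeS2 yr^-1) and the δ34S of buried pyrite, and computes
model--data misfit statistics against measured site tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .params import (
    M_FES2,
    ConversionFactors,
    KineticParams,
    SiteConditions,
    conversion_factors,
    decay_to_onset,
    diffusivity,
    nondimensionalize,
    z_from_zeta,
)
from .solver import ProfileSolution, SolverOptions, solve_profile

__all__ = [
    "BurialResult",
    "MisfitReport",
    "dimensional_solution",
    "pyrite_inventory",
    "burial_flux",
    "weighted_mean_d34s",
    "solve_site",
    "misfit",
    "MEASURED_VARIABLES",
]

MEASURED_VARIABLES = (
    "pyrite_wtpct",
    "d34s_pyrite",
    "sulfate_mM",
    "sulfide_mM",
    "d34s_sulfate",
    "oc_wtpct",
    "fehr_wtpct",
)


@dataclass
class BurialResult:
    """Per-pixel burial outputs (Eq.-52/53-style quantities)."""

    z_max: float  # cm, dimensional base of the formation zone
    n_p: float  # mol FeS2 per pixel, depth-integrated
    j_p: float  # mol FeS2 yr^-1 per pixel
    d34s_pyrite: float  # permil VCDT of buried pyrite
    delta_pyrite: float  # permil, seawater sulfate minus buried pyrite

    @property
    def j_p_mol_s(self) -> float:
        """Burial flux in mol S yr^-1 (2 mol S per mol FeS2)."""
        return 2.0 * self.j_p


def dimensional_solution(
    sol: ProfileSolution, site: SiteConditions, kin: KineticParams | None = None
) -> pd.DataFrame:
    """Depth profiles in dimensional units (z in cm from the onset).

    Columns: z_cm, sulfate_mM, sulfide_mM, oc_wtpct, fehr_wtpct,
    pyrite_wtpct, d34s_sulfate, d34s_sulfide, d34s_pyrite.
    """
    kin = kin or KineticParams()
    conv = conversion_factors(site.porosity, site.solid_density)
    _, k_g0 = decay_to_onset(
        site.oc_swi, site.oc_reactivity_swi, kin.a, site.sed_rate, site.onset_depth
    )
    d_s = diffusivity(site.temperature, site.porosity, "sulfate")
    z = z_from_zeta(sol.zeta, k_g0, d_s)
    s0 = site.sulfate
    return pd.DataFrame(
        {
            "z_cm": z,
            "sulfate_mM": sol.sigma * s0,
            "sulfide_mM": sol.eta * s0,
            "oc_wtpct": sol.gamma * s0 / conv.f_g,
            "fehr_wtpct": sol.psi * s0 / conv.f_f,
            "pyrite_wtpct": sol.pi * s0 / conv.f_p,
            "d34s_sulfate": sol.d34s_sulfate,
            "d34s_sulfide": sol.d34s_sulfide,
            "d34s_pyrite": sol.d34s_pyrite,
        }
    )


def pyrite_inventory(z_cm, pyrite_wtpct, site: SiteConditions) -> float:
    """Depth-integrated pyrite per pixel, mol FeS2.

    (1/100) ρ_sol (1−φ) A / 119.98 · ∫ P(z) dz with z in cm.
    """
    z = np.asarray(z_cm, dtype=float)
    p_wt = np.asarray(pyrite_wtpct, dtype=float)
    if site.pixel_area is None or site.pixel_area <= 0.0:
        raise ValueError("pixel_area must be positive")
    prefactor = (
        0.01
        * site.solid_density
        * (1.0 - site.porosity)
        * site.pixel_area
        / M_FES2
    )
    return float(prefactor * np.trapezoid(p_wt, z))


def burial_flux(pyrite_wtpct_at_zmax: float, site: SiteConditions) -> float:
    """Pyrite burial flux per pixel, mol FeS2 yr^-1.

    Steady state equates formation and export: w (1/100) ρ_sol (1−φ)
    A / 119.98 · P(z_max).
    """
    prefactor = (
        site.sed_rate
        * 0.01
        * site.solid_density
        * (1.0 - site.porosity)
        * site.pixel_area
        / M_FES2
    )
    return float(prefactor * pyrite_wtpct_at_zmax)


def weighted_mean_d34s(fluxes, d34s_values) -> float:
    """Flux-weighted mean δ34S across cells (NaN-flux cells excluded)."""
    j = np.asarray(fluxes, dtype=float)
    d = np.asarray(d34s_values, dtype=float)
    ok = np.isfinite(j) & np.isfinite(d) & (j > 0.0)
    if not ok.any():
        raise ValueError("no cells with positive burial flux")
    return float(np.sum(j[ok] * d[ok]) / np.sum(j[ok]))


def solve_site(
    site: SiteConditions,
    kin: KineticParams | None = None,
    options: SolverOptions | None = None,
) -> tuple[ProfileSolution, BurialResult]:
    """Full per-site pipeline: non-dimensionalize, solve, re-dimensionalize."""
    kin = kin or KineticParams()
    params = nondimensionalize(site, kin)
    sol = solve_profile(params, options)
    dims = dimensional_solution(sol, site, kin)
    _, k_g0 = decay_to_onset(
        site.oc_swi, site.oc_reactivity_swi, kin.a, site.sed_rate, site.onset_depth
    )
    d_s = diffusivity(site.temperature, site.porosity, "sulfate")
    z_max = float(z_from_zeta(sol.zeta_max, k_g0, d_s))
    # the formation zone cannot outrun the sediment column
    z_max = min(z_max, site.sediment_thickness)
    in_zone = dims["z_cm"].to_numpy() <= z_max
    n_p = pyrite_inventory(
        dims["z_cm"].to_numpy()[in_zone],
        dims["pyrite_wtpct"].to_numpy()[in_zone],
        site,
    )
    p_at_zmax = float(
        np.interp(z_max, dims["z_cm"].to_numpy(), dims["pyrite_wtpct"].to_numpy())
    )
    result = BurialResult(
        z_max=z_max,
        n_p=n_p,
        j_p=burial_flux(p_at_zmax, site),
        d34s_pyrite=sol.d34s_pyrite_buried,
        delta_pyrite=sol.delta_pyrite,
    )
    return sol, result


def net_sulfur_budget(
    burial_mol_s_yr: float,
    riverine_mol_s_yr: float = 2.8e12,
    riverine_pyrite_fraction: float = 0.5,
    electrons_per_fes2: float = 15.0,
    electrons_per_o2: float = 4.0,
) -> dict:
    """Whole-ocean sulfur budget arithmetic from a burial flux.

    Net marine S loss is burial minus riverine sulfate delivery.  The
    O2 release compares electrons buried with pyrite (15 e- per FeS2)
    against those consumed by oxidative weathering of the
    pyrite-derived share of riverine sulfate, at 4 e- per O2.
    """
    net_loss = burial_mol_s_yr - riverine_mol_s_yr
    burial_fes2 = burial_mol_s_yr / 2.0
    weathering_fes2 = riverine_mol_s_yr * riverine_pyrite_fraction / 2.0
    o2_release = (burial_fes2 - weathering_fes2) * electrons_per_fes2 / electrons_per_o2
    return {
        "net_s_loss_mol_yr": net_loss,
        "o2_release_mol_yr": o2_release,
        "burial_mol_fes2_yr": burial_fes2,
        "weathering_mol_fes2_yr": weathering_fes2,
    }


@dataclass
class MisfitReport:
    """Model--data misfit summary across sites."""

    per_site: pd.DataFrame  # site_id, variable, n, rmse, residual_median
    residuals: pd.DataFrame  # site_id, variable, depth_cm, residual
    medians: dict = field(default_factory=dict)  # variable -> median RMSE
    n_excluded_deep: int = 0  # observations below the model domain

    def to_json_dict(self) -> dict:
        return {
            "medians": self.medians,
            "n_excluded_deep": self.n_excluded_deep,
            "per_site": self.per_site.to_dict(orient="records"),
        }


def misfit(
    model_profiles: dict[str, pd.DataFrame],
    measured: pd.DataFrame,
) -> MisfitReport:
    """RMSE of model profiles against a measured site table.

    ``model_profiles`` maps site_id to a dimensional-profile frame from
    :func:`dimensional_solution`; ``measured`` has columns (site_id,
    depth_cm, variable, value[, sd]).  The model is interpolated to the
    observation depths with a monotone piecewise cubic; observations
    deeper than the model domain are excluded and counted.
    """
    required = {"site_id", "depth_cm", "variable", "value"}
    if not required.issubset(measured.columns):
        raise ValueError(f"measured table needs columns {sorted(required)}")
    rows, res_rows = [], []
    n_excluded = 0
    for (site_id, variable), grp in measured.groupby(["site_id", "variable"]):
        if site_id not in model_profiles or variable not in MEASURED_VARIABLES:
            continue
        prof = model_profiles[site_id]
        if variable not in prof.columns:
            continue
        zmod = prof["z_cm"].to_numpy()
        vmod = prof[variable].to_numpy()
        good = np.isfinite(vmod)
        zobs = grp["depth_cm"].to_numpy(dtype=float)
        vobs = grp["value"].to_numpy(dtype=float)
        inside = (zobs >= zmod[good].min()) & (zobs <= zmod[good].max())
        n_excluded += int((~inside).sum())
        if inside.sum() == 0:
            raise ValueError(
                f"no overlapping depth range for {site_id}/{variable}"
            )
        interp = PchipInterpolator(zmod[good], vmod[good])
        resid = interp(zobs[inside]) - vobs[inside]
        rows.append(
            {
                "site_id": site_id,
                "variable": variable,
                "n": int(inside.sum()),
                "rmse": float(np.sqrt(np.mean(resid**2))),
                "residual_median": float(np.median(resid)),
            }
        )
        for zz, rr in zip(zobs[inside], resid):
            res_rows.append(
                {
                    "site_id": site_id,
                    "variable": variable,
                    "depth_cm": float(zz),
                    "residual": float(rr),
                }
            )
    per_site = pd.DataFrame(rows)
    residuals = pd.DataFrame(res_rows)
    medians = (
        per_site.groupby("variable")["rmse"].median().to_dict()
        if len(per_site)
        else {}
    )
    return MisfitReport(per_site, residuals, medians, n_excluded)
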