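"""Dimensional quantities, unit conversions and non-dimensionalization.

Site boundary conditions (sedimentation rate, porosity, solid-phase
contents, bottom-water chemistry) are turned into the dimensionless
numbers that govern the diagenetic model:

* ``Γ0`` — organic-carbon-to-sulfate ratio at the top of the sulfidic
  anoxic zone, expressed in sulfate-equivalent units,
* ``Da*`` — modified Damköhler number ``sqrt(D_S k_G0) / w`` weighing
  reaction plus diffusion against sediment advection,
* ``Ψ0`` — highly reactive iron (Fe_HR) delivery in sulfide-equivalent
  units,

together with the Monod constants, the diffusivity ratio, the power-law
reactivity exponents and the equilibrium sulfur isotope fractionation
factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "M_C",
    "M_FE",
    "M_FES2",
    "R_VCDT",
    "OC_PER_SULFATE",
    "S_PER_FE",
    "SECONDS_PER_YEAR",
    "SiteConditions",
    "KineticParams",
    "ConversionFactors",
    "NonDimensionalParams",
    "DegeneratePorosityError",
    "oc_conversion_factor",
    "fe_conversion_factor",
    "pyrite_conversion_factor",
    "conversion_factors",
    "diffusivity",
    "equilibrium_alpha",
    "equilibrium_epsilon",
    "decay_to_onset",
    "oc_reactivity_from_sed_rate",
    "nondimensionalize",
    "ratio_from_delta",
    "delta_from_ratio",
    "zeta_from_z",
    "z_from_zeta",
]

# molar masses, g mol^-1
M_C = 12.011
M_FE = 55.845
M_FES2 = 119.98

#: 34S/32S ratio of the Vienna Canyon Diablo Troilite standard.
R_VCDT = 0.0441626

#: mol organic carbon respired per mol sulfate reduced.
OC_PER_SULFATE = 1.7

#: mol dissolved sulfide consumed per mol Fe pyritized (FeS2 stoichiometry).
S_PER_FE = 2.0

SECONDS_PER_YEAR = 3.1536e7

# Free-solution diffusivity linear fits D0 = (m0 + m1*T) 1e-6 cm2 s^-1
# (T in deg C), after the standard seawater-ion compilations.
_DIFFUSIVITY_COEFFS = {
    "sulfate": (4.88, 0.232),
    "sulfide": (10.4, 0.273),  # HS-, the dominant species at seawater pH
}


class DegeneratePorosityError(ValueError):
    """Raised when porosity is 0 or 1: no pore water or no solids."""


@dataclass
class SiteConditions:
    """Dimensional boundary conditions for one location.

    Contents marked ``_swi`` apply at the sediment--water interface;
    the model itself starts at the onset depth ``z0`` of the sulfidic
    anoxic zone (oxygen-penetration depth or mixed-layer depth), to
    which solids are decayed before non-dimensionalization.
    """

    water_depth: float = 1000.0  # mbsl
    temperature: float = 5.0  # deg C at seafloor
    porosity: float = 0.75  # pore-volume fraction
    solid_density: float = 2.65  # g cm^-3
    sed_rate: float = 0.008  # cm yr^-1
    oc_swi: float = 1.0  # wt% OC
    oc_reactivity_swi: float = 6.2e-7  # yr^-1
    fe_swi: float = 0.5  # wt% Fe_HR
    onset_depth: float = 0.0  # cm
    sulfate: float = 28.0  # mM
    sulfide: float = 0.0  # mM bottom water (euxinia)
    d34s_sulfate_sw: float = 28.0  # permil VCDT
    d34s_sulfide_sw: float = -10.0  # permil VCDT, used only if sulfide > 0
    sediment_thickness: float = 24300.0  # cm
    pixel_area: float = 1.0  # cm^2

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise DegeneratePorosityError(
                f"porosity must lie strictly in (0, 1), got {self.porosity}"
            )
        if self.sed_rate <= 0.0:
            raise ValueError("sedimentation rate must be positive")
        if self.sulfate <= 0.0:
            raise ValueError(
                "sulfate must be positive (model validity requires S0 > ~3 mM)"
            )
        for name in ("oc_swi", "fe_swi", "sulfide", "onset_depth"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class KineticParams:
    """Kinetic and stoichiometric constants of the reaction network.

    The power-law exponents ``a`` (OC) and ``b`` (Fe_HR) are the
    reactive-continuum shape parameters; ``chi`` is the ratio of
    Fe_HR to OC initial reactivities.  ``k_gsw_coeff``/``k_gsw_exp``
    parameterize interface OC reactivity as a power law of
    sedimentation rate, k_G_sw = c * w**d.  All defaults are package
    defaults; see docs/methods.md for how they were chosen.
    """

    a: float = 0.6
    b: float = 1.0
    chi: float = 1.0
    k_s: float = 1.6  # mM, sulfate Monod half-velocity
    k_h: float = 1.0  # mM, sulfide Monod half-velocity
    stoich_oc_per_sulfate: float = OC_PER_SULFATE
    k_gsw_coeff: float = 1.07e-5  # yr^-1 at w = 1 cm yr^-1
    k_gsw_exp: float = 0.59

    def __post_init__(self) -> None:
        for name in ("a", "b", "chi", "k_s", "k_h"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ConversionFactors:
    """wt% <-> mM conversion factors for one site's porosity/density.

    ``f_g``: mM sulfate reduced per wt% OC respired; ``f_f``: mM
    sulfide consumed per wt% Fe_HR pyritized; ``f_p``: mM sulfide per
    wt% FeS2 formed.  ``f_f / f_p`` reduces to the FeS2-to-Fe mass
    ratio 119.98/55.845, so 1 wt% Fe_HR lost yields 2.148 wt% FeS2.
    """

    f_g: float
    f_f: float
    f_p: float


@dataclass
class NonDimensionalParams:
    """Dimensionless parameter set consumed by the profile solver."""

    gamma0: float  # OC-to-sulfate ratio
    da_star: float  # modified Damkoehler number
    psi0: float  # Fe_HR delivery
    kappa_sigma: float = 1.6 / 28.0  # K_S / S0
    kappa_eta: float = 1.0 / 28.0  # K_H / S0
    delta: float = 1.95  # D_H / D_S
    chi: float = 1.0  # k_F0 / k_G0
    a: float = 0.6
    b: float = 1.0
    alpha34: float = 0.93235  # equilibrium fractionation at 15 C, sulfide/sulfate
    eta0: float = 0.0  # bottom-water sulfide / S0
    r34_sigma0: float = R_VCDT * 1.028  # seawater sulfate 34S/32S
    r34_eta0: float = R_VCDT * 0.990  # seawater sulfide 34S/32S (if eta0 > 0)

    def __post_init__(self) -> None:
        if self.gamma0 < 0.0 or self.psi0 < 0.0 or self.eta0 < 0.0:
            raise ValueError("gamma0, psi0 and eta0 must be non-negative")
        if self.da_star <= 0.0:
            raise ValueError("da_star must be positive")
        if not 0.0 < self.alpha34 <= 1.0:
            raise ValueError("alpha34 must lie in (0, 1]")
        if self.kappa_sigma <= 0.0 or self.kappa_eta <= 0.0:
            raise ValueError("Monod constants must be positive")

    @property
    def d34s_sulfate_sw(self) -> float:
        """Seawater sulfate delta34S implied by the boundary ratio, permil."""
        return delta_from_ratio(self.r34_sigma0)

    def to_dict(self) -> dict:
        return asdict(self)


def _solid_to_porewater(porosity: float, solid_density: float) -> float:
    """g solid per cm^3 pore water: rho_sol (1 - phi) / phi."""
    if not 0.0 < porosity < 1.0:
        raise DegeneratePorosityError(
            f"porosity must lie strictly in (0, 1), got {porosity}"
        )
    if solid_density < 0.0:
        raise ValueError("solid density must be non-negative")
    return solid_density * (1.0 - porosity) / porosity


def oc_conversion_factor(
    porosity: float, solid_density: float, stoich: float = OC_PER_SULFATE
) -> float:
    """mM sulfate reduced per wt% OC respired.

    1 wt% OC = 0.01 g OC per g solid; per cm^3 pore water that is
    ``rho_sol (1-phi)/phi / 100`` g, i.e. ``.../M_C`` mol C, of which
    one mol sulfate is reduced per ``stoich`` mol C.  The factor 1e4
    combines the wt%->fraction (1e-2) and mol/cm3 -> mM (1e6) steps.
    """
    return _solid_to_porewater(porosity, solid_density) * 1.0e4 / (M_C * stoich)


def fe_conversion_factor(porosity: float, solid_density: float) -> float:
    """mM sulfide consumed per wt% Fe_HR pyritized (2 mol S per mol Fe)."""
    return _solid_to_porewater(porosity, solid_density) * S_PER_FE * 1.0e4 / M_FE


def pyrite_conversion_factor(porosity: float, solid_density: float) -> float:
    """mM sulfide consumed per wt% FeS2 formed (2 mol S per mol FeS2)."""
    return _solid_to_porewater(porosity, solid_density) * S_PER_FE * 1.0e4 / M_FES2


def conversion_factors(porosity: float, solid_density: float) -> ConversionFactors:
    return ConversionFactors(
        f_g=oc_conversion_factor(porosity, solid_density),
        f_f=fe_conversion_factor(porosity, solid_density),
        f_p=pyrite_conversion_factor(porosity, solid_density),
    )


def diffusivity(
    temperature: float,
    porosity: float,
    species: str = "sulfate",
    coeffs: dict | None = None,
) -> float:
    """Sediment diffusivity in cm^2 yr^-1.

    Linear free-solution fit in temperature divided by the tortuosity
    correction ``theta^2 = 1 - 2 ln(phi)``.
    """
    if not -2.0 <= temperature <= 40.0:
        raise ValueError(f"temperature {temperature} C outside plausible range")
    table = _DIFFUSIVITY_COEFFS if coeffs is None else coeffs
    try:
        m0, m1 = table[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; expected one of {sorted(table)}"
        ) from None
    d_free = (m0 + m1 * temperature) * 1.0e-6 * SECONDS_PER_YEAR
    theta2 = 1.0 - 2.0 * np.log(porosity)
    return d_free / theta2


def equilibrium_epsilon(
    temperature: float, eps0: float = 70.2, slope: float = 0.17
) -> float:
    """Equilibrium 34S enrichment of sulfide relative to sulfate, permil.

    Linearized low-temperature equilibrium curve eps = -(eps0 - slope*T),
    about -70 permil near 0 C and weakening towards warmer water.
    Coefficients are exposed so the fractionation can be pinned exactly.
    """
    return -(eps0 - slope * temperature)


def equilibrium_alpha(
    temperature: float, eps0: float = 70.2, slope: float = 0.17
) -> float:
    """Equilibrium fractionation factor alpha34 = 1 + eps/1000 (< 1)."""
    return 1.0 + equilibrium_epsilon(temperature, eps0, slope) / 1000.0


def ratio_from_delta(delta_permil: float) -> float:
    """34S/32S ratio corresponding to a delta34S value in permil VCDT."""
    return R_VCDT * (1.0 + delta_permil / 1000.0)


def delta_from_ratio(ratio):
    """delta34S in permil VCDT from a 34S/32S ratio (array-safe)."""
    return (np.asarray(ratio) / R_VCDT - 1.0) * 1000.0


def decay_to_onset(content_swi, k_swi, exponent, sed_rate, onset_depth):
    """Decay a reactive-continuum solid from the interface to depth z0.

    Returns ``(content, reactivity)`` at the onset of the sulfidic
    anoxic zone.  The power-law profile is self-similar, so shifting
    the origin only rescales the surface content and the apparent
    rate coefficient:

        C0 = C_sw [a w / (a w + k_sw z0)]**a
        k0 = k_sw  a w / (a w + k_sw z0)

    With z0 = 0 this is the identity.
    """
    if onset_depth < 0.0:
        raise ValueError("onset depth must be non-negative")
    if content_swi < 0.0 or k_swi < 0.0:
        raise ValueError("content and reactivity must be non-negative")
    if sed_rate <= 0.0 or exponent <= 0.0:
        raise ValueError("sed_rate and exponent must be positive")
    shift = exponent * sed_rate / (exponent * sed_rate + k_swi * onset_depth)
    return content_swi * shift**exponent, k_swi * shift


def oc_reactivity_from_sed_rate(
    sed_rate, coeff: float = 1.07e-5, exponent: float = 0.59
):
    """Empirical interface OC reactivity k_G_sw = c * w**d, yr^-1 (array-safe)."""
    w = np.asarray(sed_rate, dtype=float)
    if np.any(w <= 0.0):
        raise ValueError("sed_rate must be positive")
    out = coeff * w**exponent
    return float(out) if np.isscalar(sed_rate) else out


def zeta_from_z(z_cm, k_g0: float, d_s: float):
    """Non-dimensional depth zeta = sqrt(k_G0 / D_S) * z."""
    return np.sqrt(k_g0 / d_s) * np.asarray(z_cm)


def z_from_zeta(zeta, k_g0: float, d_s: float):
    """Dimensional depth in cm from zeta."""
    return np.asarray(zeta) / np.sqrt(k_g0 / d_s)


def nondimensionalize(
    site: SiteConditions,
    kin: KineticParams | None = None,
    conv: ConversionFactors | None = None,
    alpha_coeffs: tuple[float, float] = (70.2, 0.17),
    diffusivity_coeffs: dict | None = None,
) -> NonDimensionalParams:
    """Turn dimensional site conditions into solver parameters.

    Solids are first decayed from the sediment--water interface to the
    onset depth z0, then Γ0, Da*, Ψ0 and the dimensionless Monod and
    boundary terms are assembled.  Fe_HR is decayed over the oxic zone
    with reactivity ``chi * k_G_sw`` and exponent ``b``; chi is then
    re-evaluated at the onset as k_F0 / k_G0.
    """
    kin = kin or KineticParams()
    if conv is None:
        conv = conversion_factors(site.porosity, site.solid_density)

    g0, k_g0 = decay_to_onset(
        site.oc_swi, site.oc_reactivity_swi, kin.a, site.sed_rate, site.onset_depth
    )
    f0, k_f0 = decay_to_onset(
        site.fe_swi,
        kin.chi * site.oc_reactivity_swi,
        kin.b,
        site.sed_rate,
        site.onset_depth,
    )
    d_s = diffusivity(
        site.temperature, site.porosity, "sulfate", diffusivity_coeffs
    )
    d_h = diffusivity(
        site.temperature, site.porosity, "sulfide", diffusivity_coeffs
    )
    if k_g0 <= 0.0:
        raise ValueError("onset OC reactivity must be positive")
    return NonDimensionalParams(
        gamma0=conv.f_g * g0 / site.sulfate,
        da_star=np.sqrt(d_s * k_g0) / site.sed_rate,
        psi0=conv.f_f * f0 / site.sulfate,
        kappa_sigma=kin.k_s / site.sulfate,
        kappa_eta=kin.k_h / site.sulfate,
        delta=d_h / d_s,
        chi=k_f0 / k_g0,
        a=kin.a,
        b=kin.b,
        alpha34=equilibrium_alpha(site.temperature, *alpha_coeffs),
        eta0=site.sulfide / site.sulfate,
        r34_sigma0=ratio_from_delta(site.d34s_sulfate_sw),
        r34_eta0=ratio_from_delta(site.d34s_sulfide_sw),
    )
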