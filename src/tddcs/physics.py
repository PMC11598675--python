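"""Analytic photon-migration forward models.

Diffusion-theory solutions for a semi-infinite turbid medium with an
extrapolated (zero-fluence) boundary: time-resolved diffuse reflectance for
TD NIRS, and the normalized field autocorrelation g1 of the correlation
diffusion equation for DCS (semi-infinite closed form and a two-layer
Hankel-space solution).  Also houses the Siegert relation, Beer's-law
chromophore algebra and the Stokes-Einstein relation used to predict the
Brownian diffusion coefficient of liquid phantoms.

Unit conventions
----------------
lengths cm, absorption/scattering coefficients 1/cm, TD NIRS times ps,
DCS lag times s, Brownian diffusion coefficient cm^2/s (Stokes-Einstein
helper returns SI m^2/s), wavelengths nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import j0, roots_legendre

__all__ = [
    "C_CM_PER_PS",
    "KB_J_PER_K",
    "OpticalProperties",
    "DynamicsParams",
    "Layer",
    "LayeredMedium",
    "ChromophoreBasis",
    "PhantomDynamics",
    "boundary_coefficient",
    "td_reflectance",
    "cw_reflectance",
    "g1_semi_infinite",
    "g1_two_layer",
    "siegert",
    "beer_forward",
    "beer_invert",
    "einstein_db",
    "optical_wavenumber",
]

#: speed of light in vacuum, cm/ps
C_CM_PER_PS = 0.0299792458
#: Boltzmann constant, J/K
KB_J_PER_K = 1.380649e-23


class ValidationError(ValueError):
    """Raised when physically impossible parameters are supplied."""


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a turbid medium at one wavelength.

    mua: absorption coefficient, 1/cm (>= 0)
    musp: reduced scattering coefficient, 1/cm (> 0)
    n: refractive index (>= 1)
    wavelength: nm
    """

    mua: float
    musp: float
    n: float = 1.4
    wavelength: float = 830.0

    def __post_init__(self):
        if self.mua < 0:
            raise ValidationError(f"mua must be >= 0, got {self.mua}")
        if self.musp <= 0:
            raise ValidationError(f"musp must be > 0, got {self.musp}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")

    @property
    def D(self) -> float:
        """Diffusion coefficient 1/(3 musp), cm."""
        return 1.0 / (3.0 * self.musp)

    @property
    def v(self) -> float:
        """Speed of light in the medium, cm/ps."""
        return C_CM_PER_PS / self.n


@dataclass(frozen=True)
class DynamicsParams:
    """Dynamical parameters of the scatterers seen by DCS.

    DB: effective Brownian diffusion coefficient, cm^2/s.  The blood flow
        index (BFI) is alpha*DB with alpha fixed to 1 here, so BFI and DB
        are used interchangeably.
    beta: coherence factor of the Siegert relation, 0 < beta <= 1.
    """

    DB: float
    beta: float = 0.5

    def __post_init__(self):
        if self.DB < 0:
            raise ValidationError(f"DB must be >= 0, got {self.DB}")
        if not (0 < self.beta <= 1):
            raise ValidationError(f"beta must be in (0, 1], got {self.beta}")


@dataclass(frozen=True)
class Layer:
    """One layer of a layered medium: thickness in cm (inf for the last)."""

    thickness: float
    props: OpticalProperties
    dyn: DynamicsParams


@dataclass(frozen=True)
class LayeredMedium:
    """Stack of layers, last one semi-infinite; all layers share n."""

    layers: tuple
    rho: float

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValidationError("at least one layer required")
        if not np.isinf(self.layers[-1].thickness):
            raise ValidationError("last layer must be semi-infinite")
        for lay in self.layers[:-1]:
            if not (lay.thickness > 0):
                raise ValidationError("layer thicknesses must be > 0")
        n0 = self.layers[0].props.n
        if any(abs(l.props.n - n0) > 1e-12 for l in self.layers):
            raise ValidationError("all layers must share the refractive index")


def boundary_coefficient(n: float) -> float:
    """Boundary coefficient A of the extrapolated-boundary condition.

    Uses the standard polynomial approximation of the internal-reflection
    parameter R_eff(n) for a tissue/air interface; the extrapolation length
    is z_b = 2 A D.
    """
    r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


def _zb(props: OpticalProperties) -> float:
    return 2.0 * boundary_coefficient(props.n) * props.D


def td_reflectance(rho: float, t_ps, props: OpticalProperties) -> np.ndarray:
    """Time-resolved diffuse reflectance of a semi-infinite medium.

    Extrapolated-boundary image-source solution evaluated through Fick's law
    at the physical surface: an isotropic source at z0 = 1/musp and its
    negative image mirrored about the extrapolated boundary z = -z_b.

    Parameters
    ----------
    rho : source-detector distance, cm (> 0)
    t_ps : time grid, ps (values <= 0 give 0)
    props : medium optical properties

    Returns
    -------
    Reflectance per unit area and time (1/(cm^2 ps)); shape of `t_ps`.
    """
    if rho <= 0:
        raise ValidationError(f"rho must be > 0, got {rho}")
    t = np.asarray(t_ps, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    D, v = props.D, props.v
    z0 = 1.0 / props.musp
    zb = _zb(props)
    fourDvt = 4.0 * D * v * tp
    pref = 0.5 * (4.0 * np.pi * D * v) ** -1.5 * tp**-2.5
    expo = np.exp(-props.mua * v * tp - rho**2 / fourDvt)
    z1 = z0
    z2 = z0 + 2.0 * zb
    images = z1 * np.exp(-(z1**2) / fourDvt) + z2 * np.exp(-(z2**2) / fourDvt)
    out[pos] = pref * expo * images
    return out


def cw_reflectance(rho: float, props: OpticalProperties, mua: float | None = None) -> float:
    """Continuous-wave diffuse reflectance (time integral of `td_reflectance`).

    `mua` overrides props.mua when given (used for effective, lag-dependent
    absorptions in correlation diffusion work).
    """
    mua = props.mua if mua is None else mua
    mueff = np.sqrt(3.0 * mua * props.musp)
    z0 = 1.0 / props.musp
    zb = _zb(props)
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2.0 * zb)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return float((term1 + term2) / (4.0 * np.pi))


def optical_wavenumber(n: float, wavelength_nm: float) -> float:
    """Optical wavenumber in the medium k0 = 2 pi n / lambda, 1/cm."""
    return 2.0 * np.pi * n / (wavelength_nm * 1e-7)


def g1_semi_infinite(
    tau_s,
    rho: float,
    props: OpticalProperties,
    dyn: DynamicsParams,
    wavelength_nm: float | None = None,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) of a semi-infinite medium.

    Solution of the correlation diffusion equation with effective Brownian
    motion (mean-square displacement 6 DB tau): the CW Green's function with
    the dynamic absorption mua + (1/3) musp k0^2 * 6 DB tau, normalized to
    its tau = 0 value.
    """
    if dyn.DB < 0:
        raise ValidationError("DB must be >= 0")
    tau = np.asarray(tau_s, dtype=float)
    if np.any(tau < 0):
        raise ValidationError("tau must be >= 0")
    lam = props.wavelength if wavelength_nm is None else wavelength_nm
    k0 = optical_wavenumber(props.n, lam)
    z0 = 1.0 / props.musp
    zb = _zb(props)
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2.0 * zb)

    def G(k):
        return np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2

    kd = np.sqrt(3.0 * props.mua * props.musp + props.musp**2 * k0**2 * 6.0 * dyn.DB * tau)
    k0d = np.sqrt(3.0 * props.mua * props.musp)
    return G(kd) / G(k0d)


def _g1_two_layer_hankel(s, tau, medium: LayeredMedium, wavelength_nm: float):
    """Hankel-space surface fluence of the two-layer correlation diffusion
    equation; `s` spatial frequencies (1/cm), `tau` lag grid (s).

    Returns array (len(tau), len(s)).
    """
    top, bot = medium.layers[0], medium.layers[1]
    L = top.thickness
    n = top.props.n
    k0 = optical_wavenumber(n, wavelength_nm)
    D1, D2 = top.props.D, bot.props.D
    z0 = 1.0 / top.props.musp
    if z0 >= L:
        raise ValidationError("top layer thinner than one transport mean free path")
    zb = 2.0 * boundary_coefficient(n) * D1

    tau = tau[:, None]
    s = s[None, :]
    mua1 = top.props.mua + top.props.musp * k0**2 * 2.0 * top.dyn.DB * tau
    mua2 = bot.props.mua + bot.props.musp * k0**2 * 2.0 * bot.dyn.DB * tau
    a1 = np.sqrt(s**2 + mua1 / D1)
    a2 = np.sqrt(s**2 + mua2 / D2)

    # semi-infinite part of the top layer at z = 0
    g_surf = (np.exp(-a1 * z0) - np.exp(-a1 * (z0 + 2.0 * zb))) / (2.0 * D1 * a1)
    # value of the same Green's function at the interface z = L
    g_L = (np.exp(-a1 * (L - z0)) - np.exp(-a1 * (L + z0 + 2.0 * zb))) / (2.0 * D1 * a1)

    u = a1 * (L + zb)
    E = np.exp(-2.0 * u)
    denom = D1 * a1 * (1.0 + E) + D2 * a2 * (1.0 - E)
    # B*sinh(a1*zb) with all exponentials kept <= 1
    corr = g_L * (D1 * a1 - D2 * a2) * (np.exp(a1 * zb - u) - np.exp(-a1 * zb - u)) / denom
    return g_surf + corr


def g1_two_layer(
    tau_s,
    medium: LayeredMedium,
    wavelength_nm: float = 785.0,
    n_nodes: int = 400,
    max_doublings: int = 4,
    tol: float = 1e-4,
) -> np.ndarray:
    """Normalized g1(tau) of a two-layer medium (top layer of finite
    thickness over a semi-infinite base).

    The correlation diffusion equation is solved in spatial-frequency
    (Hankel) space with each layer's dynamic absorption
    mua_i + (1/3) musp_i k0^2 * 6 DB_i tau and inverted by Gauss-Legendre
    quadrature; the node count is doubled until g1 changes by < `tol`
    (absolute) everywhere.

    Raises
    ------
    RuntimeError if the quadrature does not converge.
    """
    if len(medium.layers) != 2:
        raise ValidationError("exactly two layers required")
    tau = np.atleast_1d(np.asarray(tau_s, dtype=float))
    if np.any(tau < 0):
        raise ValidationError("tau must be >= 0")
    rho = medium.rho
    musp1 = medium.layers[0].props.musp
    s_max = 25.0 * musp1  # integrand ~ exp(-s z0): e^-25 at the cutoff

    tau_ext = np.concatenate([[0.0], tau])  # tau=0 needed for normalization

    def quad(nn):
        x, w = roots_legendre(nn)
        s = 0.5 * s_max * (x + 1.0)
        ws = 0.5 * s_max * w
        phi = _g1_two_layer_hankel(s, tau_ext, medium, wavelength_nm)
        kern = j0(s * rho) * s * ws
        return phi @ kern  # unnormalized G1 at [0, tau...]

    prev = quad(n_nodes)
    for _ in range(max_doublings):
        n_nodes *= 2
        cur = quad(n_nodes)
        g_prev = prev / prev[0]
        g_cur = cur / cur[0]
        if np.max(np.abs(g_cur - g_prev)) < tol:
            return g_cur[1:]
        prev = cur
    raise RuntimeError(
        f"two-layer Hankel inversion did not converge below {tol} "
        f"after {n_nodes} nodes (rho={rho} cm, L={medium.layers[0].thickness} cm)"
    )


def siegert(g1_values, beta: float) -> np.ndarray:
    """Siegert relation g2 = 1 + beta |g1|^2 for Gaussian-statistics light."""
    if not (0 < beta <= 1):
        raise ValidationError(f"beta must be in (0, 1], got {beta}")
    g1 = np.asarray(g1_values, dtype=float)
    return 1.0 + beta * np.abs(g1) ** 2


# ---------------------------------------------------------------------------
# Beer's-law chromophore algebra


def _load_default_extinction() -> dict:
    with resources.files("tddcs.data").joinpath("extinction_hb.csv").open() as fh:
        rows = [ln.split(",") for ln in fh.read().splitlines() if ln and not ln.startswith("#")]
    header = rows[0]
    table = {float(r[0]): (float(r[1]), float(r[2])) for r in rows[1:]}
    assert header[1].strip() == "HbO2" and header[2].strip() == "HHb"
    return table


@dataclass(frozen=True)
class ChromophoreBasis:
    """Extinction matrix linking (HbO2, HHb) in uM to mua in 1/cm.

    E rows follow `wavelengths` order, columns are (HbO2, HHb); units
    1/(cm*uM) with natural-log convention.  `water_mua` is an optional fixed
    background absorption per wavelength, 1/cm.
    """

    wavelengths: tuple = (685.0, 830.0)
    E: np.ndarray | None = None
    water_mua: np.ndarray | None = None

    def __post_init__(self):
        if self.water_mua is None:
            object.__setattr__(self, "water_mua", np.zeros(len(self.wavelengths)))
        if self.E is None:
            table = _load_default_extinction()
            E = np.array([table[w] for w in self.wavelengths])
            object.__setattr__(self, "E", E)
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        if E.shape != (len(self.wavelengths), 2):
            raise ValidationError("E must be (n_wavelengths, 2)")
        if np.any(E <= 0):
            raise ValidationError("extinction coefficients must be > 0")
        if E.shape[0] == 2 and abs(np.linalg.det(E)) < 1e-12:
            raise ValidationError("extinction matrix is singular")


def beer_forward(hbo2_um: float, hhb_um: float, basis: ChromophoreBasis | None = None) -> np.ndarray:
    """mua per wavelength (1/cm) for given chromophore concentrations (uM)."""
    basis = basis or ChromophoreBasis()
    return basis.E @ np.array([hbo2_um, hhb_um]) + basis.water_mua


def beer_invert(mua_685: float, mua_830: float, basis: ChromophoreBasis | None = None):
    """Invert Beer's law for the two-wavelength pair.

    Returns (HbO2, HHb, tHb) in uM and StO2 in % (StO2 = 100*HbO2/tHb).

    Raises
    ------
    ZeroDivisionError when tHb = 0 (StO2 undefined).
    """
    basis = basis or ChromophoreBasis()
    mua = np.array([mua_685, mua_830]) - basis.water_mua
    hbo2, hhb = np.linalg.solve(basis.E, mua)
    thb = hbo2 + hhb
    if thb == 0:
        raise ZeroDivisionError("tHb = 0: StO2 undefined")
    sto2 = 100.0 * hbo2 / thb
    return hbo2, hhb, thb, sto2


# ---------------------------------------------------------------------------
# Stokes-Einstein


@dataclass(frozen=True)
class PhantomDynamics:
    """Liquid-phantom parameters for the Stokes-Einstein prediction."""

    T_abs: float  # K
    eta: float  # Pa s
    r: float  # particle radius, m
    kB: float = KB_J_PER_K

    def __post_init__(self):
        if self.T_abs <= 0 or self.eta <= 0 or self.r <= 0:
            raise ValidationError("T_abs, eta and r must be positive")


def einstein_db(pd: PhantomDynamics) -> float:
    """Brownian diffusion coefficient DB = kB T / (6 pi eta r), in m^2/s."""
    return pd.kB * pd.T_abs / (6.0 * np.pi * pd.eta * pd.r)
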