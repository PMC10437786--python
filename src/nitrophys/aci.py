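"""A–Ci analysis: Vcmax, Jmax, respiration in light, and mesophyll conductance.

The maximum Rubisco carboxylation rate Vcmax and maximum electron
transport rate Jmax are estimated from an assimilation vs.
intercellular CO₂ (A–Ci) curve via two linearisations of the
Farquhar–von Caemmerer–Berry model:

* Rubisco-limited window (Ci in [50, 200] μmol·mol⁻¹):
  A = f′·Vcmax + c with f′ = (Ci − Γ*)/(Ci + Kc·(1 + O/Ko)).
  Vcmax is the OLS slope; respiration in light Rd is the negative of
  the intercept c.
* Electron-transport-limited window (Ci in [200, 700] μmol·mol⁻¹):
  A = g′·Jmax with g′ = (Ci − Γ*)/(4.5·Ci + 10.5·Γ*).
  Jmax is the through-origin regression slope by default; an
  Ethier-style intercept can be enabled.

Kc (μmol·mol⁻¹) and Ko (mmol·mol⁻¹) follow Arrhenius-type temperature
responses exp(a − Ea/(R·T_K)) with activation energies in kJ·mol⁻¹ and
R = 0.008315 kJ·mol⁻¹·K⁻¹ (so Kc(25°C) ≈ 408, Ko(25°C) ≈ 277). Γ* is
held at its 25 °C value of 31 μmol·mol⁻¹ by default.

Mesophyll conductance gm is obtained by the variable-J chlorophyll
fluorescence method at the ambient-CO₂ steady state:

    Cc = Γ*·(J + 8·(A + Rd)) / (J − 4·(A + Rd)),   gm = A / (Ci − Cc),

which requires J > 4·(A + Rd) and Ci > Cc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InfeasibleFluorescenceError,
    InsufficientDataError,
    InvalidInputError,
    NonphysicalConductanceError,
)

__all__ = [
    "KineticConstants",
    "ACiCurve",
    "FvCBFit",
    "michaelis_kc",
    "michaelis_ko",
    "f_prime",
    "g_prime",
    "fit_vcmax",
    "fit_jmax",
    "mesophyll_conductance",
    "fit_aci",
    "VCMAX_CI_WINDOW",
    "JMAX_CI_WINDOW",
]

#: Closed Ci windows (μmol·mol⁻¹) for the two linear regressions; a
#: point exactly at 200 belongs to both.
VCMAX_CI_WINDOW = (50.0, 200.0)
JMAX_CI_WINDOW = (200.0, 700.0)


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and gas constants used by the linearisations.

    gamma_star : CO₂ compensation point without day respiration,
        μmol·mol⁻¹ (25 °C value, held fixed across leaf temperature).
    o2 : O₂ mole fraction, mmol·mol⁻¹.
    r_gas : molar gas constant, kJ·mol⁻¹·K⁻¹.
    kc_coeffs / ko_coeffs : (pre-exponential, activation energy in
        kJ·mol⁻¹) of the Arrhenius-type Kc and Ko responses.
    """

    gamma_star: float = 31.0
    o2: float = 210.0
    r_gas: float = 0.008315
    kc_coeffs: tuple[float, float] = (38.05, 79.43)
    ko_coeffs: tuple[float, float] = (20.30, 36.38)

    def __post_init__(self) -> None:
        if self.gamma_star <= 0:
            raise InvalidInputError(f"gamma_star must be > 0, got {self.gamma_star}")
        if self.o2 <= 0:
            raise InvalidInputError(f"o2 must be > 0, got {self.o2}")
        if self.r_gas <= 0:
            raise InvalidInputError(f"r_gas must be > 0, got {self.r_gas}")


@dataclass
class ACiCurve:
    """One plant's A–Ci response plus the ambient-CO₂ steady state.

    ``j_ambient`` is the fluorescence-derived electron transport rate
    measured at the ambient steady state; it is an input, not a
    derived quantity.
    """

    plant_id: str
    ci: np.ndarray
    a_net: np.ndarray
    leaf_temp: float = 25.0
    j_ambient: float = math.nan
    a_ambient: float = math.nan
    ci_ambient: float = math.nan

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a_net = np.asarray(self.a_net, dtype=float)
        if self.ci.shape != self.a_net.shape or self.ci.ndim != 1:
            raise InvalidInputError("ci and a_net must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.ci)) or not np.all(np.isfinite(self.a_net)):
            raise InvalidInputError("A-Ci curve contains non-finite values")
        if np.any(self.ci <= 0):
            raise InvalidInputError("Ci values must be > 0")
        if not 5.0 <= self.leaf_temp <= 45.0:
            raise InvalidInputError(
                f"leaf_temp must be within 5-45 degC, got {self.leaf_temp}"
            )


@dataclass
class FvCBFit:
    """Photosynthetic capacity estimates for one A–Ci curve."""

    plant_id: str
    vcmax: float
    jmax: float
    rd_light: float
    gm: float
    vcmax_intercept: float
    jmax_intercept: float
    r2_vcmax: float
    r2_jmax: float
    points_used_vcmax: int
    points_used_jmax: int
    extras: dict = field(default_factory=dict, repr=False)


def michaelis_kc(leaf_temp: float, k: KineticConstants | None = None) -> float:
    """Rubisco Michaelis constant for CO₂, μmol·mol⁻¹, at leaf_temp (°C)."""
    k = k or KineticConstants()
    a, ea = k.kc_coeffs
    if not math.isfinite(leaf_temp):
        raise InvalidInputError("leaf_temp must be finite")
    return math.exp(a - ea / (k.r_gas * (leaf_temp + 273.15)))


def michaelis_ko(leaf_temp: float, k: KineticConstants | None = None) -> float:
    """Rubisco Michaelis constant for O₂, mmol·mol⁻¹, at leaf_temp (°C)."""
    k = k or KineticConstants()
    a, ea = k.ko_coeffs
    if not math.isfinite(leaf_temp):
        raise InvalidInputError("leaf_temp must be finite")
    return math.exp(a - ea / (k.r_gas * (leaf_temp + 273.15)))


def f_prime(
    ci: float | np.ndarray, leaf_temp: float = 25.0, k: KineticConstants | None = None
) -> float | np.ndarray:
    """Rubisco-limited linearising transform of Ci.

    f′ = (Ci − Γ*)/(Ci + Kc·(1 + O/Ko)); zero exactly at Ci = Γ* and
    strictly increasing in Ci.
    """
    k = k or KineticConstants()
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise InvalidInputError("ci must be > 0")
    kc = michaelis_kc(leaf_temp, k)
    ko = michaelis_ko(leaf_temp, k)
    out = (ci - k.gamma_star) / (ci + kc * (1.0 + k.o2 / ko))
    return float(out) if out.ndim == 0 else out


def g_prime(
    ci: float | np.ndarray, k: KineticConstants | None = None
) -> float | np.ndarray:
    """Electron-transport-limited transform: (Ci − Γ*)/(4.5·Ci + 10.5·Γ*)."""
    k = k or KineticConstants()
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise InvalidInputError("ci must be > 0")
    out = (ci - k.gamma_star) / (4.5 * ci + 10.5 * k.gamma_star)
    return float(out) if out.ndim == 0 else out


def _window_points(curve: ACiCurve, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (curve.ci >= lo) & (curve.ci <= hi)


def fit_vcmax(curve: ACiCurve, k: KineticConstants | None = None) -> dict:
    """OLS of A on f′ over the Rubisco-limited Ci window.

    Returns ``{"vcmax", "rd_light", "intercept", "r2", "n"}`` with
    vcmax the slope and rd_light = −intercept (positive magnitude
    convention). A positive intercept (negative estimated respiration)
    is reported with a warning.
    """
    k = k or KineticConstants()
    mask = _window_points(curve, VCMAX_CI_WINDOW)
    ci = curve.ci[mask]
    if ci.size < 2 or np.unique(ci).size < 2:
        raise InsufficientDataError(
            f"curve {curve.plant_id!r}: need >= 2 distinct Ci points in "
            f"[{VCMAX_CI_WINDOW[0]:g}, {VCMAX_CI_WINDOW[1]:g}] umol/mol, "
            f"got {np.unique(ci).size}"
        )
    x = f_prime(ci, curve.leaf_temp, k)
    y = curve.a_net[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    if intercept > 0:
        warnings.warn(
            f"curve {curve.plant_id!r}: positive A-f' intercept "
            f"({intercept:.3g}) implies negative respiration in light",
            UserWarning,
            stacklevel=2,
        )
    return {
        "vcmax": float(slope),
        "rd_light": float(-intercept),
        "intercept": float(intercept),
        "r2": r2,
        "n": int(ci.size),
    }


def fit_jmax(
    curve: ACiCurve, k: KineticConstants | None = None, intercept: bool = False
) -> dict:
    """Regression of A on g′ over the electron-transport Ci window.

    Through-origin by default (A = g′·Jmax as printed on gas-exchange
    reports); ``intercept=True`` adds an Ethier-style intercept.
    """
    k = k or KineticConstants()
    mask = _window_points(curve, JMAX_CI_WINDOW)
    ci = curve.ci[mask]
    if ci.size < 2 or np.unique(ci).size < 2:
        raise InsufficientDataError(
            f"curve {curve.plant_id!r}: need >= 2 distinct Ci points in "
            f"[{JMAX_CI_WINDOW[0]:g}, {JMAX_CI_WINDOW[1]:g}] umol/mol, "
            f"got {np.unique(ci).size}"
        )
    x = g_prime(ci, k)
    y = curve.a_net[mask]
    if intercept:
        slope, b0 = np.polyfit(x, y, 1)
        resid = y - (slope * x + b0)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        slope = float(np.sum(x * y) / np.sum(x * x))
        b0 = 0.0
        resid = y - slope * x
        ss_tot = float(np.sum(y**2))  # uncentred for through-origin
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return {"jmax": float(slope), "intercept": float(b0), "r2": r2, "n": int(ci.size)}


def mesophyll_conductance(
    a: float,
    ci: float,
    j: float,
    rd_light: float,
    k: KineticConstants | None = None,
) -> float:
    """Variable-J mesophyll conductance, mol·m⁻²·s⁻¹.

    Evaluated at a single (ambient-CO₂) steady state: the
    fluorescence-derived electron transport rate J fixes the
    chloroplastic CO₂ Cc = Γ*·(J + 8·(A + Rd))/(J − 4·(A + Rd)), and
    gm = A/(Ci − Cc). Requires J > 4·(A + Rd) and Ci > Cc.
    """
    k = k or KineticConstants()
    for name, value in (("a", a), ("ci", ci), ("j", j), ("rd_light", rd_light)):
        if not math.isfinite(value):
            raise InvalidInputError(f"{name} must be finite, got {value!r}")
    x = a + rd_light
    if j <= 4.0 * x:
        raise InfeasibleFluorescenceError(
            f"J={j:.3g} <= 4*(A+Rd)={4.0 * x:.3g}: electron transport too "
            "low for the variable-J formula"
        )
    cc = k.gamma_star * (j + 8.0 * x) / (j - 4.0 * x)
    if ci <= cc:
        raise NonphysicalConductanceError(
            f"Ci={ci:.4g} <= Cc={cc:.4g}: implied mesophyll conductance is "
            "not positive"
        )
    return a / (ci - cc)


def fit_aci(
    curve: ACiCurve,
    k: KineticConstants | None = None,
    jmax_intercept: bool = False,
) -> FvCBFit:
    """Full A–Ci parameter estimation for one curve.

    Runs the Vcmax and Jmax window regressions and, when the curve
    carries an ambient steady state (a_ambient/ci_ambient/j_ambient),
    the variable-J mesophyll conductance using the fitted Rd. gm is
    NaN with a warning when the ambient state is absent or infeasible.
    """
    k = k or KineticConstants()
    vc = fit_vcmax(curve, k)
    jm = fit_jmax(curve, k, intercept=jmax_intercept)
    gm = math.nan
    if all(
        math.isfinite(v) for v in (curve.a_ambient, curve.ci_ambient, curve.j_ambient)
    ):
        try:
            gm = mesophyll_conductance(
                curve.a_ambient, curve.ci_ambient, curve.j_ambient, vc["rd_light"], k
            )
        except (InfeasibleFluorescenceError, NonphysicalConductanceError) as exc:
            warnings.warn(
                f"curve {curve.plant_id!r}: gm not estimable ({exc})",
                UserWarning,
                stacklevel=2,
            )
    else:
        warnings.warn(
            f"curve {curve.plant_id!r}: no ambient steady state; gm not estimated",
            UserWarning,
            stacklevel=2,
        )
    return FvCBFit(
        plant_id=curve.plant_id,
        vcmax=vc["vcmax"],
        jmax=jm["jmax"],
        rd_light=vc["rd_light"],
        gm=gm,
        vcmax_intercept=vc["intercept"],
        jmax_intercept=jm["intercept"],
        r2_vcmax=vc["r2"],
        r2_jmax=jm["r2"],
        points_used_vcmax=vc["n"],
        points_used_jmax=jm["n"],
    )
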