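"""Photosynthesis light-response (A–PPFD) curve fitting.

The net photosynthesis rate Pn (μmol CO₂·m⁻²·s⁻¹) is modelled as an
exponential rise to an asymptote,

    Pn(I) = Pg,max·[1 − exp(−α·I / Pg,max)] − Rd,

where I is the photosynthetic photon flux density (PPFD,
μmol·m⁻²·s⁻¹), Pg,max the asymptotic maximum gross photosynthesis,
α the light-use efficiency (initial slope, μmol CO₂·mol⁻¹ photons),
and Rd the dark respiration rate. Rd is stored as a positive
magnitude and subtracted by the model; instrument files that report
respiration as negative assimilation at PPFD = 0 are handled by the
initialisation.

Two derived light points follow in closed form:

* the light saturation point (LSP), the PPFD at which *net*
  photosynthesis reaches 85% of Pg,max:
  LSP = −(Pg,max/α)·ln(0.15 − Rd/Pg,max), defined only while
  Rd < 0.15·Pg,max. With ``basis="gross"`` the criterion is applied to
  gross photosynthesis instead, LSP = −(Pg,max/α)·ln(0.15).
* the light compensation point (LCP), the root Pn = 0:
  LCP = −(Pg,max/α)·ln(1 − Rd/Pg,max), defined while Rd < Pg,max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedTraitError,
)

__all__ = [
    "LightCurve",
    "LightResponseFit",
    "predict_pn",
    "fit_light_response",
    "light_saturation_point",
    "light_compensation_point",
    "SATURATION_FRACTION",
]

#: Fraction of Pg,max that defines light saturation.
SATURATION_FRACTION = 0.85


@dataclass
class LightCurve:
    """One plant's photosynthesis–PPFD response series."""

    plant_id: str
    ppfd: np.ndarray
    a_net: np.ndarray

    def __post_init__(self) -> None:
        self.ppfd = np.asarray(self.ppfd, dtype=float)
        self.a_net = np.asarray(self.a_net, dtype=float)
        if self.ppfd.shape != self.a_net.shape or self.ppfd.ndim != 1:
            raise InvalidInputError("ppfd and a_net must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.ppfd)) or not np.all(np.isfinite(self.a_net)):
            raise InvalidInputError("light curve contains non-finite values")
        if np.any(self.ppfd < 0):
            raise InvalidInputError("PPFD values must be >= 0")
        if np.unique(self.ppfd).size < 2:
            raise InvalidInputError("need at least 2 distinct PPFD levels")
        if not np.any(self.ppfd == 0):
            warnings.warn(
                f"curve {self.plant_id!r} has no PPFD=0 point; "
                "dark respiration is weakly identified",
                UserWarning,
                stacklevel=2,
            )


@dataclass
class LightResponseFit:
    """Estimated exponential light-response parameters for one curve.

    ``rd`` is the positive magnitude of dark respiration; writers that
    mimic instrument-report conventions should emit ``-rd``.
    """

    plant_id: str
    pg_max: float
    lue: float
    rd: float
    lsp: float
    lcp: float
    residual_sse: float
    converged: bool
    n_points: int
    param_covariance: np.ndarray = field(repr=False, default=None)


def predict_pn(
    params: dict | Sequence[float], ppfd: float | np.ndarray
) -> float | np.ndarray:
    """Net photosynthesis at the given PPFD under the exponential model.

    ``params`` is a mapping with keys ``pg_max``, ``lue``, ``rd`` or a
    sequence in that order. Requires pg_max > 0 and lue > 0.
    """
    if isinstance(params, dict):
        pg_max, lue, rd = params["pg_max"], params["lue"], params["rd"]
    else:
        pg_max, lue, rd = params
    if not np.isfinite(pg_max) or pg_max <= 0:
        raise InvalidParameterError(f"pg_max must be > 0, got {pg_max}")
    if not np.isfinite(lue) or lue <= 0:
        raise InvalidParameterError(f"lue must be > 0, got {lue}")
    ppfd = np.asarray(ppfd, dtype=float)
    pn = pg_max * (1.0 - np.exp(-lue * ppfd / pg_max)) - rd
    return float(pn) if pn.ndim == 0 else pn


def _initial_guess(ppfd: np.ndarray, a_net: np.ndarray) -> np.ndarray:
    """Heuristic start: asymptote from the response range, Rd from the
    dark point, α from the slope of the two lowest light levels."""
    pg0 = max(float(np.max(a_net) - np.min(a_net)), 0.5)
    dark = a_net[ppfd == 0]
    rd0 = max(float(-dark[0]), 0.0) if dark.size else 0.5
    order = np.argsort(ppfd)
    levels = np.unique(ppfd)
    p_lo, p_hi = levels[0], levels[1]
    a_lo = float(np.mean(a_net[ppfd == p_lo]))
    a_hi = float(np.mean(a_net[ppfd == p_hi]))
    lue0 = (a_hi - a_lo) / (p_hi - p_lo)
    lue0 = float(np.clip(lue0, 1e-3, 0.5))
    del order
    return np.array([pg0, lue0, rd0])


def fit_light_response(curve: LightCurve, lsp_basis: str = "net") -> LightResponseFit:
    """Nonlinear least-squares fit of the exponential light-response model.

    Minimises Σ(a_net − Pn(I))² over (pg_max, lue, rd) with all
    parameters bounded below by zero. Raises
    :class:`InsufficientDataError` for fewer than 4 points or fewer
    than 3 distinct PPFD levels, and :class:`FitFailureError` for
    zero-variance (unidentifiable) responses or optimizer failure.
    LSP/LCP are attached when defined, else NaN with a warning.
    """
    ppfd, a_net = curve.ppfd, curve.a_net
    if ppfd.size < 4:
        raise InsufficientDataError(
            f"curve {curve.plant_id!r}: need >= 4 points, got {ppfd.size}"
        )
    if np.unique(ppfd).size < 3:
        raise InsufficientDataError(
            f"curve {curve.plant_id!r}: need >= 3 distinct PPFD levels"
        )
    if np.ptp(a_net) == 0:
        raise FitFailureError(
            f"curve {curve.plant_id!r}: constant a_net, parameters unidentifiable"
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        pg, lue, rd = theta
        return pg * (1.0 - np.exp(-lue * ppfd / pg)) - rd - a_net

    x0 = _initial_guess(ppfd, a_net)
    sol = least_squares(
        residuals,
        x0,
        bounds=([1e-8, 1e-8, 0.0], [np.inf, np.inf, np.inf]),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=5000,
    )
    if sol.status <= 0:
        raise FitFailureError(
            f"curve {curve.plant_id!r}: optimizer failed ({sol.message})"
        )
    pg, lue, rd = (float(v) for v in sol.x)
    sse = float(2.0 * sol.cost)
    dof = ppfd.size - 3
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.pinv(jtj) * (sse / dof if dof > 0 else np.nan)
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        cov = np.full((3, 3), np.nan)

    fit = LightResponseFit(
        plant_id=curve.plant_id,
        pg_max=pg,
        lue=lue,
        rd=rd,
        lsp=np.nan,
        lcp=np.nan,
        residual_sse=sse,
        converged=True,
        n_points=int(ppfd.size),
        param_covariance=cov,
    )
    for attr, func in (("lsp", light_saturation_point), ("lcp", light_compensation_point)):
        try:
            if attr == "lsp":
                setattr(fit, attr, func(fit, basis=lsp_basis))
            else:
                setattr(fit, attr, func(fit))
        except UndefinedTraitError as exc:
            warnings.warn(str(exc), UserWarning, stacklevel=2)
    return fit


def _params(fit) -> tuple[float, float, float]:
    if isinstance(fit, dict):
        return fit["pg_max"], fit["lue"], fit["rd"]
    return fit.pg_max, fit.lue, fit.rd


def light_saturation_point(fit, basis: str = "net") -> float:
    """PPFD at which photosynthesis reaches 85% of Pg,max.

    With ``basis="net"`` (default) the criterion is on net
    photosynthesis and requires Rd < 0.15·Pg,max; with
    ``basis="gross"`` it is on gross photosynthesis and is always
    defined.
    """
    pg_max, lue, rd = _params(fit)
    if pg_max <= 0 or lue <= 0:
        raise InvalidParameterError("pg_max and lue must be > 0")
    residual_fraction = 1.0 - SATURATION_FRACTION
    if basis == "gross":
        return -(pg_max / lue) * np.log(residual_fraction)
    if basis != "net":
        raise InvalidParameterError(f"unknown LSP basis {basis!r}")
    arg = residual_fraction - rd / pg_max
    if arg <= 0:
        raise UndefinedTraitError(
            "LSP undefined: net photosynthesis never reaches "
            f"{SATURATION_FRACTION:.0%} of Pg,max (rd={rd:.3g} >= "
            f"{residual_fraction:.2f}*pg_max={residual_fraction * pg_max:.3g})"
        )
    return -(pg_max / lue) * np.log(arg)


def light_compensation_point(fit) -> float:
    """PPFD at which net photosynthesis is zero; requires Rd < Pg,max."""
    pg_max, lue, rd = _params(fit)
    if pg_max <= 0 or lue <= 0:
        raise InvalidParameterError("pg_max and lue must be > 0")
    if rd >= pg_max:
        raise UndefinedTraitError(
            f"LCP undefined: rd={rd:.3g} >= pg_max={pg_max:.3g}"
        )
    return -(pg_max / lue) * np.log(1.0 - rd / pg_max)
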