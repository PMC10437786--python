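"""Synthetic experiment generator for the full analysis pipeline.

Emulates a 2 nitrogen-level × 2 cultivar × 5 replicate split-plot
poinsettia screening experiment so every pipeline stage is testable
without raw greenhouse data. Three generators share one
:class:`SimConfig`:

* :func:`generate_trait_table` — balanced per-plant trait table:
  y = cell mean + main-plot (replicate × N) effect + residual, with
  an optional path-model mode in which correlated traits are drawn
  from a linear structural model per cell and shifted to the cell
  means.
* :func:`generate_light_curves` — photosynthesis–PPFD responses from
  the exponential model at the standard 10-level PPFD sequence
  (1500 … 0 μmol·m⁻²·s⁻¹) plus Gaussian noise.
* :func:`generate_aci_curves` — A–Ci responses as the minimum of a
  Rubisco-limited branch (Vcmax·f′ − Rd) and an electron-transport
  branch (Jmax·g′) on the standard cuvette CO₂ sequence, plus an
  ambient-CO₂ steady state whose electron transport rate is
  consistent with the target mesophyll conductance. The
  minimum-of-limitations form means points near the branch crossover
  can carry the "wrong" limitation into a regression window — that
  contamination is deliberate, to exercise robustness of the
  window-based fits. Pure-branch modes are available.

Default cell means are the least-squares means of a published-scale
poinsettia nitrogen-deficiency screen (two cultivars of contrasting
tolerance). Within-cell dispersions are not published, so residual
SDs are calibrated once from the means and their Tukey letter
patterns: the target HSD is the geometric mean of the largest
within-letter-group gap and the smallest between-group gap (see
docs/methods.md); the main-plot SD is 0.3× the residual SD. All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aci import ACiCurve, KineticConstants, f_prime, g_prime
from .errors import ConfigError, InvalidParameterError
from .light_response import LightCurve, predict_pn
from .pathmodel import PathSpec, simulate_from_path_model
from .splitplot import MAIN_PLOT, REPLICATE, SUB_PLOT

__all__ = [
    "SimConfig",
    "CELLS",
    "TRAIT_CELL_MEANS",
    "TRAIT_LETTERS",
    "DEFAULT_SIGMA",
    "LIGHT_PARAMS",
    "ACI_PARAMS",
    "PPFD_LEVELS",
    "CO2_LEVELS",
    "calibrated_residual_sd",
    "generate_trait_table",
    "generate_light_curves",
    "generate_aci_curves",
    "ambient_j_for_gm",
]

#: Cell order: (nitrogen level, cultivar).
CELLS: tuple[tuple[str, str], ...] = (
    ("deficient", "sensitive"),
    ("deficient", "tolerant"),
    ("optimal", "sensitive"),
    ("optimal", "tolerant"),
)

#: Standard PPFD step sequence of the light-response protocol.
PPFD_LEVELS: tuple[float, ...] = (1500, 1000, 800, 600, 400, 200, 150, 100, 50, 0)

#: Standard cuvette CO₂ step sequence of the A–Ci protocol (the grid
#: is used directly as Ci; no stomatal model).
CO2_LEVELS: tuple[float, ...] = (400, 600, 800, 1000, 600, 400, 200, 150, 100, 50)

# Cell means per trait, ordered as CELLS, with the Tukey letter
# pattern used to calibrate dispersions. Units follow the trait table
# conventions (mg/g for tissue N; ΔOD/g for ACN; mg/100g for CHL and
# CTD; μmol m⁻² s⁻¹ for gas-exchange rates and light points;
# mol m⁻² s⁻¹ for gm; g, cm², cm²/g, g/g for the harvest traits).
_TRAIT_TABLE: dict[str, tuple[tuple[float, ...], tuple[str, ...]]] = {
    "N_Leaf": ((19.9, 27.5, 36.9, 38.7), ("c", "b", "a", "a")),
    "N_Stem": ((12.2, 14.4, 28.0, 30.1), ("b", "b", "a", "a")),
    "N_LR": ((13.7, 13.2, 19.0, 19.8), ("b", "b", "a", "a")),
    "N_FR": ((20.9, 26.1, 35.6, 35.6), ("c", "b", "a", "a")),
    "ACN": ((0.162, 0.074, 0.016, 0.018), ("a", "b", "c", "c")),
    "CTD": ((1.21, 4.80, 3.79, 5.35), ("b", "a", "a", "a")),
    "CHL": ((12.95, 28.11, 27.78, 33.48), ("b", "a", "a", "a")),
    "Rd": ((-0.99, -1.36, -0.69, -1.20), ("a", "a", "a", "a")),
    "Pg_max": ((10.10, 14.47, 15.53, 17.41), ("c", "b", "b", "a")),
    "LCP": ((19.3, 29.0, 12.5, 18.2), ("ab", "a", "b", "ab")),
    "LUE": ((0.064, 0.059, 0.064, 0.060), ("a", "a", "a", "a")),
    "LSP": ((375.2, 569.2, 536.2, 585.2), ("b", "a", "a", "a")),
    "Vcmax": ((68.42, 100.20, 108.02, 117.78), ("a", "a", "a", "a")),
    "J_max": ((88.28, 118.80, 131.40, 147.60), ("c", "b", "ab", "a")),
    "gm": ((0.158, 0.230, 0.282, 0.250), ("a", "a", "a", "a")),
    "DW_Shoot": ((14.38, 19.93, 20.26, 20.95), ("b", "a", "a", "a")),
    "DW_Stem": ((4.37, 5.14, 5.48, 4.77), ("a", "a", "a", "a")),
    "DW_Leaf": ((9.96, 14.74, 15.016, 16.41), ("b", "a", "a", "a")),
    "DW_Root": ((4.01, 5.33, 4.16, 4.15), ("a", "a", "a", "a")),
    "DW_LR": ((2.37, 3.72, 2.48, 2.79), ("b", "a", "ab", "ab")),
    "DW_FR": ((1.59, 1.55, 1.74, 1.41), ("a", "a", "a", "a")),
    "Area_Leaf": ((1824.7, 2775.1, 3756.9, 3703.4), ("c", "b", "a", "a")),
    "SLA": ((178.2, 186.2, 234.1, 209.6), ("a", "a", "a", "a")),
    "RWR": ((0.206, 0.204, 0.159, 0.154), ("a", "a", "a", "a")),
}

TRAIT_CELL_MEANS: dict[str, dict[tuple[str, str], float]] = {
    trait: dict(zip(CELLS, means)) for trait, (means, _) in _TRAIT_TABLE.items()
}
TRAIT_LETTERS: dict[str, dict[tuple[str, str], str]] = {
    trait: dict(zip(CELLS, letters)) for trait, (_, letters) in _TRAIT_TABLE.items()
}

#: Exponential light-response parameters (pg_max, lue, rd>0) per cell.
LIGHT_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("deficient", "sensitive"): (10.10, 0.064, 0.99),
    ("deficient", "tolerant"): (14.47, 0.059, 1.36),
    ("optimal", "sensitive"): (15.53, 0.064, 0.69),
    ("optimal", "tolerant"): (17.41, 0.060, 1.20),
}

#: A–Ci parameters per cell: Vcmax, Jmax, gm, day respiration.
ACI_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("deficient", "sensitive"): {"vcmax": 68.42, "jmax": 88.28, "gm": 0.158, "rd": 0.99},
    ("deficient", "tolerant"): {"vcmax": 100.20, "jmax": 118.80, "gm": 0.230, "rd": 1.36},
    ("optimal", "sensitive"): {"vcmax": 108.02, "jmax": 131.40, "gm": 0.282, "rd": 0.69},
    ("optimal", "tolerant"): {"vcmax": 117.78, "jmax": 147.60, "gm": 0.250, "rd": 1.20},
}


def calibrated_residual_sd(
    means: Sequence[float],
    letters: Sequence[str],
    replicates: int = 5,
    alpha: float = 0.05,
) -> float:
    """Residual SD that makes the Tukey letter pattern reproducible.

    The within-main-plot HSD for a 2×2 design with r replicates is
    q(α; 4, 2(r−1))·σ_e/√r. We target an HSD of the geometric mean of
    the largest gap inside a letter group and the smallest gap between
    groups, so separated means stay separated and shared-letter means
    stay together in most realisations. When no two groups differ the
    target is twice the range of means (everything non-significant);
    when every group is a singleton it is half the smallest between
    gap.
    """
    means = np.asarray(means, dtype=float)
    within_max = 0.0
    between_min = np.inf
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            gap = abs(means[i] - means[j])
            if set(letters[i]) & set(letters[j]):
                within_max = max(within_max, gap)
            else:
                between_min = min(between_min, gap)
    if not np.isfinite(between_min):
        target = 2.0 * max(float(np.ptp(means)), 1e-6)
    elif within_max == 0.0:
        target = between_min / 2.0
    else:
        target = float(np.sqrt(within_max * between_min))
    df_resid = 2 * (replicates - 1)
    q = stats.studentized_range.ppf(1.0 - alpha, 4, df_resid)
    return float(target * np.sqrt(replicates) / q)


#: (main-plot SD, residual SD) per trait, calibrated once from the
#: default means and letter patterns at r = 5.
DEFAULT_SIGMA: dict[str, tuple[float, float]] = {
    trait: (
        0.3 * calibrated_residual_sd(means, letters),
        calibrated_residual_sd(means, letters),
    )
    for trait, (means, letters) in _TRAIT_TABLE.items()
}


@dataclass
class SimConfig:
    """Everything the generators need; defaults are the study design.

    ``cell_means``/``sigma`` drive the trait table, ``light_params``/
    ``aci_params`` the gas-exchange curves. ``limitation`` selects the
    A–Ci branch rule ("min", "rubisco", or "et"). Path-model mode is
    enabled by supplying ``path_spec`` (+ slopes and error variances);
    the spec'd traits are then drawn jointly per cell on the
    standardized scale, scaled by their residual SD, and shifted to
    the cell means.
    """

    n_levels: tuple[str, ...] = ("deficient", "optimal")
    cultivars: tuple[str, ...] = ("sensitive", "tolerant")
    replicates: int = 5
    cell_means: dict = field(default_factory=lambda: dict(TRAIT_CELL_MEANS))
    sigma: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    light_params: dict = field(default_factory=lambda: dict(LIGHT_PARAMS))
    light_noise_sd: float = 0.3
    aci_params: dict = field(default_factory=lambda: dict(ACI_PARAMS))
    aci_noise_sd: float = 0.3
    ppfd_levels: tuple[float, ...] = PPFD_LEVELS
    co2_levels: tuple[float, ...] = CO2_LEVELS
    leaf_temp: float = 25.0
    ci_ambient: float = 400.0
    kinetics: KineticConstants = field(default_factory=KineticConstants)
    limitation: str = "min"
    path_spec: PathSpec | None = None
    path_slopes: dict | None = None
    path_error_variances: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        if self.light_noise_sd < 0 or self.aci_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.limitation not in ("min", "rubisco", "et"):
            raise ConfigError(f"unknown limitation mode {self.limitation!r}")
        known = set(TRAIT_CELL_MEANS)
        unknown = set(self.cell_means) - known
        if unknown:
            raise ConfigError(f"unknown trait names in cell_means: {sorted(unknown)}")
        for trait, cells in self.cell_means.items():
            missing = [c for c in self.cells if c not in cells]
            if missing:
                raise ConfigError(f"trait {trait!r} missing cell means for {missing}")
        for trait in self.cell_means:
            if trait not in self.sigma:
                raise ConfigError(f"trait {trait!r} has no variance components")

    @property
    def cells(self) -> list[tuple[str, str]]:
        return [(n, c) for n in self.n_levels for c in self.cultivars]

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent streams per generator stage from the one config seed
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def generate_trait_table(cfg: SimConfig) -> pd.DataFrame:
    """Balanced per-plant trait table (one row per replicate × cell).

    Independent mode: y = cell mean + N(0, σ_M) main-plot effect
    shared by both cultivars of a replicate × N combination +
    N(0, σ_e) residual. Path mode adds cross-trait correlation for the
    traits of ``cfg.path_spec`` (see class docstring).
    """
    rng = _stage_rng(cfg, 1)
    traits = list(cfg.cell_means)
    rows = []
    for n_level in cfg.n_levels:
        for rep in range(1, cfg.replicates + 1):
            for cult in cfg.cultivars:
                rows.append({REPLICATE: rep, MAIN_PLOT: n_level, SUB_PLOT: cult})
    table = pd.DataFrame(rows)

    path_traits: list[str] = []
    if cfg.path_spec is not None:
        path_traits = [v for v in cfg.path_spec.variables]
        missing = [v for v in path_traits if v not in cfg.cell_means]
        if missing:
            raise ConfigError(f"path_spec variables lack cell means: {missing}")
        if cfg.path_slopes is None or cfg.path_error_variances is None:
            raise ConfigError("path mode needs path_slopes and path_error_variances")

    data = {t: np.empty(len(table)) for t in traits}
    for n_level in cfg.n_levels:
        for cult in cfg.cultivars:
            cell = (n_level, cult)
            mask = (table[MAIN_PLOT] == n_level) & (table[SUB_PLOT] == cult)
            idx = np.flatnonzero(mask.to_numpy())
            if path_traits:
                z = simulate_from_path_model(
                    cfg.path_spec,
                    cfg.path_slopes,
                    cfg.path_error_variances,
                    n=cfg.replicates,
                    seed=rng,
                )
                for t in path_traits:
                    _, sigma_e = cfg.sigma[t]
                    data[t][idx] = cfg.cell_means[t][cell] + sigma_e * z[t].to_numpy()
            for t in traits:
                if t in path_traits:
                    continue
                _, sigma_e = cfg.sigma[t]
                data[t][idx] = cfg.cell_means[t][cell] + rng.normal(
                    0.0, sigma_e, size=idx.size
                )
    # main-plot effects: one draw per trait x N-level x replicate,
    # shared by the cultivars within that whole plot
    for t in traits:
        sigma_m, _ = cfg.sigma[t]
        if sigma_m == 0:
            continue
        for n_level in cfg.n_levels:
            for rep in range(1, cfg.replicates + 1):
                mask = (table[MAIN_PLOT] == n_level) & (table[REPLICATE] == rep)
                data[t][mask.to_numpy()] += rng.normal(0.0, sigma_m)
    for t in traits:
        table[t] = data[t]
    return table


def _plant_id(cell: tuple[str, str], rep: int) -> str:
    return f"{cell[0]}:{cell[1]}:rep{rep}"


def generate_light_curves(cfg: SimConfig) -> list[LightCurve]:
    """One light-response curve per plant (cell × replicate)."""
    rng = _stage_rng(cfg, 2)
    ppfd = np.asarray(cfg.ppfd_levels, dtype=float)
    curves = []
    for cell in cfg.cells:
        pg_max, lue, rd = cfg.light_params[cell]
        for rep in range(1, cfg.replicates + 1):
            a = predict_pn({"pg_max": pg_max, "lue": lue, "rd": rd}, ppfd)
            noise = rng.normal(0.0, cfg.light_noise_sd, size=ppfd.size)
            curves.append(
                LightCurve(plant_id=_plant_id(cell, rep), ppfd=ppfd, a_net=a + noise)
            )
    return curves


def _aci_response(
    ci: np.ndarray, vcmax: float, jmax: float, rd: float, k: KineticConstants,
    leaf_temp: float, limitation: str,
) -> np.ndarray:
    rub = vcmax * np.asarray(f_prime(ci, leaf_temp, k)) - rd
    et = jmax * np.asarray(g_prime(ci, k))
    if limitation == "rubisco":
        return rub
    if limitation == "et":
        return et
    return np.minimum(rub, et)


def ambient_j_for_gm(
    a: float, ci: float, gm: float, rd: float, k: KineticConstants | None = None
) -> float:
    """Electron transport rate consistent with a target gm.

    Inverts the variable-J relation at the ambient steady state:
    Cc = Ci − A/gm must exceed Γ*, then
    J = 4·(A+Rd)·(2 + Cc/Γ*)/(Cc/Γ* − 1).
    """
    k = k or KineticConstants()
    cc = ci - a / gm
    if cc <= k.gamma_star:
        raise InvalidParameterError(
            f"target gm={gm:.3g} implies Cc={cc:.3g} <= gamma_star={k.gamma_star:g}"
        )
    c_ratio = cc / k.gamma_star
    return 4.0 * (a + rd) * (2.0 + c_ratio) / (c_ratio - 1.0)


def generate_aci_curves(cfg: SimConfig) -> list[ACiCurve]:
    """One A–Ci curve per plant, with a consistent ambient steady state.

    The ambient row (Ci = ``cfg.ci_ambient``) carries the noiseless
    assimilation and the electron transport rate that makes the
    variable-J method return the cell's target gm exactly, so a
    noiseless round trip through the A–Ci fits recovers all
    parameters. Warns when the Ci grid does not span both regression
    windows.
    """
    import warnings

    from .aci import JMAX_CI_WINDOW, VCMAX_CI_WINDOW

    rng = _stage_rng(cfg, 3)
    ci = np.asarray(cfg.co2_levels, dtype=float)
    n_vc = np.sum((ci >= VCMAX_CI_WINDOW[0]) & (ci <= VCMAX_CI_WINDOW[1]))
    n_jm = np.sum((ci >= JMAX_CI_WINDOW[0]) & (ci <= JMAX_CI_WINDOW[1]))
    if n_vc < 2 or n_jm < 2:
        warnings.warn(
            "Ci grid does not span both regression windows "
            f"({n_vc} Rubisco points, {n_jm} electron-transport points)",
            UserWarning,
            stacklevel=2,
        )
    curves = []
    for cell in cfg.cells:
        p = cfg.aci_params[cell]
        for rep in range(1, cfg.replicates + 1):
            a = _aci_response(
                ci, p["vcmax"], p["jmax"], p["rd"], cfg.kinetics, cfg.leaf_temp,
                cfg.limitation,
            )
            noise = rng.normal(0.0, cfg.aci_noise_sd, size=ci.size)
            a_amb = float(
                _aci_response(
                    np.array([cfg.ci_ambient]), p["vcmax"], p["jmax"], p["rd"],
                    cfg.kinetics, cfg.leaf_temp, cfg.limitation,
                )[0]
            )
            j_amb = ambient_j_for_gm(
                a_amb, cfg.ci_ambient, p["gm"], p["rd"], cfg.kinetics
            )
            curves.append(
                ACiCurve(
                    plant_id=_plant_id(cell, rep),
                    ci=ci,
                    a_net=a + noise,
                    leaf_temp=cfg.leaf_temp,
                    j_ambient=j_amb,
                    a_ambient=a_amb,
                    ci_ambient=cfg.ci_ambient,
                )
            )
    return curves
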