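"""End-to-end pipeline: simulate/ingest → fits → ANOVA report → path models.

Orders the analysis stages the way the experiment is analysed:
pigment quantification and gas-exchange curve fits produce leaf-scale
traits, the trait table is compared across treatments with the
split-plot ANOVA and Tukey letters, and the nitrogen-deficient
subset is fed to the recursive path models. Every run logs the
package version, a config hash, and the seed, and all randomness
flows from that one seed, so any report can be reproduced from its
log header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, synthdata
from .aci import KineticConstants, fit_aci
from .errors import NitrophysError, SchemaError
from .light_response import fit_light_response
from .pathmodel import BUILTIN_SPECS, PathSpec, fit_path_model
from .pigments import quantify_pigments
from .splitplot import MAIN_PLOT, REPLICATE, SUB_PLOT, anova_split_plot

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "load_path_spec"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable).

    With ``simulate=True`` the inputs are generated from the default
    synthetic experiment; otherwise file paths must be supplied for
    the stages that are enabled.
    """

    outdir: str = "out"
    seed: int = 0
    alpha: float = 0.05
    simulate: bool = True
    trait_table: str | None = None
    light_curves: str | None = None
    aci_curves: str | None = None
    absorbance: str | None = None
    gamma_star: float = 31.0
    o2: float = 210.0
    r_gas: float = 0.008315
    lsp_basis: str = "net"
    jmax_intercept: bool = False
    anova_traits: list[str] = field(default_factory=list)
    path_models: list[str] = field(default_factory=lambda: ["acn", "chl", "pgmax"])
    path_subset: str | None = "deficient"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise NitrophysError(f"alpha must be in (0, 1), got {self.alpha}")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def load_path_spec(path: str | Path) -> PathSpec:
    """Load a custom path model from a YAML config (variables + edges)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "edges" not in raw:
        raise SchemaError("path-model config needs 'edges' (and optional 'variables')")
    edges = [tuple(e) for e in raw["edges"]]
    variables = raw.get("variables")
    if variables is None:
        variables = []
        for s, t in edges:
            for v in (s, t):
                if v not in variables:
                    variables.append(v)
    return PathSpec(
        variables=tuple(variables),
        edges=tuple(edges),
        name=str(raw.get("name", Path(path).stem)),
    )


def _kinetics(cfg: PipelineConfig) -> KineticConstants:
    return KineticConstants(gamma_star=cfg.gamma_star, o2=cfg.o2, r_gas=cfg.r_gas)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the report bundle.

    Outputs are written under ``cfg.outdir``. A stage error aborts
    downstream stages (partial outputs are retained) and re-raises.
    """
    logging.basicConfig(level=cfg.log_level)
    logger.info(
        "nitrophys %s | config %s | seed %d", __version__, cfg.config_hash(), cfg.seed
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if cfg.simulate:
        sim = synthdata.SimConfig(seed=cfg.seed)
        trait_table = synthdata.generate_trait_table(sim)
        light_curves = synthdata.generate_light_curves(sim)
        aci_curves = synthdata.generate_aci_curves(sim)
        io.write_table(trait_table, outdir / "traits.csv")
        io.write_table(io.light_curves_frame(light_curves), outdir / "light_curves.csv")
        io.write_table(io.aci_curves_frame(aci_curves), outdir / "aci_curves.csv")
    else:
        trait_table = (
            io.read_trait_table(cfg.trait_table) if cfg.trait_table else None
        )
        light_curves = io.read_light_curves(cfg.light_curves) if cfg.light_curves else []
        aci_curves = io.read_aci_curves(cfg.aci_curves) if cfg.aci_curves else []

    if cfg.absorbance:
        records = io.read_absorbance_records(cfg.absorbance)
        pigments = [(sid, quantify_pigments(rec)) for sid, rec in records]
        frame = io.pigment_results_frame(pigments)
        io.write_table(frame, outdir / "pigments.csv")
        bundle["pigments"] = frame

    if light_curves:
        fits = [fit_light_response(c, lsp_basis=cfg.lsp_basis) for c in light_curves]
        frame = io.light_fits_frame(fits)
        io.write_table(frame, outdir / "light_fits.csv")
        bundle["light_fits"] = frame

    if aci_curves:
        k = _kinetics(cfg)
        fits = [fit_aci(c, k, jmax_intercept=cfg.jmax_intercept) for c in aci_curves]
        frame = io.aci_fits_frame(fits)
        io.write_table(frame, outdir / "aci_fits.csv")
        bundle["aci_fits"] = frame

    if trait_table is not None:
        traits = cfg.anova_traits or [
            c
            for c in trait_table.columns
            if c not in (REPLICATE, MAIN_PLOT, SUB_PLOT)
            and pd.api.types.is_numeric_dtype(trait_table[c])
        ]
        missing = [t for t in traits if t not in trait_table.columns]
        if missing:
            raise SchemaError(f"anova traits not in trait table: {missing}")
        results = {t: anova_split_plot(trait_table, t, alpha=cfg.alpha) for t in traits}
        bundle["anova"] = results
        report = _means_letters_report(results)
        (outdir / "anova_report.txt").write_text(report)
        io.write_table(_means_letters_frame(results), outdir / "anova_means.csv")

        if cfg.path_models:
            subset = trait_table
            if cfg.path_subset is not None:
                subset = trait_table[trait_table[MAIN_PLOT] == cfg.path_subset]
            path_fits = {}
            for name in cfg.path_models:
                spec = (
                    BUILTIN_SPECS[name]
                    if name in BUILTIN_SPECS
                    else load_path_spec(name)
                )
                fit = fit_path_model(subset, spec)
                path_fits[spec.name] = fit
                io.write_table(fit.edges, outdir / f"path_{spec.name}_edges.csv")
            bundle["path"] = path_fits
            summary = "\n\n".join(f.summary() for f in path_fits.values())
            (outdir / "path_report.txt").write_text(summary + "\n")

    return bundle


def _means_letters_frame(results: dict) -> pd.DataFrame:
    rows = []
    for trait, res in results.items():
        for (n_level, cultivar), mean in res.cell_means.items():
            rows.append(
                {
                    "trait": trait,
                    MAIN_PLOT: n_level,
                    SUB_PLOT: cultivar,
                    "ls_mean": mean,
                    "letters": res.letters.get((n_level, cultivar), ""),
                    "p_main": res.p_main,
                    "p_sub": res.p_sub,
                    "p_interaction": res.p_interaction,
                }
            )
    return pd.DataFrame(rows)


def _means_letters_report(results: dict) -> str:
    """Plain-text table: one row per trait, 'mean letter' per cell."""
    cells = None
    lines = []
    for trait, res in results.items():
        if cells is None:
            cells = sorted(res.cell_means)
            header = ["trait".ljust(12)] + [
                f"{n}/{c}".rjust(20) for n, c in cells
            ]
            lines.append(" ".join(header))
        row = [trait.ljust(12)]
        for cell in cells:
            mean = res.cell_means[cell]
            letters = res.letters.get(cell, "")
            row.append(f"{mean:.4g} {letters}".rjust(20))
        lines.append(" ".join(row))
    return "\n".join(lines) + "\n"
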