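"""Readers and writers for the pipeline's tabular formats.

CSV is the canonical interchange format; XLSX is supported for
ingest (supplementary workbooks), with a config-driven sheet and
column mapping because deposited workbook schemas vary. All readers
validate their schema up front and raise :class:`SchemaError` naming
the expected columns, so a mismatch fails with an actionable message
rather than a KeyError deep in the analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .aci import ACiCurve, FvCBFit
from .errors import SchemaError
from .light_response import LightCurve, LightResponseFit
from .pigments import AbsorbanceRecord, PigmentResult
from .splitplot import MAIN_PLOT, REPLICATE, SUB_PLOT, check_balance
from .traits import PlantHarvest

__all__ = [
    "read_table",
    "read_trait_table",
    "write_table",
    "read_absorbance_records",
    "pigment_results_frame",
    "read_light_curves",
    "light_curves_frame",
    "light_fits_frame",
    "read_aci_curves",
    "aci_curves_frame",
    "aci_fits_frame",
    "read_harvest_table",
    "derived_traits_frame",
]

ABSORBANCE_COLUMNS = (
    "sample_id",
    "a663_2",
    "a646_8",
    "a470",
    "a530",
    "a600",
    "mass_g",
    "volume_ml",
    "dilution",
)
LIGHT_COLUMNS = ("plant_id", "ppfd", "a_net")
ACI_COLUMNS = ("plant_id", "ci", "a_net", "leaf_temp")
HARVEST_COLUMNS = ("plant_id", "dw_leaf", "dw_stem", "dw_lr", "dw_fr", "area_leaf")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing columns {missing}; expected at least "
            f"{list(required)}, got {list(df.columns)}"
        )


def read_table(
    path: str | Path,
    sheet: str | int | None = None,
    column_map: dict[str, str] | None = None,
    header_row: int = 0,
) -> pd.DataFrame:
    """Read a CSV or XLSX table, optionally renaming columns.

    ``column_map`` maps source column names to canonical names and is
    applied after reading, so a workbook with arbitrary headers can be
    ingested once its mapping is supplied.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, sheet_name=sheet or 0, header=header_row)
    else:
        df = pd.read_csv(path, header=header_row)
    if column_map:
        unknown = [c for c in column_map if c not in df.columns]
        if unknown:
            raise SchemaError(
                f"{path.name}: column_map refers to absent columns {unknown}; "
                f"available: {list(df.columns)}"
            )
        df = df.rename(columns=column_map)
    return df


def read_trait_table(
    path: str | Path,
    sheet: str | int | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a trait table (design columns + trait columns)."""
    df = read_table(path, sheet=sheet, column_map=column_map)
    _require_columns(df, (REPLICATE, MAIN_PLOT, SUB_PLOT), "trait table")
    check_balance(df)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_absorbance_records(path: str | Path) -> list[tuple[str, AbsorbanceRecord]]:
    df = read_table(path)
    _require_columns(df, ABSORBANCE_COLUMNS, "absorbance table")
    records = []
    for _, row in df.iterrows():
        records.append(
            (
                str(row["sample_id"]),
                AbsorbanceRecord(
                    a663_2=float(row["a663_2"]),
                    a646_8=float(row["a646_8"]),
                    a470=float(row["a470"]),
                    a530=float(row["a530"]),
                    a600=float(row["a600"]),
                    sample_mass=float(row["mass_g"]),
                    extraction_volume=float(row["volume_ml"]),
                    dilution_factor=float(row["dilution"]),
                ),
            )
        )
    return records


def pigment_results_frame(results: list[tuple[str, PigmentResult]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": sid,
                "chl_a_conc": r.chl_a_conc,
                "chl_b_conc": r.chl_b_conc,
                "ctd_conc": r.ctd_conc,
                "chl_a_fw": r.chl_a_fw,
                "chl_b_fw": r.chl_b_fw,
                "chl_fw": r.chl_fw,
                "ctd_fw": r.ctd_fw,
                "acn": r.acn,
            }
            for sid, r in results
        ]
    )


def read_light_curves(path: str | Path) -> list[LightCurve]:
    """Read long-format light curves (plant_id, ppfd, a_net)."""
    df = read_table(path)
    _require_columns(df, LIGHT_COLUMNS, "light-curve table")
    return [
        LightCurve(
            plant_id=str(pid),
            ppfd=grp["ppfd"].to_numpy(float),
            a_net=grp["a_net"].to_numpy(float),
        )
        for pid, grp in df.groupby("plant_id", sort=True)
    ]


def light_curves_frame(curves: list[LightCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for p, a in zip(c.ppfd, c.a_net):
            rows.append({"plant_id": c.plant_id, "ppfd": p, "a_net": a})
    return pd.DataFrame(rows)


def light_fits_frame(fits: list[LightResponseFit]) -> pd.DataFrame:
    """One row per plant; ``rd_reported`` re-emits the instrument-style
    negative sign while ``rd`` stays a positive magnitude."""
    return pd.DataFrame(
        [
            {
                "plant_id": f.plant_id,
                "pg_max": f.pg_max,
                "lue": f.lue,
                "rd": f.rd,
                "rd_reported": -f.rd,
                "lsp": f.lsp,
                "lcp": f.lcp,
                "residual_sse": f.residual_sse,
                "converged": f.converged,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )


def read_aci_curves(path: str | Path) -> list[ACiCurve]:
    """Read long-format A–Ci curves.

    Columns: plant_id, ci, a_net, leaf_temp, optional j, optional
    is_ambient flag (exactly one row per plant); the ambient row
    supplies (a_ambient, ci_ambient, j_ambient) and is excluded from
    the step series.
    """
    df = read_table(path)
    _require_columns(df, ACI_COLUMNS, "A-Ci table")
    has_ambient = "is_ambient" in df.columns
    curves = []
    for pid, grp in df.groupby("plant_id", sort=True):
        a_amb = ci_amb = j_amb = np.nan
        steps = grp
        if has_ambient:
            amb = grp[grp["is_ambient"] == 1]
            steps = grp[grp["is_ambient"] != 1]
            if len(amb) > 1:
                raise SchemaError(f"plant {pid!r}: multiple is_ambient rows")
            if len(amb) == 1:
                a_amb = float(amb["a_net"].iloc[0])
                ci_amb = float(amb["ci"].iloc[0])
                j_amb = float(amb["j"].iloc[0]) if "j" in amb.columns else np.nan
        curves.append(
            ACiCurve(
                plant_id=str(pid),
                ci=steps["ci"].to_numpy(float),
                a_net=steps["a_net"].to_numpy(float),
                leaf_temp=float(steps["leaf_temp"].iloc[0]),
                j_ambient=j_amb,
                a_ambient=a_amb,
                ci_ambient=ci_amb,
            )
        )
    return curves


def aci_curves_frame(curves: list[ACiCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for ci, a in zip(c.ci, c.a_net):
            rows.append(
                {
                    "plant_id": c.plant_id,
                    "ci": ci,
                    "a_net": a,
                    "leaf_temp": c.leaf_temp,
                    "j": np.nan,
                    "is_ambient": 0,
                }
            )
        if np.isfinite(c.a_ambient):
            rows.append(
                {
                    "plant_id": c.plant_id,
                    "ci": c.ci_ambient,
                    "a_net": c.a_ambient,
                    "leaf_temp": c.leaf_temp,
                    "j": c.j_ambient,
                    "is_ambient": 1,
                }
            )
    return pd.DataFrame(rows)


def aci_fits_frame(fits: list[FvCBFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": f.plant_id,
                "vcmax": f.vcmax,
                "jmax": f.jmax,
                "rd_light": f.rd_light,
                "gm": f.gm,
                "r2_vcmax": f.r2_vcmax,
                "r2_jmax": f.r2_jmax,
                "points_used_vcmax": f.points_used_vcmax,
                "points_used_jmax": f.points_used_jmax,
            }
            for f in fits
        ]
    )


def read_harvest_table(path: str | Path) -> list[PlantHarvest]:
    df = read_table(path)
    _require_columns(df, HARVEST_COLUMNS, "harvest table")
    return [
        PlantHarvest(
            plant_id=str(row["plant_id"]),
            dw_leaf=float(row["dw_leaf"]),
            dw_stem=float(row["dw_stem"]),
            dw_lr=float(row["dw_lr"]),
            dw_fr=float(row["dw_fr"]),
            area_leaf=float(row["area_leaf"]),
        )
        for _, row in df.iterrows()
    ]


def derived_traits_frame(derived) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": d.plant_id,
                "dw_shoot": d.dw_shoot,
                "dw_root": d.dw_root,
                "sla": d.sla,
                "rwr": d.rwr,
            }
            for d in derived
        ]
    )
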