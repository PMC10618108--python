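"""Flat CSV schemas for the simulation/estimation pipeline.

Every table has a header, explicit units in column names and a
format_version column, so outputs stay language-agnostic and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .geometry import BodyShape
from .microtome import SectionStack

FORMAT_VERSION = "1"

CELLS_COLUMNS = [
    "format_version", "cell_id", "species", "stage", "perturbation",
    "nucleus_r_nm", "V_nuc_nm3", "cytoplasm_r_nm", "V_cyto_nm3",
    "mspb1_r_nm", "mspb2_r_nm", "spb_axis_x", "spb_axis_y", "spb_axis_z",
    "N_mit_true", "V_mit_total_true_nm3", "n_spb1", "n_spb2",
]
MITOSOMES_COLUMNS = [
    "format_version", "cell_id", "mito_id", "r_nm", "L_nm", "tether",
    "cx_nm", "cy_nm", "cz_nm", "ax", "ay", "az",
]
PROFILES_COLUMNS = [
    "format_version", "cell_id", "body_id", "section_index",
    "z_lo_nm", "t_nm", "spacing_nm", "mode", "area_nm2", "point_hits",
]
ESTIMATES_COLUMNS = [
    "format_version", "cell_id", "quantity", "value", "units", "ce",
    "correction_factor",
]


def cells_frame(cells: Iterable) -> pd.DataFrame:
    rows = []
    for c in cells:
        n1, n2 = c.spb_counts
        rows.append({
            "format_version": FORMAT_VERSION,
            "cell_id": c.cell_id,
            "species": c.species,
            "stage": c.stage,
            "perturbation": c.perturbation,
            "nucleus_r_nm": c.nucleus_radius,
            "V_nuc_nm3": c.v_nucleus,
            "cytoplasm_r_nm": c.cytoplasm_radius,
            "V_cyto_nm3": c.v_cytoplasm,
            "mspb1_r_nm": c.mspb[0].radius,
            "mspb2_r_nm": c.mspb[1].radius,
            "spb_axis_x": c.mspb[0].axis[0],
            "spb_axis_y": c.mspb[0].axis[1],
            "spb_axis_z": c.mspb[0].axis[2],
            "N_mit_true": c.n_true,
            "V_mit_total_true_nm3": c.v_true,
            "n_spb1": n1,
            "n_spb2": n2,
        })
    return pd.DataFrame(rows, columns=CELLS_COLUMNS)


def mitosomes_frame(cells: Iterable) -> pd.DataFrame:
    rows = []
    for c in cells:
        for i, (m, tether) in enumerate(zip(c.mitosomes, c.tether)):
            rows.append({
                "format_version": FORMAT_VERSION,
                "cell_id": c.cell_id,
                "mito_id": f"mito{i}",
                "r_nm": m.radius,
                "L_nm": m.length,
                "tether": tether,
                "cx_nm": m.center[0], "cy_nm": m.center[1], "cz_nm": m.center[2],
                "ax": m.axis[0], "ay": m.axis[1], "az": m.axis[2],
            })
    return pd.DataFrame(rows, columns=MITOSOMES_COLUMNS)


def profiles_frame(cell_id: str, stack: SectionStack) -> pd.DataFrame:
    rows = []
    for i, slab in enumerate(stack.slabs):
        for bid, pres in stack.presence.items():
            if not pres[i]:
                continue
            rows.append({
                "format_version": FORMAT_VERSION,
                "cell_id": cell_id,
                "body_id": bid,
                "section_index": i,
                "z_lo_nm": slab.z_lo,
                "t_nm": slab.thickness,
                "spacing_nm": stack.spacing_nm,
                "mode": stack.mode,
                "area_nm2": stack.areas[bid][i] if stack.areas is not None else np.nan,
                "point_hits": "",
            })
    return pd.DataFrame(rows, columns=PROFILES_COLUMNS)


def estimates_frame(rows: Iterable[dict]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    for col in ESTIMATES_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("cell_id", "quantity", "units") else np.nan
    df["format_version"] = FORMAT_VERSION
    return df[ESTIMATES_COLUMNS]


@dataclass
class LoadedCell:
    """A cell reconstructed from cells.csv + mitosomes.csv."""

    cell_id: str
    species: str
    stage: str
    nucleus_radius: float
    cytoplasm_radius: float
    v_nucleus: float
    v_cytoplasm: float
    n_true: int
    v_true: float
    n_spb1: int
    n_spb2: int
    bodies: dict[str, BodyShape]
    tether: dict[str, str]

    @property
    def spb_counts(self) -> tuple[int, int]:
        return (self.n_spb1, self.n_spb2)

    @property
    def v_cell(self) -> float:
        return self.v_cytoplasm + self.v_nucleus

    def mitosome_bodies(self) -> dict[str, BodyShape]:
        return dict(self.bodies)


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {', '.join(missing)}")


def load_cells(cells_csv: Path | str, mitosomes_csv: Path | str) -> list[LoadedCell]:
    cells = pd.read_csv(cells_csv, dtype={"cell_id": str})
    mitos = pd.read_csv(mitosomes_csv, dtype={"cell_id": str}) if Path(mitosomes_csv).exists() else pd.DataFrame(columns=MITOSOMES_COLUMNS)
    _require_columns(cells, [c for c in CELLS_COLUMNS if c != "format_version"], "cells.csv")
    _require_columns(mitos, [c for c in MITOSOMES_COLUMNS if c != "format_version"], "mitosomes.csv")
    out = []
    for _, row in cells.iterrows():
        sub = mitos[mitos.cell_id == row.cell_id]
        bodies = {}
        tether = {}
        for _, m in sub.iterrows():
            bid = f"{row.cell_id}:{m.mito_id}"
            axis = np.array([m.ax, m.ay, m.az], dtype=float)
            axis /= np.linalg.norm(axis)
            bodies[bid] = BodyShape(
                "spherocylinder", [m.cx_nm, m.cy_nm, m.cz_nm], float(m.r_nm),
                axis=axis, length=float(m.L_nm),
            )
            tether[bid] = str(m.tether)
        out.append(LoadedCell(
            cell_id=str(row.cell_id), species=str(row.species), stage=str(row.stage),
            nucleus_radius=float(row.nucleus_r_nm),
            cytoplasm_radius=float(row.cytoplasm_r_nm),
            v_nucleus=float(row.V_nuc_nm3), v_cytoplasm=float(row.V_cyto_nm3),
            n_true=int(row.N_mit_true), v_true=float(row.V_mit_total_true_nm3),
            n_spb1=int(row.n_spb1), n_spb2=int(row.n_spb2),
            bodies=bodies, tether=tether,
        ))
    return out


def write_csv(df: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
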