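"""Tumoral/stromal compartment assignment and per-core quantification.

A core is a disc of tissue with a cytokeratin(CK)-positive tumor-cell
region inside it. Cells whose centroid falls inside (or on the boundary of)
the tumor region are *tumoral*, all others *stromal*. Densities are counts
divided by the corresponding compartment area in mm²; "total" densities use
the whole core area, which keeps the three levels mutually consistent
(tumoral count + stromal count = total count, tumor area + stromal area =
core area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

UM2_PER_MM2 = 1e6

COMPARTMENTS = ["tumoral", "stromal", "total"]

#: Immune phenotypes that make up the CD45+ composition partition.
IMMUNE_PHENOTYPES = ["T_cell", "B_cell", "NK_cell", "macrophage", "other_immune"]


class GeometryError(ValueError):
    """Degenerate or inconsistent region geometry."""


class JoinError(ValueError):
    """Core/patient identifiers do not match one-to-one."""


@dataclass
class RegionMask:
    """Tumor-region geometry of one TMA core, coordinates in µm."""

    core_id: str
    tumor: MultiPolygon | Polygon
    core: Polygon

    @property
    def tumor_area_mm2(self) -> float:
        return self.tumor.area / UM2_PER_MM2

    @property
    def core_area_mm2(self) -> float:
        return self.core.area / UM2_PER_MM2

    @property
    def stromal_area_mm2(self) -> float:
        return self.core_area_mm2 - self.tumor_area_mm2

    def validate(self) -> None:
        if not self.tumor.is_valid or not self.core.is_valid:
            raise GeometryError(f"core {self.core_id}: invalid (self-intersecting?) geometry")
        if self.stromal_area_mm2 < -1e-6:
            raise GeometryError(f"core {self.core_id}: tumor area exceeds core area")


def make_core_disc(diameter_um: float, n_vertices: int = 128) -> Polygon:
    """Polygonal approximation of a circular TMA core.

    Origin of the coordinate frame is the bounding-box corner, so the disc
    is centred at (r, r).
    """
    r = diameter_um / 2.0
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    pts = np.column_stack([r + r * np.cos(theta), r + r * np.sin(theta)])
    return Polygon(pts)


def assign_compartment(cells: pd.DataFrame, mask: RegionMask) -> pd.Series:
    """Label every cell 'tumoral' or 'stromal' by centroid-in-polygon.

    Boundary-inclusive: a centroid exactly on the tumor-region boundary is
    tumoral.
    """
    inside = shapely.intersects_xy(
        mask.tumor, cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float)
    )
    return pd.Series(np.where(inside, "tumoral", "stromal"), index=cells.index, name="compartment")


def mask_from_ck_cells(cells: pd.DataFrame, ck_positive: pd.Series,
                       core: Polygon, core_id: str, radius_um: float = 10.0) -> RegionMask:
    """Derive a tumor mask as the union of disks around CK+ cell centroids.

    Fallback for inputs that ship no region geometry; the generator and any
    upstream region map take precedence when available.
    """
    pos = cells.loc[ck_positive.to_numpy(bool)]
    if len(pos) == 0:
        return RegionMask(core_id=core_id, tumor=Polygon(), core=core)
    disks = [Point(x, y).buffer(radius_um, quad_segs=8)
             for x, y in zip(pos["x_um"], pos["y_um"])]
    tumor = unary_union(disks).intersection(core)
    if isinstance(tumor, Polygon):
        tumor = MultiPolygon([tumor])
    return RegionMask(core_id=core_id, tumor=tumor, core=core)


# --- subsets quantified per core ------------------------------------------

def _subset_masks(calls: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Boolean membership per quantified subset.

    ``calls`` carries columns phenotype, cd57, cd16, nkg2a and hlae
    (HLA-E positivity, meaningful for tumor cells).
    """
    ph = calls["phenotype"].to_numpy()
    cd57 = calls["cd57"].to_numpy(bool)
    cd16 = calls["cd16"].to_numpy(bool)
    nkg2a = calls["nkg2a"].to_numpy(bool)
    hlae = calls["hlae"].to_numpy(bool) if "hlae" in calls else np.zeros(len(calls), bool)

    is_imm = np.isin(ph, IMMUNE_PHENOTYPES)
    subsets: Dict[str, np.ndarray] = {}
    for name, label in [("T", "T_cell"), ("B", "B_cell"), ("NK", "NK_cell"),
                        ("macrophage", "macrophage"), ("other_immune", "other_immune")]:
        m = ph == label
        subsets[name] = m
        if name != "other_immune":
            subsets[f"CD16_{name}"] = m & cd16
            subsets[f"NKG2A_{name}"] = m & nkg2a
    subsets["CD57_T"] = (ph == "T_cell") & cd57
    subsets["CD57_NK"] = (ph == "NK_cell") & cd57
    subsets["CD16_CD57_NK"] = subsets["CD57_NK"] & cd16
    subsets["NKG2A_CD57_NK"] = subsets["CD57_NK"] & nkg2a
    subsets["CD45_CD57"] = is_imm & cd57
    subsets["CD45"] = is_imm
    subsets["HLAE_tumor"] = (ph == "tumor_cell") & hlae
    return subsets


@dataclass
class CoreQuant:
    """Counts, densities (cells/mm²) and composition fractions of one core."""

    core_id: str
    counts: Dict[tuple, int]
    densities: Dict[tuple, float]
    composition: Dict[str, float]
    hlae_tumor_density: float
    areas_mm2: Dict[str, float] = field(default_factory=dict)


def pooled_composition(calls: pd.DataFrame) -> Dict[str, float]:
    """Composition fractions without geometry (pooled over cells).

    Among CD45+ cells: fraction of T, B, NK, macrophage, other_immune.
    Among CD45+CD57+ cells: NK share with denominator CD57+T + CD57+NK.
    Undefined fractions (zero denominator) are reported as NaN, never 0.
    """
    subsets = _subset_masks(calls)
    n_imm = int(subsets["CD45"].sum())
    comp: Dict[str, float] = {}
    for name in ["T", "B", "NK", "macrophage", "other_immune"]:
        comp[f"{name}_of_CD45"] = subsets[name].sum() / n_imm if n_imm else float("nan")
    n57 = int(subsets["CD57_T"].sum() + subsets["CD57_NK"].sum())
    comp["NK_of_CD45_CD57"] = subsets["CD57_NK"].sum() / n57 if n57 else float("nan")
    comp["T_of_CD45_CD57"] = subsets["CD57_T"].sum() / n57 if n57 else float("nan")
    return comp


def quantify_core(calls: pd.DataFrame, compartments: pd.Series, mask: RegionMask) -> CoreQuant:
    """Per-core counts, densities and composition for every subset.

    Tumoral counts are divided by the tumor area, stromal by the stromal
    area, totals by the whole core area.
    """
    mask.validate()
    subsets = _subset_masks(calls)
    comp_arr = compartments.to_numpy()
    areas = {
        "tumoral": mask.tumor_area_mm2,
        "stromal": mask.stromal_area_mm2,
        "total": mask.core_area_mm2,
    }
    counts: Dict[tuple, int] = {}
    densities: Dict[tuple, float] = {}
    for name, member in subsets.items():
        for comp in COMPARTMENTS:
            if comp == "total":
                n = int(member.sum())
            else:
                n = int((member & (comp_arr == comp)).sum())
            counts[(name, comp)] = n
            area = areas[comp]
            if area <= 0:
                if n > 0:
                    raise GeometryError(
                        f"core {mask.core_id}: {n} {name} cells in zero-area {comp} compartment"
                    )
                densities[(name, comp)] = float("nan")
            else:
                densities[(name, comp)] = n / area
    composition = pooled_composition(calls)
    return CoreQuant(
        core_id=mask.core_id,
        counts=counts,
        densities=densities,
        composition=composition,
        hlae_tumor_density=densities[("HLAE_tumor", "tumoral")],
        areas_mm2=areas,
    )


def core_quant_table(quants: Iterable[CoreQuant]) -> pd.DataFrame:
    """Long-format per-core quantification table."""
    rows = []
    for q in quants:
        for (name, comp), n in q.counts.items():
            rows.append({
                "core_id": q.core_id, "variable": name, "compartment": comp,
                "count": n, "area_mm2": q.areas_mm2[comp],
                "density_per_mm2": q.densities[(name, comp)],
            })
    return pd.DataFrame(rows, columns=[
        "core_id", "variable", "compartment", "count", "area_mm2", "density_per_mm2"
    ])


def _wide_row(q: CoreQuant) -> Dict[str, float]:
    row: Dict[str, float] = {"core_id": q.core_id}
    for (name, comp), d in q.densities.items():
        row[f"{name}_{comp}_density"] = d
    for key, frac in q.composition.items():
        row[f"comp_{key}"] = frac
    row["hlae_tumor_density"] = q.hlae_tumor_density
    return row


def cohort_table(quants: Iterable[CoreQuant], clinical: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: all density/composition variables + clinical fields.

    The TMA design maps cores to patients 1:1; any unmatched identifier on
    either side is an error (no silent row drops).
    """
    wide = pd.DataFrame([_wide_row(q) for q in quants])
    if len(wide) == 0 and len(clinical) == 0:
        quant_cols = [c for c in wide.columns] or ["core_id"]
        return pd.DataFrame(columns=list(dict.fromkeys(quant_cols + list(clinical.columns))))
    quant_cores = set(wide["core_id"]) if len(wide) else set()
    clin_cores = set(clinical["core_id"])
    missing_clin = sorted(quant_cores - clin_cores)
    missing_quant = sorted(clin_cores - quant_cores)
    if missing_clin or missing_quant:
        raise JoinError(
            "core/patient mismatch: "
            f"cores without clinical record: {missing_clin or 'none'}; "
            f"patients without core quantification: {missing_quant or 'none'}"
        )
    if clinical["core_id"].duplicated().any() or wide["core_id"].duplicated().any():
        raise JoinError("core_id values must be unique on both sides (1:1 TMA design)")
    merged = clinical.merge(wide, on="core_id", how="inner", validate="1:1")
    return merged
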