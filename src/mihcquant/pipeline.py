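"""End-to-end orchestration: simulate -> gate -> quantify -> associate -> screen.

Each stage reads and writes plain-text files, logs structured progress to
stderr (and optionally a log file), and a JSON run manifest records
versions, the seed, a config hash and per-stage row counts. Identical
config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import shapely

from . import __version__
from . import io as mio
from . import phenotyping as ph
from . import spatial as sp
from . import stats as st
from . import survival as sv
from . import synthetic as syn

log = logging.getLogger("mihcquant")

#: Immune variables screened/correlated, by subset name of the quant stage.
ANALYSIS_VARIABLES = ["T", "B", "NK", "macrophage", "CD57_T", "CD57_NK",
                      "CD16_CD57_NK", "NKG2A_CD57_NK", "CD45_CD57"]


@dataclass
class PipelineConfig:
    output_dir: str = "mihcquant_out"
    cells_path: Optional[str] = None
    masks_path: Optional[str] = None
    clinical_path: Optional[str] = None
    simulate: bool = True
    sim: Dict = field(default_factory=dict)       # SimConfig overrides
    threshold_method: str = "distribution"
    manual_thresholds: Dict[str, float] = field(default_factory=dict)
    minprop: float = 0.1
    ties: str = "efron"
    alpha: float = 0.05
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: [
        "simulate", "gate", "quantify", "associate", "screen"])
    log_file: Optional[str] = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"significance level must be in (0,1), got {self.alpha}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be efron or breslow, got {self.ties!r}")
        if not self.simulate:
            for name in ("cells_path", "masks_path", "clinical_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def setup_logging(log_file: Optional[str] = None) -> None:
    handlers: List[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    log.setLevel(logging.INFO)
    log.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --- validation ------------------------------------------------------------

def validate_inputs(cells_path=None, masks_path=None, clinical_path=None) -> Dict[str, List[str]]:
    """Schema/geometry checks; reports per-file errors without aborting."""
    report: Dict[str, List[str]] = {}
    if cells_path is not None:
        errs = []
        try:
            mio.read_cells(cells_path)
        except Exception as exc:
            errs.append(str(exc))
        report[str(cells_path)] = errs
    if masks_path is not None:
        errs = []
        try:
            masks = mio.read_masks(masks_path)
            for core_id, mask in masks.items():
                if not mask.tumor.is_valid:
                    errs.append(f"core {core_id}: invalid (self-intersecting) tumor geometry")
                if not mask.core.is_valid:
                    errs.append(f"core {core_id}: invalid core boundary geometry")
        except Exception as exc:
            errs.append(str(exc))
        report[str(masks_path)] = errs
    if clinical_path is not None:
        errs = []
        try:
            clin = mio.read_clinical(clinical_path)
            for col in ("os_months", "pfs_months"):
                if (clin[col] < 0).any():
                    errs.append(f"negative values in {col}")
        except Exception as exc:
            errs.append(str(exc))
        report[str(clinical_path)] = errs
    return report


# --- stages ----------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    sim_dict = dict(config.sim)
    sim_dict.setdefault("seed", config.seed)
    sim = syn.SimConfig.from_dict(sim_dict)
    bundle = syn.generate_cohort(sim)
    paths = syn.write_fixture(bundle, outdir / "inputs")
    config.cells_path = str(paths["cells"])
    config.masks_path = str(paths["masks"])
    config.clinical_path = str(paths["clinical"])
    log.info("simulate: %d patients, %d cells", sim.n_patients, len(bundle.cells))
    return {"patients": len(bundle.clinical), "cells": len(bundle.cells)}


def stage_gate(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    cells = mio.read_cells(config.cells_path)
    methods = {ch: config.threshold_method for ch in ph.GATING_CHANNELS}
    for ch in config.manual_thresholds:
        methods[ch] = "manual"
    panel = ph.derive_panel(cells, ph.GATING_CHANNELS, methods=methods,
                            manual_values=config.manual_thresholds, seed=config.seed)
    mio.write_thresholds(panel, outdir / "thresholds.csv")
    calls = ph.gate_cells(cells, panel)
    gated = pd.concat(
        [cells.reset_index(drop=True),
         calls[["phenotype", "cd57", "cd16", "nkg2a", "hlae", "flags"]].reset_index(drop=True)],
        axis=1)
    gated.to_csv(outdir / "gated_cells.csv", index=False)
    log.info("gate: %d cells, thresholds %s",
             len(gated), {c: round(t, 3) for c, t in panel.thresholds.items()})
    return {"cells": len(gated), "channels": len(panel.thresholds)}


def stage_quantify(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    gated = pd.read_csv(outdir / "gated_cells.csv")
    masks = mio.read_masks(config.masks_path)
    clinical = mio.read_clinical(config.clinical_path)
    quants = []
    core_errors: Dict[str, str] = {}
    for core_id, group in gated.groupby("core_id", sort=True):
        mask = masks.get(core_id)
        if mask is None:
            core_errors[core_id] = "no mask for core"
            continue
        comp = sp.assign_compartment(group, mask)
        quants.append(sp.quantify_core(group, comp, mask))
    if core_errors:
        log.warning("quantify: per-core errors: %s", core_errors)
    sp.core_quant_table(quants).to_csv(outdir / "core_quant.csv", index=False)
    table = sp.cohort_table(quants, clinical)
    table = ph.molecular_status_table(table)
    table.to_csv(outdir / "analysis_table.csv", index=False)
    log.info("quantify: %d cores quantified, %d analysis rows", len(quants), len(table))
    return {"cores": len(quants), "analysis_rows": len(table),
            "core_errors": len(core_errors)}


def _density_columns(compartments=("tumoral", "stromal", "total")) -> List[str]:
    return [f"{v}_{c}_density" for v in ANALYSIS_VARIABLES for c in compartments]


def stage_associate(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    table = pd.read_csv(outdir / "analysis_table.csv")
    corr_vars = [f"{v}_tumoral_density" for v in
                 ["T", "B", "NK", "macrophage", "CD57_T", "CD57_NK", "CD45_CD57"]]
    corr_vars.append("hlae_tumor_density")
    corr = st.correlation_matrix(table, corr_vars, alpha=config.alpha)
    corr.to_csv(outdir / "correlations.csv", index=False)
    comparisons = []
    table["ebv_group"] = np.where(table["ebv_ish"] == 1, "EBV+", "EBV-")
    table["msi_group"] = np.where(table["msi"] == "MSI-H", "MSI-H", "MSS/MSI-L")
    table["stage_group"] = table["stage"].astype(str)
    strata = [s for s in ("ebv_group", "msi_group", "stage_group")
              if table[s].nunique() == 2]
    cmp_vars = [f"{v}_total_density" for v in ["T", "B", "NK", "macrophage"]]
    for stratum in strata:
        comparisons.append(st.group_comparisons(table, cmp_vars, stratum))
    cmp_df = pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
    cmp_df.to_csv(outdir / "comparisons.csv", index=False)
    log.info("associate: %d correlation pairs, %d comparisons", len(corr), len(cmp_df))
    return {"correlation_pairs": len(corr), "comparisons": len(cmp_df)}


def stage_screen(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    table = pd.read_csv(outdir / "analysis_table.csv")
    screen = sv.survival_screen(
        table, ANALYSIS_VARIABLES, minprop=config.minprop,
        ties=config.ties, alpha=config.alpha)
    screen.to_csv(outdir / "survival_screen.csv", index=False)
    n_flag = int(screen["flag"].sum())
    log.info("screen: %d combinations, %d flagged at alpha=%g",
             len(screen), n_flag, config.alpha)
    return {"combinations": len(screen), "flagged": n_flag}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "gate": stage_gate,
    "quantify": stage_quantify,
    "associate": stage_associate,
    "screen": stage_screen,
}

STAGE_ORDER = ["simulate", "gate", "quantify", "associate", "screen"]


def run_all(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; halt downstream stages on failure.

    Partial outputs are retained and the manifest records the failure
    point. Returns the manifest (also written to ``manifest.json``).
    """
    config.validate()
    setup_logging(config.log_file)
    outdir = mio.ensure_dir(config.output_dir)
    manifest = {
        "package": "mihcquant",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "shapely": shapely.__version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "stages": {},
        "status": "ok",
    }
    stages = [s for s in STAGE_ORDER if s in config.stages]
    if not config.simulate:
        stages = [s for s in stages if s != "simulate"]
    for name in stages:
        try:
            counts = STAGE_FUNCS[name](config, outdir)
            manifest["stages"][name] = {"status": "ok", "counts": counts}
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            manifest["status"] = f"failed at {name}"
            break
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
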