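"""Synthetic multiplex-IHC TMA cohort generator.

Emulates a ~55-patient gastric-cancer tissue-microarray cohort at the
statistical level the downstream analysis assumes: per-core tumor-region
geometry (union of convex blobs hitting a target area fraction), cells
placed uniformly over the core disc, truth phenotypes drawn from the
cohort's immune composition (T 65.5%, macrophage 25.4%, B 5.3%, CD57+ NK
3.8% of CD45+ cells), CD16/NKG2A receptor co-expression at the reported
per-phenotype rates, bimodal per-channel intensity distributions
(two-component log-normal mixtures), HLA-E expression on tumor cells linked
to intratumoral immune densities, and proportional-hazards survival
outcomes linked (by default) to tumoral NK-cell density.

Truth labels are kept on separate columns/files so that pipeline stages
under test can never read them. All randomness is derived from the master
seed by counter-based stream splitting per (core, channel), so output is
independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from shapely import affinity
from shapely.geometry import MultiPolygon, MultiPoint, Polygon
from shapely.ops import unary_union

from . import io as mio
from .io import CHANNELS, MSI_MARKERS
from .spatial import RegionMask, UM2_PER_MM2, make_core_disc
import shapely


class InvalidConfigError(ValueError):
    pass


#: Phenotype categories the generator draws from. ``non_immune`` cells are
#: split into tumor cells (CK+, inside the tumor mask) and other
#: non-immune cells (outside) by position.
GEN_PHENOTYPES = ["T_cell", "B_cell", "NK_cell", "macrophage", "other_immune", "non_immune"]

SUBTYPES = ["EBV+", "MSI-H", "EMT-like", "non-EMT p53+", "non-EMT p53-"]

#: Named (non-channel) random streams; channels use indices 0..10.
_STREAMS = {"geometry": 100, "count": 101, "position": 102, "phenotype": 103,
            "cd57": 104, "receptors": 105, "hlae": 106, "ki67": 107,
            "sma": 108, "clinical": 200, "survival": 201}

_COHORT_CORE_INDEX = 10**6  # pseudo core index for cohort-level streams


def _default_composition() -> Dict[str, float]:
    immune = 0.5
    return {
        "T_cell": 0.655 * immune,
        "B_cell": 0.053 * immune,
        "NK_cell": 0.038 * immune,
        "macrophage": 0.254 * immune,
        "other_immune": 0.0,
        "non_immune": 1.0 - immune,
    }


def _default_receptor_rates() -> Dict[str, Dict[str, float]]:
    return {
        "T_cell": {"CD16": 0.551, "NKG2A": 0.279},
        "NK_cell": {"CD16": 0.593, "NKG2A": 0.148},
        "B_cell": {"CD16": 0.05, "NKG2A": 0.02},
        "macrophage": {"CD16": 0.40, "NKG2A": 0.05},
    }


def _default_intensity_model() -> Dict[str, Dict[str, List[float]]]:
    # log-normal location/scale on the log scale; positive population well
    # separated from the negative one (e^0 = 1 vs e^3 ~ 20).
    return {ch: {"neg": [0.0, 0.35], "pos": [3.0, 0.35]} for ch in CHANNELS}


def _default_hlae_model() -> Dict:
    # Logistic link of the per-core HLA-E+ tumor-cell rate to intratumoral
    # immune densities, anchored at the cohort's median densities.
    return {
        "base_rate": 0.35,
        "coefficients": {"T_cell": 0.3, "B_cell": 0.1, "macrophage": 0.2, "NK_cell": 0.0},
        "reference_density": {"T_cell": 1281.1, "B_cell": 38.7,
                              "macrophage": 469.1, "NK_cell": 44.6},
    }


def _default_survival_model() -> Dict:
    return {
        "baseline_hazard": math.log(2) / 85.4,  # exponential median OS ~ 85.4 months
        "weibull_shape": 1.0,
        "coefficients": {"nk_tumoral_z": 0.5, "t_total_z": -0.3,
                         "macrophage_total_z": -0.3},
        "censoring_rate": 0.006,     # exponential censoring hazard per month
        "horizon_months": 108.0,
        "pfs_gap_mean_months": 20.0,
    }


def _default_subtype_frequencies() -> Dict[str, float]:
    return {"EBV+": 4 / 55, "MSI-H": 7 / 55, "EMT-like": 21 / 55,
            "non-EMT p53+": 4 / 55, "non-EMT p53-": 19 / 55}


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults emulate the study cohort."""

    n_patients: int = 55
    cells_per_core_mean: int = 4000
    core_diameter_um: float = 1200.0
    tumor_area_fraction: float = 0.4
    composition: Dict[str, float] = field(default_factory=_default_composition)
    cd57_rate_T: float = 0.232
    receptor_rates: Dict[str, Dict[str, float]] = field(default_factory=_default_receptor_rates)
    intensity_model: Dict[str, Dict[str, List[float]]] = field(default_factory=_default_intensity_model)
    hlae_model: Dict = field(default_factory=_default_hlae_model)
    survival_model: Dict = field(default_factory=_default_survival_model)
    subtype_frequencies: Dict[str, float] = field(default_factory=_default_subtype_frequencies)
    stage3_fraction: float = 41 / 55
    msi_low_rate: float = 0.1
    ki67_rate_tumor: float = 0.3
    ki67_rate_immune: float = 0.05
    sma_rate_stromal: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.tumor_area_fraction < 1:
            raise InvalidConfigError(
                f"tumor_area_fraction must be in (0,1), got {self.tumor_area_fraction}"
            )
        comp = self.composition
        extra = set(comp) - set(GEN_PHENOTYPES)
        if extra:
            raise InvalidConfigError(f"unknown composition categories: {sorted(extra)}")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"composition must sum to 1 (got {total!r})")
        for name, frac in comp.items():
            if not 0 <= frac <= 1:
                raise InvalidConfigError(f"composition[{name}] outside [0,1]: {frac}")
        for frac in [self.cd57_rate_T, self.stage3_fraction, self.msi_low_rate,
                     self.ki67_rate_tumor, self.ki67_rate_immune, self.sma_rate_stromal]:
            if not 0 <= frac <= 1:
                raise InvalidConfigError(f"rate outside [0,1]: {frac}")
        for ph, rates in self.receptor_rates.items():
            for rec, rate in rates.items():
                if not 0 <= rate <= 1:
                    raise InvalidConfigError(f"receptor rate ({ph},{rec}) outside [0,1]: {rate}")
        for ch, comps in self.intensity_model.items():
            neg, pos = comps["neg"], comps["pos"]
            if pos[0] <= neg[0]:
                raise InvalidConfigError(
                    f"channel {ch}: positive location {pos[0]} must exceed negative {neg[0]}"
                )
            if neg[1] < 0 or pos[1] < 0:
                raise InvalidConfigError(f"channel {ch}: negative scale parameter")
        if self.survival_model["baseline_hazard"] <= 0:
            raise InvalidConfigError("baseline hazard must be > 0")
        if not 0 <= self.survival_model["censoring_rate"] < 1:
            raise InvalidConfigError("censoring rate must be in [0,1)")
        sfreq = self.subtype_frequencies
        if abs(sum(sfreq.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("subtype frequencies must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


def _stream(seed: int, core_index: int, key) -> np.random.Generator:
    """Counter-based RNG stream for one (core, channel-or-purpose) pair."""
    k = _STREAMS[key] if isinstance(key, str) else int(key)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(core_index, k)))


# --- geometry --------------------------------------------------------------

def _make_tumor_mask(config: SimConfig, core_id: str, rng: np.random.Generator) -> RegionMask:
    """Tumor region as a union of 1-5 convex blobs rescaled to hit the
    target area fraction within 2%."""
    core = make_core_disc(config.core_diameter_um)
    r = config.core_diameter_um / 2.0
    center = np.array([r, r])
    target = config.tumor_area_fraction * core.area

    n_blobs = int(rng.integers(1, 6))
    blobs = []
    for _ in range(n_blobs):
        ang = rng.uniform(0, 2 * math.pi)
        rad = 0.6 * r * math.sqrt(rng.uniform())
        c = center + rad * np.array([math.cos(ang), math.sin(ang)])
        npts = int(rng.integers(8, 16))
        pts = c + rng.normal(scale=0.35 * r, size=(npts, 2))
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        if isinstance(hull, Polygon):
            blobs.append(hull)

    def scaled(s: float):
        # each blob grows in place about its own centroid, so the covered
        # area is monotone in s and converges to the whole disc
        return unary_union(
            [affinity.scale(b, xfact=s, yfact=s, origin="centroid") for b in blobs]
        ).intersection(core)

    def area_at(s: float) -> float:
        return scaled(s).area

    lo, hi = 1e-3, 1.0
    while area_at(hi) < target and hi < 64:
        hi *= 2.0
    s = hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        a = area_at(mid)
        if a < target:
            lo = mid
        else:
            hi = mid
        s = mid
        if abs(a - target) <= 0.02 * target:
            break
    tumor = scaled(s)
    if isinstance(tumor, Polygon):
        tumor = MultiPolygon([tumor])
    return RegionMask(core_id=core_id, tumor=tumor, core=core)


# --- cells -----------------------------------------------------------------

def generate_core(config: SimConfig, core_id: str, core_index: int = 0
                  ) -> Tuple[RegionMask, pd.DataFrame]:
    """One TMA core: tumor mask plus cells with truth labels (no intensities).

    Cell positions are uniform over the core disc; truth phenotypes are
    drawn from the composition; CK+ tumor cells arise only inside the
    tumor mask (non-immune cells outside it are 'other_nonimmune').
    """
    config.validate()
    seed = config.seed
    mask = _make_tumor_mask(config, core_id, _stream(seed, core_index, "geometry"))

    n = int(_stream(seed, core_index, "count").poisson(config.cells_per_core_mean))
    r = config.core_diameter_um / 2.0
    rng_pos = _stream(seed, core_index, "position")
    rad = r * np.sqrt(rng_pos.uniform(size=n))
    theta = rng_pos.uniform(0, 2 * math.pi, size=n)
    x = r + rad * np.cos(theta)
    y = r + rad * np.sin(theta)

    probs = np.array([config.composition.get(p, 0.0) for p in GEN_PHENOTYPES])
    probs = probs / probs.sum()
    pheno = _stream(seed, core_index, "phenotype").choice(GEN_PHENOTYPES, size=n, p=probs)

    inside = shapely.intersects_xy(mask.tumor, x, y) if n else np.zeros(0, bool)
    phenotype = np.where(
        pheno == "non_immune", np.where(inside, "tumor_cell", "other_nonimmune"), pheno
    )
    compartment = np.where(inside, "tumoral", "stromal")

    rng57 = _stream(seed, core_index, "cd57")
    cd57 = np.where(
        phenotype == "NK_cell", True,
        np.where(phenotype == "T_cell", rng57.uniform(size=n) < config.cd57_rate_T, False),
    ).astype(bool)

    rng_rec = _stream(seed, core_index, "receptors")
    cd16 = np.zeros(n, bool)
    nkg2a = np.zeros(n, bool)
    for ph, rates in config.receptor_rates.items():
        m = phenotype == ph
        if m.any():
            cd16[m] = rng_rec.uniform(size=int(m.sum())) < rates.get("CD16", 0.0)
            nkg2a[m] = rng_rec.uniform(size=int(m.sum())) < rates.get("NKG2A", 0.0)

    # HLA-E on tumor cells: logistic link to this core's intratumoral
    # immune densities, anchored at the configured reference densities.
    hm = config.hlae_model
    tum_area = max(mask.tumor_area_mm2, 1e-9)
    shift = 0.0
    for ph, coef in hm.get("coefficients", {}).items():
        d = ((phenotype == ph) & inside).sum() / tum_area
        ref = hm.get("reference_density", {}).get(ph, 0.0)
        shift += coef * (math.log1p(d) - math.log1p(ref))
    rate = float(expit(logit(np.clip(hm["base_rate"], 1e-9, 1 - 1e-9)) + shift))
    is_tumor = phenotype == "tumor_cell"
    hlae = np.zeros(n, bool)
    hlae[is_tumor] = _stream(seed, core_index, "hlae").uniform(size=int(is_tumor.sum())) < rate

    rng_ki = _stream(seed, core_index, "ki67")
    is_imm = np.isin(phenotype, ["T_cell", "B_cell", "NK_cell", "macrophage", "other_immune"])
    ki_rate = np.where(is_tumor, config.ki67_rate_tumor,
                       np.where(is_imm, config.ki67_rate_immune, 0.0))
    ki67 = rng_ki.uniform(size=n) < ki_rate
    sma = np.zeros(n, bool)
    other = phenotype == "other_nonimmune"
    sma[other] = _stream(seed, core_index, "sma").uniform(size=int(other.sum())) < config.sma_rate_stromal

    cells = pd.DataFrame({
        "cell_id": [f"{core_id}_c{i:05d}" for i in range(n)],
        "core_id": core_id,
        "x_um": x, "y_um": y,
        "truth_phenotype": phenotype,
        "truth_cd57": cd57, "truth_cd16": cd16, "truth_nkg2a": nkg2a,
        "truth_compartment": compartment,
        "truth_hlae": hlae, "truth_ki67": ki67, "truth_sma": sma,
    })
    return mask, cells


TRUTH_COLUMNS = ["truth_phenotype", "truth_cd57", "truth_cd16", "truth_nkg2a",
                 "truth_compartment", "truth_hlae", "truth_ki67", "truth_sma"]


def truth_positivity(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-channel truth positivity implied by the truth labels."""
    ph = cells["truth_phenotype"].to_numpy()
    is_imm = np.isin(ph, ["T_cell", "B_cell", "NK_cell", "macrophage", "other_immune"])
    return pd.DataFrame({
        "CD45": is_imm,
        "CD3": ph == "T_cell",
        "CD20": ph == "B_cell",
        "CD57": cells["truth_cd57"].to_numpy(bool),
        "CD68": ph == "macrophage",
        "CK": ph == "tumor_cell",
        "CD16": cells["truth_cd16"].to_numpy(bool) & is_imm,
        "NKG2A": cells["truth_nkg2a"].to_numpy(bool) & is_imm,
        "HLAE": cells["truth_hlae"].to_numpy(bool),
        "KI67": cells["truth_ki67"].to_numpy(bool),
        "SMA": cells["truth_sma"].to_numpy(bool),
    }, index=cells.index)


def simulate_intensities(cells: pd.DataFrame, intensity_model: Dict,
                         seed: int, core_index: int = 0) -> pd.DataFrame:
    """Draw per-channel intensities from the two-component log-normal model.

    Truth-positive cells draw from the positive component, truth-negative
    cells from the negative one; one random stream per (core, channel).
    Returns a copy of ``cells`` with the 11 channel columns appended.
    """
    pos_truth = truth_positivity(cells)
    out = cells.copy()
    n = len(cells)
    for ci, ch in enumerate(CHANNELS):
        comps = intensity_model[ch]
        (mu_n, sd_n), (mu_p, sd_p) = comps["neg"], comps["pos"]
        if mu_p <= mu_n:
            raise InvalidConfigError(
                f"channel {ch}: positive location {mu_p} must exceed negative {mu_n}"
            )
        rng = _stream(seed, core_index, ci)
        z = rng.standard_normal(n)
        is_pos = pos_truth[ch].to_numpy(bool)
        logv = np.where(is_pos, mu_p + sd_p * z, mu_n + sd_n * z)
        out[ch] = np.maximum(np.exp(logv), 0.0)
    return out


# --- survival --------------------------------------------------------------

def simulate_survival(covariates: pd.DataFrame, survival_model: Dict,
                      seed: int) -> pd.DataFrame:
    """Proportional-hazards outcome generator (Weibull; exponential default).

    hazard_i = baseline * exp(sum_k coef_k * covariate_ik); independent
    exponential censoring plus an administrative follow-up horizon. PFS is
    OS minus an exponential gap truncated at zero, so PFS <= OS always.
    """
    lam0 = survival_model["baseline_hazard"]
    if lam0 <= 0:
        raise InvalidConfigError("baseline hazard must be > 0")
    shape = survival_model.get("weibull_shape", 1.0)
    lam_c = survival_model.get("censoring_rate", 0.0)
    if not 0 <= lam_c < 1:
        raise InvalidConfigError("censoring rate must be in [0,1)")
    horizon = survival_model.get("horizon_months", math.inf)
    coeffs = survival_model.get("coefficients", {})
    n = len(covariates)
    lp = np.zeros(n)
    for name, coef in coeffs.items():
        if name not in covariates.columns:
            raise InvalidConfigError(f"survival covariate {name!r} missing from table")
        lp += coef * covariates[name].to_numpy(float)

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_COHORT_CORE_INDEX, _STREAMS["survival"])))
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (lam0 * np.exp(lp))) ** (1.0 / shape)
    t_cens = rng.exponential(1.0 / lam_c, size=n) if lam_c > 0 else np.full(n, np.inf)
    if horizon == 0:
        zeros = np.zeros(n)
        return pd.DataFrame({"os_months": zeros, "os_event": np.zeros(n, int),
                             "pfs_months": zeros, "pfs_event": np.zeros(n, int)},
                            index=covariates.index)
    os_obs = np.minimum.reduce([t_event, t_cens, np.full(n, horizon)])
    os_event = (t_event <= t_cens) & (t_event <= horizon)
    gap = rng.exponential(survival_model.get("pfs_gap_mean_months", 0.0), size=n) \
        if survival_model.get("pfs_gap_mean_months", 0.0) > 0 else np.zeros(n)
    t_prog = np.maximum(t_event - gap, 0.0)
    pfs_obs = np.minimum.reduce([t_prog, t_cens, np.full(n, horizon)])
    pfs_event = (t_prog <= t_cens) & (t_prog <= horizon)
    os_obs = np.maximum(os_obs, 0.01)
    pfs_obs = np.minimum(np.maximum(pfs_obs, 0.01), os_obs)
    return pd.DataFrame({
        "os_months": os_obs, "os_event": os_event.astype(int),
        "pfs_months": pfs_obs, "pfs_event": pfs_event.astype(int),
    }, index=covariates.index)


# --- clinical --------------------------------------------------------------

def _generate_clinical(config: SimConfig, patient_ids: List[str], core_ids: List[str],
                       covariates: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_COHORT_CORE_INDEX, _STREAMS["clinical"]))
    )
    n = len(patient_ids)
    names = list(config.subtype_frequencies)
    p = np.array([config.subtype_frequencies[s] for s in names])
    subtype = rng.choice(names, size=n, p=p / p.sum())

    msi_flags = np.zeros((n, len(MSI_MARKERS)), int)
    ebv = np.zeros(n, int)
    ecad = np.zeros(n, int)
    p53 = np.zeros(n, int)
    for i, st in enumerate(subtype):
        if st == "EBV+":
            ebv[i] = 1
            ecad[i] = int(rng.uniform() < 0.2)
            p53[i] = int(rng.uniform() < 0.3)
        elif st == "MSI-H":
            k = int(rng.integers(2, len(MSI_MARKERS) + 1))
            idx = rng.choice(len(MSI_MARKERS), size=k, replace=False)
            msi_flags[i, idx] = 1
            ecad[i] = int(rng.uniform() < 0.2)
            p53[i] = int(rng.uniform() < 0.3)
        else:
            if rng.uniform() < config.msi_low_rate:
                msi_flags[i, rng.integers(len(MSI_MARKERS))] = 1
            if st == "EMT-like":
                ecad[i] = 1
                p53[i] = int(rng.uniform() < 0.3)
            elif st == "non-EMT p53+":
                p53[i] = 1
            # non-EMT p53-: all remain 0
    stage = np.where(rng.uniform(size=n) < config.stage3_fraction, 3, 2)

    outcomes = simulate_survival(covariates, config.survival_model, config.seed)
    clinical = pd.DataFrame({"patient_id": patient_ids, "core_id": core_ids})
    clinical = pd.concat([clinical, outcomes.reset_index(drop=True)], axis=1)
    clinical["stage"] = stage
    clinical["ebv_ish"] = ebv
    for j, m in enumerate(MSI_MARKERS):
        clinical[m] = msi_flags[:, j]
    clinical["ecad_altered"] = ecad
    clinical["p53_positive"] = p53
    return clinical, pd.Series(subtype, index=clinical.index, name="subtype")


# --- cohort ----------------------------------------------------------------

@dataclass
class CohortBundle:
    """A full synthetic cohort plus generator-side truth for recovery tests."""

    cells: pd.DataFrame                 # public cells table (positions + intensities)
    masks: Dict[str, RegionMask]
    clinical: pd.DataFrame
    truth_cells: pd.DataFrame           # cell_id + truth labels
    truth_patients: pd.DataFrame
    config: SimConfig

    def validate(self) -> None:
        cores = set(self.cells["core_id"])
        if not cores <= set(self.masks):
            raise InvalidConfigError("some cells reference cores without a mask")
        if not cores <= set(self.clinical["core_id"]):
            raise InvalidConfigError("some cells reference cores without a clinical record")
        if set(self.cells["cell_id"]) != set(self.truth_cells["cell_id"]):
            raise InvalidConfigError("truth labels do not cover every cell")


def _zscore(v: np.ndarray) -> np.ndarray:
    if v.size == 0:
        return v.astype(float)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_cohort(config: Optional[SimConfig] = None) -> CohortBundle:
    """Generate the full synthetic cohort (cells, masks, clinical, truth)."""
    config = config or SimConfig()
    config.validate()
    masks: Dict[str, RegionMask] = {}
    all_cells = []
    per_core = []
    patient_ids, core_ids = [], []
    for i in range(config.n_patients):
        core_id = f"core{i:03d}"
        patient_ids.append(f"pt{i:03d}")
        core_ids.append(core_id)
        mask, cells = generate_core(config, core_id, core_index=i)
        cells = simulate_intensities(cells, config.intensity_model, config.seed, core_index=i)
        masks[core_id] = mask
        all_cells.append(cells)
        ph = cells["truth_phenotype"].to_numpy()
        tumoral = cells["truth_compartment"].to_numpy() == "tumoral"
        per_core.append({
            "core_id": core_id,
            "nk_tumoral_density": ((ph == "NK_cell") & tumoral).sum() / max(mask.tumor_area_mm2, 1e-9),
            "t_total_density": (ph == "T_cell").sum() / mask.core_area_mm2,
            "macrophage_total_density": (ph == "macrophage").sum() / mask.core_area_mm2,
        })
    dens = pd.DataFrame(per_core, columns=[
        "core_id", "nk_tumoral_density", "t_total_density", "macrophage_total_density"])
    covariates = pd.DataFrame({
        "nk_tumoral_z": _zscore(dens["nk_tumoral_density"].to_numpy()),
        "t_total_z": _zscore(dens["t_total_density"].to_numpy()),
        "macrophage_total_z": _zscore(dens["macrophage_total_density"].to_numpy()),
    })
    clinical, subtype = _generate_clinical(config, patient_ids, core_ids, covariates)

    cells = pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame(
        columns=mio.CELL_COLUMNS + TRUTH_COLUMNS)
    public = cells[mio.CELL_COLUMNS].copy() if len(cells) else cells.reindex(
        columns=mio.CELL_COLUMNS)
    truth_cells = cells[["cell_id"] + TRUTH_COLUMNS].copy() if len(cells) else cells.reindex(
        columns=["cell_id"] + TRUTH_COLUMNS)
    truth_patients = pd.concat([
        pd.DataFrame({"patient_id": patient_ids, "core_id": core_ids, "subtype": subtype}),
        dens.drop(columns="core_id"), covariates,
    ], axis=1)
    bundle = CohortBundle(cells=public, masks=masks, clinical=clinical,
                          truth_cells=truth_cells, truth_patients=truth_patients,
                          config=config)
    bundle.validate()
    return bundle


def simulate_pooled_cells(config: SimConfig, n_cells: int, core_id: str = "pooled",
                          core_index: int = 0) -> pd.DataFrame:
    """Cells with truth labels and intensities but no geometry (one pool).

    Non-immune cells become tumor cells with probability
    ``tumor_area_fraction`` (standing in for the uniform-placement rule).
    Used for large end-to-end gating experiments.
    """
    config.validate()
    seed = config.seed
    probs = np.array([config.composition.get(p, 0.0) for p in GEN_PHENOTYPES])
    probs = probs / probs.sum()
    pheno = _stream(seed, core_index, "phenotype").choice(GEN_PHENOTYPES, size=n_cells, p=probs)
    rng_pos = _stream(seed, core_index, "position")
    in_tumor = rng_pos.uniform(size=n_cells) < config.tumor_area_fraction
    phenotype = np.where(pheno == "non_immune",
                         np.where(in_tumor, "tumor_cell", "other_nonimmune"), pheno)

    rng57 = _stream(seed, core_index, "cd57")
    cd57 = np.where(phenotype == "NK_cell", True,
                    np.where(phenotype == "T_cell",
                             rng57.uniform(size=n_cells) < config.cd57_rate_T, False)).astype(bool)
    rng_rec = _stream(seed, core_index, "receptors")
    cd16 = np.zeros(n_cells, bool)
    nkg2a = np.zeros(n_cells, bool)
    for ph, rates in config.receptor_rates.items():
        m = phenotype == ph
        if m.any():
            cd16[m] = rng_rec.uniform(size=int(m.sum())) < rates.get("CD16", 0.0)
            nkg2a[m] = rng_rec.uniform(size=int(m.sum())) < rates.get("NKG2A", 0.0)
    is_tumor = phenotype == "tumor_cell"
    hlae = np.zeros(n_cells, bool)
    hlae[is_tumor] = _stream(seed, core_index, "hlae").uniform(
        size=int(is_tumor.sum())) < config.hlae_model["base_rate"]
    is_imm = np.isin(phenotype, ["T_cell", "B_cell", "NK_cell", "macrophage", "other_immune"])
    ki_rate = np.where(is_tumor, config.ki67_rate_tumor,
                       np.where(is_imm, config.ki67_rate_immune, 0.0))
    ki67 = _stream(seed, core_index, "ki67").uniform(size=n_cells) < ki_rate
    sma = np.zeros(n_cells, bool)
    other = phenotype == "other_nonimmune"
    sma[other] = _stream(seed, core_index, "sma").uniform(
        size=int(other.sum())) < config.sma_rate_stromal

    cells = pd.DataFrame({
        "cell_id": [f"{core_id}_c{i:06d}" for i in range(n_cells)],
        "core_id": core_id,
        "x_um": 0.0, "y_um": 0.0,
        "truth_phenotype": phenotype,
        "truth_cd57": cd57, "truth_cd16": cd16, "truth_nkg2a": nkg2a,
        "truth_compartment": np.where(in_tumor, "tumoral", "stromal"),
        "truth_hlae": hlae, "truth_ki67": ki67, "truth_sma": sma,
    })
    return simulate_intensities(cells, config.intensity_model, seed, core_index=core_index)


# --- fixture I/O -----------------------------------------------------------

def write_fixture(bundle: CohortBundle, directory) -> Dict[str, Path]:
    """Write the bundle as cells/masks/clinical/truth files plus the config.

    Truth labels go to separate files so that pipeline stages reading the
    public inputs can never see them.
    """
    d = mio.ensure_dir(directory)
    paths = {
        "cells": d / "cells.csv",
        "masks": d / "masks.geojson",
        "clinical": d / "clinical.csv",
        "truth_cells": d / "truth_cells.csv",
        "truth_patients": d / "truth_patients.csv",
        "config": d / "config.yaml",
    }
    mio.write_cells(bundle.cells, paths["cells"])
    mio.write_masks(bundle.masks, paths["masks"])
    mio.write_clinical(bundle.clinical, paths["clinical"])
    bundle.truth_cells.to_csv(paths["truth_cells"], index=False)
    bundle.truth_patients.to_csv(paths["truth_patients"], index=False)
    mio.write_yaml(bundle.config.to_dict(), paths["config"])
    return paths


def read_fixture(directory) -> CohortBundle:
    d = Path(directory)
    config = SimConfig.from_dict(mio.read_yaml(d / "config.yaml"))
    return CohortBundle(
        cells=mio.read_cells(d / "cells.csv"),
        masks=mio.read_masks(d / "masks.geojson"),
        clinical=mio.read_clinical(d / "clinical.csv"),
        truth_cells=pd.read_csv(d / "truth_cells.csv"),
        truth_patients=pd.read_csv(d / "truth_patients.csv"),
        config=config,
    )
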