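"""Marker thresholding, hierarchical phenotyping, and molecular classification.

Positivity for each channel is a strict threshold on the measured intensity;
thresholds are either supplied manually or derived from the bimodal
intensity distribution as the decision boundary of a two-component Gaussian
mixture fitted on log-intensity. Phenotypes are assigned by an ordered
lineage cascade on CD45+ cells (CD3 -> CD20 -> CD57 -> CD68), mirroring the
marker table used for gastric-cancer multiplex IHC:

=============  =======================================
T cell         CD45+ CD3+ CD20- (CD57+ or CD57-)
B cell         CD45+ CD3- CD20+
CD57+ NK cell  CD45+ CD3- CD20- CD57+
macrophage     CD45+ CD3- CD20- CD57- CD68+
=============  =======================================

CD45+ cells matching none of the rows are ``other_immune``; CD45- cells are
``tumor_cell`` if CK+ and ``other_nonimmune`` otherwise. The CD16
(activating) and NKG2A (inhibitory) receptor statuses are recorded for every
immune phenotype so that subsets such as CD57+NKG2A+ NK cells can be
counted; subsets are non-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .io import CHANNELS, MSI_MARKERS, SchemaError

PHENOTYPES = [
    "T_cell", "B_cell", "NK_cell", "macrophage",
    "other_immune", "tumor_cell", "other_nonimmune",
]

MSI_CLASSES = ["MSS", "MSI-L", "MSI-H"]

SUBTYPES = ["EBV+", "MSI-H", "EMT-like", "non-EMT p53+", "non-EMT p53-"]

#: Channels that the gating cascade requires thresholds for.
GATING_CHANNELS = ["CD45", "CD3", "CD20", "CD57", "CD68", "CK", "CD16", "NKG2A", "HLAE"]


class ThresholdUnderivableError(ValueError):
    """Mixture-based threshold derivation failed; supply a manual value."""


@dataclass
class MarkerPanel:
    """Per-channel thresholds and how each was obtained."""

    channels: List[str]
    thresholds: Dict[str, float]
    methods: Dict[str, str] = field(default_factory=dict)

    def validate(self, required: Sequence[str] = GATING_CHANNELS) -> None:
        for ch in required:
            if ch not in self.thresholds:
                raise SchemaError(f"panel has no threshold for gated channel {ch}")
            t = self.thresholds[ch]
            if not np.isfinite(t) or t < 0:
                raise SchemaError(f"threshold for {ch} must be finite and >= 0, got {t}")


def derive_threshold(intensities, method: str = "distribution",
                     value: Optional[float] = None, seed: int = 0) -> float:
    """Derive the positivity cut-off for one channel.

    method="distribution": fit a two-component Gaussian mixture on
    log-intensity (EM, 10 random restarts, tolerance 1e-8) and return the
    intensity at which posterior membership in the two components is equal
    — the decision boundary between the negative (lower) and positive
    (higher) populations.

    method="manual": return ``value`` unchanged.
    """
    if method == "manual":
        if value is None:
            raise ValueError("manual method requires a threshold value")
        return float(value)
    if method != "distribution":
        raise ValueError(f"unknown threshold method {method!r}")

    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 50:
        raise ValueError(f"distribution method needs >= 50 positive finite values, got {x.size}")
    y = np.log(x)
    if np.ptp(x) == 0 or np.std(y) < 1e-9:
        raise ThresholdUnderivableError("zero-variance intensities: no mixture to fit")

    gmm = GaussianMixture(n_components=2, n_init=10, tol=1e-8, max_iter=500,
                          random_state=seed)
    gmm.fit(y.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    lo, hi = int(np.argmin(means)), int(np.argmax(means))
    if means[hi] - means[lo] < 1e-6 * max(1.0, abs(means[hi])):
        raise ThresholdUnderivableError("mixture components collapsed to one mode")

    def log_odds(v: float) -> float:
        # log posterior-odds negative vs positive component
        return (np.log(weights[lo]) + norm.logpdf(v, means[lo], sds[lo])
                - np.log(weights[hi]) - norm.logpdf(v, means[hi], sds[hi]))

    a, b = means[lo], means[hi]
    fa, fb = log_odds(a), log_odds(b)
    if not (fa > 0 > fb):
        raise ThresholdUnderivableError(
            "no posterior-0.5 boundary between component means (degenerate fit)"
        )
    for _ in range(200):
        m = 0.5 * (a + b)
        if log_odds(m) > 0:
            a = m
        else:
            b = m
    return float(np.exp(0.5 * (a + b)))


def derive_panel(cells: pd.DataFrame, channels: Sequence[str] = GATING_CHANNELS,
                 methods: Optional[Dict[str, str]] = None,
                 manual_values: Optional[Dict[str, float]] = None,
                 seed: int = 0) -> MarkerPanel:
    """Derive thresholds for several channels from a cells table."""
    methods = methods or {}
    manual_values = manual_values or {}
    thresholds: Dict[str, float] = {}
    used: Dict[str, str] = {}
    for ch in channels:
        if ch not in cells.columns:
            raise SchemaError(f"cells table is missing channel column {ch}")
        method = methods.get(ch, "distribution")
        thresholds[ch] = derive_threshold(
            cells[ch], method=method, value=manual_values.get(ch), seed=seed
        )
        used[ch] = method
    return MarkerPanel(channels=list(channels), thresholds=thresholds, methods=used)


def call_positivity(cells: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Boolean positivity per cell x thresholded channel.

    Positive iff intensity is strictly greater than the threshold; a cell
    exactly at the threshold is negative.
    """
    out = {}
    for ch, thr in panel.thresholds.items():
        if ch not in cells.columns:
            raise SchemaError(f"cells table is missing channel column {ch}")
        out[ch] = cells[ch].to_numpy(float) > thr
    return pd.DataFrame(out, index=cells.index)


def assign_phenotype(positivity: pd.DataFrame) -> pd.DataFrame:
    """Ordered lineage cascade on the positivity calls.

    CD45+: CD3 -> T_cell (CD57 recorded as cd57_status); else CD20 ->
    B_cell; else CD57 -> NK_cell; else CD68 -> macrophage; else
    other_immune. CD45-: CK -> tumor_cell, else other_nonimmune.

    Profiles positive for additional lineage markers *after* their deciding
    marker in the cascade (e.g. CD3+CD20+, or CD57+CD68+ without CD3/CD20)
    are resolved by cascade order and flagged ``ambiguous_lineage``.
    """
    for ch in ["CD45", "CD3", "CD20", "CD57", "CD68", "CK"]:
        if ch not in positivity.columns:
            raise SchemaError(f"positivity calls are missing channel {ch}")
    cd45 = positivity["CD45"].to_numpy(bool)
    cd3 = positivity["CD3"].to_numpy(bool)
    cd20 = positivity["CD20"].to_numpy(bool)
    cd57 = positivity["CD57"].to_numpy(bool)
    cd68 = positivity["CD68"].to_numpy(bool)
    ck = positivity["CK"].to_numpy(bool)

    phenotype = np.select(
        [cd45 & cd3,
         cd45 & ~cd3 & cd20,
         cd45 & ~cd3 & ~cd20 & cd57,
         cd45 & ~cd3 & ~cd20 & ~cd57 & cd68,
         cd45,
         ck],
        ["T_cell", "B_cell", "NK_cell", "macrophage", "other_immune", "tumor_cell"],
        default="other_nonimmune",
    )
    # CD57 on a T cell is a legitimate subset (CD57+/- T), not a conflict.
    ambiguous = cd45 & (
        (cd3 & cd20)
        | (~cd3 & cd20 & (cd57 | cd68))
        | (~cd3 & ~cd20 & cd57 & cd68)
    )
    flags = np.where(ambiguous, "ambiguous_lineage", "")
    return pd.DataFrame(
        {"phenotype": phenotype, "cd57": cd57, "flags": flags},
        index=positivity.index,
    )


def assign_receptor_status(positivity: pd.DataFrame, phenotype: pd.Series) -> pd.DataFrame:
    """CD16/NKG2A status per cell, copied from positivity.

    Recorded for every cell; downstream immune-subset tallies only use them
    for immune phenotypes (T, B, NK, macrophage).
    """
    for ch in ["CD16", "NKG2A"]:
        if ch not in positivity.columns:
            raise SchemaError(f"positivity calls are missing channel {ch}")
    return pd.DataFrame(
        {"cd16": positivity["CD16"].to_numpy(bool),
         "nkg2a": positivity["NKG2A"].to_numpy(bool)},
        index=positivity.index,
    )


def gate_cells(cells: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Full gating pass: positivity -> phenotype -> receptor status.

    Returns one row per cell with ``cell_id, core_id, phenotype, cd57,
    cd16, nkg2a, hlae, flags`` (hlae is HLA-E positivity, meaningful on
    tumor cells).
    """
    panel.validate()
    pos = call_positivity(cells, panel)
    pheno = assign_phenotype(pos)
    rec = assign_receptor_status(pos, pheno["phenotype"])
    out = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy() if "cell_id" in cells else np.arange(len(cells)),
        "core_id": cells["core_id"].to_numpy() if "core_id" in cells else "pooled",
    }, index=cells.index)
    out["phenotype"] = pheno["phenotype"]
    out["cd57"] = pheno["cd57"]
    out["cd16"] = rec["cd16"]
    out["nkg2a"] = rec["nkg2a"]
    out["hlae"] = pos["HLAE"] if "HLAE" in pos else False
    out["flags"] = pheno["flags"]
    return out


# --- molecular classification ---------------------------------------------

def classify_msi(flags: Sequence[int]) -> str:
    """MSS / MSI-L / MSI-H from the five microsatellite-marker flags.

    Two or more unstable markers -> MSI-H, exactly one -> MSI-L,
    none -> MSS.
    """
    flags = list(flags)
    if len(flags) != len(MSI_MARKERS):
        raise SchemaError(f"expected {len(MSI_MARKERS)} marker flags, got {len(flags)}")
    n = sum(bool(f) for f in flags)
    if n >= 2:
        return "MSI-H"
    if n == 1:
        return "MSI-L"
    return "MSS"


def classify_molecular_subtype(ebv: bool, msi: str, ecad_altered: bool,
                               p53_positive: bool) -> str:
    """Five-subtype decision cascade.

    EBV+ takes precedence; then MSI-H; then (EBV-, MSS/MSI-L) tumors with
    altered E-cadherin are EMT-like; the remainder split on p53.
    """
    if msi not in MSI_CLASSES:
        raise ValueError(f"msi must be one of {MSI_CLASSES}, got {msi!r}")
    if ebv:
        return "EBV+"
    if msi == "MSI-H":
        return "MSI-H"
    if ecad_altered:
        return "EMT-like"
    return "non-EMT p53+" if p53_positive else "non-EMT p53-"


def molecular_status_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Append msi class and molecular subtype columns to a clinical table."""
    msi = [classify_msi([row[m] for m in MSI_MARKERS]) for _, row in clinical.iterrows()]
    subtype = [
        classify_molecular_subtype(bool(row["ebv_ish"]), m,
                                   bool(row["ecad_altered"]), bool(row["p53_positive"]))
        for (_, row), m in zip(clinical.iterrows(), msi)
    ]
    out = clinical.copy()
    out["msi"] = msi
    out["subtype"] = subtype
    return out
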