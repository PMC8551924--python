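"""Plate normalization, QC, hit calling and class summaries.

Each plate carries one sample screened against the whole compound library at a
single dose, with DMSO vehicle wells as the negative control and staurosporine
wells as the positive control. Normalized cytotoxicity is
``100 * (1 - RLU / median(DMSO RLU))`` so 0% means no effect, 100% complete
kill, and negative values growth stimulation. A plate passes QC when the
positive control kills and the vehicle wells are tight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DMSO",
    "STAUROSPORINE",
    "PlateReadings",
    "HitCallConfig",
    "QCResult",
    "CytotoxicityMatrix",
    "PlateError",
    "normalize_cytotoxicity",
    "qc_plate",
    "build_cytotoxicity_matrix",
    "call_hits",
    "summarize_by_class",
]

DMSO = "DMSO"
STAUROSPORINE = "STAUROSPORINE"
_CONTROLS = (DMSO, STAUROSPORINE)


class PlateError(ValueError):
    """Unusable plate (missing controls, negative RLU, zero DMSO signal)."""


@dataclass
class PlateReadings:
    """Raw luminescence readings for one sample's screening plate."""

    plate_id: str
    sample_id: str
    wells: pd.DataFrame  # columns: well, compound_id, rlu

    def __post_init__(self) -> None:
        required = {"well", "compound_id", "rlu"}
        if not required <= set(self.wells.columns):
            raise PlateError(f"{self.plate_id}: wells need columns {sorted(required)}")
        rlu = self.wells["rlu"].to_numpy(dtype=float)
        if (rlu < 0).any() or not np.isfinite(rlu).all():
            raise PlateError(f"{self.plate_id}: RLU must be finite and non-negative")
        compounds = set(self.wells["compound_id"])
        for ctrl in _CONTROLS:
            if ctrl not in compounds:
                raise PlateError(f"{self.plate_id}: missing {ctrl} control wells")

    def control_rlu(self, which: str) -> np.ndarray:
        return self.wells.loc[self.wells["compound_id"] == which, "rlu"].to_numpy(dtype=float)


@dataclass(frozen=True)
class HitCallConfig:
    """Hit threshold and plate QC cut-offs (all in % cytotoxicity / CV units)."""

    hit_threshold: float = 33.0
    qc_staurosporine_min: float = 80.0
    qc_dmso_cv_max: float = 0.2


@dataclass(frozen=True)
class QCResult:
    plate_id: str
    passed: bool
    reasons: tuple[str, ...]
    staurosporine_cytotoxicity: float
    dmso_cv: float


def _dmso_median(plate: PlateReadings) -> float:
    dmso = plate.control_rlu(DMSO)
    med = float(np.median(dmso))
    if med <= 0:
        raise PlateError(f"{plate.plate_id}: DMSO median RLU is not positive")
    return med


def normalize_cytotoxicity(plate: PlateReadings, include_controls: bool = False) -> pd.Series:
    """Per-compound % cytotoxicity vs the plate's DMSO median.

    Replicate wells of the same compound are averaged at the RLU level first.
    """
    med = _dmso_median(plate)
    mean_rlu = plate.wells.groupby("compound_id", sort=False)["rlu"].mean()
    cyto = 100.0 * (1.0 - mean_rlu / med)
    if not include_controls:
        cyto = cyto.drop(index=[c for c in _CONTROLS if c in cyto.index])
    cyto.name = plate.sample_id
    return cyto


def qc_plate(plate: PlateReadings, config: HitCallConfig = HitCallConfig()) -> QCResult:
    """Pass iff staurosporine kill is high and DMSO wells have a low CV."""
    reasons = []
    try:
        med = _dmso_median(plate)
    except PlateError:
        return QCResult(plate.plate_id, False, ("dmso_signal",), float("nan"), float("nan"))
    stauro = plate.control_rlu(STAUROSPORINE)
    stauro_cyto = 100.0 * (1.0 - float(np.mean(stauro)) / med)
    dmso = plate.control_rlu(DMSO)
    cv = float(np.std(dmso) / np.mean(dmso))
    if stauro_cyto < config.qc_staurosporine_min:
        reasons.append("positive_control")
    if cv > config.qc_dmso_cv_max:
        reasons.append("dmso_effect")
    return QCResult(plate.plate_id, not reasons, tuple(reasons), stauro_cyto, cv)


@dataclass
class CytotoxicityMatrix:
    """Drug x sample % cytotoxicity with plate QC provenance."""

    values: pd.DataFrame  # index: compound_id, columns: sample_id; NaN = failed QC
    qc: pd.DataFrame  # one row per plate
    drug_class: pd.Series | None = None  # compound_id -> mechanism label

    @property
    def drug_means(self) -> pd.Series:
        return self.values.mean(axis=1, skipna=True)


def build_cytotoxicity_matrix(
    plates: Sequence[PlateReadings],
    config: HitCallConfig = HitCallConfig(),
    drug_classes: Mapping[str, str] | pd.Series | None = None,
) -> CytotoxicityMatrix:
    """Normalize every plate; failed-QC plates propagate as missing columns."""
    columns: dict[str, pd.Series] = {}
    qc_rows = []
    for plate in plates:
        res = qc_plate(plate, config)
        qc_rows.append(
            {
                "plate_id": res.plate_id,
                "sample_id": plate.sample_id,
                "passed": res.passed,
                "reasons": ";".join(res.reasons),
                "staurosporine_cytotoxicity": res.staurosporine_cytotoxicity,
                "dmso_cv": res.dmso_cv,
            }
        )
        if res.passed:
            columns[plate.sample_id] = normalize_cytotoxicity(plate)
        else:
            columns[plate.sample_id] = pd.Series(dtype=float)
    values = pd.DataFrame(columns)
    classes = pd.Series(drug_classes) if drug_classes is not None else None
    return CytotoxicityMatrix(values, pd.DataFrame(qc_rows), classes)


def call_hits(matrix: CytotoxicityMatrix, config: HitCallConfig = HitCallConfig()) -> pd.DataFrame:
    """Drugs whose mean cytotoxicity across QC-passing samples exceeds the
    threshold (strict), sorted by mean descending with lexicographic ties."""
    means = matrix.values.mean(axis=1, skipna=True)
    sds = matrix.values.std(axis=1, skipna=True, ddof=1)
    n = matrix.values.notna().sum(axis=1)
    out = pd.DataFrame(
        {"compound_id": means.index, "mean_cytotoxicity": means.values,
         "sd": sds.values, "n_samples": n.values}
    )
    out = out[out["mean_cytotoxicity"] > config.hit_threshold]
    out = out.sort_values(
        ["mean_cytotoxicity", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return out


def summarize_by_class(matrix: CytotoxicityMatrix,
                       drug_classes: Mapping[str, str] | pd.Series | None = None) -> pd.DataFrame:
    """Mean of member drugs' per-drug mean cytotoxicity per mechanism class,
    ranked descending (ties broken by class name)."""
    classes = drug_classes if drug_classes is not None else matrix.drug_class
    if classes is None:
        raise PlateError("no drug class labels provided")
    classes = pd.Series(classes)
    missing = [d for d in matrix.values.index if d not in classes.index or pd.isna(classes[d])]
    if missing:
        raise PlateError(f"drugs without class label: {missing[:5]}")
    means = matrix.drug_means
    df = pd.DataFrame({"mechanism_class": classes.reindex(means.index), "mean": means})
    out = (
        df.groupby("mechanism_class")["mean"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_cytotoxicity", "count": "n_drugs"})
        .reset_index()
    )
    return out.sort_values(
        ["mean_cytotoxicity", "mechanism_class"], ascending=[False, True]
    ).reset_index(drop=True)
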