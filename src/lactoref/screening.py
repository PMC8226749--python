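"""Enrollment eligibility filtering and retrospective subclinical-disease exclusion.

Enrollment checks happen at sampling time on animal metadata (phase window,
parity 2-5, fever, milk drop, body condition, pregnancy for late lactation).
Retrospective exclusion happens after the laboratory panel is available:
hyperketonemia (BHB above threshold), hypocalcemia (Ca below threshold), or
more than the allowed number of outlier analytes (Tukey fences per analyte
within each phase group).  Retained animals keep their panels, but any
individually flagged value is blanked for downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalytePanel,
    CowRecord,
    InsufficientDataError,
    ScreeningConfig,
    ValidationError,
)
from .registry import DRY_ONSET_WINDOW, PHASE_ORDER, PHASE_WINDOWS

#: Machine-readable exclusion reason codes.
REASONS = ("out_of_phase_window", "parity", "fever", "milk_drop", "bcs",
           "not_pregnant", "hyperketonemia", "hypocalcemia", "multi_outlier")


@dataclass
class ScreeningOutcome:
    cow_id: str
    eligible: bool
    phase: Optional[str]
    reasons: list[str] = field(default_factory=list)


@dataclass
class OutlierMask:
    """Per-(cow, analyte) outlier flags; rows are cows, columns analytes."""

    flags: pd.DataFrame

    @property
    def outlier_count(self) -> pd.Series:
        return self.flags.sum(axis=1).astype(int)


def _in_window(x: int, window: tuple[int, int]) -> bool:
    return window[0] <= x <= window[1]


def assign_phase(dfc: int, days_from_dry_onset: Optional[int] = None,
                 pregnant: bool = True) -> Optional[str]:
    """Map days-from-calving to a lactation phase, or None when in no window.

    The dry window additionally requires 30-50 days from dry-phase onset when
    that covariate is known; late lactation requires a confirmed pregnancy.
    """
    if _in_window(dfc, PHASE_WINDOWS["dry"]):
        if days_from_dry_onset is None or _in_window(days_from_dry_onset, DRY_ONSET_WINDOW):
            return "dry"
        return None
    for label in ("postpartum", "early_lactation"):
        if _in_window(dfc, PHASE_WINDOWS[label]):
            return label
    if _in_window(dfc, PHASE_WINDOWS["late_lactation"]):
        return "late_lactation" if pregnant else None
    return None


def enrollment_filter(cow: CowRecord, cfg: Optional[ScreeningConfig] = None) -> ScreeningOutcome:
    """Evaluate every enrollment criterion, collecting all violations.

    The milk-drop criterion applies only to the lactating phases with milk
    records (early and late lactation); the drop fraction is
    (prior week mean − today) / prior week mean, flagged when strictly above
    the threshold.
    """
    cfg = cfg or ScreeningConfig()
    reasons: list[str] = []

    phase = assign_phase(cow.dfc, cow.days_from_dry_onset, cow.pregnant)
    if phase is None:
        in_late_window = _in_window(cow.dfc, PHASE_WINDOWS["late_lactation"])
        reasons.append("not_pregnant" if in_late_window and not cow.pregnant
                       else "out_of_phase_window")

    if not (cfg.parity_min <= cow.parity <= cfg.parity_max):
        reasons.append("parity")
    if cow.rectal_temp > cfg.fever_threshold:
        reasons.append("fever")
    if phase in ("early_lactation", "late_lactation"):
        if cow.milk_today is not None and cow.milk_prior_week_mean is not None:
            if cow.milk_prior_week_mean == 0:
                raise ValidationError(
                    f"{cow.cow_id}: milk drop undefined with zero prior-week mean")
            drop = (cow.milk_prior_week_mean - cow.milk_today) / cow.milk_prior_week_mean
            if drop > cfg.milk_drop_threshold:
                reasons.append("milk_drop")
    if cow.bcs_class != "optimal":
        reasons.append("bcs")

    return ScreeningOutcome(cow_id=cow.cow_id, eligible=not reasons,
                            phase=phase, reasons=reasons)


def flag_outliers(values, multiplier: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier mask: outside Q1 − m·IQR or Q3 + m·IQR.

    Quartiles use linear interpolation between order statistics
    (h = (n−1)p + 1).  Missing values are never flagged.  Requires at least
    4 non-missing values.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 4:
        raise InsufficientDataError(
            f"need >= 4 non-missing values to set fences, got {int(finite.sum())}")
    q1, q3 = np.quantile(arr[finite], [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    mask = np.zeros(arr.shape, dtype=bool)
    mask[finite] = (arr[finite] < lo) | (arr[finite] > hi)
    return mask


def retrospective_exclude(
    panels_by_phase: Mapping[str, Sequence[AnalytePanel]],
    cfg: Optional[ScreeningConfig] = None,
) -> tuple[list[str], dict[str, list[str]], OutlierMask]:
    """Apply the subclinical-disorder exclusion rules within each phase group.

    One pass: Tukey fences are computed per analyte within each phase group,
    then an animal is excluded when BHB exceeds ``bhb_max`` (hyperketonemia),
    Ca falls below ``ca_min`` (hypocalcemia), or strictly more than
    ``max_outlier_analytes`` of its analytes are flagged.  Returns
    (retained cow ids, excluded cow id -> reasons, outlier mask over all cows).
    Flagged values of retained animals should be blanked downstream (see
    :func:`apply_mask`); whole animals are never dropped for a within-limit
    flag count.
    """
    cfg = cfg or ScreeningConfig()
    retained: list[str] = []
    excluded: dict[str, list[str]] = {}
    mask_frames: list[pd.DataFrame] = []

    for phase, panels in panels_by_phase.items():
        if phase not in PHASE_ORDER:
            raise ValidationError(f"unknown phase {phase!r}")
        if len(panels) < 4:
            raise InsufficientDataError(
                f"phase {phase!r} has {len(panels)} animals; need >= 4")
        df = pd.DataFrame([p.values for p in panels],
                          index=[p.cow_id for p in panels], dtype=float)
        flags = pd.DataFrame(False, index=df.index, columns=df.columns)
        for analyte in df.columns:
            col = df[analyte]
            if col.notna().sum() >= 4:
                flags[analyte] = flag_outliers(col.to_numpy(), cfg.iqr_multiplier)
        mask_frames.append(flags)

        counts = flags.sum(axis=1)
        for cow_id in df.index:
            reasons = []
            bhb = df.at[cow_id, "BHB"] if "BHB" in df.columns else np.nan
            ca = df.at[cow_id, "Ca"] if "Ca" in df.columns else np.nan
            if np.isfinite(bhb) and bhb > cfg.bhb_max:
                reasons.append("hyperketonemia")
            if np.isfinite(ca) and ca < cfg.ca_min:
                reasons.append("hypocalcemia")
            if counts[cow_id] > cfg.max_outlier_analytes:
                reasons.append("multi_outlier")
            if reasons:
                excluded[cow_id] = reasons
            else:
                retained.append(cow_id)

    mask = OutlierMask(flags=pd.concat(mask_frames).fillna(False).astype(bool))
    return retained, excluded, mask


def apply_mask(
    panels_by_phase: Mapping[str, Sequence[AnalytePanel]],
    retained: Sequence[str],
    mask: OutlierMask,
) -> pd.DataFrame:
    """Tidy retained dataset with flagged values blanked.

    Returns a DataFrame indexed by cow_id with a ``phase`` column plus one
    column per analyte; values flagged in ``mask`` are set to missing.
    """
    retained_set = set(retained)
    rows, phases, ids = [], [], []
    for phase, panels in panels_by_phase.items():
        for p in panels:
            if p.cow_id in retained_set:
                rows.append(p.values)
                phases.append(phase)
                ids.append(p.cow_id)
    df = pd.DataFrame(rows, index=ids, dtype=float)
    flags = mask.flags.reindex(index=df.index, columns=df.columns, fill_value=False)
    df = df.mask(flags)
    df.insert(0, "phase", phases)
    df.index.name = "cow_id"
    return df
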