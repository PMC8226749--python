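"""Domain types, the analyte registry, and CSV readers/writers.

All tabular exchange uses comma-separated UTF-8 files with a header row, "."
as decimal separator, and empty cells for missing values.  Units are fixed
per analyte and never converted on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import registry as _reg
from .registry import (  # noqa: F401  (re-exported surface)
    DRY_ONSET_WINDOW,
    LOG_TRANSFORMED,
    PHASE_ORDER,
    PHASE_WINDOWS,
    RETINOL_UG_PER_100ML_FACTOR,
)


class ValidationError(ValueError):
    """An input value violates a documented invariant."""


class SchemaError(ValueError):
    """A CSV header does not match the documented schema."""


class DuplicateIdError(ValueError):
    """The same cow_id occurs more than once in a file."""


class InsufficientDataError(ValueError):
    """Too few non-missing values for the requested statistic."""


class DegenerateSampleError(ValueError):
    """A sample with zero variance where dispersion is required."""


@dataclass(frozen=True)
class Phase:
    """A lactation phase with its closed days-from-calving window."""

    label: str
    dfc_window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.label not in PHASE_ORDER:
            raise ValidationError(f"unknown phase label {self.label!r}")
        if self.dfc_window != PHASE_WINDOWS[self.label]:
            raise ValidationError(
                f"phase {self.label!r} must use window {PHASE_WINDOWS[self.label]}"
            )


PHASES: tuple[Phase, ...] = tuple(Phase(lbl, PHASE_WINDOWS[lbl]) for lbl in PHASE_ORDER)

BCS_CLASSES = ("scarce", "optimal", "excessive")


@dataclass
class CowRecord:
    """One animal's enrollment-relevant attributes."""

    cow_id: str
    farm_id: str
    parity: int
    dfc: int
    rectal_temp: float
    pregnant: bool
    days_from_dry_onset: Optional[int] = None
    milk_today: Optional[float] = None
    milk_prior_week_mean: Optional[float] = None
    bcs_class: str = "optimal"

    def __post_init__(self) -> None:
        if self.parity < 1:
            raise ValidationError(f"parity must be >= 1, got {self.parity}")
        if not (30 < self.rectal_temp < 45):
            raise ValidationError(f"implausible rectal temperature {self.rectal_temp}")
        if self.bcs_class not in BCS_CLASSES:
            raise ValidationError(f"bcs_class must be one of {BCS_CLASSES}")
        for name in ("milk_today", "milk_prior_week_mean"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")


@dataclass
class AnalytePanel:
    """One animal's plasma analyte values, keyed by registry name.

    Missing analytes are simply absent (or NaN).  PCV is a volume fraction in
    (0, 1); all other registered analytes are concentrations/activities >= 0.
    """

    cow_id: str
    values: dict[str, float] = field(default_factory=dict)

    def validate(self, reg: "AnalyteRegistry") -> None:
        for name, v in self.values.items():
            if name not in reg:
                raise ValidationError(f"unregistered analyte {name!r}")
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if not math.isfinite(v):
                raise ValidationError(f"non-finite value for {name!r}: {v}")
            if name == "PCV":
                if not (0 < v < 1):
                    raise ValidationError(f"PCV must lie in (0,1), got {v}")
            elif v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class AnalyteSpec:
    """Registry entry: unit, transform flag, and per-phase defaults."""

    name: str
    unit: str
    log_transform: bool
    n: dict[str, int]              # phase -> reference-sample size
    mean: dict[str, float]         # phase -> healthy mean
    sd: dict[str, float]           # phase -> healthy SD
    r_squared: float               # phase-model coefficient of determination


class AnalyteRegistry:
    """The 34-analyte plasma panel with per-phase healthy-population defaults."""

    def __init__(self, specs: Iterable[AnalyteSpec]):
        self._specs: dict[str, AnalyteSpec] = {}
        for s in specs:
            if s.name in self._specs:
                raise ValidationError(f"duplicate analyte {s.name!r}")
            if any(sd <= 0 for sd in s.sd.values()):
                raise ValidationError(f"{s.name}: SDs must be > 0")
            if any(n <= 0 for n in s.n.values()):
                raise ValidationError(f"{s.name}: ns must be > 0")
            self._specs[s.name] = s

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> AnalyteSpec:
        return self._specs[name]

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    @property
    def log_transformed(self) -> list[str]:
        return [s.name for s in self if s.log_transform]


def default_registry() -> AnalyteRegistry:
    """Build the packaged registry (34 analytes; ln-flag for BHB, Zn, AOPP)."""
    specs = []
    for name, unit, ns, params, r2 in _reg.ANALYTE_TABLE:
        specs.append(AnalyteSpec(
            name=name,
            unit=unit,
            log_transform=name in LOG_TRANSFORMED,
            n=dict(zip(PHASE_ORDER, ns)),
            mean={p: m for p, (m, _) in zip(PHASE_ORDER, params)},
            sd={p: s for p, (_, s) in zip(PHASE_ORDER, params)},
            r_squared=r2,
        ))
    return AnalyteRegistry(specs)


@dataclass
class ScreeningConfig:
    """Thresholds for enrollment filtering and retrospective SCD exclusion."""

    fever_threshold: float = 39.5        # °C, fever when strictly above
    milk_drop_threshold: float = 0.15    # fraction, at-risk when strictly above
    parity_min: int = 2
    parity_max: int = 5
    bhb_max: float = 1.2                 # mmol/L, hyperketonemia when above
    ca_min: float = 2.0                  # mmol/L, hypocalcemia when below
    max_outlier_analytes: int = 3        # exclusion when strictly more flagged
    iqr_multiplier: float = 1.5

    def __post_init__(self) -> None:
        for name in ("fever_threshold", "milk_drop_threshold", "bhb_max",
                     "ca_min", "iqr_multiplier"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.parity_min > self.parity_max:
            raise ValidationError("parity_min must not exceed parity_max")
        if self.max_outlier_analytes < 0:
            raise ValidationError("max_outlier_analytes must be >= 0")


# ---------------------------------------------------------------------------
# CSV I/O

COW_COLUMNS = ("cow_id", "farm_id", "parity", "dfc", "days_from_dry_onset",
               "rectal_temp", "milk_today", "milk_prior_week_mean",
               "bcs_class", "pregnant")


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot parse boolean {v!r}")


def _opt(v, cast):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return cast(v)


def read_cohort(
    cow_csv_path, panel_csv_path, reg: Optional[AnalyteRegistry] = None,
) -> list[tuple[CowRecord, AnalytePanel]]:
    """Read and join the cow and panel files into per-animal records.

    Raises SchemaError on a malformed header (naming the offending column) and
    DuplicateIdError if a cow appears twice in either file.  Empty cells become
    missing values, never zeros.
    """
    reg = reg or default_registry()
    cows = pd.read_csv(cow_csv_path, dtype={"cow_id": str, "farm_id": str},
                       float_precision="round_trip")
    panels = pd.read_csv(panel_csv_path, dtype={"cow_id": str},
                         float_precision="round_trip")

    missing = [c for c in COW_COLUMNS if c not in cows.columns]
    if missing:
        raise SchemaError(f"cows file is missing column(s): {', '.join(missing)}")
    extra = [c for c in cows.columns if c not in COW_COLUMNS]
    if extra:
        raise SchemaError(f"cows file has unknown column(s): {', '.join(extra)}")
    if "cow_id" not in panels.columns:
        raise SchemaError("panels file is missing column: cow_id")
    unknown = [c for c in panels.columns if c != "cow_id" and c not in reg]
    if unknown:
        raise SchemaError(f"panels file has unknown analyte column(s): {', '.join(unknown)}")

    for df, label in ((cows, "cows"), (panels, "panels")):
        dup = df["cow_id"][df["cow_id"].duplicated()]
        if not dup.empty:
            raise DuplicateIdError(f"duplicate cow_id in {label} file: {dup.iloc[0]}")

    panel_map = panels.set_index("cow_id")
    joined = []
    for row in cows.itertuples(index=False):
        rec = CowRecord(
            cow_id=row.cow_id,
            farm_id=row.farm_id,
            parity=int(row.parity),
            dfc=int(row.dfc),
            rectal_temp=float(row.rectal_temp),
            pregnant=_parse_bool(row.pregnant),
            days_from_dry_onset=_opt(row.days_from_dry_onset, lambda v: int(float(v))),
            milk_today=_opt(row.milk_today, float),
            milk_prior_week_mean=_opt(row.milk_prior_week_mean, float),
            bcs_class=str(row.bcs_class),
        )
        values: dict[str, float] = {}
        if rec.cow_id in panel_map.index:
            for name, v in panel_map.loc[rec.cow_id].items():
                if not (v is None or (isinstance(v, float) and math.isnan(v))):
                    values[str(name)] = float(v)
        panel = AnalytePanel(cow_id=rec.cow_id, values=values)
        panel.validate(reg)
        joined.append((rec, panel))
    return joined


def write_cohort(records: Sequence[tuple[CowRecord, AnalytePanel]],
                 cow_csv_path, panel_csv_path,
                 reg: Optional[AnalyteRegistry] = None) -> None:
    """Write per-animal records back to the two-file CSV schema."""
    reg = reg or default_registry()
    cow_rows, panel_rows = [], []
    for rec, panel in records:
        cow_rows.append({
            "cow_id": rec.cow_id, "farm_id": rec.farm_id, "parity": rec.parity,
            "dfc": rec.dfc, "days_from_dry_onset": rec.days_from_dry_onset,
            "rectal_temp": rec.rectal_temp, "milk_today": rec.milk_today,
            "milk_prior_week_mean": rec.milk_prior_week_mean,
            "bcs_class": rec.bcs_class, "pregnant": rec.pregnant,
        })
        panel_rows.append({"cow_id": rec.cow_id,
                           **{a: panel.values.get(a) for a in reg.names}})
    # %.17g guarantees binary round-trip of doubles through the text format
    pd.DataFrame(cow_rows, columns=list(COW_COLUMNS)).to_csv(
        cow_csv_path, index=False, float_format="%.17g")
    pd.DataFrame(panel_rows, columns=["cow_id"] + reg.names).to_csv(
        panel_csv_path, index=False, float_format="%.17g")


def write_report_tables(results: Mapping, out_dir) -> dict[str, Path]:
    """Emit the three wide report tables as CSV files.

    ``results`` holds up to three keys:

    * ``moments`` — list of dicts (analyte, phase, n, skew, kurt); emitted one
      row per analyte with per-phase n/skew/kurt columns.
    * ``anova`` — list of AnovaResult-like objects; one row per analyte with
      R², per-phase mean/sd and the six pairwise significance codes.
    * ``ri`` — list of RefInterval-like objects (one per analyte per phase);
      one row per analyte with per-phase lower/upper limits and CIs.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to report directory {out_dir}: {exc}") from exc

    paths: dict[str, Path] = {}

    mom_cols = ["analyte"] + [f"{p}_{f}" for p in PHASE_ORDER for f in ("n", "skew", "kurt")]
    rows: dict[str, dict] = {}
    for m in results.get("moments", []):
        d = m if isinstance(m, dict) else vars(m)
        r = rows.setdefault(d["analyte"], {"analyte": d["analyte"]})
        p = d["phase"]
        r[f"{p}_n"], r[f"{p}_skew"], r[f"{p}_kurt"] = d["n"], d["skew"], d["kurt"]
    paths["moments"] = out_dir / "moments.csv"
    pd.DataFrame(list(rows.values()), columns=mom_cols).to_csv(paths["moments"], index=False)

    pair_names = [f"{a}_x_{b}" for i, a in enumerate(PHASE_ORDER)
                  for b in PHASE_ORDER[i + 1:]]
    an_cols = (["analyte", "r_squared"]
               + [f"{p}_{f}" for p in PHASE_ORDER for f in ("mean", "sd")]
               + [f"p_{pn}" for pn in pair_names])
    an_rows = []
    for a in results.get("anova", []):
        d = a if isinstance(a, dict) else vars(a)
        row = {"analyte": d["analyte"], "r_squared": d.get("r_squared")}
        for p in PHASE_ORDER:
            row[f"{p}_mean"] = d.get("means", {}).get(p)
            row[f"{p}_sd"] = d.get("sds", {}).get(p)
        for (pair, pval) in d.get("pairwise_p", {}).items():
            row[f"p_{pair[0]}_x_{pair[1]}"] = pval
        an_rows.append(row)
    paths["anova"] = out_dir / "anova.csv"
    pd.DataFrame(an_rows, columns=an_cols).to_csv(paths["anova"], index=False)

    ri_cols = ["analyte"] + [
        f"{p}_{f}" for p in PHASE_ORDER
        for f in ("lower", "lower_ci_low", "lower_ci_high",
                  "upper", "upper_ci_low", "upper_ci_high")
    ]
    ri_rows: dict[str, dict] = {}
    for ri in results.get("ri", []):
        d = ri if isinstance(ri, dict) else vars(ri)
        r = ri_rows.setdefault(d["analyte"], {"analyte": d["analyte"]})
        for p in d["block"]:
            r[f"{p}_lower"] = d["lower"]
            r[f"{p}_lower_ci_low"], r[f"{p}_lower_ci_high"] = d["lower_ci"]
            r[f"{p}_upper"] = d["upper"]
            r[f"{p}_upper_ci_low"], r[f"{p}_upper_ci_high"] = d["upper_ci"]
    paths["ri"] = out_dir / "ri_table.csv"
    pd.DataFrame(list(ri_rows.values()), columns=ri_cols).to_csv(paths["ri"], index=False)
    return paths


def retinol_to_ug_per_100ml(value_umol_l: float) -> float:
    """Display-only conversion of retinol from µmol/L to µg/100 mL."""
    return value_umol_l * RETINOL_UG_PER_100ML_FACTOR
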