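"""Nonparametric bootstrap estimation of reference limits with confidence intervals.

For a healthy reference sample the reference interval is the central
``coverage`` fraction (default 95%) of the distribution.  Each bootstrap
replicate resamples the n observations with replacement and records the two
tail quantiles; the reported lower/upper limits are the means of the
replicate quantiles and each limit's confidence interval is the 2.5th-97.5th
percentile range of its replicate distribution.  Quantiles use linear
interpolation between order statistics (h = (n−1)p + 1), the same convention
as the outlier fences.  Phases merged by the pairwise testing stage are
pooled before resampling and share one interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import InsufficientDataError, ValidationError
from .phase_stats import PhasePartition
from .registry import PHASE_ORDER

DEFAULT_B = 5000
MIN_N = 20


@dataclass
class RefInterval:
    analyte: str
    block: frozenset[str]
    lower: float
    upper: float
    lower_ci: tuple[float, float]
    upper_ci: tuple[float, float]
    n_used: int
    B: int
    coverage: float = 0.95

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper + 1e-12):
            raise ValidationError(f"{self.analyte}: lower exceeds upper")


def bootstrap_ri(
    values, coverage: float = 0.95, B: int = DEFAULT_B,
    seed=None, estimator: str = "mean", analyte: str = "",
    block: frozenset[str] = frozenset(), allow_small: bool = False,
) -> RefInterval:
    """Percentile-bootstrap reference interval on one pooled sample.

    ``seed`` may be an int or a numpy SeedSequence/Generator; identical
    (values, coverage, B, seed) give a bit-identical result.  ``estimator``
    selects the point estimate over replicate quantiles ("mean" or "median").
    Samples below 20 values are refused unless ``allow_small`` is set.
    """
    if not (0 < coverage < 1):
        raise ValidationError("coverage must lie in (0,1)")
    if B < 200:
        raise ValidationError("B must be >= 200")
    if estimator not in ("mean", "median"):
        raise ValidationError("estimator must be 'mean' or 'median'")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n < MIN_N and not allow_small:
        raise InsufficientDataError(
            f"{analyte or 'sample'}: n={n} below the minimum of {MIN_N} "
            "(pass allow_small=True to override)")

    rng = np.random.default_rng(seed)
    lo_p, hi_p = (1 - coverage) / 2, 1 - (1 - coverage) / 2
    idx = rng.integers(0, n, size=(B, n))
    reps = np.quantile(arr[idx], [lo_p, hi_p], axis=1)
    point = np.mean(reps, axis=1) if estimator == "mean" else np.median(reps, axis=1)
    lo_ci = np.percentile(reps[0], [2.5, 97.5])
    hi_ci = np.percentile(reps[1], [2.5, 97.5])
    return RefInterval(
        analyte=analyte, block=block,
        lower=float(point[0]), upper=float(point[1]),
        lower_ci=(float(lo_ci[0]), float(lo_ci[1])),
        upper_ci=(float(hi_ci[0]), float(hi_ci[1])),
        n_used=n, B=B, coverage=coverage,
    )


def _block_seed(seed: Optional[int], analyte_index: int, block: frozenset[str]):
    """Deterministic per-(analyte, block) stream, order-independent."""
    phase_key = sorted(PHASE_ORDER.index(p) for p in block)
    return np.random.SeedSequence([0 if seed is None else int(seed),
                                   analyte_index, *phase_key])


def ri_table(
    data: pd.DataFrame,
    partitions: Mapping[str, PhasePartition],
    coverage: float = 0.95, B: int = DEFAULT_B, seed: Optional[int] = None,
    estimator: str = "mean", allow_small: bool = False,
) -> list[RefInterval]:
    """Reference intervals per analyte per merged phase block.

    ``data`` is the tidy retained dataset (``phase`` column + analyte
    columns).  The bootstrap runs once per block on the pooled block values
    — always on the original measurement scale, since nonparametric
    resampling needs no normality — and every phase in a block shares the
    block's interval.  Per-(analyte, block) RNG streams derive from ``seed``
    so evaluation order cannot change results.
    """
    analytes = [c for c in data.columns if c != "phase"]
    phases = data["phase"]
    out: list[RefInterval] = []
    for ai, analyte in enumerate(analytes):
        part = partitions[analyte]
        for block in part.blocks:
            vals = data.loc[phases.isin(block), analyte]
            out.append(bootstrap_ri(
                vals.to_numpy(), coverage=coverage, B=B,
                seed=_block_seed(seed, ai, block), estimator=estimator,
                analyte=analyte, block=block, allow_small=allow_small))
    return out


def expand_to_phases(intervals: list[RefInterval]) -> pd.DataFrame:
    """Long-format view: one row per analyte per phase (block rows repeated)."""
    rows = []
    for ri in intervals:
        for phase in sorted(ri.block, key=PHASE_ORDER.index):
            rows.append({
                "analyte": ri.analyte, "phase": phase,
                "lower": ri.lower, "lower_ci_low": ri.lower_ci[0],
                "lower_ci_high": ri.lower_ci[1],
                "upper": ri.upper, "upper_ci_low": ri.upper_ci[0],
                "upper_ci_high": ri.upper_ci[1],
                "n_used": ri.n_used, "B": ri.B, "coverage": ri.coverage,
            })
    return pd.DataFrame(rows)
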