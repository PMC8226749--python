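"""Normality gating, phase ANOVA, pairwise t-tests and the phase-merging rule.

Each analyte is tested for a fixed effect of lactation phase with a one-way
ANOVA (R² = SS_between / SS_total), followed by two-sided pairwise t-tests
over the six phase pairs with Holm family-wise adjustment.  Analytes whose
moment-based skewness or excess kurtosis falls outside ±1.5 are
ln-transformed before testing.  Phases whose adjusted pairwise p exceeds the
significance limit (0.05) are merged — connected components of the
"not-significantly-different" graph — and each merged block later receives a
single shared reference interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import DegenerateSampleError, InsufficientDataError, ValidationError
from .registry import PHASE_ORDER

PHASE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(PHASE_ORDER, 2))


@dataclass
class MomentsReport:
    analyte: str
    phase: str
    n: int
    skew: float
    kurt: float            # excess kurtosis


@dataclass
class AnovaResult:
    analyte: str
    r_squared: float
    f_stat: float
    p_overall: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


@dataclass
class PhasePartition:
    """Disjoint blocks of phase labels covering all four phases."""

    analyte: str
    blocks: list[frozenset[str]]

    def __post_init__(self) -> None:
        union = set().union(*self.blocks) if self.blocks else set()
        if union != set(PHASE_ORDER) or sum(len(b) for b in self.blocks) != len(PHASE_ORDER):
            raise ValidationError(f"{self.analyte}: blocks must partition the four phases")

    def block_of(self, phase: str) -> frozenset[str]:
        for b in self.blocks:
            if phase in b:
                return b
        raise KeyError(phase)


def sample_moments(values) -> tuple[float, float]:
    """Moment-based sample skewness g1 and excess kurtosis g2 (divisor n).

    g1 = m3 / m2^1.5, g2 = m4 / m2² − 3 with m_k the central sample moments.
    Requires n >= 4 and positive variance.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise InsufficientDataError(f"need >= 4 values, got {arr.size}")
    if np.var(arr) == 0:
        raise DegenerateSampleError("zero variance sample")
    return float(sps.skew(arr, bias=True)), float(sps.kurtosis(arr, fisher=True, bias=True))


def needs_log(skew: float, excess_kurt: float, limit: float = 1.5) -> bool:
    """True iff |skew| or |excess kurtosis| strictly exceeds the ±limit gate."""
    if not (math.isfinite(skew) and math.isfinite(excess_kurt)):
        raise ValidationError("moments must be finite")
    return abs(skew) > limit or abs(excess_kurt) > limit


def ln_transform(values) -> np.ndarray:
    """Natural log of strictly positive raw values."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if np.any(finite <= 0):
        raise ValidationError("ln transform requires strictly positive values")
    return np.log(arr)


def _group_arrays(values, phase_labels) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    phase_labels = np.asarray(phase_labels)
    keep = np.isfinite(values)
    values, phase_labels = values[keep], phase_labels[keep]
    groups = {}
    for lbl in PHASE_ORDER:
        g = values[phase_labels == lbl]
        if g.size:
            groups[lbl] = g
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise InsufficientDataError("need >= 2 phases with >= 2 values each")
    return groups


def anova_phase(values, phase_labels, analyte: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA of an analyte on lactation phase.

    R² = SS_between / SS_total; the overall p comes from F with
    (k−1, N−k) degrees of freedom.
    """
    groups = _group_arrays(values, phase_labels)
    all_vals = np.concatenate(list(groups.values()))
    if np.all(all_vals == all_vals[0]):
        raise DegenerateSampleError("all values identical")
    grand = all_vals.mean()
    ss_total = float(np.sum((all_vals - grand) ** 2))
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups.values()))
    ss_within = ss_total - ss_between
    k, n = len(groups), all_vals.size
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    return AnovaResult(
        analyte=analyte,
        r_squared=ss_between / ss_total,
        f_stat=f_stat,
        p_overall=min(max(p, np.nextafter(0, 1)), 1.0),
        means={lbl: float(g.mean()) for lbl, g in groups.items()},
        sds={lbl: float(g.std(ddof=1)) for lbl, g in groups.items()},
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, capped at 1."""
    return np.minimum(multipletests(np.asarray(pvalues, dtype=float),
                                    method="holm")[1], 1.0)


def pairwise_holm(values, phase_labels, sd_pooling: str = "pair",
                  adjust: str = "holm") -> dict[tuple[str, str], float]:
    """Two-sided pairwise t-tests over phase pairs with Holm adjustment.

    ``sd_pooling="pair"`` (default) pools the two compared groups' variances
    (classic two-sample t, df = n1+n2−2); ``"all"`` uses the ANOVA residual
    SD across every group (df = N−k).  ``adjust`` is ``"holm"`` or ``"none"``.
    Adjusted p-values are capped at 1.
    """
    if sd_pooling not in ("pair", "all"):
        raise ValidationError("sd_pooling must be 'pair' or 'all'")
    if adjust not in ("holm", "none"):
        raise ValidationError("adjust must be 'holm' or 'none'")
    groups = _group_arrays(values, phase_labels)

    if sd_pooling == "all":
        n = sum(g.size for g in groups.values())
        k = len(groups)
        ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups.values())
        pooled_var_all = ss_within / (n - k)
        df_all = n - k

    pairs = [p for p in PHASE_PAIRS if p[0] in groups and p[1] in groups]
    raw = []
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        if sd_pooling == "pair":
            df = ga.size + gb.size - 2
            pooled_var = (np.sum((ga - ga.mean()) ** 2)
                          + np.sum((gb - gb.mean()) ** 2)) / df
        else:
            df, pooled_var = df_all, pooled_var_all
        se = math.sqrt(pooled_var * (1 / ga.size + 1 / gb.size))
        if se == 0:
            raw.append(1.0 if ga.mean() == gb.mean() else 0.0)
            continue
        t = (ga.mean() - gb.mean()) / se
        raw.append(float(2 * sps.t.sf(abs(t), df)))

    adj = holm_adjust(raw) if adjust == "holm" else np.asarray(raw)
    return {pair: float(min(p, 1.0)) for pair, p in zip(pairs, adj)}


def merge_phases(pairwise_p: Mapping[tuple[str, str], float],
                 alpha: float = 0.05, analyte: str = "") -> PhasePartition:
    """Merge phases not significantly different pairwise (p > alpha).

    Builds a graph on the four phases with an edge per pair with p > alpha
    and returns its connected components, so merging is transitive.
    """
    parent = {p: p for p in PHASE_ORDER}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), p in pairwise_p.items():
        if p > alpha:
            parent[find(a)] = find(b)
    comp: dict[str, set[str]] = {}
    for ph in PHASE_ORDER:
        comp.setdefault(find(ph), set()).add(ph)
    blocks = sorted((frozenset(b) for b in comp.values()),
                    key=lambda b: min(PHASE_ORDER.index(p) for p in b))
    return PhasePartition(analyte=analyte, blocks=list(blocks))


def significance_code(p: float) -> str:
    """Display code used in the phase-comparison report: *** p<0.01, * p<0.1."""
    if p < 0.01:
        return "***"
    if p < 0.1:
        return "*"
    return "ns"


@dataclass
class AnalytePhaseStats:
    """Full per-analyte phase analysis bundle."""

    analyte: str
    log_used: bool
    moments: list[MomentsReport]
    anova: AnovaResult
    partition: PhasePartition


def analyze_analyte(
    values, phase_labels, analyte: str, log_transform: Optional[bool] = None,
    skew_kurt_limit: float = 1.5, alpha: float = 0.05,
    sd_pooling: str = "pair", adjust: str = "holm",
) -> AnalytePhaseStats:
    """Moments → normality gate → (optional ln) → ANOVA → pairwise → merging.

    When ``log_transform`` is None the ±limit moment gate decides, evaluated
    on the pooled sample; registry-flagged analytes may pass True explicitly.
    """
    values = np.asarray(values, dtype=float)
    phase_labels = np.asarray(phase_labels)
    groups = _group_arrays(values, phase_labels)
    moments = []
    for lbl, g in groups.items():
        sk, ku = sample_moments(g)
        moments.append(MomentsReport(analyte=analyte, phase=lbl, n=g.size,
                                     skew=sk, kurt=ku))
    if log_transform is None:
        pooled_sk, pooled_ku = sample_moments(values[np.isfinite(values)])
        log_transform = needs_log(pooled_sk, pooled_ku, skew_kurt_limit)
    work = ln_transform(values) if log_transform else values
    anova = anova_phase(work, phase_labels, analyte=analyte)
    anova.pairwise_p = pairwise_holm(work, phase_labels,
                                     sd_pooling=sd_pooling, adjust=adjust)
    partition = merge_phases(anova.pairwise_p, alpha=alpha, analyte=analyte)
    return AnalytePhaseStats(analyte=analyte, log_used=bool(log_transform),
                             moments=moments, anova=anova, partition=partition)


def analyze_dataset(
    data: pd.DataFrame, registry=None, alpha: float = 0.05,
    sd_pooling: str = "pair", adjust: str = "holm",
) -> dict[str, AnalytePhaseStats]:
    """Run the per-analyte phase analysis over a tidy retained dataset.

    ``data`` is indexed by cow with a ``phase`` column plus analyte columns
    (the output of the screening stage).  Registry log flags decide the
    transform; analytes missing from the registry fall back to the moment gate.
    """
    results = {}
    phases = data["phase"].to_numpy()
    for analyte in [c for c in data.columns if c != "phase"]:
        flag = registry[analyte].log_transform if registry and analyte in registry else None
        results[analyte] = analyze_analyte(
            data[analyte].to_numpy(), phases, analyte,
            log_transform=flag, alpha=alpha,
            sd_pooling=sd_pooling, adjust=adjust)
    return results
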