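"""Synthetic herd generator with the statistical structure the analysis assumes.

Each animal is cross-sectional (sampled in exactly one phase, as in the real
sampling design).  Analytes are drawn independently per phase at the
registry's healthy mean/SD: ln-flagged analytes (BHB, Zn, AOPP) from a
moment-matched lognormal, all others from a zero-truncated normal whose
parent parameters are solved numerically so the truncated draw reproduces
the configured mean and SD exactly (plain normal when mean/SD > 6, where the
truncated mass is negligible).  Subclinical-disorder contamination is
injected on top: hyperketonemia (BHB above threshold), hypocalcemia (Ca
below threshold) or a multi-outlier pattern (several analytes pushed beyond
their phase fences), with injected animals recorded as ground truth.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .core import (
    AnalytePanel,
    AnalyteRegistry,
    CowRecord,
    ScreeningConfig,
    ValidationError,
    default_registry,
)
from .registry import DRY_ONSET_WINDOW, FARM_TABLE, PHASE_ORDER, PHASE_WINDOWS

logger = logging.getLogger(__name__)

#: mean/sd ratio above which zero-truncation is numerically irrelevant.
_TRUNC_FREE_RATIO = 6.0

SCD_MECHANISMS = ("hyperketonemia", "hypocalcemia", "multi_outlier")


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched lognormal: σ² = ln(1 + sd²/mean²), µ = ln(mean) − σ²/2."""
    if mean <= 0 or sd <= 0:
        raise ValidationError("lognormal moment matching needs mean, sd > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2), float(np.sqrt(sigma2))


@functools.lru_cache(maxsize=512)
def truncated_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (µ, σ) of a zero-truncated normal with the target mean and SD.

    Solved from the truncated-normal moment identities with λ(a)=φ(a)/(1−Φ(a)),
    a=−µ/σ: mean = µ + σλ, var = σ²(1 + aλ − λ²).
    """
    if mean <= 0:
        raise ValidationError(f"infeasible truncation: target mean {mean} <= 0")
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    if mean / sd > _TRUNC_FREE_RATIO:
        return float(mean), float(sd)

    def residual(params):
        mu, sigma = params
        sigma = abs(sigma)
        a = -mu / sigma
        lam = sps.norm.pdf(a) / sps.norm.sf(a)
        m = mu + sigma * lam
        v = sigma ** 2 * (1 + a * lam - lam ** 2)
        return [m - mean, np.sqrt(max(v, 1e-300)) - sd]

    sol = optimize.root(residual, x0=[mean, sd], method="hybr")
    if not sol.success:
        raise ValidationError(
            f"truncated-normal moment matching failed for mean={mean}, sd={sd}")
    mu, sigma = float(sol.x[0]), float(abs(sol.x[1]))
    return mu, sigma


def draw_analyte(mean: float, sd: float, size: int, rng: np.random.Generator,
                 log_family: bool = False) -> np.ndarray:
    """Draw one analyte's phase sample at the configured healthy moments."""
    if log_family:
        mu, sigma = lognormal_params(mean, sd)
        return rng.lognormal(mu, sigma, size)
    mu, sigma = truncated_normal_params(mean, sd)
    if mean / sd > _TRUNC_FREE_RATIO:
        return rng.normal(mu, sigma, size)
    a = (0.0 - mu) / sigma
    return sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size,
                             random_state=rng)


@dataclass
class GeneratorSpec:
    """Study-condition parameterization of the synthetic herd.

    Defaults reproduce the packaged tables: per-analyte per-phase means/SDs
    from the registry, enrollment layout from the 11-farm herd table
    (92/103/84/82 animals over the four phases, 361 in total), clean panels
    (no contamination) unless rates or per-phase counts are supplied.
    """

    registry: AnalyteRegistry = field(default_factory=default_registry)
    layout: dict[str, dict[str, int]] = field(default_factory=lambda: {
        f["farm_id"]: dict(f["enrolled"]) for f in FARM_TABLE})
    contamination: dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for farm, counts in self.layout.items():
            for phase, c in counts.items():
                if phase not in PHASE_ORDER or c < 0:
                    raise ValidationError(f"bad layout entry {farm}/{phase}={c}")
        for mech, r in self.contamination.items():
            if mech not in SCD_MECHANISMS or not (0 <= r <= 1):
                raise ValidationError(f"bad contamination entry {mech}={r}")
        for spec in self.registry:
            for phase in PHASE_ORDER:
                if not spec.log_transform and spec.mean[phase] <= 0:
                    raise ValidationError(
                        f"{spec.name}/{phase}: mean must be > 0 for truncated draws")

    def phase_totals(self) -> dict[str, int]:
        totals = {p: 0 for p in PHASE_ORDER}
        for counts in self.layout.values():
            for p, c in counts.items():
                totals[p] += c
        return totals


def _cow_metadata(rng: np.random.Generator, farm_id: str, phase: str,
                  index: int, fever_threshold: float = 39.5) -> CowRecord:
    lo, hi = PHASE_WINDOWS[phase]
    dfc = int(rng.integers(lo, hi + 1))
    temp = float(np.clip(rng.normal(38.6, 0.3), 36.5, fever_threshold - 0.1))
    kwargs = dict(
        cow_id=f"{farm_id}-{phase}-{index:03d}",
        farm_id=farm_id,
        parity=int(rng.integers(2, 6)),
        dfc=dfc,
        rectal_temp=temp,
        pregnant=True,
        bcs_class="optimal",
    )
    if phase == "dry":
        kwargs["days_from_dry_onset"] = int(
            rng.integers(DRY_ONSET_WINDOW[0], DRY_ONSET_WINDOW[1] + 1))
    if phase in ("early_lactation", "late_lactation"):
        prior = float(max(rng.normal(35.0, 5.0), 12.0))
        kwargs["milk_prior_week_mean"] = round(prior, 1)
        kwargs["milk_today"] = round(prior * rng.uniform(0.92, 1.10), 1)
    return CowRecord(**kwargs)


def generate_cohort(
    spec: Optional[GeneratorSpec] = None, seed: Optional[int] = None,
) -> tuple[list[CowRecord], list[AnalytePanel]]:
    """Draw a full multi-farm cohort at the spec's study conditions.

    Animal metadata is synthesized to pass the enrollment filter; panels are
    drawn per phase at the healthy parameterization.  Reproducible by seed
    (``seed`` overrides ``spec.seed`` when given).
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    reg = spec.registry

    cows: list[CowRecord] = []
    phase_members: dict[str, list[int]] = {p: [] for p in PHASE_ORDER}
    for farm_id in sorted(spec.layout, key=str):
        for phase in PHASE_ORDER:
            for i in range(spec.layout[farm_id].get(phase, 0)):
                phase_members[phase].append(len(cows))
                cows.append(_cow_metadata(rng, farm_id, phase, i))

    values_by_cow: list[dict[str, float]] = [{} for _ in cows]
    for aspec in reg:
        for phase in PHASE_ORDER:
            members = phase_members[phase]
            if not members:
                continue
            draws = draw_analyte(aspec.mean[phase], aspec.sd[phase],
                                 len(members), rng, aspec.log_transform)
            for idx, v in zip(members, draws):
                values_by_cow[idx][aspec.name] = float(v)

    panels = [AnalytePanel(cow_id=c.cow_id, values=v)
              for c, v in zip(cows, values_by_cow)]

    if spec.contamination:
        cows, panels, _ = inject_scd(cows, panels, spec.contamination,
                                     seed=int(rng.integers(2 ** 31)))
    return cows, panels


def simulate_analyte_groups(
    analyte: str, seed: Optional[int] = None,
    registry: Optional[AnalyteRegistry] = None,
    ns: Optional[Mapping[str, int]] = None,
) -> dict[str, np.ndarray]:
    """Per-phase samples of a single analyte at its registry parameterization.

    Group sizes default to the registry's reference-sample sizes.  Used for
    significance-reproduction simulations.
    """
    reg = registry or default_registry()
    aspec = reg[analyte]
    rng = np.random.default_rng(seed)
    out = {}
    for phase in PHASE_ORDER:
        n = int(ns[phase]) if ns else aspec.n[phase]
        out[phase] = draw_analyte(aspec.mean[phase], aspec.sd[phase], n, rng,
                                  aspec.log_transform)
    return out


def inject_scd(
    cows: Sequence[CowRecord],
    panels: Sequence[AnalytePanel],
    rates: Union[Mapping[str, float], None] = None,
    per_phase_counts: Optional[Mapping[str, int]] = None,
    seed: Optional[int] = None,
    cfg: Optional[ScreeningConfig] = None,
    registry: Optional[AnalyteRegistry] = None,
) -> tuple[list[CowRecord], list[AnalytePanel], pd.DataFrame]:
    """Inject subclinical disorders, returning the cohort plus ground truth.

    Either ``rates`` (mechanism -> per-animal probability) or
    ``per_phase_counts`` (phase -> number of animals to contaminate, mechanism
    drawn uniformly) selects the affected animals.  Hyperketonemia sets BHB
    uniformly in (bhb_max, 3.0]; hypocalcemia sets Ca uniformly in
    [1.2, ca_min); the multi-outlier pattern pushes ``max_outlier_analytes+1``
    randomly chosen other analytes beyond their phase group's upper Tukey
    fence.  Ground truth lists (cow_id, phase, mechanism).
    """
    cfg = cfg or ScreeningConfig()
    reg = registry or default_registry()
    rng = np.random.default_rng(seed)
    if rates:
        for mech, r in rates.items():
            if mech not in SCD_MECHANISMS or not (0 <= r <= 1):
                raise ValidationError(f"bad contamination entry {mech}={r}")

    panels = [AnalytePanel(p.cow_id, dict(p.values)) for p in panels]
    by_phase: dict[str, list[int]] = {p: [] for p in PHASE_ORDER}
    from .screening import assign_phase  # local import avoids a cycle

    for i, cow in enumerate(cows):
        ph = assign_phase(cow.dfc, cow.days_from_dry_onset, cow.pregnant)
        if ph is not None:
            by_phase[ph].append(i)

    targets: list[tuple[int, str, str]] = []   # (index, phase, mechanism)
    for phase, members in by_phase.items():
        if not members:
            continue
        if per_phase_counts is not None:
            k = int(per_phase_counts.get(phase, 0))
            if k > len(members) - 4:
                raise ValidationError(
                    f"{phase}: injecting {k} of {len(members)} leaves <4 clean animals")
            chosen = rng.choice(members, size=k, replace=False)
            mechs = rng.choice(SCD_MECHANISMS, size=k)
            targets += [(int(i), phase, str(m)) for i, m in zip(chosen, mechs)]
        elif rates:
            for mech in SCD_MECHANISMS:
                r = rates.get(mech, 0.0)
                if r == 0:
                    continue
                hits = [i for i in members if rng.random() < r]
                targets += [(i, phase, mech) for i in hits]
            clean = len(members) - len({i for i, p, _ in targets if p == phase})
            if clean < 4:
                raise ValidationError(f"{phase}: contamination leaves <4 clean animals")

    # Upper fences from the pre-injection phase groups.
    fence: dict[tuple[str, str], tuple[float, float]] = {}
    for phase, members in by_phase.items():
        if len(members) >= 4:
            df = pd.DataFrame([panels[i].values for i in members], dtype=float)
            for analyte in df.columns:
                col = df[analyte].dropna()
                if len(col) >= 4:
                    q1, q3 = np.quantile(col, [0.25, 0.75])
                    fence[(phase, analyte)] = (q3, q3 - q1)

    truth_rows = []
    shiftable = [a for a in reg.names if a not in ("BHB", "Ca")]
    for idx, phase, mech in targets:
        vals = panels[idx].values
        if mech == "hyperketonemia":
            vals["BHB"] = float(rng.uniform(cfg.bhb_max + 1e-6, 3.0))
        elif mech == "hypocalcemia":
            vals["Ca"] = float(rng.uniform(1.2, cfg.ca_min - 1e-6))
        else:
            picks = rng.choice(shiftable, size=cfg.max_outlier_analytes + 1,
                               replace=False)
            for analyte in picks:
                q3, iqr = fence.get((phase, analyte), (vals.get(analyte, 1.0), 0.0))
                spread = iqr if iqr > 0 else max(abs(q3), 1.0) * 0.1
                vals[analyte] = float(q3 + (cfg.iqr_multiplier + 1.5 + rng.uniform(0, 1.5))
                                      * spread)
        truth_rows.append({"cow_id": panels[idx].cow_id, "phase": phase,
                           "mechanism": mech})

    truth = pd.DataFrame(truth_rows, columns=["cow_id", "phase", "mechanism"])
    logger.info("injected %d subclinical-disorder animals", len(truth))
    return list(cows), panels, truth
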