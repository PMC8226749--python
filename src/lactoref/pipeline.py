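"""One-command end-to-end run: herd gate → screen → phase stats → reference intervals.

Stages execute in sampling order: farms failing the high-welfare gate are
dropped before any cow-level processing; animals are enrolled through the
eligibility filter, retrospectively screened for subclinical disorders, the
retained panels analyzed per analyte (normality gate, phase ANOVA, pairwise
tests, phase merging) and bootstrap reference intervals computed per merged
block.  A JSON manifest records seeds, input digests and per-stage counts so
any run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .core import (
    AnalytePanel,
    CowRecord,
    ScreeningConfig,
    default_registry,
    write_cohort,
    write_report_tables,
)
from .phase_stats import significance_code
from .phase_stats import analyze_dataset
from .reference_intervals import expand_to_phases, ri_table
from .registry import PHASE_ORDER, SCD_EXCLUDED_PER_PHASE
from .screening import apply_mask, enrollment_filter, retrospective_exclude
from .synthetic import GeneratorSpec, generate_cohort, inject_scd
from .welfare import FarmProfile, high_welfare_farms, packaged_farms, read_farms

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; unset paths mean synthetic mode."""

    out_dir: str = "lactoref_run"
    cows_csv: Optional[str] = None
    panels_csv: Optional[str] = None
    farms_csv: Optional[str] = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    # phase-stats options
    alpha: float = 0.05
    sd_pooling: str = "pair"
    adjust: str = "holm"
    # reference-interval options
    bootstrap_B: int = 5000
    coverage: float = 0.95
    # synthetic-mode options
    seed: int = 0
    inject_counts: Optional[dict[str, int]] = field(
        default_factory=lambda: dict(SCD_EXCLUDED_PER_PHASE))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "screening" in d and isinstance(d["screening"], dict):
            d["screening"] = ScreeningConfig(**d["screening"])
        return cls(**d)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, write artifacts under ``cfg.out_dir``, return the manifest.

    On failure the partial outputs written so far are preserved under
    ``<out_dir>/failed/`` and a stage-tagged :class:`StageError` is raised.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "python": platform.python_version(),
                      "seed": cfg.seed, "stages": {}}
    stage = "init"
    try:
        # ------------------------------------------------------------------
        stage = "welfare_gate"
        farms = read_farms(cfg.farms_csv) if cfg.farms_csv else packaged_farms()
        hwf = high_welfare_farms(farms)
        dropped = [f.farm_id for f in farms if f not in hwf]
        for fid in dropped:
            logger.info("farm %s fails the high-welfare gate; dropped", fid)
        manifest["stages"][stage] = {"farms": len(farms), "high_welfare": len(hwf),
                                     "dropped": dropped}

        # ------------------------------------------------------------------
        stage = "cohort"
        if cfg.cows_csv and cfg.panels_csv:
            from .core import read_cohort
            records = read_cohort(cfg.cows_csv, cfg.panels_csv)
            cows = [r for r, _ in records]
            panels = [p for _, p in records]
            manifest["stages"][stage] = {
                "mode": "load",
                "inputs": {"cows": _digest(cfg.cows_csv),
                           "panels": _digest(cfg.panels_csv)},
            }
        else:
            layout = {f.farm_id: dict(f.enrolled) for f in hwf}
            spec = GeneratorSpec(layout=layout, seed=cfg.seed)
            cows, panels = generate_cohort(spec)
            truth = pd.DataFrame(columns=["cow_id", "phase", "mechanism"])
            if cfg.inject_counts:
                cows, panels, truth = inject_scd(
                    cows, panels, per_phase_counts=cfg.inject_counts,
                    seed=cfg.seed + 1, cfg=cfg.screening)
            truth.to_csv(out_dir / "ground_truth.csv", index=False)
            manifest["stages"][stage] = {"mode": "simulate",
                                         "generated": len(cows),
                                         "injected": len(truth)}
        hwf_ids = {f.farm_id for f in hwf}
        keep = [i for i, c in enumerate(cows) if c.farm_id in hwf_ids]
        cows = [cows[i] for i in keep]
        panels = [panels[i] for i in keep]
        write_cohort(list(zip(cows, panels)),
                     out_dir / "cows.csv", out_dir / "panels.csv")

        # ------------------------------------------------------------------
        stage = "enrollment"
        outcomes = [enrollment_filter(c, cfg.screening) for c in cows]
        enrolled_idx = [i for i, o in enumerate(outcomes) if o.eligible]
        reject_reasons: dict[str, int] = {}
        for o in outcomes:
            for r in o.reasons:
                reject_reasons[r] = reject_reasons.get(r, 0) + 1
        by_phase: dict[str, list[AnalytePanel]] = {p: [] for p in PHASE_ORDER}
        phase_of: dict[str, str] = {}
        for i in enrolled_idx:
            ph = outcomes[i].phase
            by_phase[ph].append(panels[i])
            phase_of[cows[i].cow_id] = ph
        manifest["stages"][stage] = {
            "enrolled": len(enrolled_idx),
            "enrolled_per_phase": {p: len(v) for p, v in by_phase.items()},
            "rejected": len(cows) - len(enrolled_idx),
            "rejection_reasons": reject_reasons,
        }

        # ------------------------------------------------------------------
        stage = "retrospective_exclusion"
        retained, excluded, mask = retrospective_exclude(by_phase, cfg.screening)
        data = apply_mask(by_phase, retained, mask)
        data.reset_index().to_csv(out_dir / "retained.csv", index=False)
        pd.DataFrame(
            [{"cow_id": cid, "phase": phase_of[cid], "reasons": ";".join(rs)}
             for cid, rs in sorted(excluded.items())],
        ).to_csv(out_dir / "excluded.csv", index=False)
        mask.flags.rename_axis("cow_id").reset_index().to_csv(
            out_dir / "outlier_mask.csv", index=False)
        excl_reasons: dict[str, int] = {}
        for rs in excluded.values():
            for r in rs:
                excl_reasons[r] = excl_reasons.get(r, 0) + 1
        manifest["stages"][stage] = {
            "retained": len(retained),
            "retained_per_phase": data["phase"].value_counts().to_dict(),
            "excluded": len(excluded),
            "excluded_per_phase": pd.Series(
                [phase_of[c] for c in excluded]).value_counts().to_dict(),
            "exclusion_reasons": excl_reasons,
        }
        assert len(retained) + len(excluded) == len(enrolled_idx)

        # ------------------------------------------------------------------
        stage = "phase_stats"
        reg = default_registry()
        stats = analyze_dataset(data, registry=reg, alpha=cfg.alpha,
                                sd_pooling=cfg.sd_pooling, adjust=cfg.adjust)
        manifest["stages"][stage] = {
            "analytes": len(stats),
            "log_transformed": sorted(a for a, s in stats.items() if s.log_used),
        }

        # ------------------------------------------------------------------
        stage = "reference_intervals"
        partitions = {a: s.partition for a, s in stats.items()}
        intervals = ri_table(data, partitions, coverage=cfg.coverage,
                             B=cfg.bootstrap_B, seed=cfg.seed)
        expand_to_phases(intervals).to_csv(out_dir / "ri_long.csv", index=False)
        manifest["stages"][stage] = {"intervals": len(intervals),
                                     "B": cfg.bootstrap_B,
                                     "coverage": cfg.coverage}

        # ------------------------------------------------------------------
        stage = "report"
        moments = [dataclasses.asdict(m) for s in stats.values() for m in s.moments]
        anova = []
        for a, s in stats.items():
            d = dataclasses.asdict(s.anova)
            d["pairwise_p"] = dict(s.anova.pairwise_p)
            d["significance"] = {pair: significance_code(p)
                                 for pair, p in s.anova.pairwise_p.items()}
            anova.append(d)
        write_report_tables({"moments": moments, "anova": anova,
                             "ri": intervals}, out_dir)
        manifest["out_dir"] = str(out_dir)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        failed = out_dir / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(f"[{stage}] {exc}") from exc
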