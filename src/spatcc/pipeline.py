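"""Study orchestration: per-group difference-of-K and scan analyses.

A "study" iterates over disjoint groups of one dataset (typically cancer
cause x region group), runs the difference-of-K envelope test and the spatial
scan on each, and collects a summary table with one row per group: counts,
primary-cluster population, cases, expected cases, Monte Carlo p-value,
radius and center. Groups too small for analysis are skipped with a warning,
never a crash. All randomness derives from one seed, so a rerun with the
same configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dstat import CaseControlPattern, DFunctionResult, interpret, random_labeling_envelope
from .geometry import default_s_grid
from .scanstat import ScanResult, scan

__all__ = ["AnalysisConfig", "GroupResult", "StudyReport", "run_study", "plot_d_function"]


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of a full study run.

    Defaults follow the analysis conventions this package targets: D(s) up to
    8 km, scan windows up to 5 km, 9999 scan replications, alpha = 0.05,
    isotropic edge correction, 6 matched controls per case.
    """

    s_max_dstat: float = 8000.0
    max_radius_scan: float = 5000.0
    n_sim_dstat: int = 999
    n_replications_scan: int = 9999
    alpha: float = 0.05
    correction: str = "isotropic"
    envelope_rule: str = "minmax"
    stratified: bool = False
    kernel: str = "paper"
    matching_ratio: int = 6
    seed: Optional[int] = None
    group_by: tuple[str, ...] = ()

    def __post_init__(self):
        if self.s_max_dstat <= 0 or self.max_radius_scan <= 0:
            raise ValueError("distance caps must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_sim_dstat < 19 or self.n_replications_scan < 1:
            raise ValueError("replication counts too small")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["group_by"] = list(self.group_by)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "AnalysisConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        d = json.loads(text)
        if "group_by" in d:
            d["group_by"] = tuple(d["group_by"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class GroupResult:
    key: tuple
    d_result: DFunctionResult
    scan_result: ScanResult


@dataclasses.dataclass(frozen=True)
class StudyReport:
    config: AnalysisConfig
    groups: dict
    summary: pd.DataFrame
    skipped: list
    timings: dict


def _group_seeds(seed, keys: Sequence[tuple]) -> dict:
    """Two independent child seeds (dstat, scan) per group, stable in key order."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(keys))
    return {
        key: (children[2 * i], children[2 * i + 1]) for i, key in enumerate(sorted(keys))
    }


def _summary_row(key, group_cols, data: CaseControlPattern, sres: ScanResult) -> dict:
    row = dict(zip(group_cols, key))
    row["n_cases"] = data.n_cases
    row["n_controls"] = data.n_controls
    primary = sres.primary
    if primary is None:
        row.update(
            population=0, cases=0, expected_cases=float("nan"),
            p_value=float("nan"), radius_m=0, center_x=float("nan"),
            center_y=float("nan"),
        )
    else:
        row.update(
            population=primary.atrisk_inside,
            cases=primary.n_inside,
            expected_cases=round(primary.expected_cases, 2),
            p_value=round(primary.p_value, 3),
            radius_m=int(round(primary.radius)),
            center_x=primary.center[0],
            center_y=primary.center[1],
        )
    return row


def run_study(
    config: AnalysisConfig,
    dataset: Union[CaseControlPattern, Mapping[tuple, CaseControlPattern]],
    outdir: Optional[Union[str, Path]] = None,
) -> StudyReport:
    """Run both analyses on every group and assemble the report bundle.

    ``dataset`` is either one pattern or a mapping from group key to pattern
    (as produced by :func:`spatcc.io.read_dataset` with ``group_by``). When
    ``outdir`` is given, per-group D(s) CSVs, cluster CSVs, plots, the summary
    table and a JSON log (config echo, seeds, timings) are written there.
    """
    if isinstance(dataset, CaseControlPattern):
        dataset = {("all",): dataset}
    group_cols = list(config.group_by) or [f"group{i+1}" for i in range(len(next(iter(dataset))))]
    seeds = _group_seeds(config.seed, list(dataset))
    s_grid = default_s_grid(config.s_max_dstat)

    groups: dict = {}
    skipped: list = []
    rows = []
    timings: dict = {}
    for key in sorted(dataset):
        data = dataset[key]
        if data.n_cases < 2 or data.n_controls < 2:
            warnings.warn(
                f"group {key} skipped: needs >= 2 cases and >= 2 controls "
                f"(has {data.n_cases}/{data.n_controls})",
                stacklevel=2,
            )
            skipped.append(key)
            continue
        t0 = time.perf_counter()
        dseed, sseed = seeds[key]
        dres = random_labeling_envelope(
            data,
            s_grid=s_grid,
            n_sim=config.n_sim_dstat,
            rule=config.envelope_rule,
            stratified=config.stratified,
            seed=dseed,
            correction=config.correction,
        )
        sres = scan(
            data,
            max_radius=config.max_radius_scan,
            n_replications=config.n_replications_scan,
            alpha=config.alpha,
            seed=sseed,
            kernel=config.kernel,
        )
        groups[key] = GroupResult(key=key, d_result=dres, scan_result=sres)
        rows.append(_summary_row(key, group_cols, data, sres))
        timings[key] = time.perf_counter() - t0

    summary = pd.DataFrame(rows)
    report = StudyReport(
        config=config, groups=groups, summary=summary, skipped=skipped, timings=timings
    )
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _slug(key: tuple) -> str:
    return "_".join(str(k) for k in key)


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(outdir / "summary.csv", index=False)
    log = {
        "config": json.loads(report.config.to_json()),
        "skipped_groups": [list(k) for k in report.skipped],
        "timings_s": {_slug(k): round(v, 3) for k, v in report.timings.items()},
    }
    (outdir / "study_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    for key, gres in report.groups.items():
        slug = _slug(key)
        d = gres.d_result
        pd.DataFrame(
            {
                "s": d.s_grid,
                "d": d.d_values,
                "lower": d.lower_envelope,
                "upper": d.upper_envelope,
                "verdict": interpret(d),
            }
        ).to_csv(outdir / f"dstat_{slug}.csv", index=False)
        pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "center_x": c.center[0],
                    "center_y": c.center[1],
                    "radius_m": c.radius,
                    "population": c.atrisk_inside,
                    "cases": c.n_inside,
                    "expected_cases": round(c.expected_cases, 2),
                    "log_lr": c.log_lr,
                    "p_value": round(c.p_value, 3),
                }
                for i, c in enumerate(gres.scan_result.ranked)
            ]
        ).to_csv(outdir / f"clusters_{slug}.csv", index=False)
        try:
            fig = plot_d_function(d, title=slug)
            fig.savefig(outdir / f"dstat_{slug}.png", dpi=120)
            import matplotlib.pyplot as plt

            plt.close(fig)
        except Exception as exc:  # plotting must never sink a study run
            warnings.warn(f"plotting failed for group {key}: {exc}", stacklevel=2)


def plot_d_function(result: DFunctionResult, title: str = "", ax=None):
    """D(s) as a red curve with dotted Monte Carlo envelopes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.plot(result.s_grid, result.d_values, color="red", lw=1.5, label="D(s)")
    ax.plot(result.s_grid, result.upper_envelope, "k:", lw=1, label="envelope")
    ax.plot(result.s_grid, result.lower_envelope, "k:", lw=1)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("distance s (m)")
    ax.set_ylabel("D(s) (m$^2$)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig
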