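"""Writers for time-series, sweep-summary and validation outputs.

All outputs are delimited text (or JSON) with full-precision numbers,
so identical inputs produce byte-identical files (manifest timestamps
excepted). Unit annotations appear in each file's header.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Iterable

from . import __version__
from .config import BedModelConfig, config_digest
from .engine import RunResult
from .scenarios import RunSummary

__all__ = [
    "write_timeseries",
    "write_summaries",
    "write_manifest",
    "write_json",
]

_TS_HEADER = "# time [calendar year]; value [units of each variable per the model definition]\n"

SUMMARY_COLUMNS = (
    "scenario",
    "policy",
    "end_beds [beds]",
    "end_home_care [service-days/yr]",
    "first_shortage_time [years from start]",
    "peak_shortage [bed-days/yr]",
    "bed_addition [beds/yr]",
    "home_care_addition [service-days/yr/yr]",
    "error",
)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_timeseries(run: RunResult, path: str | Path) -> None:
    """Tidy delimited text: columns time, variable, value."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_TS_HEADER)
        fh.write("time,variable,value\n")
        for name in sorted(run.values):
            vals = run.values[name]
            for t, v in zip(run.times, vals):
                fh.write(f"{t!r},{name},{v!r}\n")


def write_summaries(summaries: Iterable[RunSummary], path: str | Path) -> None:
    """The end-state summary table, one row per scenario × policy cell."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            row = (
                s.scenario_id,
                s.policy_id,
                _fmt(s.end_beds),
                _fmt(s.end_home_care),
                _fmt(s.first_shortage_time),
                _fmt(s.peak_shortage),
                _fmt(s.bed_addition),
                _fmt(s.home_care_addition),
                _fmt(s.error),
            )
            fh.write(",".join(row) + "\n")


def write_manifest(
    config: BedModelConfig,
    path: str | Path,
    *,
    scenario_id: str | None = None,
    policy_id: str | None = None,
) -> None:
    manifest = {
        "config_digest": config_digest(config),
        "scenario_id": scenario_id or config.scenario.id,
        "policy_id": policy_id or config.policy.id,
        "settings": dataclasses.asdict(config.simulation),
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    write_json(manifest, path)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
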