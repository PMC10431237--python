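"""Run summaries: a tidy machine-readable results table plus a
human-readable report.

Each pipeline stage contributes rows to one tidy table
(stage, measure, group_a, group_b, n_a, n_b, statistic, p,
adjusted_alpha, value) and optional figure callables.  Reports carry a
provenance header (seed, config hash, package version) and contain no
timestamps, so re-running with the same seed reproduces them byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version

__all__ = ["ResultsTable", "render_report", "config_hash"]

_COLUMNS = ["stage", "measure", "group_a", "group_b", "n_a", "n_b",
            "statistic", "p", "adjusted_alpha", "value"]


def config_hash(config: Dict) -> str:
    """Stable short hash of a (JSON-serialisable) configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class ResultsTable:
    """Accumulates tidy result rows across pipeline stages."""

    def __init__(self):
        self._rows: List[dict] = []

    def add(self, stage: str, measure: str, value: float = np.nan,
            group_a: str = "", group_b: str = "", n_a: int = 0, n_b: int = 0,
            statistic: float = np.nan, p: float = np.nan,
            adjusted_alpha: float = np.nan) -> None:
        self._rows.append(dict(stage=stage, measure=measure, group_a=group_a,
                               group_b=group_b, n_a=n_a, n_b=n_b,
                               statistic=statistic, p=p,
                               adjusted_alpha=adjusted_alpha, value=value))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=_COLUMNS)

    def __len__(self):
        return len(self._rows)


def render_report(table: ResultsTable, out_dir, seed: Optional[int] = None,
                  config: Optional[Dict] = None) -> Path:
    """Write results.tsv, provenance.json and report.md into ``out_dir``.

    Returns the path of the markdown report.  An empty table yields an
    empty report with the provenance header only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = table.frame()
    chash = config_hash(config or {})
    df.to_csv(out / "results.tsv", sep="\t", index=False,
              float_format="%.10g")
    provenance = {"package_version": _pkg_version, "seed": seed,
                  "config_hash": chash, "config": config or {}}
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n")

    lines = ["# retinophys run report", "",
             f"- package version: {_pkg_version}",
             f"- master seed: {seed}",
             f"- config hash: {chash}", ""]
    if len(df):
        for stage, sub in df.groupby("stage", sort=False):
            lines.append(f"## {stage}")
            lines.append("")
            lines.append("```")
            lines.append(sub.drop(columns="stage")
                            .to_string(index=False, float_format="%.4g"))
            lines.append("```")
            lines.append("")
    else:
        lines.append("(no completed stages)")
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
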