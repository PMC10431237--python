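"""Flat-file formats shared across the pipeline.

Every artefact (current traces, voltage-clamp families, spike rasters,
depth profiles, result tables) is stored as a plain-text table: ``#``
header lines carrying ``key = value`` metadata (including an embedded
stimulus block as ``stimulus.<field>`` keys), followed by tab-separated
columns.  The formats are deliberately trivial so that any stage of the
pipeline can be run on files produced by another run or another tool.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

from .stimulus import StimulusSpec

__all__ = ["write_table", "read_table", "meta_from_stimulus",
           "stimulus_from_meta", "write_json", "read_json"]


def _format_value(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    return str(v)


def _parse_value(s: str):
    s = s.strip()
    if s in ("true", "false"):
        return s == "true"
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def write_table(path, df: pd.DataFrame, meta: Optional[Dict] = None) -> None:
    """Write a metadata-headed TSV table."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {_format_value(v)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> Tuple[pd.DataFrame, Dict]:
    """Read a metadata-headed TSV table; returns (dataframe, metadata)."""
    path = Path(path)
    meta: Dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = _parse_value(v)
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, meta


def meta_from_stimulus(stimulus: Optional[StimulusSpec]) -> Dict:
    """Flatten a stimulus into ``stimulus.<field>`` metadata keys."""
    if stimulus is None:
        return {}
    return {f"stimulus.{k}": v for k, v in stimulus.to_dict().items()}


def stimulus_from_meta(meta: Dict) -> Optional[StimulusSpec]:
    d = {k.split(".", 1)[1]: v for k, v in meta.items()
         if k.startswith("stimulus.")}
    return StimulusSpec.from_dict(d) if d else None


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
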