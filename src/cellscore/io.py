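"""Reading and writing cytometry event data and cohort manifests.

Event tables are TSV/CSV with a header of channel names and one row per
cell.  Cohort manifests are JSON or YAML listing per-sample file path, label,
burden and optional split assignment, plus the panel definition.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from ._fcs import FCSFormatError, read_fcs_file, write_fcs_file
from .cohort import Cohort, EventMatrix, SampleRecord
from .panel import MarkerPanel

__all__ = [
    "read_fcs",
    "write_fcs",
    "read_table",
    "write_table",
    "read_manifest",
    "write_manifest",
    "FCSFormatError",
]


def read_fcs(path, panel: Optional[MarkerPanel] = None, sample_id: Optional[str] = None) -> EventMatrix:
    """Read an FCS 3.0/3.1 file into an event matrix.

    When a panel is given, channels are matched case-insensitively by stain
    name ($PnS) with short-name ($PnN) fallback and reordered to panel order;
    a panel channel absent from the file raises a channel-mismatch KeyError.
    """
    path = Path(path)
    events, names, _ = read_fcs_file(path)
    if panel is not None:
        lookup: Dict[str, int] = {}
        for idx, n in enumerate(names):
            lookup.setdefault(n.upper(), idx)
        cols = []
        for want in panel.names:
            idx = lookup.get(want.upper())
            if idx is None:
                raise KeyError(
                    f"channel {want!r} not found in {path.name} (file channels: {names})"
                )
            cols.append(idx)
        events = events[:, cols]
    return EventMatrix(sample_id or path.stem, events)


def write_fcs(path, events: EventMatrix, panel: MarkerPanel) -> None:
    """Write a minimal float32 FCS 3.0 file (fixtures / round-trip tests)."""
    write_fcs_file(path, events.values, panel.names)


def read_table(path, delimiter: str = "\t", sample_id: Optional[str] = None) -> EventMatrix:
    """Read a delimited event table (header = channel names, one row per cell)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: no events (empty file)") from e
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: parse error: {e}") from e
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no events")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for c in non_numeric:
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else 0
            raise ValueError(f"{path}: non-numeric value in column {c!r} at data row {row}")
    return EventMatrix(sample_id or path.stem, df.to_numpy(dtype=float))


def write_table(path, events: EventMatrix, panel: MarkerPanel, delimiter: str = "\t") -> None:
    """Write an event matrix as a delimited table with channel-name header."""
    df = pd.DataFrame(events.values, columns=panel.names)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6g")


def write_manifest(path, cohort: Cohort, sample_paths: Dict[str, str]) -> None:
    """Write a cohort manifest (JSON or YAML by extension)."""
    entries = []
    for s in cohort.samples:
        entries.append(
            {
                "sample_id": s.sample_id,
                "path": sample_paths[s.sample_id],
                "label": s.label,
                "burden": s.burden,
                "split": cohort.split_assignment.get(s.sample_id),
            }
        )
    doc = {"panel": cohort.panel.to_dict(), "samples": entries}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def read_manifest(path, delimiter: str = "\t") -> Cohort:
    """Load a cohort from a manifest; sample paths resolve relative to it."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
    else:
        doc = json.loads(path.read_text())
    panel = MarkerPanel.from_dict(doc["panel"])
    samples = []
    split: Dict[str, object] = {}
    for entry in doc["samples"]:
        spath = Path(entry["path"])
        if not spath.is_absolute():
            spath = path.parent / spath
        if spath.suffix.lower() == ".fcs":
            events = read_fcs(spath, panel=panel, sample_id=entry["sample_id"])
        else:
            events = read_table(spath, delimiter=delimiter, sample_id=entry["sample_id"])
        samples.append(
            SampleRecord(
                events=events,
                label=entry.get("label"),
                burden=entry.get("burden"),
            )
        )
        if entry.get("split") is not None:
            split[entry["sample_id"]] = entry["split"]
    return Cohort(panel=panel, samples=samples, split_assignment=split)
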