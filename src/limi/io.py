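"""CSV / config reading and writing, and structured run logs.

Datasets are RFC-4180 CSV with a header row; missing values are an empty
field or the token "NA" on input, and are always written as "NA".
Variable specifications are YAML or JSON lists of mappings with keys
name, kind, n_levels, count_treatment, reference_level.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scenarios import SummaryTable
from .variables import VariableSpec

_NA_TOKENS = ["", "NA"]


def read_variable_specs(path: str | Path) -> list[VariableSpec]:
    """Load variable declarations from a YAML or JSON config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a list of variable mappings")
    specs = []
    for entry in raw:
        if not isinstance(entry, dict) or "name" not in entry or "kind" not in entry:
            raise ValueError(f"{path}: each entry needs 'name' and 'kind': {entry!r}")
        allowed = {"name", "kind", "n_levels", "count_treatment", "reference_level"}
        unknown = set(entry) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)} in {entry['name']!r}")
        specs.append(VariableSpec(**entry))
    return specs


def read_dataset(path: str | Path, specs: list[VariableSpec]) -> pd.DataFrame:
    """Read a CSV dataset and validate it against the variable specs.

    Empty fields and "NA" become missing; categorical codes, binary values
    and counts are validated with row/column diagnostics.
    """
    df = pd.read_csv(path, na_values=_NA_TOKENS, keep_default_na=False)
    missing_cols = [s.name for s in specs if s.name not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for s in specs:
        col = pd.to_numeric(df[s.name], errors="coerce")
        bad_parse = col.isna() & df[s.name].notna()
        if bad_parse.any():
            row = int(np.flatnonzero(bad_parse)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[s.name].iloc[row]!r} in column "
                f"{s.name!r}, row {row}"
            )
        obs = col.dropna()
        if s.kind == "binary":
            bad = ~obs.isin([0.0, 1.0])
        elif s.kind == "categorical":
            bad = (obs != np.round(obs)) | (obs < 1) | (obs > s.n_levels)
        elif s.kind == "count":
            bad = (obs != np.round(obs)) | (obs < 0)
        else:
            bad = pd.Series(False, index=obs.index)
        if bad.any():
            row = int(bad[bad].index[0])
            raise ValueError(
                f"{path}: invalid {s.kind} value {obs[row]!r} in column "
                f"{s.name!r}, row {row}"
            )
        df[s.name] = col.astype(float)
    return df[[s.name for s in specs]]


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset as CSV with "NA" for missing cells."""
    df.to_csv(path, index=False, na_rep="NA")


def write_summary(table: SummaryTable, path: str | Path) -> None:
    """Write a SummaryTable as CSV with a deterministic row order."""
    frame = table.frame
    order = {m: i for i, m in enumerate(frame["method"].unique())}
    frame = frame.sort_values(
        ["scenario", "method", "parameter"],
        key=lambda s: s.map(order) if s.name == "method" else s,
        kind="stable",
    )
    frame.to_csv(path, index=False, na_rep="NA")


@dataclass
class RunLog:
    """Structured record of one CLI run."""

    command: str
    seed: int | None
    settings: dict = field(default_factory=dict)
    mh_acceptance: dict = field(default_factory=dict)
    rejection_cap_hits: int = 0
    excluded_replications: int = 0
    wall_clock_s: float = 0.0
    version: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
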