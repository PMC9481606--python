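"""PLUMED-COLVAR-dialect time series tables.

The interchange format between all stages is a whitespace table whose first
line is ``#! FIELDS time <name> ...``.  Floats are written in scientific
notation with 9 significant digits so that write -> read round-trips at full
printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ColvarSeries", "read_colvar", "write_colvar"]


@dataclass
class ColvarSeries:
    """Time-stamped named series (CVs, bias, positions).

    ``data`` is a DataFrame whose first column is ``time`` (strictly
    increasing); ``metadata`` carries units/seed provenance as plain strings.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if "time" not in self.data.columns:
            raise ValueError("ColvarSeries requires a 'time' column")
        t = self.data["time"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def columns(self) -> list[str]:
        return [c for c in self.data.columns]

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def __contains__(self, name: str) -> bool:
        return name in self.data.columns

    @classmethod
    def from_columns(cls, time, metadata: dict | None = None, **columns) -> "ColvarSeries":
        frame = pd.DataFrame({"time": np.asarray(time, dtype=float)})
        for name, values in columns.items():
            frame[name] = np.asarray(values, dtype=float)
        return cls(frame, metadata or {})

    def write(self, path) -> None:
        write_colvar(self, path)


def write_colvar(series: ColvarSeries, path) -> None:
    """Write a series in the COLVAR dialect (9 significant digits)."""
    cols = series.columns
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for key, value in series.metadata.items():
            fh.write(f"#! SET {key} {value}\n")
        np.savetxt(fh, series.data.to_numpy(), fmt="%.8e")


def read_colvar(path) -> ColvarSeries:
    """Read a COLVAR-dialect table.

    Tolerates comment lines and interleaved ``#! FIELDS`` restart headers
    (segments are concatenated; the time column must stay strictly
    increasing across the joint).  Ragged rows raise with the line number.
    """
    fields: list[str] | None = None
    metadata: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                tokens = line.split()
                if len(tokens) >= 2 and tokens[1] == "FIELDS":
                    new_fields = tokens[2:]
                    if fields is None:
                        fields = new_fields
                    elif new_fields != fields:
                        raise ValueError(
                            f"{path}: line {lineno}: restart header fields "
                            f"{new_fields} differ from {fields}")
                elif len(tokens) >= 4 and tokens[1] == "SET":
                    metadata[tokens[2]] = " ".join(tokens[3:])
                continue
            if line.startswith("#"):
                continue
            if fields is None:
                raise ValueError(f"{path}: data before '#! FIELDS' header")
            values = line.split()
            if len(values) != len(fields):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(fields)} columns, "
                    f"got {len(values)}")
            rows.append([float(v) for v in values])
    if fields is None:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    if not rows:
        raise ValueError(f"{path}: empty data section")
    frame = pd.DataFrame(np.asarray(rows, dtype=float), columns=fields)
    return ColvarSeries(frame, metadata)
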