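"""Event-table file I/O and run configuration.

The CSV dialect is deliberately minimal: a header ``time_min,value_au``
and one row per cell per measurement time.  FCS 3.0/3.1 reading (one file
per time point) is available when the optional ``fcsparser`` dependency is
installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import EventTable, InputError

CSV_COLUMNS = ("time_min", "value_au")


class FormatError(ValueError):
    pass


def write_event_table(data: EventTable, path) -> None:
    frames = [
        pd.DataFrame({"time_min": t, "value_au": v})
        for t, v in zip(data.times, data.values)
    ]
    # %.17g keeps the write->read cycle bit-lossless for float64 values
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_event_table_csv(path) -> EventTable:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(df.columns) != list(CSV_COLUMNS):
        raise FormatError(
            f"{path}: expected header {','.join(CSV_COLUMNS)!r}, got {','.join(map(str, df.columns))!r}"
        )
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = df.index[numeric.isna().any(axis=1) | ~np.isfinite(numeric).all(axis=1)]
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(f"{path}: malformed row at line {int(bad[0]) + 2}")
    df = numeric
    times = np.sort(df["time_min"].unique()).astype(float)
    values = tuple(
        df.loc[df["time_min"] == t, "value_au"].to_numpy(dtype=float) for t in times
    )
    return EventTable(times=times, values=values)


def read_event_table_fcs(paths, times, channel: str) -> EventTable:
    """One FCS 3.0/3.1 file per time point, a named fluorescence channel."""
    try:
        import fcsparser
    except ImportError as exc:
        raise ImportError(
            "FCS reading requires the optional dependency 'fcsparser'; "
            "install it with: pip install modefit[fcs]"
        ) from exc
    values = []
    for p in paths:
        _, events = fcsparser.parse(str(p))
        if channel not in events.columns:
            raise FormatError(
                f"{p}: channel {channel!r} not found; available: {list(events.columns)}"
            )
        values.append(events[channel].to_numpy(dtype=float))
    return EventTable(times=np.asarray(times, dtype=float), values=tuple(values))


def read_event_table(path, format: str = "csv", channel: str | None = None, times=None) -> EventTable:
    """Dispatch on format (``csv`` or ``fcs``)."""
    if format == "csv":
        return read_event_table_csv(path)
    if format == "fcs":
        paths = [path] if isinstance(path, (str, Path)) else list(path)
        if channel is None:
            raise FormatError("FCS reading needs a channel name")
        if times is None:
            times = list(range(len(paths)))
        return read_event_table_fcs(paths, times, channel)
    raise FormatError(f"unknown format {format!r}")


@dataclass
class RunConfig:
    """Validated configuration of one fitting run.

    A snapshot of this object is embedded in every result JSON so a run
    can be re-validated from its own output.
    """

    model: str = "irf7"
    method: str = "rs"  # "rs" | "ga"
    ns: int = 1000
    beta_low: float = 0.95
    beta_up: float = 1.05
    penalty: float = 1e12
    phi: float = 1.0
    seed: int = 0
    n_iter: int = 1000  # random search
    ga: dict = field(default_factory=dict)  # GAConfig overrides
    bounds: dict = field(default_factory=dict)  # ParameterSpace overrides
    fixed: dict = field(default_factory=dict)
    modes: list | None = None  # override mode detection

    def validate(self) -> "RunConfig":
        if self.model not in ("constitutive", "irf7"):
            raise FormatError(f"unknown model {self.model!r}")
        if self.method not in ("rs", "ga"):
            raise FormatError(f"unknown method {self.method!r}")
        if self.ns < 1 or self.n_iter < 1:
            raise FormatError("ns and n_iter must be >= 1")
        if not (0 <= self.beta_low <= 1 <= self.beta_up):
            raise FormatError("require 0 <= beta_low <= 1 <= beta_up")
        if self.phi <= 0:
            raise FormatError("phi must be positive")
        if self.penalty <= 0:
            raise FormatError("penalty must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc).validate()

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
        }
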