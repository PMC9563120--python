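"""Plain-text force-trace files and summary tables.

The trace format stands in for a chart-recorder export: ``#``-prefixed
``key=value`` header lines followed by a two-column body (``time_s``,
``force_mN``), tab- or comma-delimited.  Numbers are written at repr-level
precision so a write/read round trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ForceTrace

__all__ = ["read_trace", "write_trace", "write_summary"]

_KNOWN_HEADER = {"sample_id", "group", "sampling_rate_hz", "seed"}


class TraceFormatError(ValueError):
    """Raised when a trace file violates the expected dialect."""


def write_trace(trace: ForceTrace, path: str | Path, delimiter: str = "\t") -> None:
    """Write a trace; deterministic byte output for a given trace."""
    if delimiter not in ("\t", ","):
        raise ValueError("delimiter must be tab or comma")
    lines = [
        f"# sample_id={trace.sample_id}",
        f"# group={trace.group}",
        f"# sampling_rate_hz={trace.sampling_rate!r}",
    ]
    for key in sorted(trace.metadata):
        lines.append(f"# {key}={trace.metadata[key]!r}")
    lines.append(delimiter.join(("time_s", "force_mN")))
    for t, f in zip(trace.time.tolist(), trace.force.tolist()):
        lines.append(f"{t!r}{delimiter}{f!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header_value(raw: str):
    raw = raw.strip()
    if raw.startswith("'") and raw.endswith("'") and len(raw) >= 2:
        return raw[1:-1]
    for caster in (int, float):
        try:
            return caster(raw)
        except ValueError:
            continue
    return raw


def read_trace(path: str | Path) -> ForceTrace:
    """Read a trace file; the delimiter is auto-detected (tab or comma).

    A missing ``sampling_rate_hz`` header is inferred from the median time
    step of the body.
    """
    path = Path(path)
    header: dict = {}
    body_lines: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            if key:
                header[key.strip()] = _parse_header_value(val)
        else:
            body_lines.append(line)

    if not body_lines:
        raise TraceFormatError(f"{path}: no data rows")
    delimiter = "\t" if "\t" in body_lines[0] else ","
    start = 1 if body_lines[0].split(delimiter)[0].strip() == "time_s" else 0
    if len(body_lines) <= start:
        raise TraceFormatError(f"{path}: header only, no data rows")

    try:
        data = np.array(
            [[float(x) for x in line.split(delimiter)[:2]]
             for line in body_lines[start:]]
        )
    except (ValueError, IndexError) as exc:
        raise TraceFormatError(f"{path}: unparseable body: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 2:
        raise TraceFormatError(f"{path}: body must have two columns")

    time, force = data[:, 0], data[:, 1]
    if time.size > 1 and np.any(np.diff(time) <= 0):
        raise TraceFormatError(f"{path}: time column must be strictly increasing")

    sampling_rate = header.get("sampling_rate_hz")
    if sampling_rate is None:
        if time.size < 2:
            raise TraceFormatError(f"{path}: cannot infer sampling rate from one row")
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    metadata = {k: v for k, v in header.items() if k not in ("sample_id", "group",
                                                            "sampling_rate_hz")}
    return ForceTrace(
        time=time,
        force=force,
        sampling_rate=float(sampling_rate),
        group=str(header.get("group", "experimental")),
        sample_id=str(header.get("sample_id", path.stem)),
        metadata=metadata,
    )


def write_summary(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write the per-sample summary table as CSV (stable column order)."""
    summaries.to_csv(path, index=False)
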