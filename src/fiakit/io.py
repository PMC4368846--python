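"""Trace-file and configuration I/O.

Trace files are plain delimited text (comma or tab, autodetected) with
'#'-prefixed ``key = value`` header lines and three columns:
``time_ms, F_rel, light_state``.  Output is deterministic: fixed column
order, fixed float format, header first.

Configuration files are flat YAML mappings holding protocol segments,
model parameters, noise and seed; reports are flat ``key = value`` text at
4 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml

from .params import PhotochemParams, ThermalParams
from .trace import FluorTrace, NoiseSpec, PulseProtocol, PulseSegment

__all__ = [
    "read_trace",
    "write_trace",
    "read_config",
    "write_report",
    "protocol_from_config",
    "params_from_config",
]

_COLUMNS = ("time_ms", "F_rel", "light_state")
_FLOAT_FMT = "{:.12g}"  # round-trip identical to 12 significant digits


class TraceParseError(ValueError):
    """A trace file failed validation; the message names the offending line."""


def write_trace(trace: FluorTrace, path) -> None:
    """Write a trace as deterministic delimited text (tab-separated)."""
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    lines = []
    for key in sorted(trace.meta):
        lines.append(f"# {key} = {trace.meta[key]}")
    if trace.protocol is not None:
        proto = ";".join(f"{d:g},{i:g},{on}" for d, i, on in trace.protocol)
        lines.append(f"# protocol = {proto}")
    lines.append("\t".join(_COLUMNS))
    for t, f, s in zip(trace.time, trace.f_rel, trace.light_state):
        lines.append(f"{_FLOAT_FMT.format(t)}\t{_FLOAT_FMT.format(f)}\t{int(s)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_protocol_meta(text: str):
    out = []
    for part in text.split(";"):
        d, i, on = part.split(",")
        out.append((float(d), float(i), int(on)))
    return out


def read_trace(path) -> FluorTrace:
    """Read and validate a trace file written by :func:`write_trace`.

    Delimiter (comma or tab) is autodetected from the column-header line.
    Parse and validation errors carry 1-based line numbers.  No silent
    rescaling is performed: F_rel values are returned exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    meta: dict = {}
    protocol = None
    rows = []
    header_cols = None
    delim = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key in meta:
                        raise TraceParseError(f"line {lineno}: duplicate header key {key!r}")
                    if key == "protocol":
                        protocol = _parse_protocol_meta(val)
                    else:
                        meta[key] = val
                continue
            if header_cols is None:
                delim = "\t" if "\t" in line else ","
                header_cols = tuple(c.strip() for c in line.split(delim))
                if header_cols != _COLUMNS:
                    raise TraceParseError(
                        f"line {lineno}: expected columns {_COLUMNS}, got {header_cols}"
                    )
                continue
            parts = line.split(delim)
            if len(parts) != 3:
                raise TraceParseError(
                    f"line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1]), int(float(parts[2])), lineno))
            except ValueError as exc:
                raise TraceParseError(f"line {lineno}: {exc}") from None
    if header_cols is None or not rows:
        raise TraceParseError(f"{path}: no data rows found")

    time = np.array([r[0] for r in rows])
    f_rel = np.array([r[1] for r in rows])
    light = np.array([r[2] for r in rows])
    linenos = [r[3] for r in rows]
    bad = np.flatnonzero(np.diff(time) <= 0)
    if len(bad):
        raise TraceParseError(
            f"line {linenos[bad[0] + 1]}: time_ms not strictly increasing"
        )
    bad = np.flatnonzero(f_rel <= 0)
    if len(bad):
        raise TraceParseError(f"line {linenos[bad[0]]}: F_rel must be > 0")
    return FluorTrace(time, f_rel, light, protocol=protocol, meta=meta)


# ---------------------------------------------------------------------------
# configuration and reports
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Load a flat YAML configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def protocol_from_config(cfg: dict) -> PulseProtocol:
    """Build a protocol from ``segments: [[duration, intensity, on], ...]``
    and ``resolution`` config keys."""
    segs = [PulseSegment(float(d), float(i), bool(on)) for d, i, on in cfg["segments"]]
    return PulseProtocol(tuple(segs), resolution=float(cfg.get("resolution", 0.01)))


def params_from_config(cfg: dict) -> tuple[PhotochemParams, ThermalParams, NoiseSpec]:
    """Extract model-parameter, thermal-parameter and noise records."""
    p = PhotochemParams.from_dict(cfg)
    th = ThermalParams.from_dict(cfg) if "kqbf" in cfg else ThermalParams(0.0, 0.0)
    noise = NoiseSpec(sd_rel=float(cfg.get("noise_sd_rel", 0.0)),
                      seed=int(cfg.get("seed", 0)))
    return p, th, noise


def write_report(d: dict, path=None) -> str:
    """Render a flat key-value report (floats at 4 significant digits)."""
    buf = _io.StringIO()
    for key, val in d.items():
        if isinstance(val, float):
            buf.write(f"{key} = {val:.4g}\n")
        else:
            buf.write(f"{key} = {val}\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
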