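"""Readers and writers for the package's plain-text curve, event and result formats.

Curve table format (UTF-8 text, records separated by blank lines)::

    #curve_id=wt-0001
    #kind=fd
    #spring_constant_pN_per_nm=70.0
    #velocity_um_per_s=3.1
    #contact_time_ms=2
    #sample_label=wt
    separation_nm<TAB>force_pN<TAB>segment
    0.000<TAB>1.23<TAB>retract
    ...

Height-clamp records use ``#kind=ft`` with columns ``time_s force_pN`` and
an optional ``#clamp_height_nm`` header. Event tables are TAB-separated with
a header row. Fit reports are JSON documents whose body is deterministic
for a fixed input (no timestamps), carrying provenance (seed, input hash,
package version).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    BellEvansFit,
    BellParams,
    BondscapeError,
    ClampEvent,
    ClampTrace,
    ForceCurve,
    RuptureEvent,
)

__version__ = "0.1.0"


class FormatError(BondscapeError):
    """Raised for a malformed curve/event table (carries file context)."""


_FD_HEADER_KEYS = {
    "curve_id",
    "kind",
    "spring_constant_pN_per_nm",
    "velocity_um_per_s",
    "contact_time_ms",
    "sample_label",
}
_FT_HEADER_KEYS = {"curve_id", "kind"}


def write_curve_table(records: Iterable[ForceCurve | ClampTrace], path) -> None:
    """Write force curves and/or clamp traces to one curve-table file."""
    blocks = []
    for rec in records:
        lines = []
        if isinstance(rec, ForceCurve):
            lines.append(f"#curve_id={rec.curve_id}")
            lines.append("#kind=fd")
            lines.append(f"#spring_constant_pN_per_nm={float(rec.spring_constant)!r}")
            lines.append(f"#velocity_um_per_s={float(rec.pulling_velocity)!r}")
            lines.append(f"#contact_time_ms={float(rec.contact_time)!r}")
            lines.append(f"#sample_label={rec.sample_label}")
            lines.append("separation_nm\tforce_pN\tsegment")
            for s, f in zip(rec.separation.tolist(), rec.force.tolist()):
                lines.append(f"{s!r}\t{f!r}\t{rec.segment}")
        elif isinstance(rec, ClampTrace):
            lines.append(f"#curve_id={rec.trace_id}")
            lines.append("#kind=ft")
            lines.append(f"#clamp_height_nm={float(rec.clamp_height)!r}")
            lines.append("time_s\tforce_pN")
            for t, f in zip(rec.time.tolist(), rec.force.tolist()):
                lines.append(f"{t!r}\t{f!r}")
        else:  # pragma: no cover - caller error
            raise TypeError(f"unsupported record type {type(rec)!r}")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


def _parse_block(header: dict, rows: list[tuple[int, str]], path) -> ForceCurve | ClampTrace:
    kind = header.get("kind")
    if kind is None:
        raise FormatError(f"{path}: record is missing mandatory header key 'kind'")
    if kind == "fd":
        missing = _FD_HEADER_KEYS - set(header)
        if missing:
            raise FormatError(
                f"{path}: fd record {header.get('curve_id', '?')} missing header "
                f"key(s): {', '.join(sorted(missing))}"
            )
        sep, force, segments = [], [], []
        for lineno, row in rows:
            parts = row.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                sep.append(float(parts[0]))
                force.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell: {exc}") from exc
            segments.append(parts[2])
        if len(set(segments)) > 1:
            raise FormatError(f"{path}: mixed segments in one record")
        return ForceCurve(
            separation=np.array(sep),
            force=np.array(force),
            segment=segments[0],
            spring_constant=float(header["spring_constant_pN_per_nm"]),
            pulling_velocity=float(header["velocity_um_per_s"]),
            contact_time=float(header["contact_time_ms"]),
            sample_label=header["sample_label"],
            curve_id=header["curve_id"],
        )
    if kind == "ft":
        missing = _FT_HEADER_KEYS - set(header)
        if missing:
            raise FormatError(
                f"{path}: ft record missing header key(s): {', '.join(sorted(missing))}"
            )
        time, force = [], []
        for lineno, row in rows:
            parts = row.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                time.append(float(parts[0]))
                force.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell: {exc}") from exc
        return ClampTrace(
            time=np.array(time),
            force=np.array(force),
            clamp_height=float(header.get("clamp_height_nm", "nan")),
            trace_id=header["curve_id"],
        )
    raise FormatError(f"{path}: unknown record kind {kind!r} (expected fd|ft)")


def read_curve_table(path) -> list[ForceCurve | ClampTrace]:
    """Read a curve-table file into ForceCurve / ClampTrace records."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records: list[ForceCurve | ClampTrace] = []
    header: dict = {}
    rows: list[tuple[int, str]] = []
    saw_column_header = False

    def flush():
        nonlocal header, rows, saw_column_header
        if header or rows:
            if not rows:
                raise FormatError(f"{path}: record {header.get('curve_id', '?')} has no data rows")
            records.append(_parse_block(header, rows, path))
        header, rows, saw_column_header = {}, [], False

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, value = line[1:].partition("=")
            header[key.strip()] = value.strip()
        elif not saw_column_header and not line[0].isdigit() and not line[0] == "-":
            saw_column_header = True  # column-name row; names are fixed by kind
        else:
            rows.append((lineno, line))
    flush()
    if not records:
        raise FormatError(f"{path}: file contains no records")
    return records


# -- event tables ------------------------------------------------------------

def write_rupture_events(events: Sequence[RuptureEvent], path) -> None:
    df = pd.DataFrame(
        {
            "curve_id": [e.curve_id for e in events],
            "rupture_distance_nm": [e.rupture_distance for e in events],
            "rupture_force_pN": [e.rupture_force for e in events],
            "loading_rate_pN_per_s": [e.loading_rate for e in events],
            "specific": [e.specific for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_rupture_events(path) -> list[RuptureEvent]:
    df = pd.read_csv(path, sep="\t")
    required = {"curve_id", "rupture_distance_nm", "rupture_force_pN"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            RuptureEvent(
                rupture_distance=float(row.rupture_distance_nm),
                rupture_force=float(row.rupture_force_pN),
                loading_rate=float(getattr(row, "loading_rate_pN_per_s", math.nan)),
                specific=bool(getattr(row, "specific", False)),
                curve_id=str(row.curve_id),
            )
        )
    return events


def write_clamp_events(events: Sequence[ClampEvent], path) -> None:
    df = pd.DataFrame(
        {
            "trace_id": [e.trace_id for e in events],
            "lifetime_s": [e.lifetime for e in events],
            "force_step_pN": [e.force_step for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_clamp_events(path) -> list[ClampEvent]:
    df = pd.read_csv(path, sep="\t")
    required = {"trace_id", "lifetime_s", "force_step_pN"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    return [
        ClampEvent(
            lifetime=float(r.lifetime_s),
            force_step=float(r.force_step_pN),
            trace_id=str(r.trace_id),
        )
        for r in df.itertuples(index=False)
    ]


# -- fit reports -------------------------------------------------------------

_UNITS = {
    "t0": "s",
    "t0_ci": "s",
    "x_beta": "nm",
    "x_beta_ci": "nm",
    "k0": "1/s",
    "k0_ci": "1/s",
    "delta_g": "kBT",
    "delta_g_err": "kBT",
    "tau_d": "s",
}


def hash_file(path) -> str:
    """SHA-256 of a file, for report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results(
    fit: BellParams | BellEvansFit,
    path,
    *,
    seed: int | None = None,
    input_hash: str | None = None,
) -> None:
    """Write a fit as a deterministic JSON report with units and provenance."""
    fields = {k: (None if isinstance(v, float) and math.isnan(v) else v)
              for k, v in asdict(fit).items()}
    doc = {
        "model": "bell" if isinstance(fit, BellParams) else "bell_evans",
        "parameters": fields,
        "units": {k: _UNITS[k] for k in fields},
        "provenance": {
            "package": "bondscape",
            "version": __version__,
            "seed": seed,
            "input_hash": input_hash,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_results(path) -> BellParams | BellEvansFit:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    params = {k: (math.nan if v is None else v) for k, v in doc["parameters"].items()}
    if doc["model"] == "bell":
        return BellParams(**params)
    if doc["model"] == "bell_evans":
        return BellEvansFit(**params)
    raise FormatError(f"{path}: unknown model {doc['model']!r}")
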