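"""On-disk formats: TRAST-curve CSV/JSON dialects and raw-recording JSON.

Curve CSV dialect (one file per curve)::

    # i_exc_kw_cm2: 10.3
    # label: Tyr
    pulse_width_s,f_norm,sem
    1e-07,0.9992,0.0031
    ...

Header lines are ``# key: value`` with YAML-scalar values; unknown keys
are preserved round-trip. The JSON mirror carries the same keys under
``{"meta": ..., "pulse_width_s": [...], "f_norm": [...], "sem": [...]}``.

Raw recordings serialize to a JSON schema with per-point counts, flags and
acquisition indices. Importers for external raw formats register in
:data:`RAW_IMPORTERS` keyed by dialect name; the published deposit's
on-disk layout is not documented, so its importer is a stub until mapped.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from .forward import PulseScheme, TrastCurve
from .synthetic import RawPoint, RawRecording

__all__ = [
    "ParseError",
    "read_trast",
    "write_trast",
    "read_raw_recording",
    "write_raw_recording",
    "import_raw",
    "register_importer",
    "RAW_IMPORTERS",
]


class ParseError(ValueError):
    """Malformed curve or recording file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


# ---------------------------------------------------------------------------
# TrastCurve


def _meta_scalar(value):
    """Parse a metadata value as a YAML scalar (number, bool, null or str)."""
    return yaml.safe_load(value)


def write_trast(curve: TrastCurve, path: str | Path) -> None:
    """Write a curve in the dialect selected by the file extension
    (``.csv`` or ``.json``)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "meta": dict(curve.meta),
            "pulse_width_s": curve.w_values.tolist(),
            "f_norm": curve.f_norm.tolist(),
            "sem": [None if math.isnan(s) else s for s in curve.sem.tolist()],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = [f"# {k}: {v}" for k, v in curve.meta.items()]
    lines.append("pulse_width_s,f_norm,sem")
    for w, f, s in zip(curve.w_values, curve.f_norm, curve.sem):
        s_txt = "" if math.isnan(s) else repr(float(s))
        lines.append(f"{float(w)!r},{float(f)!r},{s_txt}")
    path.write_text("\n".join(lines) + "\n")


def _read_trast_csv(path: Path) -> TrastCurve:
    meta: dict = {}
    w, f, sem = [], [], []
    header_seen = False
    has_sem = True
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise ParseError(f"malformed metadata line {body!r}", lineno)
            key, _, value = body.partition(":")
            meta[key.strip()] = _meta_scalar(value.strip())
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols[:2] != ["pulse_width_s", "f_norm"]:
                raise ParseError(f"unexpected column header {line!r}", lineno)
            has_sem = len(cols) > 2 and cols[2] == "sem"
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) < 2:
            raise ParseError(f"expected at least 2 columns, got {line!r}", lineno)
        try:
            w.append(float(parts[0]))
            f.append(float(parts[1]))
            if has_sem and len(parts) > 2 and parts[2].strip():
                sem.append(float(parts[2]))
            else:
                sem.append(float("nan"))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
    if not header_seen:
        raise ParseError("no column header found")
    if not has_sem or all(math.isnan(s) for s in sem):
        warnings.warn(f"{path.name}: no sem column; filled with NaN", stacklevel=3)
    w_arr = np.array(w)
    if np.any(np.diff(w_arr) <= 0):
        bad = int(np.argmax(np.diff(w_arr) <= 0)) + 1
        raise ParseError(
            "pulse_width_s must be strictly ascending",
            line=bad + (2 + len(meta)),
        )
    return TrastCurve(w_values=w_arr, f_norm=np.array(f), sem=np.array(sem), meta=meta)


def _read_trast_json(path: Path) -> TrastCurve:
    payload = json.loads(path.read_text())
    sem = [float("nan") if s is None else s for s in payload.get("sem", [])]
    if not sem:
        sem = [float("nan")] * len(payload["pulse_width_s"])
        warnings.warn(f"{path.name}: no sem entry; filled with NaN", stacklevel=3)
    w = np.array(payload["pulse_width_s"], dtype=float)
    if np.any(np.diff(w) <= 0):
        raise ParseError("pulse_width_s must be strictly ascending")
    return TrastCurve(
        w_values=w,
        f_norm=np.array(payload["f_norm"], dtype=float),
        sem=np.array(sem, dtype=float),
        meta=payload.get("meta", {}),
    )


def read_trast(path: str | Path) -> TrastCurve:
    """Read a curve file; dialect auto-detected (JSON if the first
    non-blank character is ``{``, CSV otherwise)."""
    path = Path(path)
    head = path.read_text(encoding="utf-8")[:64].lstrip()
    if head.startswith("{"):
        return _read_trast_json(path)
    return _read_trast_csv(path)


# ---------------------------------------------------------------------------
# RawRecording


def write_raw_recording(rec: RawRecording, path: str | Path) -> None:
    payload = {
        "format": "trast-raw-json/1",
        "meta": dict(rec.meta),
        "scheme": {
            "w_s": rec.scheme.w,
            "eta": rec.scheme.eta,
            "M": rec.scheme.M,
            "w0_s": rec.scheme.w0,
        },
        "points": [
            {
                "w_s": p.w,
                "is_reference": p.is_reference,
                "raw_counts": p.raw_counts,
                "index": p.index,
                "exposure_s": p.exposure_s,
            }
            for p in rec.points
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_raw_recording(path: str | Path) -> RawRecording:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "trast-raw-json/1":
        raise ParseError(f"not a trast raw recording: format={payload.get('format')!r}")
    s = payload["scheme"]
    scheme = PulseScheme(w=s["w_s"], eta=s["eta"], M=s["M"], w0=s["w0_s"])
    points = [
        RawPoint(
            w=p["w_s"],
            is_reference=p["is_reference"],
            raw_counts=p["raw_counts"],
            index=p["index"],
            exposure_s=p["exposure_s"],
        )
        for p in payload["points"]
    ]
    return RawRecording(points=points, scheme=scheme, meta=payload.get("meta", {}))


# ---------------------------------------------------------------------------
# raw importer registry


def _import_own_dialect(path: str | Path) -> list[RawRecording]:
    return [read_raw_recording(path)]


def _import_zenodo_deposit(path: str | Path) -> list[RawRecording]:
    raise NotImplementedError(
        "The on-disk layout of the deposited raw data (zenodo.10419469) is "
        "not documented; map its files to RawRecording and register the "
        "importer with register_importer('zenodo-10419469', fn)."
    )


RAW_IMPORTERS: dict[str, Callable[[str | Path], list[RawRecording]]] = {
    "trast-json": _import_own_dialect,
    "zenodo-10419469": _import_zenodo_deposit,
}


def register_importer(
    name: str, fn: Callable[[str | Path], list[RawRecording]]
) -> None:
    RAW_IMPORTERS[name] = fn


def import_raw(path: str | Path, dialect: str = "trast-json") -> list[RawRecording]:
    """Import raw recordings through the registered dialect importer."""
    try:
        importer = RAW_IMPORTERS[dialect]
    except KeyError:
        raise KeyError(
            f"unknown raw dialect {dialect!r}; registered: "
            f"{', '.join(sorted(RAW_IMPORTERS))}"
        ) from None
    return importer(path)
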