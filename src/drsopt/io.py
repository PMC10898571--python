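"""Spectrum CSV readers/writers, manifests and machine-readable run reports."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .snr import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_report",
    "report_hash",
]

log = logging.getLogger("drsopt")


class SpectrumParseError(ValueError):
    pass


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a two-column CSV (wavenumber_cm1, counts) with '#' metadata header."""
    path = Path(path)
    lines = []
    for key, value in spectrum.meta.items():
        lines.append(f"# {key}: {json.dumps(value, sort_keys=True, default=str)}")
    lines.append("wavenumber_cm1,counts")
    for wn, c in zip(spectrum.wavenumbers, spectrum.counts):
        lines.append(f"{float(wn)!r},{float(c)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column wavenumber/counts CSV.

    '#'-prefixed header comments become metadata; a header row is optional.
    A descending axis is sorted ascending with a logged warning; duplicate
    wavenumbers and non-numeric rows raise descriptive errors.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    linenos: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    try:
                        meta[key.strip()] = json.loads(value.strip())
                    except json.JSONDecodeError:
                        meta[key.strip()] = value.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
                linenos.append(lineno)
            except ValueError:
                if rows:
                    raise SpectrumParseError(
                        f"{path}:{lineno}: non-numeric row {line!r}") from None
                continue  # tolerated: a single header row before any data
    if len(rows) < 4:
        raise SpectrumParseError(f"{path}: fewer than 4 channels")
    wn = np.array([r[0] for r in rows])
    counts = np.array([r[1] for r in rows])
    seen: dict[float, int] = {}
    for value, lineno in zip(wn, linenos):
        if value in seen:
            raise SpectrumParseError(
                f"{path}:{lineno}: duplicated wavenumber {value} "
                f"(first at line {seen[value]})")
        seen[value] = lineno
    if np.all(np.diff(wn) < 0):
        log.warning("%s: descending wavenumber axis; sorting ascending", path)
        order = np.argsort(wn)
        wn, counts = wn[order], counts[order]
    return Spectrum(wn, counts, meta)


def read_manifest(directory: str | Path) -> pd.DataFrame:
    """Read a thickness-series manifest, resolving spectrum paths."""
    directory = Path(directory)
    df = pd.read_csv(directory / "manifest.csv")
    for col in ("fbr", "initial"):
        df[col] = df[col].map(lambda name: str(directory / name))
    return df


def write_report(report: dict, path: str | Path) -> Path:
    """Write a self-describing JSON report (sorted keys, stable layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return path


def report_hash(report: dict) -> str:
    """SHA-256 of a report excluding volatile keys (timestamps)."""
    stable = {k: v for k, v in report.items() if k != "timestamp"}
    blob = json.dumps(stable, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
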