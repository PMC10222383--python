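"""Readers and writers for the external formats the pipeline touches.

* single-lead CSV signals (``sample_index, voltage_mV``, header optional)
* WFDB header + signal pairs (format 16 only — the storage format of the
  PhysioNet ECG archives this tool targets)
* the template repository: versioned JSON holding per-user encoder
  embeddings and never any raw signal samples
* evaluation reports round-trip through :mod:`ecgverify.metrics`

The repository stores floats via Python ``repr`` (shortest round-trip
representation), so save/load is bit-exact for 64-bit values.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    InvalidArgumentError,
    LeadNotFoundError,
    ParseError,
    UnsupportedVersionError,
)
from .synthetic import ECGRecord

REPOSITORY_FORMAT_VERSION = "1"


# ---------------------------------------------------------------- CSV

def read_csv(path: str | Path, fs: float, subject_id: str) -> ECGRecord:
    """Read a single-lead CSV signal.

    Accepts one- or two-column rows (``voltage`` or ``index, voltage``),
    with or without a header row.  Malformed rows raise :class:`ParseError`
    carrying the 1-based line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            cell = row[-1].strip()
            try:
                values.append(float(cell))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"cannot parse voltage {cell!r}", lineno)
    if not values:
        raise ParseError(f"no samples found in {path}")
    return ECGRecord(
        samples=np.array(values), fs=fs, subject_id=subject_id, source="csv"
    )


def write_csv(record: ECGRecord, path: str | Path) -> None:
    """Write ``record`` as ``sample_index, voltage_mV`` with a header row."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["sample_index", "voltage_mV"])
        for i, v in enumerate(record.samples):
            wr.writerow([i, repr(float(v))])


# ---------------------------------------------------------------- WFDB

@dataclass
class _WfdbSignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    name: str


def _parse_header(header_path: Path) -> tuple[str, float, int, list[_WfdbSignalSpec]]:
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError(f"empty WFDB header {header_path}")
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(f) > 2:
            g = f[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if g else 200.0
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        name = f[8] if len(f) > 8 else f"sig{len(specs)}"
        specs.append(
            _WfdbSignalSpec(
                file_name=f[0], fmt=fmt, gain=gain or 200.0,
                baseline=baseline, units=units, name=name,
            )
        )
    return record_name, fs, n_samples, specs


def read_wfdb(path: str | Path, lead: str = "i") -> ECGRecord:
    """Read one lead of a WFDB record (header ``<record>.hea`` + signal file).

    Only format 16 (interleaved little-endian int16) is supported, which is
    the storage format of the ECG-ID and PTB archives.  Samples are
    converted to physical units via ``(adc - baseline) / gain``; the
    subject id is derived from the record name.
    """
    path = Path(path)
    header_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {header_path}")
    record_name, fs, n_samples, specs = _parse_header(header_path)

    names = [s.name for s in specs]
    matches = [i for i, n in enumerate(names) if n.lower() == lead.lower()]
    if not matches:
        raise LeadNotFoundError(lead, names)
    lead_idx = matches[0]

    fmts = {s.fmt for s in specs}
    if fmts != {16}:
        raise InvalidArgumentError(
            f"unsupported WFDB signal format(s) {sorted(fmts)}; "
            "only format 16 is supported"
        )
    sig_path = header_path.parent / specs[lead_idx].file_name
    if not sig_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {sig_path}")
    raw = np.fromfile(sig_path, dtype="<i2")
    n_sig = len(specs)
    raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)
    if n_samples:
        raw = raw[:n_samples]
    spec = specs[lead_idx]
    physical = (raw[:, lead_idx].astype(np.float64) - spec.baseline) / spec.gain
    return ECGRecord(
        samples=physical, fs=fs, subject_id=record_name, source="wfdb"
    )


def write_wfdb(
    path: str | Path,
    leads: dict[str, np.ndarray],
    fs: float,
    gain: float = 200.0,
    baseline: int = 0,
) -> Path:
    """Write a format-16 WFDB record (used for fixtures and export).

    Physical values are quantized as ``round(v * gain) + baseline``.
    Returns the header path.
    """
    path = Path(path)
    record_name = path.stem
    names = list(leads)
    arrays = [np.asarray(leads[n], dtype=np.float64) for n in names]
    n_samples = len(arrays[0])
    if any(len(a) != n_samples for a in arrays):
        raise InvalidArgumentError("all leads must have equal length")
    adc = np.stack(
        [np.round(a * gain).astype(np.int64) + baseline for a in arrays],
        axis=1,
    )
    if np.any(np.abs(adc) > 32767):
        raise InvalidArgumentError("signal exceeds int16 range at this gain")
    dat_name = f"{record_name}.dat"
    header_path = path.with_suffix(".hea")
    with open(header_path, "w") as fh:
        fh.write(f"{record_name} {len(names)} {fs:g} {n_samples}\n")
        for name in names:
            fh.write(
                f"{dat_name} 16 {gain:g}({baseline})/mV 16 0 0 0 0 {name}\n"
            )
    adc.astype("<i2").tofile(path.with_suffix(".dat"))
    return header_path


# ------------------------------------------------------- template repository

@dataclass
class RepositoryFile:
    """Per-user stored embeddings enabling enrollment without retraining.

    Holds exactly ``n_ref`` embedding vectors per user plus enrollment
    metadata; raw signal samples never appear in the file.
    """

    n_ref: int
    embed_dim: int
    format_version: str = REPOSITORY_FORMAT_VERSION
    users: dict[str, dict] = field(default_factory=dict)
    # users[user_id] = {"embeddings": [np.ndarray x n_ref],
    #                   "enrolled_at": iso-str, "preset": str}

    def validate(self) -> None:
        if self.n_ref < 1:
            raise InvalidArgumentError("n_ref must be >= 1")
        for uid, entry in self.users.items():
            embs = entry["embeddings"]
            if len(embs) != self.n_ref:
                raise InvalidArgumentError(
                    f"user {uid!r} has {len(embs)} embeddings, "
                    f"expected n_ref={self.n_ref}"
                )
            for e in embs:
                if len(e) != self.embed_dim:
                    raise InvalidArgumentError(
                        f"user {uid!r} embedding dimension {len(e)} != "
                        f"{self.embed_dim}"
                    )


def save_repository(repo: RepositoryFile, path: str | Path) -> None:
    repo.validate()
    doc = {
        "format_version": repo.format_version,
        "n_ref": repo.n_ref,
        "embed_dim": repo.embed_dim,
        "users": {
            uid: {
                "embeddings": [
                    [repr(float(x)) for x in np.asarray(e).ravel()]
                    for e in entry["embeddings"]
                ],
                "enrolled_at": entry.get("enrolled_at", ""),
                "preset": entry.get("preset", ""),
            }
            for uid, entry in repo.users.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_repository(path: str | Path) -> RepositoryFile:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != REPOSITORY_FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"repository format version {version!r} unsupported "
            f"(expected {REPOSITORY_FORMAT_VERSION!r})"
        )
    repo = RepositoryFile(
        n_ref=int(doc["n_ref"]),
        embed_dim=int(doc["embed_dim"]),
        format_version=version,
        users={
            uid: {
                "embeddings": [
                    np.array([float(x) for x in e]) for e in entry["embeddings"]
                ],
                "enrolled_at": entry.get("enrolled_at", ""),
                "preset": entry.get("preset", ""),
            }
            for uid, entry in doc["users"].items()
        },
    )
    repo.validate()
    return repo
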