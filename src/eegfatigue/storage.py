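"""File formats: recordings (TSV + JSON sidecar, or EDF), feature tables,
serialized models and study manifests.

The EDF support is a minimal self-contained reader/writer for the classic
16-bit European Data Format (continuous signals, uniform rate); it exists so
recordings can round-trip through the standard interchange format without an
external dependency.
"""
from __future__ import annotations

import csv
import json
import struct
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .rols import RBFNetwork
from .types import FeatureSet, Recording

MODEL_FORMAT_VERSION = 1

STATE_NAMES = {0: "alert", 1: "fatigue"}
STATE_LABELS = {"alert": 0, "fatigue": 1}


# ---------------------------------------------------------------- recordings

def write_recording(rec: Recording, path) -> Path:
    """Write channels-as-rows TSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t")
    sidecar = {
        "rate": rec.rate,
        "channel_names": list(rec.channel_names),
        "label": None if rec.label is None else STATE_NAMES[rec.label],
        "subject_id": rec.subject_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path, sidecar: Optional[dict] = None) -> Recording:
    """Load a recording from EDF or from a delimited matrix + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    if sidecar is None:
        sc_path = path.with_suffix(path.suffix + ".json")
        if not sc_path.exists():
            raise FileNotFoundError(f"sidecar {sc_path} not found for {path}")
        sidecar = json.loads(sc_path.read_text())
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    names = sidecar["channel_names"]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"sidecar lists {len(names)} channels but matrix has {data.shape[0]} rows"
        )
    label = sidecar.get("label")
    if isinstance(label, str):
        label = STATE_LABELS[label]
    return Recording(
        data=data,
        rate=float(sidecar["rate"]),
        channel_names=names,
        label=label,
        subject_id=sidecar.get("subject_id", ""),
    )


# ------------------------------------------------------------------ EDF I/O

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _fit_float(v: float) -> str:
    """Format a float into <= 8 ASCII chars, EDF header field width."""
    for fmt in (".6g", ".5g", ".4g", ".3g", ".2g", ".1g"):
        s = format(float(v), fmt)
        if len(s) <= 8:
            return s
    return format(float(v), ".0e")[:8]


def write_edf(rec: Recording, path) -> Path:
    """Write a classic 16-bit EDF file (1-second data records).

    The sampling rate must be a positive integer and the sample count a
    multiple of the rate. Amplitudes are quantized to 16 bits over each
    channel's observed range.
    """
    path = Path(path)
    rate = int(rec.rate)
    if rate != rec.rate or rate <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n = rec.n_samples
    if n % rate != 0:
        raise ValueError("sample count must be a whole number of 1-s records")
    n_records = n // rate
    ns = rec.n_channels

    pmins, pmaxs, scaled = [], [], []
    dig_min, dig_max = -32768, 32767
    for ch in rec.data:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        # use the header-representable values for the actual quantization
        lo = float(_fit_float(lo))
        hi = float(_fit_float(hi))
        if hi <= lo:
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        dig = np.round((ch - lo) / (hi - lo) * (dig_max - dig_min) + dig_min)
        scaled.append(np.clip(dig, dig_min, dig_max).astype("<i2"))

    header = b""
    header += _pad("0", 8)
    header += _pad(rec.subject_id or "X", 80)
    state = "" if rec.label is None else STATE_NAMES[rec.label]
    header += _pad(f"Startdate 01-JAN-2000 {state}".strip(), 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + ns)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)
    for name in rec.channel_names:
        header += _pad(str(name), 16)
    header += b" " * (80 * ns)  # transducer
    for _ in range(ns):
        header += _pad("uV", 8)
    for v in pmins:
        header += _pad(_fit_float(v), 8)
    for v in pmaxs:
        header += _pad(_fit_float(v), 8)
    header += _pad(str(dig_min), 8) * ns
    header += _pad(str(dig_max), 8) * ns
    header += b" " * (80 * ns)  # prefiltering
    header += _pad(str(rate), 8) * ns
    header += b" " * (32 * ns)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ch in scaled:
                fh.write(ch[r * rate : (r + 1) * rate].tobytes())
    return path


def read_edf(path) -> Recording:
    """Read a classic continuous 16-bit EDF file written by :func:`write_edf`
    or any writer using uniform per-signal rates."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def field(off, width):
        return raw[off : off + width].decode("ascii", "replace").strip()

    subject = field(8, 80)
    rec_field = field(88, 80)
    n_records = int(field(236, 8))
    duration = float(field(244, 8))
    ns = int(field(252, 4))
    off = 256
    labels = [field(off + 16 * i, 16) for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns
    pmin = [float(field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    pmax = [float(field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    dmin = [int(field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    dmax = [int(field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns + 80 * ns
    spr = [int(field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns + 32 * ns

    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal rates are not supported")
    rate = spr[0] / duration
    total = n_records * sum(spr)
    payload = np.frombuffer(raw, dtype="<i2", count=total, offset=off).astype(float)
    data = np.empty((ns, n_records * spr[0]))
    pos = 0
    for r in range(n_records):
        for i in range(ns):
            seg = payload[pos : pos + spr[i]]
            pos += spr[i]
            scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
            data[i, r * spr[0] : (r + 1) * spr[0]] = (seg - dmin[i]) * scale + pmin[i]
    label = None
    for name, value in STATE_LABELS.items():
        if name in rec_field.lower().split():
            label = value
    return Recording(
        data=data, rate=rate, channel_names=labels, label=label, subject_id=subject
    )


# ----------------------------------------------------------------- features

def write_features(fs: FeatureSet, path) -> Path:
    """One row per epoch, feature columns then label; JSON sidecar for stats."""
    path = Path(path)
    d = fs.n_features
    header = ",".join([f"f{i}" for i in range(d)] + ["label"])
    table = np.column_stack([fs.X, fs.y.astype(float)])
    np.savetxt(path, table, delimiter=",", header=header, comments="")
    meta = {
        "norm_stats": fs.norm_stats,
        "params": fs.params,
        "variance_ratios": fs.variance_ratios.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_features(path) -> FeatureSet:
    path = Path(path)
    table = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
    X, y = table[:, :-1], table[:, -1].astype(int)
    meta_path = path.with_suffix(path.suffix + ".json")
    norm_stats, params, vr = None, {}, np.zeros(X.shape[0])
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        norm_stats = meta.get("norm_stats")
        params = meta.get("params", {})
        vr = np.asarray(meta.get("variance_ratios", vr))
    return FeatureSet(X, y, vr, norm_stats, params)


# ------------------------------------------------------------------- models

def save_model(net: RBFNetwork, path) -> Path:
    path = Path(path)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "rho": float(net.rho),
        "lambda": float(net.lam),
        "beta": float(net.beta),
        "centers": np.asarray(net.centers).tolist(),
        "theta": np.asarray(net.theta).tolist(),
        "selected_indices": [int(i) for i in net.selected_indices],
        "pipeline_params": net.pipeline_params,
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> RBFNetwork:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    if payload.get("pipeline_params") is None:
        warnings.warn(
            f"{path}: model has no pipeline_params; prediction on raw "
            "recordings is refused, only pre-built features are accepted",
            stacklevel=2,
        )
    return RBFNetwork(
        centers=np.asarray(payload["centers"], dtype=float),
        rho=float(payload["rho"]),
        theta=np.asarray(payload["theta"], dtype=float),
        lam=float(payload["lambda"]),
        beta=float(payload["beta"]),
        selected_indices=list(payload["selected_indices"]),
        pipeline_params=payload.get("pipeline_params"),
    )


# ----------------------------------------------------------------- manifest

def write_manifest(rows: list, path) -> Path:
    path = Path(path)
    fields = ["subject_id", "state", "label", "path", "rate", "channels", "duration_s"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
    return path


def read_manifest(path) -> list:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    base = path.parent
    for row in rows:
        row["label"] = int(row["label"])
        if row["label"] not in (0, 1):
            raise ValueError("manifest labels must be binary")
        row["rate"] = float(row["rate"])
        if "path" in row and row["path"]:
            p = base / row["path"]
            if not p.exists():
                raise FileNotFoundError(f"manifest entry missing on disk: {p}")
    return rows
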