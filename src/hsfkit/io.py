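"""File formats: raw scan tables, fingerprint grids, device/registry config.

Raw scans are UTF-8 delimited text with a header line and exactly the
columns ``led_index, emission_nm, intensity, integration_time,
brightness`` (any column order; parsing is header-driven). Values
round-trip losslessly to 6 significant digits. Fingerprints are CSV
grids with ``# key=value`` comment lines carrying pad count and
provenance. Device configs and class registries are YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hsfkit.device import DeviceConfig, RawScan
from hsfkit.preprocess import HSF_SIDE, HSFMatrix

SCAN_COLUMNS = ("led_index", "emission_nm", "intensity", "integration_time", "brightness")


def write_scan(scan: RawScan, path) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "led_index": np.asarray(scan.led_index, dtype=int),
        "emission_nm": scan.emission_nm,
        "intensity": scan.intensity,
        "integration_time": scan.integration_time,
        "brightness": scan.brightness,
    })
    with path.open("w", encoding="utf-8") as fh:
        for key in ("seed", "sample_id"):
            if scan.metadata.get(key) not in (None, ""):
                fh.write(f"# {key}={scan.metadata[key]}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_scan(path) -> RawScan:
    path = Path(path)
    meta: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scan file {path} is missing columns: {sorted(missing)}")
    return RawScan(
        led_index=df["led_index"].to_numpy(dtype=int),
        emission_nm=df["emission_nm"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
        integration_time=df["integration_time"].to_numpy(dtype=float),
        brightness=df["brightness"].to_numpy(dtype=float),
        metadata=meta,
    )


def write_fingerprint(fp: HSFMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# pad_count={fp.pad_count}\n")
        if fp.provenance:
            fh.write(f"# provenance={fp.provenance}\n")
        grid = fp.values[:, :, 0]
        for row in grid:
            fh.write(",".join(f"{x:.9g}" for x in row) + "\n")


def read_fingerprint(path) -> HSFMatrix:
    path = Path(path)
    pad_count = 0
    provenance = ""
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").strip().partition("=")
                if key.strip() == "pad_count":
                    pad_count = int(val)
                elif key.strip() == "provenance":
                    provenance = val.strip()
                continue
            rows.append([float(x) for x in line.split(",")])
    grid = np.asarray(rows, dtype=float)
    if grid.shape != (HSF_SIDE, HSF_SIDE):
        raise ValueError(f"fingerprint grid in {path} has shape {grid.shape}")
    return HSFMatrix(values=grid[:, :, None], pad_count=pad_count, provenance=provenance)


def write_device_config(config: DeviceConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["led_wavelengths"] = [float(w) for w in data["led_wavelengths"]]
    data["emission_span"] = [float(x) for x in data["emission_span"]]
    Path(path).write_text(yaml.safe_dump({"device": data}, sort_keys=True), encoding="utf-8")


def read_device_config(path) -> DeviceConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict) or "device" not in data:
        raise ValueError(f"{path}: expected a top-level 'device' mapping")
    fields = dict(data["device"])
    if "led_wavelengths" in fields:
        fields["led_wavelengths"] = tuple(fields["led_wavelengths"])
    if "emission_span" in fields:
        fields["emission_span"] = tuple(fields["emission_span"])
    return DeviceConfig(**fields)
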