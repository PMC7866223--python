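"""Plain-text file formats and run configuration.

Measurement sets and images are stored as delimited text with ``#``-prefixed
header lines: desk-scale sizes, diffable, no binary dependency.  Antenna
indices are written 1-based in files (matching the hardware numbering
convention, antenna #1 at the bottom of the array) and exposed 0-based in
the API.
"""

from __future__ import annotations

import ast
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .forward import MeasurementSet, measurement_pairs
from .geometry import ImagingZone

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_measurements",
    "write_measurements",
    "write_image",
    "read_image",
    "write_run_log",
]

#: sentinel marking out-of-zone grid nodes in image files.
IMAGE_SENTINEL = float("nan")


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration with unit-suffixed keys.

    Defaults reproduce the reference experimental configuration (25 cm /
    64-cell grid, 69.8 mm zone, 16 antennas on 15.2 cm, 1500 MHz,
    glycerin-water bath, 4 cm inclusion toward antennas #6-#7).
    """

    domain_size_m: float = 0.25
    n_cells: int = 64
    zone_radius_m: float = 0.0698
    n_antennas: int = 16
    array_diameter_m: float = 0.152
    source_amplitude: float = 1.0
    frequency_hz: float = 1.5e9
    eps_r_background: float = 20.9
    sigma_background_s_per_m: float = 1.35
    eps_r_object: float = 16.9
    sigma_object_s_per_m: float = 1.15
    inclusion_radius_m: float = 0.02
    inclusion_center_x_m: float | None = None  # None: toward antennas #6-#7
    inclusion_center_y_m: float | None = None
    noise_level: float = 0.01
    fine_factor: int = 2
    rng_seed: int = 0
    max_iterations: int = 25
    stop_delta: float = 1e-3
    regularization_lambda: float = 0.1
    lm_decay: float = 0.9
    step_clamp: float | None = None


def load_config(path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected with a diagnostic."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key: value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def _parse_header_value(text: str):
    """Parse a header value as a Python literal, falling back to the raw string."""
    try:
        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text


def _parse_header_line(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if "=" in body:
        key, _, val = body.partition("=")
        meta[key.strip()] = _parse_header_value(val.strip())


# ---------------------------------------------------------------------------
# measurement sets


def write_measurements(mset: MeasurementSet, path) -> None:
    """Write one row per ordered (s, r) pair: s r Re(E) Im(E) (1-based s, r)."""
    lines = ["# mwtomo measurement set"]
    for key, val in sorted(mset.meta.items()):
        if isinstance(val, complex):  # keep headers literal-parsable
            val = f"({val.real!r}, {val.imag!r})"
        lines.append(f"# {key} = {val!r}" if isinstance(val, str) else f"# {key} = {val}")
    lines.append("# columns: s r re_e im_e (antenna indices 1-based)")
    for (s, r), v in zip(mset.pairs, mset.values):
        lines.append(f"{s + 1} {r + 1} {float(v.real)!r} {float(v.imag)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_measurements(path) -> MeasurementSet:
    """Read and validate a measurement file.

    Every ordered (s, r) pair with s != r must appear exactly once;
    duplicate, missing, self-reception or malformed rows are reported with
    their line number.
    """
    path = Path(path)
    meta: dict = {}
    rows: dict[tuple[int, int], complex] = {}
    n_ant = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            _parse_header_line(stripped, meta)
            continue
        parts = stripped.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: malformed row (expected 4 columns)")
        try:
            s, r = int(parts[0]), int(parts[1])
            re_e, im_e = float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
        if s < 1 or r < 1:
            raise ValueError(f"{path}:{lineno}: antenna indices are 1-based")
        if s == r:
            raise ValueError(f"{path}:{lineno}: self-reception row s == r == {s}")
        key = (s - 1, r - 1)
        if key in rows:
            raise ValueError(f"{path}:{lineno}: duplicate pair ({s}, {r})")
        rows[key] = complex(re_e, im_e)
        n_ant = max(n_ant, s, r)

    if "n_antennas" in meta:
        n_ant = int(meta["n_antennas"])
    pairs = measurement_pairs(n_ant)
    missing = [tuple(p) for p in pairs if tuple(p) not in rows]
    if missing:
        s, r = missing[0]
        raise ValueError(
            f"{path}: missing {len(missing)} pair(s), first ({s + 1}, {r + 1})"
        )
    if len(rows) != len(pairs):
        extra = sorted(set(rows) - {tuple(p) for p in pairs})
        raise ValueError(f"{path}: unexpected pairs beyond n_antennas={n_ant}: {extra[:3]}")
    values = np.array([rows[tuple(p)] for p in pairs])
    return MeasurementSet(pairs, values, meta)


# ---------------------------------------------------------------------------
# images


def write_image(
    eps_r: np.ndarray,
    sigma: np.ndarray,
    zone: ImagingZone,
    path,
    header: dict | None = None,
) -> None:
    """Write eps_r / sigma images over the full node lattice as gridded text.

    One row per grid node: ``i j x_m y_m eps_r sigma``; out-of-zone nodes
    carry NaN sentinels.  In-zone node count equals the unknown count.
    """
    n1 = zone.grid.n_nodes_per_side
    full_eps = np.full((n1, n1), IMAGE_SENTINEL)
    full_sig = np.full((n1, n1), IMAGE_SENTINEL)
    for t, (i, j) in enumerate(zone.node_ij):
        full_eps[i, j] = eps_r[t]
        full_sig[i, j] = sigma[t]
    lines = ["# mwtomo property image"]
    info = {
        "n_cells": zone.grid.n_cells_per_side,
        "domain_size_m": zone.grid.side_length,
        "zone_radius_m": zone.zone_radius,
        "n_zone_nodes": zone.n_nodes,
        "sentinel": "nan",
    }
    info.update(header or {})
    for key, val in info.items():
        lines.append(f"# {key} = {val!r}" if isinstance(val, str) else f"# {key} = {val}")
    lines.append("# columns: i j x_m y_m eps_r sigma")
    for i in range(n1):
        for j in range(n1):
            x, y = zone.grid.node_coordinates(np.array([i, j]))
            lines.append(
                f"{i} {j} {float(x)!r} {float(y)!r} "
                f"{float(full_eps[i, j])!r} {float(full_sig[i, j])!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_image(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a gridded image file back as (eps_r, sigma) node lattices + header."""
    meta: dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            _parse_header_line(stripped, meta)
            continue
        parts = stripped.split()
        rows.append((int(parts[0]), int(parts[1]), float(parts[4]), float(parts[5])))
    n1 = max(r[0] for r in rows) + 1
    eps = np.full((n1, n1), IMAGE_SENTINEL)
    sig = np.full((n1, n1), IMAGE_SENTINEL)
    for i, j, e, s in rows:
        eps[i, j] = e
        sig[i, j] = s
    return eps, sig, meta


def write_run_log(path, params: dict, counters: dict, extra: dict | None = None) -> None:
    """Machine-readable run log: resolved parameters and per-stage counters."""
    payload = {"parameters": params, "counters": counters}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
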