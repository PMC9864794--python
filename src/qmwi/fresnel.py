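"""Reader/writer for Fresnel-database-style ASCII experiment files.

The Marseille laboratory scattering database distributes multi-static
measurements as plain-text files: header lines describing the geometry
followed by whitespace-separated records carrying, per (transmitter, receiver,
frequency) triple, the real and imaginary parts of the total and incident
fields; the scattered field is their difference.  Several dialect variants
exist in the wild, so this module defines one documented dialect
(``qmwi-fresnel-ascii v1``, written by :func:`write_experiment`) and parses it
strictly; files from other variants need their headers adapted.  Aspect-limited
receiver patterns (records missing for some Tx/Rx pairs) are preserved via an
availability mask; missing entries are zero in the field arrays, which simply
drop out of the OSM receiver sums.

Dialect layout::

    # qmwi-fresnel-ascii v1
    # tx_radius_m: 1.67
    # rx_radius_m: 1.67
    # n_tx: 8
    # n_rx: 241
    # frequencies_hz: 2e9 3e9
    # n_records: 3856
    # columns: tx_angle_deg rx_angle_deg freq_hz re_total im_total re_inc im_inc
    0.0 0.0 2e9 1.234e-3 -5.6e-4 ...
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import MeasurementConfig

_MAGIC = "qmwi-fresnel-ascii v1"


class FresnelParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class FresnelExperiment:
    """Parsed multi-static experiment with geometry in package conventions."""

    config: MeasurementConfig
    total_field: np.ndarray      # (Nm, Nv, Nf) complex, 0 where unavailable
    incident_field: np.ndarray   # (Nm, Nv, Nf) complex, 0 where unavailable
    available: np.ndarray        # (Nm, Nv, Nf) bool

    @property
    def scattered_field(self) -> np.ndarray:
        """Total minus incident; zero where the record was absent."""
        return self.total_field - self.incident_field


def _angles_to_index(angles_deg: np.ndarray) -> dict[float, int]:
    return {float(a): i for i, a in enumerate(angles_deg)}


def write_experiment(
    path,
    config: MeasurementConfig,
    total_field: np.ndarray,
    incident_field: np.ndarray,
    available: np.ndarray | None = None,
) -> None:
    """Serialize an experiment in the documented ASCII dialect."""
    total_field = np.asarray(total_field)
    shape = (config.n_rx, config.n_tx, config.n_freq)
    if total_field.shape != shape or np.asarray(incident_field).shape != shape:
        raise ValueError(f"field arrays must have shape {shape}")
    if available is None:
        available = np.ones(shape, bool)
    tx_ang = np.degrees(np.arctan2(config.tx_positions[:, 1], config.tx_positions[:, 0])) % 360
    rx_ang = np.degrees(np.arctan2(config.rx_positions[:, 1], config.rx_positions[:, 0])) % 360

    records = []
    for vi in range(config.n_tx):
        for mi in range(config.n_rx):
            for fi, f in enumerate(config.frequencies):
                if not available[mi, vi, fi]:
                    continue
                tf, inc = total_field[mi, vi, fi], incident_field[mi, vi, fi]
                records.append(
                    f"{tx_ang[vi]:.6f} {rx_ang[mi]:.6f} {f:.6e} "
                    f"{tf.real:.9e} {tf.imag:.9e} {inc.real:.9e} {inc.imag:.9e}"
                )
    header = [
        f"# {_MAGIC}",
        f"# tx_radius_m: {config.tx_radius:.6f}",
        f"# rx_radius_m: {config.rx_radius:.6f}",
        f"# n_tx: {config.n_tx}",
        f"# n_rx: {config.n_rx}",
        "# frequencies_hz: " + " ".join(f"{f:.6e}" for f in config.frequencies),
        "# tx_angles_deg: " + " ".join(f"{a:.6f}" for a in tx_ang),
        "# rx_angles_deg: " + " ".join(f"{a:.6f}" for a in rx_ang),
        f"# n_records: {len(records)}",
        "# columns: tx_angle_deg rx_angle_deg freq_hz re_total im_total re_inc im_inc",
    ]
    Path(path).write_text("\n".join(header + records) + "\n")


def parse_fresnel(path) -> FresnelExperiment:
    """Parse a dialect-tagged ASCII experiment file; strict validation."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].lstrip("# ").strip() != _MAGIC:
        raise FresnelParseError(f"missing dialect tag {_MAGIC!r}", line=1)

    header: dict[str, str] = {}
    body_start = 0
    for ln, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s.startswith("#"):
            body_start = ln
            break
        if ":" in s:
            key, _, val = s.lstrip("# ").partition(":")
            header[key.strip()] = val.strip()
    else:
        body_start = len(lines) + 1

    def need(key: str) -> str:
        if key not in header:
            raise FresnelParseError(f"missing header field {key!r}")
        return header[key]

    try:
        n_tx = int(need("n_tx"))
        n_rx = int(need("n_rx"))
        tx_radius = float(need("tx_radius_m"))
        rx_radius = float(need("rx_radius_m"))
        freqs = np.array([float(v) for v in need("frequencies_hz").split()])
        tx_ang = np.array([float(v) for v in need("tx_angles_deg").split()])
        rx_ang = np.array([float(v) for v in need("rx_angles_deg").split()])
        n_records = int(need("n_records"))
    except ValueError as e:
        raise FresnelParseError(f"malformed header: {e}") from None
    if tx_ang.size != n_tx or rx_ang.size != n_rx:
        raise FresnelParseError("angle list lengths disagree with n_tx/n_rx")

    config = MeasurementConfig(
        tx_positions=tx_radius
        * np.column_stack([np.cos(np.radians(tx_ang)), np.sin(np.radians(tx_ang))]),
        rx_positions=rx_radius
        * np.column_stack([np.cos(np.radians(rx_ang)), np.sin(np.radians(rx_ang))]),
        frequencies=freqs,
    )
    tx_idx = _angles_to_index(np.round(tx_ang, 6))
    rx_idx = _angles_to_index(np.round(rx_ang, 6))
    f_idx = {float(f): i for i, f in enumerate(freqs)}

    shape = (n_rx, n_tx, freqs.size)
    total = np.zeros(shape, complex)
    inc = np.zeros(shape, complex)
    avail = np.zeros(shape, bool)
    count = 0
    for ln in range(body_start, len(lines) + 1):
        s = lines[ln - 1].strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 7:
            raise FresnelParseError(f"expected 7 fields, got {len(parts)}", line=ln)
        try:
            ta, ra, f = float(parts[0]), float(parts[1]), float(parts[2])
            vals = [float(v) for v in parts[3:]]
        except ValueError:
            raise FresnelParseError("non-numeric record field", line=ln) from None
        try:
            vi = tx_idx[round(ta, 6)]
            mi = rx_idx[round(ra, 6)]
            fi = f_idx[f]
        except KeyError:
            raise FresnelParseError(
                f"record angles/frequency ({ta}, {ra}, {f:g}) not declared in header",
                line=ln,
            ) from None
        if avail[mi, vi, fi]:
            raise FresnelParseError("duplicate record", line=ln)
        total[mi, vi, fi] = complex(vals[0], vals[1])
        inc[mi, vi, fi] = complex(vals[2], vals[3])
        avail[mi, vi, fi] = True
        count += 1
    if count != n_records:
        raise FresnelParseError(
            f"header declares {n_records} records but file contains {count}",
            line=len(lines),
        )
    return FresnelExperiment(config, total, inc, avail)
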