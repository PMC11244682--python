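"""File I/O: scan files, machine configuration, QA logs and reports.

Scan files are plain delimited text with two numeric columns (depth in cm,
reading), comma- or tab-separated, with ``#``-prefixed comment lines.  The
writer emits a ``# eslope scan v1`` header and preserves metadata as
``# key: value`` comments.

A machine configuration is one YAML file per linac holding, per energy
label: the commissioned measurement depths, baseline slope and ratio, the
exponential calibration constants, and the warning/action thresholds.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import ScanCurve
from .errors import ConfigurationError, ScanFormatError
from .slope import ACTION_LEVEL, WARNING_LEVEL, CalibrationModel, SlopePoints
from .tracking import Baseline, QARecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_scan",
    "write_scan",
    "ToolConfig",
    "load_config",
    "save_config",
    "write_qa_log",
    "read_qa_log",
    "config_digest",
]

SCAN_HEADER = "# eslope scan v1"


def read_scan(path: str | Path) -> ScanCurve:
    """Read a two-column delimited scan file into a :class:`ScanCurve`.

    Accepts comma or tab delimiters; ``#`` lines are treated as comments and
    ``key: value`` comments are recovered into the curve metadata.  Raises
    :class:`ScanFormatError` with the offending line number on bad input.
    """
    path = Path(path)
    depths, readings, meta = [], [], {}
    prev_depth, prev_line = None, None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body and not body.startswith("eslope scan"):
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            cells = [c for c in line.replace("\t", ",").split(",") if c.strip()]
            if len(cells) != 2:
                raise ScanFormatError(
                    f"expected 2 columns, found {len(cells)}", lineno
                )
            try:
                depth, reading = float(cells[0]), float(cells[1])
            except ValueError:
                raise ScanFormatError(f"non-numeric cell in {line!r}", lineno) from None
            if prev_depth is not None and depth <= prev_depth:
                raise ScanFormatError(
                    f"depth {depth} cm does not increase past {prev_depth} cm "
                    f"(previous data line {prev_line})",
                    lineno,
                )
            prev_depth, prev_line = depth, lineno
            depths.append(depth)
            readings.append(reading)
    if not depths:
        raise ScanFormatError(f"no data rows in {path}")
    epom = str(meta.pop("epom_shifted", "false")).lower() == "true"
    return ScanCurve(
        depths=np.array(depths), readings=np.array(readings),
        epom_shifted=epom, meta=meta,
    )


def write_scan(curve: ScanCurve, path: str | Path) -> None:
    """Write a scan as comma-delimited text with metadata comments.

    Depths are stored in cm with 4 decimal places; readings with 6
    significant digits, enough for round-trip identity at that precision.
    """
    path = Path(path)
    lines = [SCAN_HEADER, "# depth_cm,reading"]
    for key, value in curve.meta.items():
        lines.append(f"# {key}: {value}")
    if curve.epom_shifted:
        lines.append("# epom_shifted: true")
    for z, r in zip(curve.depths, curve.readings):
        lines.append(f"{z:.4f},{r:.6g}")
    path.write_text("\n".join(lines) + "\n")


class ToolConfig:
    """Per-machine QA configuration: baselines, calibrations, thresholds."""

    def __init__(
        self,
        machine: str,
        baselines: dict[float, Baseline],
        calibrations: dict[float, dict[str, CalibrationModel]],
        warning: float = WARNING_LEVEL,
        action: float = ACTION_LEVEL,
    ):
        if not 0 < warning < action:
            raise ConfigurationError("need 0 < warning < action")
        missing = set(baselines) ^ set(calibrations)
        if missing:
            raise ConfigurationError(
                f"energies without a complete baseline/calibration block: "
                f"{sorted(missing)}"
            )
        self.machine = machine
        self.baselines = baselines
        self.calibrations = calibrations
        self.warning = warning
        self.action = action

    @property
    def energies(self) -> list[float]:
        return sorted(self.baselines)

    def baseline(self, energy_label: float) -> Baseline:
        try:
            return self.baselines[energy_label]
        except KeyError:
            raise ConfigurationError(
                f"no baseline for {energy_label} MeV on machine {self.machine!r}"
            ) from None

    def calibration(self, energy_label: float, kind: str) -> CalibrationModel:
        block = self.calibrations.get(energy_label, {})
        if kind not in block:
            raise ConfigurationError(
                f"no {kind!r} calibration for {energy_label} MeV"
            )
        return block[kind]

    def to_dict(self) -> dict:
        out = {
            "machine": self.machine,
            "thresholds": {"warning_pct": self.warning, "action_pct": self.action},
            "energies": {},
        }
        for label in self.energies:
            b = self.baselines[label]
            block = {
                "d_ref_cm": b.points.d_ref,
                "d70_cm": b.points.d70,
                "d30_cm": b.points.d30,
                "i50_depth_cm": b.i50_depth,
                "baseline_slope": b.slope_m,
                "baseline_ratio": b.ratio,
                "calibration": {},
            }
            for kind, model in self.calibrations[label].items():
                block["calibration"][kind] = {
                    "amplitude_a": model.amplitude_a,
                    "rate_b": model.rate_b,
                    "r_squared": model.r_squared,
                }
            out["energies"][label] = block
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ToolConfig":
        try:
            thresholds = data.get("thresholds", {})
            baselines, calibrations = {}, {}
            for label, block in data["energies"].items():
                label = float(label)
                points = SlopePoints(
                    d70=block["d70_cm"], d30=block["d30_cm"], d_ref=block["d_ref_cm"]
                )
                baselines[label] = Baseline(
                    energy_label=label,
                    points=points,
                    i50_depth=block["i50_depth_cm"],
                    slope_m=block["baseline_slope"],
                    ratio=block["baseline_ratio"],
                )
                calibrations[label] = {
                    kind: CalibrationModel(
                        amplitude_a=c["amplitude_a"],
                        rate_b=c["rate_b"],
                        kind=kind,
                        r_squared=c.get("r_squared", 1.0),
                    )
                    for kind, c in block.get("calibration", {}).items()
                }
        except KeyError as exc:
            raise ConfigurationError(f"config is missing key {exc}") from None
        return cls(
            machine=data.get("machine", "unnamed"),
            baselines=baselines,
            calibrations=calibrations,
            warning=thresholds.get("warning_pct", WARNING_LEVEL),
            action=thresholds.get("action_pct", ACTION_LEVEL),
        )


def load_config(path: str | Path) -> ToolConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not hold a configuration mapping")
    return ToolConfig.from_dict(data)


def save_config(config: ToolConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def config_digest(config: ToolConfig) -> str:
    """Short stable hash of a configuration, for reproducibility logs."""
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


QA_LOG_COLUMNS = [
    "date",
    "energy_mev",
    "slope_pct_per_cm",
    "ratio",
    "slope_change_pct",
    "ratio_change_pct",
    "z_score",
    "status",
]


def write_qa_log(records: list[QARecord], path: str | Path) -> None:
    """Write QA records as comma-delimited text, one row per measurement."""
    frame = pd.DataFrame(
        [
            {
                "date": r.date,
                "energy_mev": r.energy_label,
                "slope_pct_per_cm": r.slope_m,
                "ratio": r.ratio,
                "slope_change_pct": r.slope_change,
                "ratio_change_pct": r.ratio_change,
                "z_score": r.z_score,
                "status": r.status,
            }
            for r in records
        ],
        columns=QA_LOG_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.6g")


def read_qa_log(path: str | Path) -> list[QARecord]:
    frame = pd.read_csv(path)
    missing = set(QA_LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ScanFormatError(f"QA log missing columns: {sorted(missing)}")
    return [
        QARecord(
            date=str(row.date),
            energy_label=float(row.energy_mev),
            slope_m=float(row.slope_pct_per_cm),
            ratio=float(row.ratio),
            slope_change=float(row.slope_change_pct),
            ratio_change=float(row.ratio_change_pct),
            status=str(row.status),
            z_score=float(row.z_score),
        )
        for row in frame.itertuples()
    ]
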