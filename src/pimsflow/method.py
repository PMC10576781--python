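"""Convert a bin assignment plus isolation windows into an MS² method table.

Bin positions become chronological acquisition events through the probe scan
rate (time = position / probe_rate).  Targets below a mass threshold
(default 17 kDa) are fragmented in conventional ensemble mode; heavier
targets use individual-ion detection, which needs gentler collision energy
and many more scans.  The neutral CSV schema written here is meant to be
mapped onto a vendor targeted-MS²/DIA method import; it is not a vendor
file.  The fragmentation line runs parallel to the survey line with a small
(~20 µm) lateral offset, recorded as metadata only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .allocation import BinAssignment
from .errors import InvalidInputError, MissingWindowError
from .geometry import ScanGeometry
from .targets import IsolationWindow

METHOD_COLUMNS = [
    "start_time_min",
    "end_time_min",
    "center_mz",
    "isolation_width",
    "ce",
    "mode",
    "target_id",
]

#: Default lateral offset between survey and MS2 lines, µm (metadata only).
DEFAULT_LINE_OFFSET_UM = 20.0


@dataclass
class AcquisitionEvent:
    """One timed MS² acquisition window."""

    target_feature_id: str
    start_time: float  # s
    end_time: float  # s
    center_mz: float
    isolation_width: float
    collision_energy: float
    detection_mode: str  # "ensemble" | "i2ms"


def events_from_assignment(
    assignment: BinAssignment,
    windows: dict[str, IsolationWindow],
    feature_masses: dict[str, float],
    geometry: ScanGeometry,
    mode_threshold: float = 17_000.0,
    ensemble_nce: float = 35.0,
    i2ms_ce: float = 10.0,
) -> list[AcquisitionEvent]:
    """Chronological MS² events from assigned bins and isolation windows."""
    events = []
    for b in sorted(assignment.mapping):
        fid = assignment.mapping[b]
        if fid not in windows:
            raise MissingWindowError(f"target {fid} has no isolation window")
        if fid not in feature_masses:
            raise InvalidInputError(f"target {fid} has no mass entry")
        win = windows[fid]
        mass = feature_masses[fid]
        ensemble = mass < mode_threshold
        events.append(
            AcquisitionEvent(
                target_feature_id=fid,
                start_time=float(assignment.bin_edges[b] / geometry.probe_rate),
                end_time=float(assignment.bin_edges[b + 1] / geometry.probe_rate),
                center_mz=win.center_mz,
                isolation_width=win.width,
                collision_energy=ensemble_nce if ensemble else i2ms_ce,
                detection_mode="ensemble" if ensemble else "i2ms",
            )
        )
    for a, b in zip(events, events[1:]):
        if b.start_time < a.end_time - 1e-9:
            raise InvalidInputError("events overlap; bins must be disjoint")
    return events


def write_method_csv(events: list[AcquisitionEvent], path) -> None:
    """Write the method table (RFC 4180, 2-decimal minutes, 4-decimal m/z)."""
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(METHOD_COLUMNS)
            for ev in events:
                writer.writerow(
                    [
                        f"{ev.start_time / 60.0:.2f}",
                        f"{ev.end_time / 60.0:.2f}",
                        f"{ev.center_mz:.4f}",
                        f"{ev.isolation_width:.4f}",
                        f"{ev.collision_energy:.1f}",
                        ev.detection_mode,
                        ev.target_feature_id,
                    ]
                )
    except OSError as exc:
        raise OSError(f"failed writing method CSV to {path}: {exc}") from exc


def read_method_csv(path) -> list[AcquisitionEvent]:
    """Read a method table back into events (times in seconds)."""
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(
                AcquisitionEvent(
                    target_feature_id=row["target_id"],
                    start_time=float(row["start_time_min"]) * 60.0,
                    end_time=float(row["end_time_min"]) * 60.0,
                    center_mz=float(row["center_mz"]),
                    isolation_width=float(row["isolation_width"]),
                    collision_energy=float(row["ce"]),
                    detection_mode=row["mode"],
                )
            )
    return events
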