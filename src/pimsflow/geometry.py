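"""Scan geometry: mapping MS scan indices to positions on the tissue."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of a line-scan acquisition.

    Parameters
    ----------
    probe_rate : float
        Lateral probe speed in µm/s.
    acquisition_rate : float
        Spectral acquisition rate in spectra/s.
    strip_step : float
        Across-track spacing between adjacent lines, µm.
    scans_per_line : int
        Number of MS scans recorded along one line.
    n_lines : int
        Number of parallel lines (1 for a single survey line).
    """

    probe_rate: float
    acquisition_rate: float
    strip_step: float
    scans_per_line: int
    n_lines: int = 1

    def __post_init__(self):
        for name in ("probe_rate", "acquisition_rate", "strip_step"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.scans_per_line < 1 or self.n_lines < 1:
            raise InvalidInputError("scans_per_line and n_lines must be >= 1")

    @property
    def scan_pitch(self) -> float:
        """Along-track distance between consecutive scans, µm."""
        return self.probe_rate / self.acquisition_rate

    @property
    def line_length(self) -> float:
        """Length of one scanned line, µm."""
        return self.scans_per_line * self.scan_pitch

    def scan_coordinate(self, scan_index) -> np.ndarray | float:
        """Along-track coordinate of a scan (µm): ``k * probe_rate / acquisition_rate``."""
        return np.asarray(scan_index) * self.scan_pitch
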