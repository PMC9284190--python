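"""Sampled spectral response curves.

Every optical element in the imaging chain -- LED emission, excitation
filter, fluorochrome excitation/emission, penta emission filter, and the
R/G/B sensitivities of the color sensor -- is represented as a
:class:`SpectralCurve`: a non-negative response sampled on a strictly
increasing wavelength grid (nm). Curves are plain data; all physics lives
in :mod:`pentaplex.fingerprint`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectralCurve", "common_grid", "overlap_integral"]


@dataclass(frozen=True)
class SpectralCurve:
    """A response sampled against wavelength.

    Parameters
    ----------
    wavelengths_nm:
        Strictly increasing wavelength grid in nanometres.
    values:
        Non-negative response at each wavelength. Filters and sensor
        sensitivities are dimensionless transmissions/efficiencies in
        [0, 1]; emission and excitation spectra are in arbitrary units.
    name:
        Optional label used in error messages and serialization.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError(
                f"curve {self.name!r}: wavelengths and values must be 1-D "
                f"arrays of equal length (got {wl.shape} vs {vals.shape})"
            )
        if wl.size < 2:
            raise ValueError(f"curve {self.name!r}: need at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"curve {self.name!r}: wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"curve {self.name!r}: values must be finite and >= 0")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    @property
    def peak_nm(self) -> float:
        """Wavelength of the maximum response."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def resample(self, grid_nm: np.ndarray) -> "SpectralCurve":
        """Linearly interpolate onto ``grid_nm``; zero outside support."""
        vals = np.interp(grid_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        return SpectralCurve(np.asarray(grid_nm, dtype=float), vals, name=self.name)

    def scaled_to_max(self, new_max: float = 1.0) -> "SpectralCurve":
        peak = self.values.max()
        if peak == 0:
            return self
        return SpectralCurve(self.wavelengths_nm, self.values * (new_max / peak), name=self.name)

    # -- CSV round trip (wavelength_nm,value) --------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "SpectralCurve":
        df = pd.read_csv(path)
        missing = {"wavelength_nm", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            df["wavelength_nm"].to_numpy(float),
            df["value"].to_numpy(float),
            name=name if name is not None else Path(path).stem,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "value": self.values}
        ).to_csv(path, index=False, float_format="%.6g")


def common_grid(*curves: SpectralCurve) -> np.ndarray:
    """Overlapping wavelength grid of several curves.

    The grid spans the intersection of the curves' supports at the finest
    native step among them. Raises if the supports do not overlap.
    """
    lo = max(c.wavelengths_nm[0] for c in curves)
    hi = min(c.wavelengths_nm[-1] for c in curves)
    if hi <= lo:
        names = ", ".join(repr(c.name) for c in curves)
        raise ValueError(f"wavelength grids do not overlap for curves: {names}")
    step = min(float(np.min(np.diff(c.wavelengths_nm))) for c in curves)
    n = max(int(round((hi - lo) / step)) + 1, 2)
    return np.linspace(lo, hi, n)


def overlap_integral(*curves: SpectralCurve, grid_nm: np.ndarray | None = None) -> float:
    """Trapezoidal integral of the pointwise product of curves."""
    if grid_nm is None:
        grid_nm = common_grid(*curves)
    prod = np.ones_like(grid_nm)
    for c in curves:
        prod = prod * c.resample(grid_nm).values
    return float(np.trapezoid(prod, grid_nm))
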