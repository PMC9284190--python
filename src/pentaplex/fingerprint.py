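"""Fingerprint (unmixing) matrix construction and estimation.

With LED-sequential acquisition on an RGB sensor, one pixel yields a
stacked signal vector ``S`` of length ``n_led x 3`` (LED-major order,
then R, G, B). The linear mixing model is ``S = A F`` where ``F`` holds
the per-fluorochrome abundances and the columns of ``A`` are the
fluorochrome *fingerprints*: the characteristic pattern of RGB responses
across LEDs. ``A`` can be predicted from spectra (forward model) or
estimated from single-stain control slides, matching how the matrix is
obtained on a real instrument.

Each predicted column factorizes into an excitation term per LED
(LED emission x excitation filter x dye excitation, integrated over
wavelength) and an emission term per sensor channel (dye emission x
penta transmission x channel sensitivity, integrated), scaled by the
dye brightness. Columns are normalized to unit maximum so that
abundances carry the intensity scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .optics import Fluorochrome, LEDChannel, OpticsConfig, PentaFilter, SensorResponse
from .spectra import SpectralCurve, common_grid

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import AcquisitionStack

__all__ = [
    "FingerprintMatrix",
    "predict_fingerprint_column",
    "build_fingerprint_matrix",
    "estimate_fingerprint_from_singlestains",
    "window_signal_fractions",
]

_COLOR_NAMES = ("R", "G", "B")


@dataclass(frozen=True)
class FingerprintMatrix:
    """The unmixing matrix ``A`` with labeled rows and columns.

    Rows are (LED, color-channel) pairs in LED-major order; columns are
    fluorochromes. All entries are non-negative and each column is
    scaled to unit maximum.
    """

    A: np.ndarray
    row_labels: tuple[tuple[str, str], ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be 2-D")
        if A.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"shape {A.shape} does not match {len(self.row_labels)} row labels "
                f"x {len(self.col_labels)} column labels"
            )
        if np.any(A < 0) or not np.all(np.isfinite(A)):
            raise ValueError("fingerprint entries must be finite and >= 0")
        zero_cols = [self.col_labels[j] for j in range(A.shape[1]) if not np.any(A[:, j] > 0)]
        if zero_cols:
            raise ValueError(f"all-zero fingerprint column(s): {zero_cols}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        object.__setattr__(
            self, "row_labels", tuple((str(l), str(c)) for l, c in self.row_labels)
        )

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_fluors(self) -> int:
        return self.A.shape[1]

    @property
    def led_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for led, _ in self.row_labels:
            if led not in seen:
                seen.append(led)
        return tuple(seen)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))

    def column(self, fluor: str) -> np.ndarray:
        return self.A[:, self.col_labels.index(fluor)]

    def led_block(self, led: str) -> np.ndarray:
        """Rows of ``A`` belonging to one LED (the R, G, B triplet)."""
        idx = [i for i, (l, _) in enumerate(self.row_labels) if l == led]
        if not idx:
            raise KeyError(f"no rows for LED {led!r}")
        return self.A[idx]

    def to_csv(self, path: str | Path) -> None:
        index = [f"{led}:{c}" for led, c in self.row_labels]
        pd.DataFrame(self.A, index=index, columns=list(self.col_labels)).to_csv(
            path, float_format="%.8g", index_label="row"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FingerprintMatrix":
        df = pd.read_csv(path, index_col=0)
        rows = tuple(tuple(r.split(":")) for r in df.index)
        return cls(df.to_numpy(float), rows, tuple(df.columns))


def _excitation_terms(
    fluor: Fluorochrome, leds: Sequence[LEDChannel]
) -> np.ndarray:
    """Per-LED excitation efficiency: integral of LED x filter x dye excitation."""
    terms = np.empty(len(leds))
    for i, led in enumerate(leds):
        grid = common_grid(led.emission, led.excitation_filter, fluor.excitation)
        prod = led.filtered_emission(grid) * fluor.excitation.resample(grid).values
        terms[i] = np.trapezoid(prod, grid)
    return terms


def _emission_terms(
    fluor: Fluorochrome,
    penta: PentaFilter,
    sensor: SensorResponse,
    window: int | None = None,
) -> np.ndarray:
    """Per-color detection efficiency: integral of dye emission x penta x sensor.

    When ``window`` is given, the integral is restricted to that penta
    passband (used for bleed-through decomposition).
    """
    terms = np.empty(3)
    for c, channel in enumerate(sensor.channels):
        grid = common_grid(fluor.emission, penta.transmission, channel)
        prod = (
            fluor.emission.resample(grid).values
            * penta.transmission.resample(grid).values
            * channel.resample(grid).values
        )
        if window is not None:
            prod = prod * penta.window_mask(grid, window)
        terms[c] = np.trapezoid(prod, grid)
    return terms


def predict_fingerprint_column(
    fluor: Fluorochrome,
    leds: Sequence[LEDChannel],
    penta: PentaFilter,
    sensor: SensorResponse,
    *,
    normalize: bool = True,
) -> np.ndarray:
    """Predict one fingerprint column from spectra.

    Returns the length ``3 * n_led`` column (LED-major, R/G/B within each
    LED). The unscaled entry for (LED l, color c) is

        brightness * [int LED_l x filter_l x excitation dlambda]
                   * [int emission x penta x sensor_c dlambda]

    i.e. excitation and detection factorize because emission spectra do
    not depend on the excitation wavelength (Kasha's rule). With
    ``normalize`` the column is scaled to unit maximum.

    Raises if the spectra grids do not overlap or if the column is
    entirely zero (the dye is invisible to this optical chain).
    """
    exc = _excitation_terms(fluor, leds)
    em = _emission_terms(fluor, penta, sensor)
    col = fluor.brightness * np.outer(exc, em).ravel()
    if not np.any(col > 0):
        raise ValueError(
            f"fluorochrome {fluor.name!r} is invisible to the optical chain "
            "(zero excitation or zero in-band emission)"
        )
    if normalize:
        col = col / col.max()
    return col


def build_fingerprint_matrix(
    fluors: Sequence[Fluorochrome],
    leds: Sequence[LEDChannel],
    penta: PentaFilter,
    sensor: SensorResponse,
) -> FingerprintMatrix:
    """Assemble the predicted fingerprint matrix for a panel of dyes."""
    if len(fluors) == 0 or len(leds) == 0:
        raise ValueError("need at least one fluorochrome and one LED")
    names = [f.name for f in fluors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate fluorochrome names: {names}")
    cols = [predict_fingerprint_column(f, leds, penta, sensor) for f in fluors]
    rows = tuple((led.name, c) for led in leds for c in _COLOR_NAMES)
    return FingerprintMatrix(np.column_stack(cols), rows, tuple(names))


def fingerprint_from_optics(optics: OpticsConfig) -> FingerprintMatrix:
    """Predicted fingerprint matrix for a full optics configuration."""
    return build_fingerprint_matrix(optics.fluors, optics.leds, optics.penta, optics.sensor)


def window_signal_fractions(
    optics: OpticsConfig, fluors: Sequence[str] | None = None
) -> pd.DataFrame:
    """Fraction of each dye's detected signal arriving through each penta window.

    Rows are fluorochromes, columns are penta window indices; each row
    sums to 1. The out-of-window (bleed-through) fraction of a dye is
    ``1 - row[nominal window]``.
    """
    names = tuple(fluors) if fluors is not None else optics.fluor_names
    n_win = optics.penta.n_windows
    out = np.zeros((len(names), n_win))
    for i, name in enumerate(names):
        fl = optics.fluor(name)
        exc_total = _excitation_terms(fl, optics.leds).sum()
        for w in range(n_win):
            em_w = _emission_terms(fl, optics.penta, optics.sensor, window=w)
            out[i, w] = exc_total * em_w.sum()
        total = out[i].sum()
        if total <= 0:
            raise ValueError(f"fluorochrome {name!r} has zero total detected signal")
        out[i] /= total
    return pd.DataFrame(out, index=list(names), columns=list(range(n_win)))


def estimate_fingerprint_from_singlestains(
    stacks: Mapping[str, "AcquisitionStack"],
    dark: np.ndarray,
    fg_threshold_quantile: float = 0.95,
    *,
    fg_smooth_sigma: float = 2.0,
) -> FingerprintMatrix:
    """Estimate ``A`` from single-fluorochrome control acquisitions.

    For each single-stain stack: dark-subtract every (LED, channel)
    plane, find foreground pixels above the ``fg_threshold_quantile``
    quantile of the *brightest* plane, and average each plane over those
    pixels. The resulting column is scaled to unit maximum. This mirrors
    the experimental calibration where the unmixing matrix is measured
    from slides each stained with a single dye.

    Foreground selection thresholds a Gaussian-smoothed copy of the
    brightest plane (``fg_smooth_sigma``); selecting on the raw plane
    would prefer pixels whose own shot noise fluctuated high and bias
    that plane's average upward (and every normalized entry downward).
    Averages are always computed on the raw planes.

    Negative plane averages (over-subtraction) are clamped to zero with
    a warning; an empty foreground raises.
    """
    from scipy.ndimage import gaussian_filter

    if not 0.0 <= fg_threshold_quantile < 1.0:
        raise ValueError("fg_threshold_quantile must be in [0, 1)")
    columns = {}
    row_labels: tuple[tuple[str, str], ...] | None = None
    for fluor_name, stack in stacks.items():
        planes = stack.signal_planes()  # (n_led*3, H, W), LED-major
        if row_labels is None:
            row_labels = tuple((led, c) for led in stack.led_names for c in _COLOR_NAMES)
        if dark.ndim == 2:  # single gray frame
            dark_full = dark[None, ...]
        elif dark.shape[0] == 3 and planes.shape[0] != 3:  # one RGB frame
            dark_full = np.tile(dark, (planes.shape[0] // 3, 1, 1))
        else:
            dark_full = dark
        if dark_full.shape[-2:] != planes.shape[-2:]:
            raise ValueError(
                f"dark frame {dark.shape} does not match image geometry {planes.shape[-2:]}"
            )
        corrected = planes - dark_full
        brightest = corrected[
            int(np.argmax(corrected.reshape(corrected.shape[0], -1).mean(axis=1)))
        ]
        selector = (
            gaussian_filter(brightest, fg_smooth_sigma) if fg_smooth_sigma > 0 else brightest
        )
        thresh = np.quantile(selector, fg_threshold_quantile)
        fg = selector > thresh
        if not np.any(fg):
            raise ValueError(
                f"empty foreground for single-stain {fluor_name!r} at "
                f"quantile {fg_threshold_quantile}"
            )
        col = corrected[:, fg].mean(axis=1)
        if np.any(col < 0):
            warnings.warn(
                f"single-stain {fluor_name!r}: negative plane averages clamped to 0",
                stacklevel=2,
            )
            col = np.clip(col, 0.0, None)
        if col.max() <= 0:
            raise ValueError(f"single-stain {fluor_name!r}: no signal above dark level")
        columns[fluor_name] = col / col.max()
    assert row_labels is not None
    A = np.column_stack([columns[name] for name in columns])
    return FingerprintMatrix(A, row_labels, tuple(columns))
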