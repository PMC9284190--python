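"""The optical chain of a filterless cyclic-IF color imager.

The instrument images one LED at a time through a fixed five-window
("penta") emission filter onto an RGB CMOS sensor. Each LED carries its
own excitation band-pass (or short-pass) filter; no filters move between
channels. Six fluorochromes (DAPI, BV605, AF488, AF555, AF647, CF750)
are discriminated not by dedicated emission filters but by their joint
signature across (LED, sensor-channel) pairs -- the "fingerprint".

An :class:`OpticsConfig` bundles LEDs, fluorochromes, the penta filter
and the sensor response. Spectra are configuration data loaded from CSV
files referenced by a YAML config; :func:`load_default_optics` loads the
set shipped with the package (Gaussian-mixture approximations of the
published part numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .spectra import SpectralCurve

__all__ = [
    "LEDChannel",
    "Fluorochrome",
    "PentaFilter",
    "SensorResponse",
    "OpticsConfig",
    "load_optics",
    "load_default_optics",
    "LED_NAMES",
    "FLUOR_NAMES",
]

#: Fluorescence LED channels in canonical order (brightfield "BF" is
#: excluded from unmixing and not part of this list).
LED_NAMES = ("L385", "L470", "L567", "L627", "L720")

#: Default fluorochrome panel in canonical order.
FLUOR_NAMES = ("DAPI", "BV605", "AF488", "AF555", "AF647", "CF750")


@dataclass(frozen=True)
class LEDChannel:
    """One excitation channel: an LED plus its in-line excitation filter."""

    name: str
    emission: SpectralCurve
    excitation_filter: SpectralCurve

    def __post_init__(self) -> None:
        if self.excitation_filter.values.max() > 1.0 + 1e-9:
            raise ValueError(f"LED {self.name}: excitation filter transmission must be <= 1")

    def filtered_emission(self, grid_nm: np.ndarray) -> np.ndarray:
        """LED output after the excitation filter, on ``grid_nm``."""
        return (
            self.emission.resample(grid_nm).values
            * self.excitation_filter.resample(grid_nm).values
        )


@dataclass(frozen=True)
class Fluorochrome:
    """A fluorescent dye: excitation/emission spectra and relative brightness.

    ``brightness`` is a dimensionless proxy for quantum yield x extinction
    coefficient, relative to the panel; it scales the whole fingerprint
    column linearly.
    """

    name: str
    excitation: SpectralCurve
    emission: SpectralCurve
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.brightness <= 0:
            raise ValueError(f"fluorochrome {self.name}: brightness must be > 0")
        if self.emission.peak_nm < self.excitation.peak_nm:
            raise ValueError(
                f"fluorochrome {self.name}: emission peak ({self.emission.peak_nm} nm) "
                f"must be red of the excitation peak ({self.excitation.peak_nm} nm)"
            )


@dataclass(frozen=True)
class PentaFilter:
    """Multi-band emission filter: disjoint passbands, one transmission curve."""

    passbands: tuple[tuple[float, float], ...]
    transmission: SpectralCurve

    def __post_init__(self) -> None:
        bands = tuple((float(lo), float(hi)) for lo, hi in self.passbands)
        for lo, hi in bands:
            if hi <= lo:
                raise ValueError(f"passband ({lo}, {hi}): high edge must exceed low edge")
        for (_, hi_prev), (lo_next, _) in zip(bands, bands[1:]):
            if lo_next <= hi_prev:
                raise ValueError("passbands must be disjoint and sorted")
        if self.transmission.values.max() > 1.0 + 1e-9:
            raise ValueError("penta filter transmission must be <= 1")
        object.__setattr__(self, "passbands", bands)

    @property
    def n_windows(self) -> int:
        return len(self.passbands)

    def window_of(self, wavelength_nm: float) -> int | None:
        """Index of the passband containing ``wavelength_nm``, else None."""
        for i, (lo, hi) in enumerate(self.passbands):
            if lo <= wavelength_nm <= hi:
                return i
        return None

    def window_mask(self, grid_nm: np.ndarray, window: int) -> np.ndarray:
        lo, hi = self.passbands[window]
        return (grid_nm >= lo) & (grid_nm <= hi)


@dataclass(frozen=True)
class SensorResponse:
    """Relative sensitivity of the sensor's R, G and B channels."""

    r: SpectralCurve
    g: SpectralCurve
    b: SpectralCurve

    def __post_init__(self) -> None:
        for c in (self.r, self.g, self.b):
            if c.values.max() > 1.0 + 1e-9:
                raise ValueError(f"sensor channel {c.name!r}: sensitivity must be <= 1")

    @property
    def channels(self) -> tuple[SpectralCurve, SpectralCurve, SpectralCurve]:
        return (self.r, self.g, self.b)


@dataclass(frozen=True)
class OpticsConfig:
    """Complete optical model of the imager."""

    leds: tuple[LEDChannel, ...]
    fluors: tuple[Fluorochrome, ...]
    penta: PentaFilter
    sensor: SensorResponse
    #: fluorochrome name -> index of its nominal penta emission window
    nominal_windows: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        led_names = [led.name for led in self.leds]
        if len(set(led_names)) != len(led_names):
            raise ValueError(f"duplicate LED names: {led_names}")
        fluor_names = [f.name for f in self.fluors]
        if len(set(fluor_names)) != len(fluor_names):
            raise ValueError(f"duplicate fluorochrome names: {fluor_names}")

    @property
    def led_names(self) -> tuple[str, ...]:
        return tuple(led.name for led in self.leds)

    @property
    def fluor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fluors)

    def fluor(self, name: str) -> Fluorochrome:
        for f in self.fluors:
            if f.name == name:
                return f
        raise KeyError(f"unknown fluorochrome {name!r}; have {self.fluor_names}")


def _load_curve(base: Path, rel: str, name: str) -> SpectralCurve:
    path = base / rel
    if not path.exists():
        raise FileNotFoundError(f"spectra file not found: {path}")
    return SpectralCurve.from_csv(path, name=name)


def load_optics(config_path: str | Path) -> OpticsConfig:
    """Load an optics configuration from a YAML file.

    The YAML lists, per component, relative paths of ``wavelength_nm,value``
    CSV files::

        leds:
          L385: {emission: led_L385_emission.csv, filter: led_L385_filter.csv}
          ...
        fluorochromes:
          DAPI: {excitation: ..., emission: ..., brightness: 1.0, window: 0}
          ...
        penta:
          transmission: penta_transmission.csv
          passbands: [[414, 450], ...]
        sensor: {r: ..., g: ..., b: ...}
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    leds = tuple(
        LEDChannel(
            name=name,
            emission=_load_curve(base, spec["emission"], f"{name}_emission"),
            excitation_filter=_load_curve(base, spec["filter"], f"{name}_filter"),
        )
        for name, spec in cfg["leds"].items()
    )
    fluors = []
    nominal = {}
    for name, spec in cfg["fluorochromes"].items():
        fluors.append(
            Fluorochrome(
                name=name,
                excitation=_load_curve(base, spec["excitation"], f"{name}_excitation"),
                emission=_load_curve(base, spec["emission"], f"{name}_emission"),
                brightness=float(spec.get("brightness", 1.0)),
            )
        )
        if "window" in spec:
            nominal[name] = int(spec["window"])
    penta = PentaFilter(
        passbands=tuple((float(lo), float(hi)) for lo, hi in cfg["penta"]["passbands"]),
        transmission=_load_curve(base, cfg["penta"]["transmission"], "penta"),
    )
    sensor = SensorResponse(
        r=_load_curve(base, cfg["sensor"]["r"], "sensor_r"),
        g=_load_curve(base, cfg["sensor"]["g"], "sensor_g"),
        b=_load_curve(base, cfg["sensor"]["b"], "sensor_b"),
    )
    return OpticsConfig(
        leds=leds, fluors=tuple(fluors), penta=penta, sensor=sensor, nominal_windows=nominal
    )


def load_default_optics() -> OpticsConfig:
    """Load the default optics shipped with the package.

    The default set approximates a 5-LED (385/470/567/627/720 nm)
    side-illumination system with a 432/515/595/681/809 nm penta filter,
    an RGB CMOS sensor with near-infrared response, and the six-dye panel
    DAPI/BV605/AF488/AF555/AF647/CF750.
    """
    base = resources.files("pentaplex") / "data"
    return load_optics(Path(str(base)) / "default_optics.yaml")
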