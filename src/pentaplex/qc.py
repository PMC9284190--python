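"""Acquisition-quality metrics: SNR, coefficient of variation,
reference-free focus scoring, and bead-based daily calibration checks.

Conventions (stated here because published figures depend on them):
SNR = (foreground mean - background mean) / background SD; CV uses the
sample (n-1) standard deviation and is reported in percent. The focus
score is gradient energy (mean squared Sobel magnitude), a standard
reference-free sharpness functional that decreases monotonically under
Gaussian defocus of a structured image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel_h, sobel_v, threshold_otsu

__all__ = [
    "FocusStack",
    "QCReport",
    "snr",
    "cv",
    "focus_score",
    "select_focus_plane",
    "calibration_check",
]


@dataclass(frozen=True)
class FocusStack:
    """An ordered axial sweep of images at uniform step (default: seven
    planes, 150 um apart)."""

    planes: tuple[np.ndarray, ...]
    step_um: float = 150.0

    def __post_init__(self) -> None:
        if len(self.planes) < 2:
            raise ValueError("focus stack needs at least 2 planes")
        if self.step_um <= 0:
            raise ValueError("step_um must be > 0")
        shapes = {p.shape for p in self.planes}
        if len(shapes) != 1:
            raise ValueError(f"planes must share geometry, got {shapes}")
        object.__setattr__(self, "planes", tuple(np.asarray(p, float) for p in self.planes))

    @property
    def n_planes(self) -> int:
        return len(self.planes)


@dataclass
class QCReport:
    """Per-channel calibration metrics and pass/fail with reasons."""

    channels: dict[str, dict] = field(default_factory=dict)
    passed: bool = True
    reasons: list[str] = field(default_factory=list)

    def fail(self, reason: str) -> None:
        self.passed = False
        self.reasons.append(reason)

    def to_dict(self) -> dict:
        return {"passed": self.passed, "reasons": self.reasons, "channels": self.channels}


def snr(image: np.ndarray, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """(mean(fg) - mean(bg)) / sd(bg); infinite when the background has
    zero spread (flagged as ``inf`` rather than an error)."""
    image = np.asarray(image, float)
    fg_mask = np.asarray(fg_mask, bool)
    bg_mask = np.asarray(bg_mask, bool)
    if np.any(fg_mask & bg_mask):
        raise ValueError("foreground and background masks overlap")
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("foreground and background masks must be non-empty")
    bg_sd = float(np.std(image[bg_mask], ddof=1)) if bg_mask.sum() > 1 else 0.0
    diff = float(image[fg_mask].mean() - image[bg_mask].mean())
    if bg_sd == 0:
        return math.inf if diff != 0 else 0.0
    return diff / bg_sd


def cv(values: np.ndarray) -> float:
    """Coefficient of variation in percent, with sample (n-1) SD."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(np.std(values, ddof=1) / mean * 100.0)


def focus_score(image: np.ndarray) -> float:
    """Gradient-energy sharpness: mean squared Sobel gradient magnitude.

    Zero for a constant image; strictly decreasing under increasing
    Gaussian defocus of a structured image; scales quadratically under
    linear intensity rescaling, so plane *rankings* are rescale
    invariant.
    """
    image = np.asarray(image, float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.max() == image.min():
        return 0.0
    gh, gv = sobel_h(image), sobel_v(image)
    return float(np.mean(gh * gh + gv * gv))


def select_focus_plane(stack: FocusStack) -> tuple[int, list[float]]:
    """Index of the sharpest plane (ties -> lower index) and all scores."""
    scores = [focus_score(p) for p in stack.planes]
    return int(np.argmax(scores)), scores


def _detect_beads(image: np.ndarray, min_area: int = 5) -> np.ndarray:
    """Label bright discs on a composite image by Otsu threshold."""
    if image.max() <= image.min():
        return np.zeros(image.shape, dtype=np.int32)
    mask = image > threshold_otsu(image)
    labels, _ = ndi.label(mask)
    areas = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, labels.max() + 1))
    small = np.flatnonzero(areas < min_area) + 1
    if small.size:
        labels[np.isin(labels, small)] = 0
    return labels


def calibration_check(
    bead_stack,
    thresholds: dict[str, tuple[float, float]],
    *,
    min_beads: int = 3,
) -> QCReport:
    """Daily bead-slide calibration: per-LED SNR and bead-to-bead CV
    against ``{led: (min_snr, max_cv_percent)}`` thresholds.

    Beads are detected on the summed RGB composite of each LED after
    dark subtraction; only beads bright in a given LED (above background
    mean + 3 SD) contribute to that LED's statistics. Fails with a
    reason when no beads are detected or a channel misses its bounds.
    """
    report = QCReport()
    dark = bead_stack.dark_planes()
    planes = np.clip(bead_stack.signal_planes() - dark, 0.0, None)
    any_beads = False
    for i, led in enumerate(bead_stack.led_names):
        composite = planes[3 * i : 3 * i + 3].sum(axis=0)
        labels = _detect_beads(composite)
        bg_mask = labels == 0
        entry: dict = {"n_beads": 0, "snr": None, "cv_pct": None, "pass": True, "reason": ""}
        bead_ids = np.unique(labels[labels > 0])
        if bead_ids.size > 0:
            bead_means = ndi.mean(composite, labels, bead_ids)
            bg_mean = composite[bg_mask].mean()
            bg_sd = composite[bg_mask].std(ddof=1)
            bright = bead_means > bg_mean + 3 * max(bg_sd, 1e-12)
            n_bright = int(bright.sum())
            entry["n_beads"] = n_bright
            if n_bright >= min_beads:
                any_beads = True
                fg_mask = np.isin(labels, bead_ids[bright])
                entry["snr"] = snr(composite, fg_mask, bg_mask)
                entry["cv_pct"] = cv(bead_means[bright])
        if led in thresholds:
            min_snr, max_cv = thresholds[led]
            if entry["snr"] is None:
                entry["pass"] = False
                entry["reason"] = "no beads detected in channel"
            elif entry["snr"] < min_snr:
                entry["pass"] = False
                entry["reason"] = f"SNR {entry['snr']:.1f} < {min_snr}"
            elif entry["cv_pct"] is not None and entry["cv_pct"] > max_cv:
                entry["pass"] = False
                entry["reason"] = f"CV {entry['cv_pct']:.1f}% > {max_cv}%"
            if not entry["pass"]:
                report.fail(f"{led}: {entry['reason']}")
        report.channels[led] = entry
    if not any_beads:
        report.fail("no beads detected")
    return report
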