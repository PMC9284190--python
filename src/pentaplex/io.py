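"""Reading and writing run artifacts.

Acquisition stacks are multi-page TIFFs (page order: LED-major, then
R, G, B; then the 3 dark pages; then quenched pages if present) with a
JSON sidecar holding the metadata (cycle, LED names, mounting-transform
truth for simulations). Unmixed abundance images are one
single-channel TIFF per fluorochrome plus the residual. Label masks
are 16-bit TIFFs; cell tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .pipeline import RigidTransform
from .simulate import AcquisitionStack
from .unmix import FluorImageSet

__all__ = [
    "write_stack",
    "read_stack",
    "write_fluor_images",
    "read_fluor_images",
    "write_masks",
]


def _transform_to_json(tf: RigidTransform | None) -> dict | None:
    if tf is None:
        return None
    return {
        "rotation_rad": tf.rotation_rad,
        "translation_px": list(tf.translation_px),
        "reference_cycle": tf.reference_cycle,
    }


def _transform_from_json(d: dict | None) -> RigidTransform | None:
    if d is None:
        return None
    return RigidTransform(
        rotation_rad=d["rotation_rad"],
        translation_px=tuple(d["translation_px"]),
        reference_cycle=d.get("reference_cycle", 1),
    )


def write_stack(stack: AcquisitionStack, path: str | Path) -> Path:
    """Write one cycle's acquisition as TIFF + JSON sidecar."""
    path = Path(path)
    pages = [stack.stained, stack.dark]
    if stack.quenched is not None:
        pages.append(stack.quenched)
    data = np.concatenate(pages, axis=0).astype(np.float32)
    tifffile.imwrite(path, data)
    meta = {
        "cycle_index": stack.cycle_index,
        "led_names": list(stack.led_names),
        "has_quenched": stack.quenched is not None,
        "transform_truth": _transform_to_json(stack.transform_truth),
        "exposure_meta": stack.exposure_meta,
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path: str | Path) -> AcquisitionStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    try:
        data = tifffile.imread(path).astype(np.float64)
    except Exception as e:
        raise IOError(f"cannot read TIFF {path}: {e}") from e
    meta = json.loads(path.with_suffix(".json").read_text())
    n_led = len(meta["led_names"])
    n_sig = 3 * n_led
    stained = data[:n_sig]
    dark = data[n_sig : n_sig + 3]
    quenched = data[n_sig + 3 :] if meta["has_quenched"] else None
    return AcquisitionStack(
        cycle_index=meta["cycle_index"],
        stained=stained,
        dark=dark,
        led_names=tuple(meta["led_names"]),
        quenched=quenched,
        transform_truth=_transform_from_json(meta.get("transform_truth")),
        exposure_meta=meta.get("exposure_meta", {}),
    )


def write_fluor_images(images: FluorImageSet, out_dir: str | Path, prefix: str = "") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, img in images.images.items():
        p = out_dir / f"{prefix}{name}.tiff"
        tifffile.imwrite(p, img.astype(np.float32))
        written.append(p)
    p = out_dir / f"{prefix}residual.tiff"
    tifffile.imwrite(p, images.residual.astype(np.float32))
    written.append(p)
    return written


def read_fluor_images(out_dir: str | Path, fluor_names: list[str], prefix: str = "") -> FluorImageSet:
    out_dir = Path(out_dir)
    images = {
        name: tifffile.imread(out_dir / f"{prefix}{name}.tiff").astype(float)
        for name in fluor_names
    }
    residual = tifffile.imread(out_dir / f"{prefix}residual.tiff").astype(float)
    return FluorImageSet(images=images, residual=residual)


def write_masks(nucleus_labels: np.ndarray, cell_labels: np.ndarray, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "nucleus_labels.tiff", nucleus_labels.astype(np.uint16))
    tifffile.imwrite(out_dir / "cell_labels.tiff", cell_labels.astype(np.uint16))
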