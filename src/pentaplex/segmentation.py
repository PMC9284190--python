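"""Nucleus/cell segmentation with pluggable backends, and the cell-level
QC filter.

The reference backend is classical: threshold the cross-cycle DAPI
maximum-intensity projection, fill holes, split touching nuclei by
distance-transform watershed, and grow cell bodies by bounded dilation
(or a cytoplasm-guided watershed when a cytoplasm image is supplied).
Learned segmenters can be registered under their own backend name; any
callable ``(dapi_mip, cytoplasm_image, **params) -> LabelMasks``
qualifies.

QC follows the standard cyclic-IF rules: cells containing more than one
nucleus and cells with a nucleus-to-cell size ratio greater than 1 are
excluded; orphan nuclei and nucleus-free cells are dropped and logged
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

__all__ = ["LabelMasks", "segment", "qc_filter", "register_backend", "available_backends"]


@dataclass
class LabelMasks:
    """Integer nucleus and cell label images (0 = background) plus the
    nucleus -> cell assignment."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    nucleus_to_cell: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nucleus_labels.shape != self.cell_labels.shape:
            raise ValueError("nucleus and cell label images must share geometry")
        if not self.nucleus_to_cell:
            self.nucleus_to_cell = _map_nuclei_to_cells(
                self.nucleus_labels, self.cell_labels
            )

    @property
    def n_nuclei(self) -> int:
        return int(np.count_nonzero(np.unique(self.nucleus_labels)))

    @property
    def n_cells(self) -> int:
        return len(np.unique(self.cell_labels)) - (1 if (self.cell_labels == 0).any() else 0)


def _map_nuclei_to_cells(nuclei: np.ndarray, cells: np.ndarray) -> dict[int, int]:
    """Assign each nucleus to the cell label covering most of its pixels."""
    out: dict[int, int] = {}
    for nuc_label in np.unique(nuclei):
        if nuc_label == 0:
            continue
        overlap = cells[nuclei == nuc_label]
        vals, counts = np.unique(overlap, return_counts=True)
        out[int(nuc_label)] = int(vals[np.argmax(counts)])
    return out


def _watershed_backend(
    dapi_mip: np.ndarray,
    cytoplasm_image: np.ndarray | None = None,
    *,
    smooth_sigma: float = 1.0,
    min_nucleus_area: int = 20,
    cell_dilation_px: float = 5.0,
    min_peak_distance: int = 5,
    threshold: float | None = None,
) -> LabelMasks:
    """Classical DAPI watershed segmentation (the built-in reference)."""
    img = gaussian(np.asarray(dapi_mip, float), smooth_sigma, preserve_range=True)
    if img.max() <= img.min():
        z = np.zeros(img.shape, dtype=np.int32)
        return LabelMasks(z, z.copy(), {})
    thr = threshold if threshold is not None else threshold_otsu(img)
    fg = img > thr
    fg = ndi.binary_fill_holes(fg)
    lab, n_obj = ndi.label(fg)
    if n_obj:
        areas = ndi.sum_labels(np.ones_like(lab), lab, np.arange(1, n_obj + 1))
        small = np.flatnonzero(areas < min_nucleus_area) + 1
        if small.size:
            fg &= ~np.isin(lab, small)
    if not fg.any():
        z = np.zeros(img.shape, dtype=np.int32)
        return LabelMasks(z, z.copy(), {})

    dist = ndi.distance_transform_edt(fg)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(fg)
    nuclei = watershed(-dist, markers, mask=fg).astype(np.int32)

    # cell bodies: watershed from the nuclei, limited either by the
    # cytoplasm foreground or by a fixed dilation radius
    if cytoplasm_image is not None:
        cyto = gaussian(np.asarray(cytoplasm_image, float), smooth_sigma, preserve_range=True)
        cyto_thr = threshold_otsu(cyto) if cyto.max() > cyto.min() else np.inf
        cell_mask = (cyto > cyto_thr) | fg
    else:
        cell_mask = ndi.distance_transform_edt(nuclei == 0) <= cell_dilation_px
        cell_mask |= fg
    dist_out = ndi.distance_transform_edt(nuclei == 0)
    cells = watershed(dist_out, nuclei, mask=cell_mask).astype(np.int32)
    return LabelMasks(nucleus_labels=nuclei, cell_labels=cells)


_BACKENDS: dict[str, Callable[..., LabelMasks]] = {"watershed": _watershed_backend}


def register_backend(name: str, fn: Callable[..., LabelMasks]) -> None:
    """Register a segmentation backend (e.g. a learned segmenter wrapper)."""
    _BACKENDS[name] = fn


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def segment(
    dapi_mip: np.ndarray,
    cytoplasm_image: np.ndarray | None = None,
    backend: str = "watershed",
    **params,
) -> LabelMasks:
    """Segment nuclei and cells from the DAPI maximum-intensity projection."""
    dapi_mip = np.asarray(dapi_mip)
    if dapi_mip.size == 0:
        raise ValueError("dapi_mip is empty")
    if backend not in _BACKENDS:
        raise KeyError(
            f"unknown segmentation backend {backend!r}; registered: {available_backends()}"
        )
    return _BACKENDS[backend](dapi_mip, cytoplasm_image, **params)


def qc_filter(masks: LabelMasks) -> tuple[LabelMasks, dict[str, int]]:
    """Apply the cell-level QC rules.

    Excludes cells with more than one nucleus, cells whose
    nucleus-to-cell area ratio exceeds 1, cells without a nucleus, and
    nuclei without a cell. Returns filtered masks and a report counting
    each exclusion reason (in cells, except ``orphan_nucleus`` which
    counts nuclei). Idempotent.
    """
    nuclei = masks.nucleus_labels
    cells = masks.cell_labels
    n2c = masks.nucleus_to_cell

    nuc_areas = dict(
        zip(*np.unique(nuclei[nuclei > 0], return_counts=True))
    )
    cell_areas = dict(zip(*np.unique(cells[cells > 0], return_counts=True)))

    cell_nuclei: dict[int, list[int]] = {}
    orphan_nuclei = []
    for nuc, cell in n2c.items():
        if cell == 0 or cell not in cell_areas:
            orphan_nuclei.append(nuc)
        else:
            cell_nuclei.setdefault(cell, []).append(nuc)

    report = {"multi_nucleus": 0, "ratio_gt_1": 0, "no_nucleus": 0, "orphan_nucleus": len(orphan_nuclei)}
    keep_cells: set[int] = set()
    keep_nuclei: set[int] = set()
    for cell_label, area in cell_areas.items():
        nucs = cell_nuclei.get(int(cell_label), [])
        if len(nucs) == 0:
            report["no_nucleus"] += 1
            continue
        if len(nucs) > 1:
            report["multi_nucleus"] += 1
            continue
        nuc = nucs[0]
        if nuc_areas.get(nuc, 0) / area > 1.0:
            report["ratio_gt_1"] += 1
            continue
        keep_cells.add(int(cell_label))
        keep_nuclei.add(int(nuc))

    new_nuclei = np.where(np.isin(nuclei, sorted(keep_nuclei)), nuclei, 0).astype(np.int32)
    new_cells = np.where(np.isin(cells, sorted(keep_cells)), cells, 0).astype(np.int32)
    filtered = LabelMasks(
        nucleus_labels=new_nuclei,
        cell_labels=new_cells,
        nucleus_to_cell={n: c for n, c in n2c.items() if n in keep_nuclei},
    )
    return filtered, report
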