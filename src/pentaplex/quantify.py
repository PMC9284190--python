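"""Per-cell marker quantification, normalization, positivity calling and
phenotype classification.

The cell table pipeline is: mean abundance per cell and marker (nuclear
markers over the nucleus mask, membranous ones over the whole cell) ->
per-marker normalization (divide by the 10th percentile across cells,
winsorize above the 99th) -> positivity against the isotype-control
null (threshold = IgG mean + 3 SD on the same normalized scale, strict
inequality) -> rule-based phenotypes where the first matching rule
wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import LabelMasks
from .simulate import CyclePanel
from .unmix import FluorImageSet

__all__ = [
    "IgGStats",
    "quantify",
    "normalize",
    "igg_stats_from_table",
    "call_positivity",
    "classify_phenotypes",
    "RULES_TUMOR_IMMUNE",
    "RULES_MOSAIC",
]

#: CD45 vs the QUAD composite (HER2/EpCAM/MUC1/EGFR): immune cells are
#: CD45+, tumor cells express at least one QUAD marker without CD45.
RULES_TUMOR_IMMUNE: tuple[tuple[str, str], ...] = (
    ("immune", "CD45"),
    ("tumor", "(HER2 | EpCAM | MUC1 | EGFR) & ~CD45"),
)

#: Five-way tumor-cell mosaic over HER2/ER/PR/Ki67: cells positive for
#: several of the four, single-positive cells, and quad-negative cells.
RULES_MOSAIC: tuple[tuple[str, str], ...] = (
    ("multi-marker", "(HER2 + ER + PR + Ki67) >= 2"),
    ("Ki67-only", "Ki67"),
    ("HER2-only", "HER2"),
    ("ER/PR-only", "ER | PR"),
    ("quad-negative", "~(HER2 | ER | PR | Ki67)"),
)


@dataclass(frozen=True)
class IgGStats:
    """Null-staining statistics per fluorochrome channel, computed from
    isotype-control (IgG) intensities on the normalized scale."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("IgG statistics need at least 2 cells")
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("IgG standard deviations must be >= 0")

    def threshold(self, channel: str, k: float = 3.0) -> float:
        """Positivity threshold: mean + k*SD of the control channel."""
        return self.mean[channel] + k * self.sd[channel]


def _mean_per_label(image: np.ndarray, labels: np.ndarray, index: np.ndarray) -> np.ndarray:
    return ndi.mean(image, labels=labels, index=index)


def quantify(
    masks: LabelMasks,
    fluor_images: dict[int, FluorImageSet],
    panel: CyclePanel,
    *,
    nuclear_compartment: bool = True,
) -> pd.DataFrame:
    """Build the cell table: one row per retained cell with centroid,
    areas, and the mean abundance of every panel marker.

    ``fluor_images`` maps cycle index -> unmixed abundance images.
    Marker values are routed through the panel's (cycle, fluorochrome)
    assignment. With ``nuclear_compartment`` (default), nuclear markers
    are averaged over the nucleus mask instead of the whole cell.
    """
    cells = masks.cell_labels
    nuclei = masks.nucleus_labels
    cell_ids = np.unique(cells[cells > 0]).astype(int)
    if cell_ids.size == 0:
        cols = ["label", "centroid_row", "centroid_col", "nucleus_area_px", "cell_area_px"]
        return pd.DataFrame(columns=cols)

    centroids = ndi.center_of_mass(np.ones_like(cells), labels=cells, index=cell_ids)
    cell_areas = ndi.sum_labels(np.ones_like(cells), labels=cells, index=cell_ids)
    cell_to_nuc = {c: n for n, c in masks.nucleus_to_cell.items()}
    nuc_index = np.array([cell_to_nuc.get(int(c), 0) for c in cell_ids])
    nuc_areas = np.where(
        nuc_index > 0,
        ndi.sum_labels(np.ones_like(nuclei), labels=nuclei, index=np.maximum(nuc_index, 1)),
        0.0,
    )

    table = pd.DataFrame(
        {
            "label": cell_ids,
            "centroid_row": [r for r, _ in centroids],
            "centroid_col": [c for _, c in centroids],
            "nucleus_area_px": nuc_areas,
            "cell_area_px": cell_areas,
        }
    )

    for marker in panel.markers():
        cycle, fluor = panel.marker_channel(marker)
        if cycle not in fluor_images:
            raise KeyError(f"marker {marker!r}: no unmixed images for cycle {cycle}")
        image = fluor_images[cycle][fluor]
        if nuclear_compartment and marker in panel.nuclear_markers:
            vals = np.where(
                nuc_index > 0,
                _mean_per_label(image, nuclei, np.maximum(nuc_index, 1)),
                np.nan,
            )
        else:
            vals = _mean_per_label(image, cells, cell_ids)
        table[f"mean_{marker}"] = vals

    # DAPI (counterstain) from cycle 1 over the nucleus, as a QC column
    if 1 in fluor_images and "DAPI" in fluor_images[1].images:
        table["mean_DAPI"] = np.where(
            nuc_index > 0,
            _mean_per_label(fluor_images[1]["DAPI"], nuclei, np.maximum(nuc_index, 1)),
            np.nan,
        )
    return table


def normalize(
    table: pd.DataFrame,
    markers: list[str] | None = None,
    *,
    low_q: float = 0.10,
    high_q: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker normalization of cell mean intensities.

    Each marker's cell means are divided by their 10th percentile across
    cells (so a 'background' cell sits near 1) and winsorized at the
    99th percentile to suppress outliers. Returns the table with added
    ``norm_<marker>`` columns and a reference frame recording the two
    percentile values per marker.

    Raises for fewer than 10 cells or a zero 10th percentile
    ("degenerate baseline": add a noise-floor offset or check
    background subtraction).
    """
    markers = markers or [c[len("mean_") :] for c in table.columns if c.startswith("mean_")]
    if len(table) < 10:
        raise ValueError(f"need >= 10 cells to normalize, got {len(table)}")
    out = table.copy()
    refs = []
    for m in markers:
        vals = table[f"mean_{m}"].to_numpy(float)
        p_lo = float(np.nanpercentile(vals, low_q * 100))
        p_hi = float(np.nanpercentile(vals, high_q * 100))
        if p_lo <= 0:
            raise ValueError(
                f"degenerate baseline for {m!r}: {low_q:.0%} percentile is {p_lo}; "
                "consider adding a noise-floor offset"
            )
        norm = vals / p_lo
        norm = np.minimum(norm, p_hi / p_lo)  # winsorize at the high percentile
        out[f"norm_{m}"] = norm
        refs.append({"marker": m, "p_low": p_lo, "p_high": p_hi})
    return out, pd.DataFrame(refs).set_index("marker")


def igg_stats_from_table(table: pd.DataFrame, panel: CyclePanel) -> IgGStats:
    """Per-fluorochrome null statistics from the IgG-designated channels
    of the same run, on the normalized scale."""
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n = len(table)
    for cycle, fluor in sorted(panel.igg_controls):
        marker = panel.cycles[cycle - 1][fluor]
        col = f"norm_{marker}"
        if col not in table.columns:
            raise KeyError(f"IgG channel {marker!r} missing from table (column {col})")
        vals = table[col].to_numpy(float)
        mean[fluor] = float(np.nanmean(vals))
        sd[fluor] = float(np.nanstd(vals, ddof=1))
    if not mean:
        raise ValueError("panel designates no IgG controls")
    return IgGStats(mean=mean, sd=sd, n_cells=n)


def call_positivity(
    table: pd.DataFrame,
    igg: IgGStats | None,
    panel: CyclePanel,
    *,
    k_sd: float = 3.0,
    constant_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Call each marker positive when its normalized intensity strictly
    exceeds the matching channel's IgG mean + ``k_sd`` x SD.

    A marker's null channel is the IgG control carried on the same
    fluorochrome. Cells exactly at the threshold are negative. Returns
    the table with ``pos_<marker>`` columns and the threshold per marker.

    Without IgG statistics (``igg=None``) a user-supplied
    ``constant_threshold`` is applied to every marker, with a warning --
    a fallback for runs lacking an isotype-control cycle.
    """
    import warnings

    if igg is None:
        if constant_threshold is None:
            raise ValueError("need IgG statistics or a constant_threshold")
        warnings.warn(
            f"no IgG statistics: using constant threshold {constant_threshold} "
            "for every marker",
            stacklevel=2,
        )
    out = table.copy()
    thresholds: dict[str, float] = {}
    for marker in panel.markers():
        if marker.startswith("IgG"):
            continue
        if igg is None:
            thr = float(constant_threshold)
        else:
            _, fluor = panel.marker_channel(marker)
            if fluor not in igg.mean:
                raise KeyError(f"no IgG control for channel {fluor!r} (marker {marker!r})")
            thr = igg.threshold(fluor, k_sd)
        thresholds[marker] = thr
        out[f"pos_{marker}"] = out[f"norm_{marker}"].to_numpy(float) > thr
    return out, thresholds


def classify_phenotypes(
    table: pd.DataFrame,
    rules: tuple[tuple[str, str], ...] = RULES_TUMOR_IMMUNE,
    default: str = "other",
) -> pd.DataFrame:
    """Assign a phenotype per cell from ordered boolean rules.

    Rules are ``(label, expression)`` pairs evaluated over the marker
    positivity flags (as 0/1 integers), e.g. ``"CD45"``,
    ``"(HER2 | EpCAM) & ~CD45"`` or ``"(HER2 + ER + PR + Ki67) >= 2"``.
    The first matching rule wins; unmatched cells get ``default``.
    """
    flags = pd.DataFrame(
        {
            c[len("pos_") :]: table[c].astype("int8")
            for c in table.columns
            if c.startswith("pos_")
        }
    )
    out = table.copy()
    phenotype = pd.Series(default, index=table.index, dtype=object)
    assigned = pd.Series(False, index=table.index)
    for label, expr in rules:
        try:
            hit = flags.eval(expr)
        except Exception as e:
            raise ValueError(f"malformed phenotype rule {label!r}: {expr!r} ({e})") from e
        hit = pd.Series(np.asarray(hit).astype(bool), index=table.index)
        phenotype[hit & ~assigned] = label
        assigned |= hit
    out["phenotype"] = phenotype
    return out
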