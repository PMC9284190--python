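"""Optical forward simulator for cyclic multiplexed immunofluorescence.

Generates seeded synthetic slides (elliptical cells with contained
nuclei, or calibration beads) and renders per-cycle, per-LED RGB
acquisitions through the linear mixing model ``S = A F``, with shot
noise, read noise, dark offset, uniform autofluorescence, incomplete
quenching, and inter-cycle rigid misalignment. Every downstream stage
(registration, quench subtraction, unmixing, segmentation,
quantification, phenotyping) is validated against the ground truth this
module records.

Emulated study conditions: fine-needle-aspirate-like fields of a few
hundred to a few thousand cells at ~0.6 um/px, a 70/30 tumor/immune
mixture (tumor cells expressing HER2/EpCAM/MUC1/EGFR and hormone
receptors, immune cells CD45+), four staining cycles with a DAPI
counterstain in every cycle, and an IgG isotype-control cycle that
defines the null staining distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fingerprint import FingerprintMatrix
from .pipeline import RigidTransform, apply_alignment

__all__ = [
    "CellTruth",
    "Scene",
    "CyclePanel",
    "NoiseModel",
    "AcquisitionStack",
    "GeometryParams",
    "generate_scene",
    "render_acquisition",
    "render_run",
    "generate_bead_slide",
    "render_single_stain",
    "ground_truth_table",
    "defocus_stack",
    "default_panel",
    "DEFAULT_EXPRESSION",
    "NUCLEAR_MARKERS",
]

_COLOR_NAMES = ("R", "G", "B")

#: Markers quantified over the nucleus mask (transcription factors,
#: hormone receptors, proliferation); everything else is membranous /
#: cytoplasmic and is rendered on the cytoplasmic ring.
NUCLEAR_MARKERS = frozenset({"ER", "PR", "Ki67", "GATA3", "DAPI"})

#: Per-phenotype log-normal expression parameters ``(median, sigma_log)``
#: in abundance units (photoelectron-proportional). Markers absent from a
#: phenotype's table are expressed at the nonspecific-binding level only.
DEFAULT_EXPRESSION: dict[str, dict[str, tuple[float, float]]] = {
    "tumor": {
        "HER2": (150.0, 0.35),
        "EpCAM": (140.0, 0.35),
        "MUC1": (120.0, 0.35),
        "EGFR": (110.0, 0.35),
        "ER": (90.0, 0.4),
        "PR": (80.0, 0.4),
        "Ki67": (70.0, 0.5),
        "GATA3": (70.0, 0.4),
        "CK7": (90.0, 0.4),
        "TROP2": (80.0, 0.4),
    },
    "immune": {
        "CD45": (150.0, 0.35),
        "CD8": (60.0, 0.5),
    },
}

#: Median abundance of nonspecific antibody binding per cell and channel
#: (the IgG-control null level), and its log-sigma.
NONSPECIFIC = (3.0, 0.3)

#: DAPI counterstain level (median, sigma_log) per nucleus.
DAPI_LEVEL = (300.0, 0.2)


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth geometry and expression of one simulated cell."""

    center: tuple[float, float]  # (row, col) px
    cell_axes: tuple[float, float]  # semi-axes, px
    nucleus_axes: tuple[float, float]
    orientation: float  # radians
    phenotype: str
    marker_levels: dict[str, float] = field(default_factory=dict)
    dapi_level: float = 300.0

    def __post_init__(self) -> None:
        if self.nucleus_axes[0] > self.cell_axes[0] or self.nucleus_axes[1] > self.cell_axes[1]:
            raise ValueError("nucleus must be contained in the cell")
        if any(v < 0 for v in self.marker_levels.values()):
            raise ValueError("marker levels must be >= 0")


@dataclass(frozen=True)
class Scene:
    """Simulator ground truth: frame geometry and the cells in it."""

    width_px: int
    height_px: int
    cells: tuple[CellTruth, ...]
    autofluorescence_level: np.ndarray | float = 4.0  # per (LED,channel) row or scalar
    pixel_size_um: float = 0.6

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for cell in self.cells:
            r, c = cell.center
            if not (0 <= r < self.height_px and 0 <= c < self.width_px):
                raise ValueError(f"cell center {cell.center} outside frame")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def autofluorescence_rows(self, n_rows: int) -> np.ndarray:
        af = np.asarray(self.autofluorescence_level, dtype=float)
        if af.ndim == 0:
            return np.full(n_rows, float(af))
        if af.shape != (n_rows,):
            raise ValueError(f"autofluorescence must be scalar or length {n_rows}")
        return af


@dataclass(frozen=True)
class CyclePanel:
    """Cycle -> fluorochrome -> marker assignment.

    DAPI is a counterstain present in every cycle; any other marker may
    appear at most once across the panel. ``igg_controls`` designates
    (cycle, fluorochrome) pairs carrying isotype controls.
    """

    cycles: tuple[dict[str, str], ...]
    igg_controls: frozenset[tuple[int, str]] = frozenset()
    nuclear_markers: frozenset[str] = NUCLEAR_MARKERS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, cyc in enumerate(self.cycles, start=1):
            if cyc.get("DAPI") != "DAPI":
                raise ValueError(f"cycle {i}: DAPI counterstain must be assigned in every cycle")
            for fluor, marker in cyc.items():
                if marker == "DAPI":
                    continue
                if marker in seen:
                    raise ValueError(f"marker {marker!r} assigned more than once in the panel")
                seen.add(marker)
        for cycle, fluor in self.igg_controls:
            if not 1 <= cycle <= len(self.cycles):
                raise ValueError(f"IgG control references missing cycle {cycle}")
            if fluor not in self.cycles[cycle - 1]:
                raise ValueError(f"IgG control references unassigned fluorochrome {fluor!r}")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def markers(self) -> list[str]:
        """All non-DAPI markers in panel order."""
        out = []
        for cyc in self.cycles:
            out.extend(m for m in cyc.values() if m != "DAPI")
        return out

    def marker_channel(self, marker: str) -> tuple[int, str]:
        """(cycle, fluorochrome) carrying ``marker``."""
        for i, cyc in enumerate(self.cycles, start=1):
            for fluor, m in cyc.items():
                if m == marker and m != "DAPI":
                    return i, fluor
        raise KeyError(f"marker {marker!r} not in panel")

    def is_igg(self, cycle: int, fluor: str) -> bool:
        return (cycle, fluor) in self.igg_controls


def default_panel() -> CyclePanel:
    """Four-cycle breast-panel layout: three marker cycles plus one
    IgG-control cycle, DAPI counterstained throughout."""
    cycles = (
        {"DAPI": "DAPI", "AF488": "HER2", "BV605": "EpCAM", "AF555": "ER",
         "AF647": "PR", "CF750": "MUC1"},
        {"DAPI": "DAPI", "AF488": "EGFR", "BV605": "GATA3", "AF555": "CD45",
         "AF647": "Ki67", "CF750": "CK7"},
        {"DAPI": "DAPI", "AF488": "CD31", "BV605": "CD34", "AF555": "SMA",
         "AF647": "CD8", "CF750": "TROP2"},
        {"DAPI": "DAPI", "AF488": "IgG-AF488", "BV605": "IgG-BV605",
         "AF555": "IgG-AF555", "AF647": "IgG-AF647", "CF750": "IgG-CF750"},
    )
    igg = frozenset((4, f) for f in ("AF488", "BV605", "AF555", "AF647", "CF750"))
    return CyclePanel(cycles=cycles, igg_controls=igg)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise model: Poisson shot noise on the expected
    photoelectron-proportional signal, then Gaussian read noise, then a
    constant dark offset."""

    read_noise_sd: float = 2.0
    dark_offset: float = 100.0
    shot_noise: bool = True
    quench_residual_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.dark_offset < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.quench_residual_fraction < 1:
            raise ValueError("quench_residual_fraction must be in [0, 1)")

    @property
    def noiseless(self) -> bool:
        return not self.shot_noise and self.read_noise_sd == 0


@dataclass
class AcquisitionStack:
    """One cycle's raw acquisition: stained (and, except for the
    autofluorescence reference, quenched) per-LED RGB planes plus a dark
    frame. Planes are LED-major, (R, G, B) within each LED."""

    cycle_index: int
    stained: np.ndarray  # (n_led*3, H, W)
    dark: np.ndarray  # (3, H, W) single RGB dark frame
    led_names: tuple[str, ...]
    quenched: np.ndarray | None = None
    transform_truth: RigidTransform | None = None
    exposure_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stained.ndim != 3 or self.stained.shape[0] != 3 * len(self.led_names):
            raise ValueError(
                f"stained planes {self.stained.shape} inconsistent with "
                f"{len(self.led_names)} LEDs"
            )
        if self.dark.shape != (3, *self.stained.shape[1:]):
            raise ValueError("dark frame must be a single RGB image matching geometry")
        if self.quenched is not None and self.quenched.shape != self.stained.shape:
            raise ValueError("quenched planes must match stained geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stained.shape[1:]

    @property
    def row_labels(self) -> tuple[tuple[str, str], ...]:
        return tuple((led, c) for led in self.led_names for c in _COLOR_NAMES)

    def signal_planes(self) -> np.ndarray:
        return self.stained

    def dark_planes(self) -> np.ndarray:
        """Dark frame tiled to the (n_led*3, H, W) plane layout."""
        return np.tile(self.dark, (len(self.led_names), 1, 1))

    def dapi_window_image(self, dapi_led: str = "L385") -> np.ndarray:
        """G+B composite under the DAPI excitation LED, used for
        registration and (via the cross-cycle maximum) segmentation."""
        i = self.led_names.index(dapi_led)
        return self.stained[3 * i + 1] + self.stained[3 * i + 2]


@dataclass(frozen=True)
class GeometryParams:
    """Cell/nucleus ellipse geometry (px, at ~0.6 um/px)."""

    cell_radius_mean: float = 9.0
    cell_radius_sd: float = 1.2
    cell_eccentricity: float = 0.25  # max relative semi-axis asymmetry
    nucleus_fraction: float = 0.55  # nucleus semi-axis / cell semi-axis
    min_center_distance_factor: float = 2.6  # x cell_radius_mean


def _auto_frame(n_cells: int, geom: GeometryParams) -> int:
    d = geom.min_center_distance_factor * geom.cell_radius_mean
    side = int(math.ceil(math.sqrt(max(n_cells, 1) * d * d * 1.9))) + 2 * int(
        geom.cell_radius_mean * 3
    )
    return max(side, 64)


def generate_scene(
    n_cells: int,
    phenotype_mix: dict[str, float] | None = None,
    geometry_params: GeometryParams | None = None,
    expression_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    *,
    shape: tuple[int, int] | None = None,
    markers: list[str] | None = None,
    autofluorescence_level: float = 4.0,
    max_tries_per_cell: int = 200,
) -> Scene:
    """Place ``n_cells`` elliptical cells with rejection-sampled,
    non-overlapping nucleus centers and draw per-phenotype log-normal
    marker levels. Deterministic given ``seed``.

    Every cell additionally carries a small nonspecific-binding level on
    each panel marker (including IgG controls), so that null channels
    have a realistic non-zero baseline.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    phenotype_mix = phenotype_mix or {"tumor": 0.7, "immune": 0.3}
    total = sum(phenotype_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"phenotype fractions must sum to 1 (got {total})")
    geom = geometry_params or GeometryParams()
    expr = expression_params or DEFAULT_EXPRESSION
    if markers is None:
        markers = default_panel().markers()
    rng = np.random.default_rng(seed)

    if shape is None:
        side = _auto_frame(n_cells, geom)
        shape = (side, side)
    H, W = shape
    margin = geom.cell_radius_mean * (1 + geom.cell_eccentricity) + 3 * geom.cell_radius_sd
    if n_cells > 0 and (H <= 2 * margin or W <= 2 * margin):
        raise ValueError(f"frame {shape} too small for cells of this size")

    min_d2 = (geom.min_center_distance_factor * geom.cell_radius_mean) ** 2
    labels = sorted(phenotype_mix)
    probs = np.array([phenotype_mix[k] for k in labels])
    phenos = rng.choice(len(labels), size=n_cells, p=probs)

    centers: list[tuple[float, float]] = []
    cells: list[CellTruth] = []
    placed = np.empty((0, 2))
    for i in range(n_cells):
        for _ in range(max_tries_per_cell):
            r = rng.uniform(margin, H - margin)
            c = rng.uniform(margin, W - margin)
            if placed.shape[0] == 0 or np.min(
                (placed[:, 0] - r) ** 2 + (placed[:, 1] - c) ** 2
            ) >= min_d2:
                break
        else:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n_cells} after {max_tries_per_cell} tries; "
                "use a larger frame or fewer cells"
            )
        placed = np.vstack([placed, [r, c]])
        radius = max(rng.normal(geom.cell_radius_mean, geom.cell_radius_sd), 3.0)
        ecc = rng.uniform(0, geom.cell_eccentricity)
        cell_axes = (radius * (1 + ecc), radius * (1 - ecc))
        nucleus_axes = (cell_axes[0] * geom.nucleus_fraction, cell_axes[1] * geom.nucleus_fraction)
        pheno = labels[phenos[i]]
        table = expr.get(pheno, {})
        levels: dict[str, float] = {}
        for m in markers:
            med, sig = table.get(m, NONSPECIFIC)
            levels[m] = float(rng.lognormal(math.log(med), sig))
        cells.append(
            CellTruth(
                center=(r, c),
                cell_axes=cell_axes,
                nucleus_axes=nucleus_axes,
                orientation=float(rng.uniform(0, math.pi)),
                phenotype=pheno,
                marker_levels=levels,
                dapi_level=float(rng.lognormal(math.log(DAPI_LEVEL[0]), DAPI_LEVEL[1])),
            )
        )
    return Scene(
        width_px=W,
        height_px=H,
        cells=tuple(cells),
        autofluorescence_level=autofluorescence_level,
    )


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation: float,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Boolean ellipse mask restricted to its bounding box."""
    H, W = shape
    r0, c0 = center
    a, b = axes
    ext = max(a, b) + 1.5
    rs = slice(max(int(r0 - ext), 0), min(int(r0 + ext) + 2, H))
    cs = slice(max(int(c0 - ext), 0), min(int(c0 + ext) + 2, W))
    rr, cc = np.mgrid[rs, cs]
    dr, dc = rr - r0, cc - c0
    cos_t, sin_t = math.cos(orientation), math.sin(orientation)
    u = dr * cos_t + dc * sin_t
    v = -dr * sin_t + dc * cos_t
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0, (rs, cs)


def cell_masks(scene: Scene, cell: CellTruth):
    """(nucleus_mask, cell_mask, window) restricted to the cell bounding box."""
    nuc, win = _ellipse_mask(scene.shape, cell.center, cell.nucleus_axes, cell.orientation)
    outer, win2 = _ellipse_mask(scene.shape, cell.center, cell.cell_axes, cell.orientation)
    # nucleus window is contained in the cell window; re-embed
    full_nuc = np.zeros_like(outer)
    r_off = win[0].start - win2[0].start
    c_off = win[1].start - win2[1].start
    full_nuc[r_off : r_off + nuc.shape[0], c_off : c_off + nuc.shape[1]] = nuc
    return full_nuc, outer, win2


def abundance_images(
    scene: Scene,
    panel: CyclePanel,
    cycle: int,
    fluor_order: tuple[str, ...],
) -> np.ndarray:
    """Per-fluorochrome true abundance images for one cycle's fresh stain.

    DAPI is painted on nuclei; nuclear markers on the nucleus, membrane
    markers on the cytoplasmic ring. IgG control channels receive the
    nonspecific level only (which is what their marker level already is).
    """
    if not 1 <= cycle <= panel.n_cycles:
        raise ValueError(f"cycle {cycle} outside panel (1..{panel.n_cycles})")
    assignment = panel.cycles[cycle - 1]
    for fluor in assignment:
        if fluor not in fluor_order:
            raise KeyError(f"fluorochrome {fluor!r} has no fingerprint column")
    F = np.zeros((len(fluor_order), *scene.shape), dtype=np.float64)
    idx = {name: i for i, name in enumerate(fluor_order)}
    for cell in scene.cells:
        nuc, outer, win = cell_masks(scene, cell)
        ring = outer & ~nuc
        for fluor, marker in assignment.items():
            j = idx[fluor]
            if marker == "DAPI":
                F[j][win][nuc[:]] += cell.dapi_level
                continue
            level = cell.marker_levels.get(marker, 0.0)
            if level == 0.0:
                continue
            target = nuc if marker in panel.nuclear_markers else ring
            F[j][win][target[:]] += level
    return F


def _fresh_plus_residual(
    scene: Scene,
    panel: CyclePanel,
    cycle: int,
    fluor_order: tuple[str, ...],
    qrf: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(total abundance seen by the stained image of ``cycle``, the
    pre-existing residual component). Residuals accumulate geometrically:
    what survives quenching of cycle n-1 is still present in cycle n."""
    residual = np.zeros((len(fluor_order), *scene.shape))
    for prev in range(1, cycle):
        residual = qrf * (residual + abundance_images(scene, panel, prev, fluor_order))
    fresh = abundance_images(scene, panel, cycle, fluor_order) if cycle >= 1 else residual * 0
    return fresh + residual, residual


def _capture(
    expected: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply the camera model: Poisson shot noise, Gaussian read noise,
    dark offset; clipped at zero like an unsigned sensor output."""
    out = rng.poisson(np.clip(expected, 0, None)).astype(float) if noise.shot_noise else expected.astype(float)
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    out = out + noise.dark_offset
    return np.clip(out, 0.0, None)


def render_acquisition(
    scene: Scene,
    panel: CyclePanel,
    cycle: int,
    A: FingerprintMatrix,
    noise: NoiseModel,
    transform: RigidTransform | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> AcquisitionStack:
    """Render one cycle's acquisition (stained + quenched planes).

    ``cycle = 0`` renders the unstained autofluorescence reference.
    The expected signal is ``A @ F`` per pixel plus the scene's uniform
    autofluorescence; planes are warped by ``transform`` (the cycle's
    mounting error), then passed through the camera noise model. The
    quenched planes repeat the render with all fluorochrome abundances
    multiplied by ``quench_residual_fraction``.
    """
    transform = transform or RigidTransform()
    if rng is None:
        rng = np.random.default_rng(noise.seed + 7919 * max(cycle, 0))
    n_rows = A.n_rows
    af = scene.autofluorescence_rows(n_rows)
    H, W = scene.shape

    def expected_planes(F: np.ndarray) -> np.ndarray:
        S = np.tensordot(A.A, F, axes=(1, 0))
        return S + af[:, None, None]

    def warped(S: np.ndarray) -> np.ndarray:
        if transform.is_identity:
            return S
        out = apply_alignment(S, transform.inverse())
        oob = np.mean(out[0] == 0.0)
        if oob > 0.2:
            raise ValueError(
                f"transform pushes {oob:.0%} of the frame out of bounds (> 20%)"
            )
        return out

    dark = _capture(np.zeros((3, H, W)), noise, rng)

    if cycle == 0:
        F0 = np.zeros((A.n_fluors, H, W))
        stained = _capture(warped(expected_planes(F0)), noise, rng)
        return AcquisitionStack(
            cycle_index=0,
            stained=stained,
            dark=dark,
            led_names=A.led_names,
            quenched=None,
            transform_truth=transform,
        )

    qrf = noise.quench_residual_fraction
    F_total, _ = _fresh_plus_residual(scene, panel, cycle, A.col_labels, qrf)
    stained = _capture(warped(expected_planes(F_total)), noise, rng)
    quenched = _capture(warped(expected_planes(qrf * F_total)), noise, rng)
    return AcquisitionStack(
        cycle_index=cycle,
        stained=stained,
        dark=dark,
        led_names=A.led_names,
        quenched=quenched,
        transform_truth=transform,
        exposure_meta={"seed": noise.seed},
    )


def render_run(
    scene: Scene,
    panel: CyclePanel,
    A: FingerprintMatrix,
    noise: NoiseModel,
    transforms: list[RigidTransform] | None = None,
) -> list[AcquisitionStack]:
    """Render the autofluorescence reference (cycle 0) and every panel
    cycle with per-cycle mounting transforms (cycle 1 and the reference
    share the identity by convention)."""
    n = panel.n_cycles
    if transforms is None:
        rng = np.random.default_rng(noise.seed + 104729)
        transforms = [RigidTransform()]  # reference cycle
        for _ in range(n - 1):
            transforms.append(
                RigidTransform(
                    rotation_rad=float(rng.uniform(-0.6, 0.6) * math.pi / 180),
                    translation_px=(float(rng.uniform(-6, 6)), float(rng.uniform(-6, 6))),
                )
            )
    if len(transforms) != n:
        raise ValueError(f"need {n} transforms, got {len(transforms)}")
    rng_master = np.random.default_rng(noise.seed)
    stacks = [
        render_acquisition(scene, panel, 0, A, noise, RigidTransform(), rng=rng_master)
    ]
    for cycle in range(1, n + 1):
        stacks.append(
            render_acquisition(
                scene, panel, cycle, A, noise, transforms[cycle - 1], rng=rng_master
            )
        )
    return stacks


def render_single_stain(
    scene: Scene,
    fluor: str,
    A: FingerprintMatrix,
    noise: NoiseModel,
    *,
    level: float = 150.0,
    rng: np.random.Generator | None = None,
) -> AcquisitionStack:
    """Render a calibration slide stained with a single fluorochrome.

    Every cell carries only ``fluor`` (on the nucleus for DAPI, the
    whole cell otherwise) at ``level`` scaled by the cell's relative
    DAPI brightness, emulating the single-stain controls used to
    measure the unmixing matrix. The scene's autofluorescence setting
    is honored; use 0 for clean calibration slides.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    j = A.col_labels.index(fluor)
    F = np.zeros((A.n_fluors, *scene.shape))
    for cell in scene.cells:
        nuc, outer, win = cell_masks(scene, cell)
        target = nuc if fluor == "DAPI" else outer
        F[j][win][target[:]] += level * cell.dapi_level / DAPI_LEVEL[0]
    af = scene.autofluorescence_rows(A.n_rows)
    S = np.tensordot(A.A, F, axes=(1, 0)) + af[:, None, None]
    stained = _capture(S, noise, rng)
    dark = _capture(np.zeros((3, *scene.shape)), noise, rng)
    return AcquisitionStack(
        cycle_index=1,
        stained=stained,
        dark=dark,
        led_names=A.led_names,
        transform_truth=RigidTransform(),
        exposure_meta={"single_stain": fluor},
    )


def generate_bead_slide(
    n_beads: int,
    bead_intensity_per_fluor: dict[str, float],
    A: FingerprintMatrix,
    noise: NoiseModel,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (512, 512),
    bead_radius_px: float = 4.0,
) -> tuple[AcquisitionStack, pd.DataFrame]:
    """Render a calibration slide of single-fluorochrome beads.

    ``n_beads`` beads *per listed fluorochrome* are placed as uniform
    discs. Returns the acquisition and a truth table (bead center,
    fluorochrome, intensity).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    H, W = shape
    margin = bead_radius_px + 2
    min_d2 = (6 * bead_radius_px) ** 2
    F = np.zeros((A.n_fluors, H, W))
    placed = np.empty((0, 2))
    records = []
    for fluor, intensity in bead_intensity_per_fluor.items():
        j = A.col_labels.index(fluor)
        for _ in range(n_beads):
            for _ in range(500):
                r = rng.uniform(margin, H - margin)
                c = rng.uniform(margin, W - margin)
                if placed.shape[0] == 0 or np.min(
                    (placed[:, 0] - r) ** 2 + (placed[:, 1] - c) ** 2
                ) >= min_d2:
                    break
            else:
                raise RuntimeError("could not place beads; enlarge the frame")
            placed = np.vstack([placed, [r, c]])
            mask, win = _ellipse_mask(shape, (r, c), (bead_radius_px, bead_radius_px), 0.0)
            F[j][win][mask[:]] = intensity
            records.append({"row": r, "col": c, "fluor": fluor, "intensity": intensity})
    S = np.tensordot(A.A, F, axes=(1, 0))
    stained = _capture(S, noise, rng)
    dark = _capture(np.zeros((3, H, W)), noise, rng)
    stack = AcquisitionStack(
        cycle_index=1, stained=stained, dark=dark, led_names=A.led_names,
        transform_truth=RigidTransform(),
    )
    return stack, pd.DataFrame.from_records(records)


def ground_truth_table(scene: Scene) -> pd.DataFrame:
    """One row per cell: centroid, phenotype, and true marker levels
    (columns ``true_<marker>``). The oracle for end-to-end accuracy."""
    records = []
    for i, cell in enumerate(scene.cells, start=1):
        rec = {
            "cell_id": i,
            "row": cell.center[0],
            "col": cell.center[1],
            "phenotype": cell.phenotype,
            "dapi_level": cell.dapi_level,
        }
        for m, v in cell.marker_levels.items():
            rec[f"true_{m}"] = v
        records.append(rec)
    cols = ["cell_id", "row", "col", "phenotype", "dapi_level"]
    if records:
        extra = [k for k in records[0] if k not in cols]
        return pd.DataFrame.from_records(records, columns=cols + extra)
    return pd.DataFrame(columns=cols)


def defocus_stack(
    image: np.ndarray,
    n_planes: int = 7,
    step_um: float = 150.0,
    focus_index: int = 3,
    blur_um_per_sigma_px: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Simulate an axial focus sweep by Gaussian defocus blur.

    Plane ``i`` is blurred with sigma proportional to its axial distance
    ``|i - focus_index| * step_um``; the in-focus plane is unblurred.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    planes = []
    for i in range(n_planes):
        sigma = abs(i - focus_index) * step_um / blur_um_per_sigma_px
        plane = gaussian_filter(np.asarray(image, float), sigma) if sigma > 0 else np.asarray(image, float).copy()
        if noise_sd > 0:
            plane = plane + rng.normal(0, noise_sd, plane.shape)
        planes.append(plane)
    return planes
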