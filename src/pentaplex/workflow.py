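"""End-to-end orchestration: simulate a run, analyze a run, summarize a
cohort.

``analyze_stacks`` executes the full fixed-order pipeline on in-memory
acquisitions:

    dark -> align (DAPI window, ORB + RANSAC) -> quench-subtract
         -> unmix -> segment (DAPI MIP) -> QC filter -> quantify
         -> normalize -> call positivity (IgG) -> classify phenotypes

and records a machine-readable provenance log of every parameter and
per-stage outcome. The CLI in :mod:`pentaplex.cli` is a thin wrapper
over these functions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .fingerprint import FingerprintMatrix, fingerprint_from_optics
from .optics import load_default_optics
from .pipeline import (
    RigidTransform,
    apply_alignment,
    dapi_max_projection,
    estimate_alignment,
    quench_subtract,
    subtract_dark,
)
from .quantify import (
    RULES_TUMOR_IMMUNE,
    call_positivity,
    classify_phenotypes,
    igg_stats_from_table,
    normalize,
    quantify,
)
from .segmentation import LabelMasks, qc_filter, segment
from .simulate import (
    AcquisitionStack,
    CyclePanel,
    NoiseModel,
    Scene,
    default_panel,
    generate_scene,
    ground_truth_table,
    render_run,
)
from .unmix import FluorImageSet, unmix_image

__all__ = ["AnalysisResult", "simulate_run", "analyze_stacks", "analyze_dir", "cohort_summary"]


@dataclass
class AnalysisResult:
    """Everything the analysis pipeline produced for one sample."""

    cell_table: pd.DataFrame
    masks: LabelMasks
    fluor_images: dict[int, FluorImageSet]
    transforms: dict[int, RigidTransform]
    norm_refs: pd.DataFrame
    thresholds: dict[str, float]
    qc_report: dict[str, int]
    provenance: dict = field(default_factory=dict)


def simulate_run(
    n_cells: int = 500,
    seed: int = 1,
    *,
    panel: CyclePanel | None = None,
    noise: NoiseModel | None = None,
    A: FingerprintMatrix | None = None,
    phenotype_mix: dict[str, float] | None = None,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[Scene, list[AcquisitionStack], FingerprintMatrix, CyclePanel]:
    """Generate a seeded synthetic slide and render all cycles.

    With ``out_dir``, stacks are written as TIFF+JSON (cycle_00.tiff is
    the autofluorescence reference) alongside the scene truth table and
    the fingerprint matrix.
    """
    panel = panel or default_panel()
    noise = noise or NoiseModel(seed=seed)
    if noise.seed != seed:
        noise = NoiseModel(
            read_noise_sd=noise.read_noise_sd,
            dark_offset=noise.dark_offset,
            shot_noise=noise.shot_noise,
            quench_residual_fraction=noise.quench_residual_fraction,
            seed=seed,
        )
    if A is None:
        A = fingerprint_from_optics(load_default_optics())
    scene = generate_scene(
        n_cells, phenotype_mix=phenotype_mix, seed=seed, markers=panel.markers()
    )
    stacks = render_run(scene, panel, A, noise)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for stack in stacks:
            p = out_dir / f"cycle_{stack.cycle_index:02d}.tiff"
            if p.exists() and not overwrite:
                raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
            pio.write_stack(stack, p)
        ground_truth_table(scene).to_csv(out_dir / "truth.csv", index=False)
        A.to_csv(out_dir / "fingerprint.csv")
    return scene, stacks, A, panel


def analyze_stacks(
    stacks: list[AcquisitionStack],
    A: FingerprintMatrix,
    panel: CyclePanel,
    *,
    segmentation_backend: str = "watershed",
    segmentation_params: dict | None = None,
    phenotype_rules=RULES_TUMOR_IMMUNE,
    noise_floor: float | None = None,
    registration_seed: int = 0,
) -> AnalysisResult:
    """Run the full analysis pipeline on per-cycle acquisitions.

    ``stacks`` must contain the cycle-0 autofluorescence reference and
    every panel cycle. Cycle 1 is the registration reference.
    """
    t0 = time.perf_counter()
    prov: dict = {"stages": [], "parameters": {
        "segmentation_backend": segmentation_backend,
        "noise_floor": noise_floor,
        "phenotype_rules": [list(r) for r in phenotype_rules],
    }}
    by_cycle = {s.cycle_index: s for s in stacks}
    n_cycles = panel.n_cycles
    for c in range(0, n_cycles + 1):
        if c not in by_cycle:
            raise ValueError(f"missing acquisition for cycle {c}")

    # 1) dark subtraction (stained and quenched planes alike)
    dark_corr: dict[int, dict[str, np.ndarray]] = {}
    for c, stack in by_cycle.items():
        dark = stack.dark_planes()
        entry = {"stained": subtract_dark(stack.stained, dark)}
        if stack.quenched is not None:
            entry["quenched"] = subtract_dark(stack.quenched, dark)
        dark_corr[c] = entry
    prov["stages"].append({"stage": "dark", "cycles": sorted(by_cycle)})

    # 2) rigid alignment of every cycle to cycle 1 via the DAPI window
    def dapi_window(planes: np.ndarray, stack: AcquisitionStack) -> np.ndarray:
        i = stack.led_names.index("L385")
        return planes[3 * i + 1] + planes[3 * i + 2]

    reference = dapi_window(dark_corr[1]["stained"], by_cycle[1])
    transforms: dict[int, RigidTransform] = {0: RigidTransform(), 1: RigidTransform()}
    aligned: dict[int, dict[str, np.ndarray]] = {}
    for c in range(0, n_cycles + 1):
        if c <= 1:
            aligned[c] = dark_corr[c]
            continue
        moving = dapi_window(dark_corr[c]["stained"], by_cycle[c])
        tf, n_inliers = estimate_alignment(moving, reference, seed=registration_seed)
        transforms[c] = tf
        aligned[c] = {
            kind: apply_alignment(planes, tf) for kind, planes in dark_corr[c].items()
        }
        prov["stages"].append(
            {
                "stage": "align",
                "cycle": c,
                "rotation_rad": tf.rotation_rad,
                "translation_px": list(tf.translation_px),
                "inliers": n_inliers,
            }
        )

    # 3) quench subtraction: cycle n minus quenched n-1 (cycle 1 minus
    # the autofluorescence reference)
    corrected: dict[int, np.ndarray] = {}
    # tolerate sign flips of pure noise when counting clamped pixels:
    # ~5 read-noise SDs estimated from the reference dark frame
    dark_ref = by_cycle[1].dark
    noise_tol = 5.0 * float(np.median(np.std(dark_ref, axis=(1, 2))))
    for c in range(1, n_cycles + 1):
        background = aligned[c - 1]["quenched" if c > 1 else "stained"]
        corrected[c], clamp = quench_subtract(
            aligned[c]["stained"], background, noise_tol=noise_tol
        )
        prov["stages"].append({"stage": "quench_subtract", "cycle": c, "clamp_fraction": clamp})

    # 4) spectral unmixing per cycle
    fluor_images = {
        c: unmix_image(corrected[c], A, noise_floor=noise_floor)
        for c in range(1, n_cycles + 1)
    }
    prov["stages"].append({"stage": "unmix", "n_fluors": A.n_fluors})

    # 5) segmentation on the cross-cycle DAPI maximum projection
    mip = dapi_max_projection([fluor_images[c]["DAPI"] for c in fluor_images])
    masks = segment(mip, backend=segmentation_backend, **(segmentation_params or {}))
    masks, qc_report = qc_filter(masks)
    prov["stages"].append(
        {"stage": "segment", "n_cells": masks.n_cells, "qc_exclusions": qc_report}
    )

    # 6) quantification, normalization, positivity, phenotypes
    table = quantify(masks, fluor_images, panel)
    table, norm_refs = normalize(table)
    igg = igg_stats_from_table(table, panel)
    table, thresholds = call_positivity(table, igg, panel)
    table = classify_phenotypes(table, phenotype_rules)
    prov["stages"].append({"stage": "cell_table", "n_cells": len(table)})
    prov["elapsed_s"] = time.perf_counter() - t0

    return AnalysisResult(
        cell_table=table,
        masks=masks,
        fluor_images=fluor_images,
        transforms=transforms,
        norm_refs=norm_refs,
        thresholds=thresholds,
        qc_report=qc_report,
        provenance=prov,
    )


def analyze_dir(
    in_dir: str | Path,
    A: FingerprintMatrix | None = None,
    panel: CyclePanel | None = None,
    **kwargs,
) -> AnalysisResult:
    """Analyze a directory of ``cycle_NN.tiff`` stacks (as written by
    :func:`simulate_run`)."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("cycle_*.tiff"))
    if not paths:
        raise FileNotFoundError(f"no cycle_*.tiff stacks in {in_dir}")
    stacks = [pio.read_stack(p) for p in paths]
    if A is None:
        fp = in_dir / "fingerprint.csv"
        A = FingerprintMatrix.from_csv(fp) if fp.exists() else fingerprint_from_optics(load_default_optics())
    panel = panel or default_panel()
    return analyze_stacks(stacks, A, panel, **kwargs)


def cohort_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-sample positive fractions and phenotype counts.

    ``tables`` maps sample name -> cell table (with ``pos_*`` and
    ``phenotype`` columns). Samples must share marker columns; empty
    tables are excluded with a warning. Returns one row per sample.
    """
    import warnings

    rows = []
    marker_sets = {}
    for name, tbl in tables.items():
        if len(tbl) == 0:
            warnings.warn(f"sample {name!r}: empty cell table excluded", stacklevel=2)
            continue
        markers = sorted(c[len("pos_") :] for c in tbl.columns if c.startswith("pos_"))
        marker_sets[name] = markers
    if not marker_sets:
        raise ValueError("no non-empty cell tables")
    ref = next(iter(marker_sets.values()))
    mismatched = {n: m for n, m in marker_sets.items() if m != ref}
    if mismatched:
        raise ValueError(f"marker sets differ across samples: {sorted(mismatched)}")

    for name, tbl in tables.items():
        if name not in marker_sets:
            continue
        row: dict = {"sample": name, "n_cells": len(tbl)}
        for m in ref:
            row[f"frac_pos_{m}"] = float(tbl[f"pos_{m}"].mean())
        if "phenotype" in tbl.columns:
            for ph, count in tbl["phenotype"].value_counts().items():
                row[f"n_{ph}"] = int(count)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)
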