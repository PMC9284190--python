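"""Per-pixel bounded linear least-squares spectral unmixing.

The mixing model is ``S = A F`` with ``S`` the stacked (LED, R/G/B)
signal vector, ``A`` the fingerprint matrix and ``F >= 0`` the
fluorochrome abundances. Each pixel solves

    min_{f >= 0} || A f - s ||_2

Single pixels go through scipy's active-set NNLS. Whole images use a
vectorized solver that enumerates candidate active sets (there are only
``2^n_fluor``) and accepts a pixel's solution when it satisfies the
KKT conditions -- primal feasibility ``f >= 0`` on the support and
non-negative gradient off it -- which for this convex problem certifies
global optimality. Supports are visited from largest to smallest so
most pixels resolve immediately on the unconstrained solution.

Unmixing dominates pipeline runtime on real data, so the image path is
fully vectorized, processes pixels in tiles, and can skip pixels below
a noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .fingerprint import FingerprintMatrix, window_signal_fractions
from .optics import OpticsConfig

__all__ = [
    "AbundanceVector",
    "FluorImageSet",
    "unmix_pixel",
    "unmix_image",
    "bleedthrough_fraction",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Non-negative abundances for one pixel plus the fit residual."""

    f: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        if np.any(self.f < 0) or self.residual_norm < 0:
            raise ValueError("abundances and residual must be >= 0")


@dataclass
class FluorImageSet:
    """Per-fluorochrome abundance images plus the residual-norm image."""

    images: dict[str, np.ndarray]
    residual: np.ndarray

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()} | {self.residual.shape}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent image geometries: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.residual.shape

    def __getitem__(self, fluor: str) -> np.ndarray:
        return self.images[fluor]


def unmix_pixel(s: np.ndarray, A: FingerprintMatrix) -> AbundanceVector:
    """Solve one pixel exactly with active-set NNLS."""
    s = np.asarray(s, dtype=float).ravel()
    if s.size != A.n_rows:
        raise ValueError(f"signal length {s.size} != {A.n_rows} fingerprint rows")
    if not np.all(np.isfinite(s)):
        raise ValueError("signal vector contains non-finite values")
    if np.linalg.matrix_rank(A.A) < A.n_fluors:
        import warnings

        warnings.warn("fingerprint matrix is column-rank deficient; solution is a minimizer "
                      "but may not be unique", stacklevel=2)
    f, rnorm = nnls(A.A, s)
    return AbundanceVector(f=f, residual_norm=float(rnorm))


def _support_solvers(A: np.ndarray) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Pseudo-inverses for every support, largest first."""
    k = A.shape[1]
    out = []
    for size in range(k, 0, -1):
        for S in combinations(range(k), size):
            out.append((S, np.linalg.pinv(A[:, S])))
    return out


def _unmix_block(
    A: np.ndarray,
    S_mat: np.ndarray,
    solvers: list[tuple[tuple[int, ...], np.ndarray]],
    tol: float,
) -> np.ndarray:
    """Vectorized NNLS on a block of pixel signal vectors.

    Parameters: ``A`` (m, k); ``S_mat`` (m, N). Returns ``F`` (k, N).
    """
    m, k = A.shape
    N = S_mat.shape[1]
    F = np.zeros((k, N))
    unresolved = np.ones(N, dtype=bool)

    # empty support first: f = 0 is optimal iff A^T s <= 0
    grad0 = A.T @ S_mat
    zero_ok = np.all(grad0 <= tol, axis=0)
    unresolved &= ~zero_ok

    for S, pinv_S in solvers:
        if not unresolved.any():
            break
        idx = np.flatnonzero(unresolved)
        s_blk = S_mat[:, idx]
        f_S = pinv_S @ s_blk  # (|S|, n)
        feasible = np.all(f_S >= -tol, axis=0)
        if not feasible.any():
            continue
        comp = [j for j in range(k) if j not in S]
        if comp:
            resid = s_blk[:, feasible] - A[:, S] @ f_S[:, feasible]
            dual_ok = np.all(A[:, comp].T @ resid <= tol, axis=0)
        else:
            dual_ok = np.ones(int(feasible.sum()), dtype=bool)
        good = np.flatnonzero(feasible)[dual_ok]
        if good.size:
            cols = idx[good]
            block = np.zeros((k, good.size))
            block[list(S), :] = np.clip(f_S[:, good], 0.0, None)
            F[:, cols] = block
            unresolved[cols] = False

    if unresolved.any():  # numerically marginal pixels: exact fallback
        for j in np.flatnonzero(unresolved):
            F[:, j], _ = nnls(A, S_mat[:, j])
    return F


def unmix_image(
    stack_corrected: np.ndarray | dict[str, np.ndarray],
    A: FingerprintMatrix,
    *,
    noise_floor: float | None = None,
    tile_px: int = 262144,
) -> FluorImageSet:
    """Unmix a corrected acquisition pixel-by-pixel.

    ``stack_corrected`` is either the ``(n_led*3, H, W)`` plane array in
    fingerprint row order, or a mapping LED name -> ``(3, H, W)`` RGB
    planes. Inputs must already be dark- and quench-corrected; this
    operation performs no background work.

    Pixels whose signal max is below ``noise_floor`` (if given) skip the
    solver and return zero abundances.
    """
    if isinstance(stack_corrected, dict):
        missing = [led for led in A.led_names if led not in stack_corrected]
        if missing:
            raise KeyError(f"missing LED plane(s): {missing}")
        planes = np.concatenate([np.asarray(stack_corrected[led], float)
                                 for led in A.led_names], axis=0)
    else:
        planes = np.asarray(stack_corrected, dtype=float)
    if planes.ndim != 3 or planes.shape[0] != A.n_rows:
        raise ValueError(f"expected ({A.n_rows}, H, W) planes, got {planes.shape}")

    H, W = planes.shape[1:]
    S_all = planes.reshape(A.n_rows, -1)
    scale = max(float(np.abs(S_all).max()), 1.0)
    tol = 1e-9 * scale
    solvers = _support_solvers(A.A)

    F_all = np.zeros((A.n_fluors, H * W))
    active = np.ones(H * W, dtype=bool)
    if noise_floor is not None:
        active = S_all.max(axis=0) > noise_floor
    idx_active = np.flatnonzero(active)
    for start in range(0, idx_active.size, tile_px):
        cols = idx_active[start : start + tile_px]
        F_all[:, cols] = _unmix_block(A.A, S_all[:, cols], solvers, tol)

    residual = np.linalg.norm(A.A @ F_all - S_all * active, axis=0)
    images = {
        name: F_all[j].reshape(H, W) for j, name in enumerate(A.col_labels)
    }
    return FluorImageSet(images=images, residual=residual.reshape(H, W))


def bleedthrough_fraction(
    optics: OpticsConfig, fluors: list[str] | None = None
) -> pd.DataFrame:
    """Fraction of each dye's detected signal in each penta emission window.

    Rows (fluorochromes) sum to 1; the bleed-through of a dye is the
    total fraction outside its nominal window, reported in the
    ``out_of_window`` column (requires ``optics.nominal_windows``).
    """
    frac = window_signal_fractions(optics, fluors)
    if optics.nominal_windows:
        out = []
        for name in frac.index:
            w = optics.nominal_windows.get(name)
            out.append(1.0 - frac.loc[name, w] if w is not None else np.nan)
        frac = frac.copy()
        frac["out_of_window"] = out
    return frac
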