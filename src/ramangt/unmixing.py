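"""Constrained spectral unmixing of measured pixels against the reference family.

Each measured window spectrum m is explained as

    m ~ alpha * y_x + beta * b + gamma * s + delta * 1,   alpha, beta >= 0,

where y_x is the continuous reference spectrum at mixing ratio x, b the
measured background spectrum, s the integer channel ramp and 1 the constant
offset.  The amplitudes are profiled out exactly for any candidate x (the
two inequality constraints are handled by enumerating the four sign-pattern
subproblems of the quadratic), and x itself is found by a coarse grid over
the reference domain followed by bounded local refinement.  A pixel-quality
statistic SNR2 = ||alpha*y_x||^2 / RSS accompanies every fit.

The flank-based background subtraction used for spectrum display fits
(beta, gamma, delta) on the two silent-region flanks (1800-2000 and
2300-2500 cm^-1, 140 channels each) and subtracts the fitted background
model over a display window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .reference_builder import ReferenceModel
from .spectral_core import (
    HyperspectralCube,
    Spectrum,
    WavenumberAxis,
    crop_window,
    design_vectors,
    resample_to_axis,
)

__all__ = [
    "AmplitudeFit",
    "UnmixResult",
    "FlankFit",
    "fit_amplitudes_given_x",
    "fit_pixel",
    "snr2",
    "unmix_cube",
    "subtract_background_flanks",
    "flank_ramp",
]

# sign patterns over (alpha, beta): True = free, False = clamped to zero.
_PATTERNS = ((True, True), (False, True), (True, False), (False, False))


@dataclass
class AmplitudeFit:
    alpha: float
    beta: float
    gamma: float
    delta: float
    rss2: float
    rank_deficient: bool = False

    def coefficients(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])


@dataclass
class UnmixResult:
    """Per-pixel unmixing outcome."""

    x: float
    alpha: float
    beta: float
    gamma: float
    delta: float
    rss2: float
    snr2: float
    identifiable: bool = True
    rank_deficient: bool = False


@dataclass
class FlankFit:
    beta: float
    gamma: float
    delta: float
    rss: float
    subtracted: Spectrum


def _solve_pattern(A: np.ndarray, m: np.ndarray, free_alpha: bool, free_beta: bool):
    """Least squares with alpha and/or beta columns removed (clamped to 0)."""
    cols = []
    if free_alpha:
        cols.append(0)
    if free_beta:
        cols.append(1)
    cols += [2, 3]
    sol, _res, rank, _sv = np.linalg.lstsq(A[:, cols], m, rcond=None)
    full = np.zeros(4)
    full[cols] = sol
    resid = m - A[:, cols] @ sol
    return full, float(resid @ resid), rank < len(cols)


def fit_amplitudes_given_x(
    m: np.ndarray, y_x: np.ndarray, b: np.ndarray
) -> AmplitudeFit:
    """Exact solution of the amplitude quadratic at fixed x.

    Solves min ||m - (alpha y_x + beta b + gamma s + delta 1)||^2 subject to
    alpha, beta >= 0 by enumerating the four sign-pattern subproblems and
    keeping the feasible one with the lowest RSS (ties prefer the fully
    unconstrained solution).  Rank-deficient designs fall back to the
    minimum-norm solution and are flagged.
    """
    m = np.asarray(m, dtype=float)
    y_x = np.asarray(y_x, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (m.shape == y_x.shape == b.shape):
        raise ValueError("m, y_x and b must have equal length")
    L = m.size
    ramp, ones = design_vectors(L)
    A = np.column_stack([y_x, b, ramp, ones])

    best: tuple[np.ndarray, float, bool] | None = None
    for free_alpha, free_beta in _PATTERNS:
        coef, rss, deficient = _solve_pattern(A, m, free_alpha, free_beta)
        if coef[0] < 0 or coef[1] < 0:
            continue
        # strict improvement required: exact ties keep the earlier,
        # less-constrained pattern (both constraints inactive comes first)
        if best is None or rss < best[1]:
            best = (coef, rss, deficient)
    assert best is not None  # pattern (False, False) is always feasible
    coef, rss, deficient = best
    return AmplitudeFit(coef[0], coef[1], coef[2], coef[3], max(rss, 0.0), deficient)


def snr2(alpha: float, y_x: np.ndarray, rss2: float) -> float:
    """Signal-to-noise statistic ||alpha y_x||^2 / RSS2.

    Returns 0 when alpha = 0 and +inf when the fit is exact (RSS2 = 0) with
    nonzero signal.
    """
    if alpha == 0:
        return 0.0
    num = float(alpha**2 * (np.asarray(y_x) @ np.asarray(y_x)))
    if rss2 <= 0:
        return np.inf
    return num / rss2


def _prepare_vector(vec: Spectrum | np.ndarray, model: ReferenceModel) -> np.ndarray:
    if isinstance(vec, Spectrum):
        if vec.axis != model.axis:
            vec = resample_to_axis(vec, model.axis)
        return vec.intensity
    arr = np.asarray(vec, dtype=float)
    if arr.size != model.n_channels:
        raise ValueError(
            f"vector length {arr.size} != model channel count {model.n_channels}"
        )
    return arr


def fit_pixel(
    m: Spectrum | np.ndarray,
    model: ReferenceModel,
    b: Spectrum | np.ndarray,
    grid_step: float = 0.05,
    snr_identifiable: float = 100.0,
) -> UnmixResult:
    """Full five-parameter fit (x, alpha, beta, gamma, delta) for one pixel.

    The profiled objective g(x) = min_amplitudes RSS2 is evaluated on a
    coarse grid over the reference domain, then refined by bounded scalar
    minimization around the best grid point.
    """
    mv = _prepare_vector(m, model)
    bv = _prepare_vector(b, model)
    lo, hi = model.domain
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    Y = model.evaluate_many(grid)  # (S, n_grid)

    rss_grid = np.empty(grid.size)
    for i in range(grid.size):
        rss_grid[i] = fit_amplitudes_given_x(mv, Y[:, i], bv).rss2
    i_best = int(np.argmin(rss_grid))

    def g(x: float) -> float:
        y = model.evaluate_many(np.array([x]))[:, 0]
        return fit_amplitudes_given_x(mv, y, bv).rss2

    x_lo = max(lo, grid[i_best] - grid_step)
    x_hi = min(hi, grid[i_best] + grid_step)
    res = minimize_scalar(g, bounds=(x_lo, x_hi), method="bounded",
                          options={"xatol": 1e-7})
    x_best = float(res.x) if res.fun <= rss_grid[i_best] else float(grid[i_best])

    y_best = model.evaluate_many(np.array([x_best]))[:, 0]
    amp = fit_amplitudes_given_x(mv, y_best, bv)
    s2 = snr2(amp.alpha, y_best, amp.rss2)
    return UnmixResult(
        x=x_best,
        alpha=amp.alpha,
        beta=amp.beta,
        gamma=amp.gamma,
        delta=amp.delta,
        rss2=amp.rss2,
        snr2=s2,
        identifiable=amp.alpha > 0 and s2 > snr_identifiable,
        rank_deficient=amp.rank_deficient,
    )


def _batched_pattern_rss(A: np.ndarray, M: np.ndarray):
    """Best feasible (alpha, beta >= 0) coefficients/RSS for all pixels at once.

    A is (S, 4) = [y_x, b, ramp, ones]; M is (S, P).  Returns (coef (4, P),
    rss (P,)).  Mirrors :func:`fit_amplitudes_given_x` exactly, vectorized
    over pixels.
    """
    P = M.shape[1]
    best_rss = np.full(P, np.inf)
    best_coef = np.zeros((4, P))
    for free_alpha, free_beta in _PATTERNS:
        cols = ([0] if free_alpha else []) + ([1] if free_beta else []) + [2, 3]
        Asub = A[:, cols]
        sol, _res, _rank, _sv = np.linalg.lstsq(Asub, M, rcond=None)
        resid = M - Asub @ sol
        rss = np.einsum("ij,ij->j", resid, resid)
        coef = np.zeros((4, P))
        coef[cols] = sol
        feasible = (coef[0] >= 0) & (coef[1] >= 0) & (rss < best_rss)
        best_rss[feasible] = rss[feasible]
        best_coef[:, feasible] = coef[:, feasible]
    return best_coef, np.maximum(best_rss, 0.0)


def unmix_cube(
    cube: HyperspectralCube,
    model: ReferenceModel,
    background_pixel: tuple[int, int],
    grid_step: float = 0.05,
    refine_step: float = 0.002,
    snr_identifiable: float = 100.0,
) -> dict[str, np.ndarray]:
    """Per-pixel unmixing of a hyperspectral cube.

    The cube is cropped to the model window; the background regressor is the
    measured spectrum at ``background_pixel``.  Returns float images ``x``,
    ``alpha``, ``beta``, ``gamma``, ``delta``, ``rss2``, ``snr2``,
    ``intensity`` (the fitted signal magnitude ||alpha y_x||, i.e. alpha for
    unit-norm references) and the boolean ``identifiable`` map.

    The coarse x grid is refined per pixel with a local fine grid of step
    ``refine_step`` spanning one coarse step either side of the best coarse
    point, which brackets the profiled minimum to well under the coarse
    resolution.
    """
    lo_w, hi_w = model.axis.values[0], model.axis.values[-1]
    work = cube
    if cube.axis != model.axis:
        work = crop_window(cube, lo_w, hi_w)
        if work.axis != model.axis:
            raise ValueError("cube axis does not match the model window axis")
    r_bg, c_bg = background_pixel
    if not (0 <= r_bg < work.height and 0 <= c_bg < work.width):
        raise ValueError(f"background pixel {background_pixel} out of bounds")

    H, W, S = work.data.shape
    M = work.data.reshape(H * W, S).T.astype(float)  # (S, P)
    b = M[:, r_bg * W + c_bg].copy()
    ramp, ones = design_vectors(S)

    lo, hi = model.domain
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    Ygrid = model.evaluate_many(grid)

    P = H * W
    best_rss = np.full(P, np.inf)
    best_ix = np.zeros(P, dtype=int)
    for i in range(grid.size):
        A = np.column_stack([Ygrid[:, i], b, ramp, ones])
        _coef, rss = _batched_pattern_rss(A, M)
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_ix[better] = i

    # local refinement: shared fine grids per coarse-grid group
    best_x = grid[best_ix].astype(float)
    best_coef = np.zeros((4, P))
    for i in np.unique(best_ix):
        sel = np.flatnonzero(best_ix == i)
        x_lo = max(lo, grid[i] - grid_step)
        x_hi = min(hi, grid[i] + grid_step)
        fine = np.arange(x_lo, x_hi + refine_step / 2, refine_step)
        Yfine = model.evaluate_many(fine)
        Msel = M[:, sel]
        sel_rss = best_rss[sel].copy()
        sel_x = best_x[sel].copy()
        sel_coef = np.zeros((4, sel.size))
        # seed with the coarse solution so refinement can only improve
        A0 = np.column_stack([Ygrid[:, i], b, ramp, ones])
        sel_coef, sel_rss0 = _batched_pattern_rss(A0, Msel)
        sel_rss = sel_rss0
        for k in range(fine.size):
            A = np.column_stack([Yfine[:, k], b, ramp, ones])
            coef, rss = _batched_pattern_rss(A, Msel)
            better = rss < sel_rss
            sel_rss[better] = rss[better]
            sel_x[better] = fine[k]
            sel_coef[:, better] = coef[:, better]
        best_rss[sel] = sel_rss
        best_x[sel] = sel_x
        best_coef[:, sel] = sel_coef

    ynorm2 = np.einsum(
        "ij,ij->j", model.evaluate_many(best_x), model.evaluate_many(best_x)
    )
    alpha = best_coef[0]
    signal2 = alpha**2 * ynorm2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(alpha == 0, 0.0, np.where(best_rss > 0, signal2 / best_rss, np.inf))

    shape = (H, W)
    return {
        "x": best_x.reshape(shape),
        "alpha": alpha.reshape(shape),
        "beta": best_coef[1].reshape(shape),
        "gamma": best_coef[2].reshape(shape),
        "delta": best_coef[3].reshape(shape),
        "rss2": best_rss.reshape(shape),
        "snr2": s2.reshape(shape),
        "intensity": np.sqrt(signal2).reshape(shape),
        "identifiable": ((alpha > 0) & (s2 > snr_identifiable)).reshape(shape),
    }


def flank_ramp(
    axis: WavenumberAxis,
    flanks: tuple[tuple[float, float], tuple[float, float]],
) -> np.ndarray:
    """Concatenated-index ramp over the full axis.

    Channels inside the lower flank count 1..n1; channels inside the upper
    flank continue n1+1..n1+n2; channels in the gap between the flanks are
    assigned by linear interpolation between the flank endpoints, giving a
    continuous baseline coordinate everywhere on the axis.
    """
    w = axis.values
    (lo1, hi1), (lo2, hi2) = flanks
    in1 = (w >= lo1) & (w <= hi1)
    in2 = (w >= lo2) & (w <= hi2)
    # fewer than 3 channels cannot support the 3-parameter flank fit
    if in1.sum() < 3 or in2.sum() < 3:
        raise ValueError("flank missing from axis")
    ramp = np.full(w.size, np.nan)
    n1 = int(in1.sum())
    n2 = int(in2.sum())
    ramp[in1] = np.arange(1, n1 + 1, dtype=float)
    ramp[in2] = np.arange(n1 + 1, n1 + n2 + 1, dtype=float)
    idx1 = np.flatnonzero(in1)
    idx2 = np.flatnonzero(in2)
    gap = np.flatnonzero(np.isnan(ramp))
    below = gap < idx1[0]
    above = gap > idx2[-1]
    mid = ~(below | above)
    # continue linearly past the outer edges; interpolate across the gap
    ramp[gap[below]] = 1.0 + (gap[below] - idx1[0])
    ramp[gap[above]] = n1 + n2 + (gap[above] - idx2[-1])
    if mid.any():
        ramp[gap[mid]] = np.interp(
            gap[mid].astype(float), [float(idx1[-1]), float(idx2[0])], [float(n1), float(n1 + 1)]
        )
    return ramp


def subtract_background_flanks(
    m_target: Spectrum,
    m_bg: Spectrum,
    flanks: tuple[tuple[float, float], tuple[float, float]] = (
        (1800.0, 2000.0),
        (2300.0, 2500.0),
    ),
    display_window: tuple[float, float] | None = None,
) -> FlankFit:
    """Fit (beta, gamma, delta) on the concatenated flanks; subtract over a window.

    The design columns on the concatenated flank sub-vectors are the
    background spectrum, the concatenated-index ramp and a constant.  The
    fitted model is then subtracted from the target over ``display_window``
    (default: full shared axis span).
    """
    if m_target.axis != m_bg.axis:
        m_bg = resample_to_axis(m_bg, m_target.axis)
    w = m_target.axis.values
    ramp_full = flank_ramp(m_target.axis, flanks)
    (lo1, hi1), (lo2, hi2) = flanks
    sel = ((w >= lo1) & (w <= hi1)) | ((w >= lo2) & (w <= hi2))

    A = np.column_stack([m_bg.intensity[sel], ramp_full[sel], np.ones(int(sel.sum()))])
    sol, _res, _rank, _sv = np.linalg.lstsq(A, m_target.intensity[sel], rcond=None)
    beta, gamma, delta = (float(v) for v in sol)
    resid = m_target.intensity[sel] - A @ sol
    rss = float(resid @ resid)

    if display_window is None:
        display_window = (float(w[0]), float(w[-1]))
    disp = (w >= display_window[0]) & (w <= display_window[1])
    if not disp.any():
        raise ValueError("display window outside axis")
    fitted = beta * m_bg.intensity + gamma * ramp_full + delta
    subtracted = Spectrum(
        WavenumberAxis(w[disp]),
        (m_target.intensity - fitted)[disp],
        f"{m_target.label} - background",
    )
    return FlankFit(beta, gamma, delta, rss, subtracted)
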