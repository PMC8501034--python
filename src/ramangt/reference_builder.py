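"""Per-channel PCHIP regression of reference spectra over the mixing ratio.

Each spectral channel's normalized intensity is modelled as a shape-preserving
piecewise cubic Hermite interpolant (PCHIP) of five knot values placed at
mixing ratios [0, 2, 4, 6, 8]; the knot values are free parameters fitted by
least squares against all replicate measurements at the 17 measured ratio
levels (0.0 ... 8.0 in steps of 0.5).  Stacking the fitted channel functions
gives a continuous reference spectrum y_x for any mixing ratio x in [0, 8].

Derivative rule: interior knot derivatives are the PCHIP weighted harmonic
mean of adjacent secant slopes (zero on local extrema); endpoint derivatives
use the one-sided three-point formula without the monotonicity clipping that
some library implementations add, so endpoint segments can differ from, e.g.,
scipy's PchipInterpolator when the boundary slope estimate changes sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .spectral_core import WavenumberAxis

__all__ = [
    "DEFAULT_KNOTS",
    "FitError",
    "ChannelFit",
    "ReferenceModel",
    "ReferenceDataset",
    "pchip_derivatives",
    "pchip_segment_coeffs",
    "evaluate_pchip",
    "fit_channel",
    "build_reference_model",
    "evaluate_reference",
]

DEFAULT_KNOTS = np.array([0.0, 2.0, 4.0, 6.0, 8.0])


class FitError(RuntimeError):
    """Raised when a channel fit fails to converge; carries the best iterate."""

    def __init__(self, message: str, best_values=None, diagnostics=None):
        super().__init__(message)
        self.best_values = best_values
        self.diagnostics = diagnostics or {}


def pchip_derivatives(values: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
    """Shape-preserving knot derivatives for the 5-knot Hermite interpolant.

    ``values`` may be a batch with shape (..., n_knots).  Interior knots get
    zero derivative where the adjacent differences change sign or vanish and
    otherwise the weighted harmonic mean of the adjacent secant slopes (the
    plain harmonic mean for the equally spaced default knots).  Endpoints use
    the unclipped one-sided three-point estimate.
    """
    y = np.asarray(values, dtype=float)
    x = DEFAULT_KNOTS if knots is None else np.asarray(knots, dtype=float)
    if y.shape[-1] != x.size:
        raise ValueError("values last dimension must match knot count")
    h = np.diff(x)  # (n-1,)
    w = np.diff(y, axis=-1)  # differences of values
    slopes = w / h
    d = np.zeros_like(y)

    s1 = slopes[..., :-1]
    s2 = slopes[..., 1:]
    h1 = h[:-1]
    h2 = h[1:]
    # weighted harmonic mean (Fritsch-Butland weights); equals
    # 2*s1*s2/(s1+s2) for equal spacing
    w1 = 2.0 * h2 + h1
    w2 = h2 + 2.0 * h1
    prod = s1 * s2
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = (w1 + w2) / (w1 / s1 + w2 / s2)
    d[..., 1:-1] = np.where(prod > 0, hm, 0.0)

    # unclipped one-sided three-point endpoint slopes
    d[..., 0] = ((2.0 * h[0] + h[1]) * slopes[..., 0] - h[0] * slopes[..., 1]) / (
        h[0] + h[1]
    )
    d[..., -1] = ((2.0 * h[-1] + h[-2]) * slopes[..., -1] - h[-1] * slopes[..., -2]) / (
        h[-1] + h[-2]
    )
    return d


def pchip_segment_coeffs(
    knots: np.ndarray, values: np.ndarray, derivatives: np.ndarray
) -> np.ndarray:
    """Cubic coefficients (a, b, c, d) per segment in monomial form.

    On each segment the cubic a*x^3 + b*x^2 + c*x + d matches both endpoint
    values and endpoint derivatives (the 4x4 Hermite collocation system).
    """
    x = np.asarray(knots, dtype=float)
    y = np.asarray(values, dtype=float)
    z = np.asarray(derivatives, dtype=float)
    if not np.all(np.diff(x) > 0):
        raise ValueError("knots must be strictly increasing")
    n_seg = x.size - 1
    coeffs = np.empty((n_seg, 4))
    for j in range(n_seg):
        x0, x1 = x[j], x[j + 1]
        A = np.array(
            [
                [x0**3, x0**2, x0, 1.0],
                [x1**3, x1**2, x1, 1.0],
                [3 * x0**2, 2 * x0, 1.0, 0.0],
                [3 * x1**2, 2 * x1, 1.0, 0.0],
            ]
        )
        rhs = np.array([y[j], y[j + 1], z[j], z[j + 1]])
        try:
            coeffs[j] = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:  # coincident knots
            raise ValueError(f"singular Hermite system on segment {j}") from exc
    return coeffs


def evaluate_pchip(
    knots: np.ndarray, values: np.ndarray, x: np.ndarray | float
) -> np.ndarray | float:
    """Evaluate the 5-knot interpolant of ``values`` at ``x`` (vectorized).

    ``values`` may be batched (..., n_knots); ``x`` is scalar or 1-D.  The
    evaluation goes through the Hermite form (equivalent to the monomial
    segment coefficients but numerically stable for batched use).
    """
    kx = np.asarray(knots, dtype=float)
    y = np.asarray(values, dtype=float)
    d = pchip_derivatives(y, kx)
    xq = np.atleast_1d(np.asarray(x, dtype=float))
    seg = np.clip(np.searchsorted(kx, xq, side="right") - 1, 0, kx.size - 2)
    x0 = kx[seg]
    h = kx[seg + 1] - kx[seg]
    t = (xq - x0) / h
    h00 = (1 + 2 * t) * (1 - t) ** 2
    h10 = t * (1 - t) ** 2
    h01 = t**2 * (3 - 2 * t)
    h11 = t**2 * (t - 1)
    out = (
        y[..., seg] * h00
        + d[..., seg] * (h * h10)
        + y[..., seg + 1] * h01
        + d[..., seg + 1] * (h * h11)
    )
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return out[..., 0] if out.ndim > 0 else float(out)
    return out


@dataclass
class ChannelFit:
    """Fitted 5-knot regression for a single spectral channel."""

    knots: np.ndarray
    values: np.ndarray
    derivatives: np.ndarray = field(default=None)  # type: ignore[assignment]
    coeffs: np.ndarray = field(default=None)  # type: ignore[assignment]
    rss1: float = 0.0

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.derivatives is None:
            self.derivatives = pchip_derivatives(self.values, self.knots)
        if self.coeffs is None:
            self.coeffs = pchip_segment_coeffs(self.knots, self.values, self.derivatives)

    def __call__(self, x):
        return evaluate_pchip(self.knots, self.values, x)


@dataclass
class ReferenceDataset:
    """Replicate observations y_(x', s, N) on one shared analysis axis.

    ``x_obs`` holds the mixing ratio of every replicate spectrum and ``Y``
    the corresponding (n_obs, n_channels) intensity matrix.  Spectra are
    normally stored after :func:`~ramangt.spectral_core.preprocess_normalize`
    (``from_family(..., preprocess=True)``); pass already-normalized data
    with ``preprocess=False``.
    """

    axis: WavenumberAxis
    x_obs: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.x_obs = np.asarray(self.x_obs, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (self.x_obs.size, len(self.axis)):
            raise ValueError("Y must be (n_obs, n_channels)")

    @classmethod
    def from_family(cls, family, preprocess: bool = True) -> "ReferenceDataset":
        """Assemble from a synthetic (or measured) reference family."""
        from .spectral_core import preprocess_normalize

        xs, rows = [], []
        for ratio, _rep, spectrum in family.records:
            if spectrum.axis != family.axis:
                raise ValueError("all replicates must share one axis")
            xs.append(ratio)
            rows.append(
                preprocess_normalize(spectrum.intensity)
                if preprocess
                else spectrum.intensity
            )
        return cls(family.axis, np.asarray(xs), np.vstack(rows))

    @property
    def n_channels(self) -> int:
        return self.Y.shape[1]


def _perturbed_starts(y0: np.ndarray, n_restarts: int) -> list[np.ndarray]:
    starts = [y0]
    rng = np.random.default_rng(0)  # fixed: restarts must be deterministic
    scale = np.maximum(np.abs(y0), 1e-3)
    for _ in range(n_restarts):
        starts.append(y0 + rng.uniform(-0.05, 0.05, size=y0.shape) * scale)
    return starts


def fit_channel(
    x_obs: np.ndarray,
    y_obs: np.ndarray,
    knots: np.ndarray | None = None,
    n_restarts: int = 2,
) -> ChannelFit:
    """Least-squares fit of the 5 knot values for one channel.

    The interpolant evaluation makes the objective piecewise-smooth (the
    derivative rule has conditionals), so a derivative-free Nelder-Mead
    search is run from the data-driven start plus ``n_restarts`` slightly
    perturbed starts, keeping the lowest residual sum of squares.
    """
    x = np.asarray(x_obs, dtype=float)
    y = np.asarray(y_obs, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("x_obs and y_obs must be equal-length, non-empty")
    if np.unique(x).size < 2:
        raise ValueError("need observations at >= 2 distinct ratio levels")
    kx = DEFAULT_KNOTS if knots is None else np.asarray(knots, dtype=float)

    # start: mean of observations at the ratio levels nearest each knot
    y0 = np.empty(kx.size)
    for i, k in enumerate(kx):
        dist = np.abs(x - k)
        nearest = dist <= dist.min() + 1e-12
        y0[i] = y[nearest].mean()

    def objective(v: np.ndarray) -> float:
        return float(np.sum((evaluate_pchip(kx, v, x) - y) ** 2))

    best = None
    for start in _perturbed_starts(y0, n_restarts):
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000, "maxfev": 6000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not np.all(np.isfinite(best.x)):
        raise FitError(
            "channel fit diverged", best_values=best.x, diagnostics={"result": best}
        )
    return ChannelFit(knots=kx, values=best.x, rss1=float(best.fun))


@dataclass
class ReferenceModel:
    """Continuous reference-spectrum family y_x over the analysis window."""

    axis: WavenumberAxis
    channel_fits: list[ChannelFit]

    def __post_init__(self) -> None:
        if len(self.channel_fits) != len(self.axis):
            raise ValueError("need exactly one channel fit per axis channel")
        # cache the (n_channels, n_knots) value matrix for fast evaluation
        self._values = np.vstack([f.values for f in self.channel_fits])
        self._knots = self.channel_fits[0].knots

    @property
    def n_channels(self) -> int:
        return len(self.channel_fits)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self._knots[0]), float(self._knots[-1])

    def __call__(self, x: float) -> np.ndarray:
        return evaluate_reference(self, x)

    def evaluate_many(self, x: np.ndarray) -> np.ndarray:
        """(n_channels, n_x) matrix of reference spectra; domain-checked."""
        xq = np.asarray(x, dtype=float)
        lo, hi = self.domain
        if np.any(xq < lo) or np.any(xq > hi):
            raise ValueError(f"mixing ratio outside [{lo}, {hi}] (no extrapolation)")
        return evaluate_pchip(self._knots, self._values, np.atleast_1d(xq))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "wavenumbers": [float(v) for v in self.axis.values],
            "knots": [float(v) for v in self._knots],
            "knot_values": self._values.tolist(),
            "rss1": [float(f.rss1) for f in self.channel_fits],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        with open(path) as fh:
            payload = json.load(fh)
        knots = np.asarray(payload["knots"], dtype=float)
        values = np.asarray(payload["knot_values"], dtype=float)
        rss = payload.get("rss1", [0.0] * values.shape[0])
        fits = [
            ChannelFit(knots=knots, values=v, rss1=float(r))
            for v, r in zip(values, rss)
        ]
        return cls(WavenumberAxis(np.asarray(payload["wavenumbers"])), fits)


def build_reference_model(
    dataset: ReferenceDataset,
    knots: np.ndarray | None = None,
    n_restarts: int = 2,
) -> ReferenceModel:
    """Fit every channel of the dataset; failures carry the channel index."""
    fits: list[ChannelFit] = []
    for s in range(dataset.n_channels):
        try:
            fits.append(fit_channel(dataset.x_obs, dataset.Y[:, s], knots, n_restarts))
        except (FitError, ValueError) as exc:
            raise FitError(f"channel {s}: {exc}") from exc
    return ReferenceModel(dataset.axis, fits)


def evaluate_reference(model: ReferenceModel, x: float) -> np.ndarray:
    """Reference spectrum y_x; errors outside the knot domain [0, 8]."""
    lo, hi = model.domain
    if not (lo <= x <= hi):
        raise ValueError(f"mixing ratio {x} outside [{lo}, {hi}] (no extrapolation)")
    return model.evaluate_many(np.array([x]))[:, 0]
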