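"""Kinetic saturation model linking lipid composition to chain conformation.

Treating gauche/trans interconversion of the saturated chains as two
competing pseudo-reactions -- one catalysed by the saturated lipid itself,
one by the unsaturated lipid -- equilibrium gives a Hill-type saturation
curve for the gauche/trans ratio as a function of the unsaturated/saturated
mixing ratio x:

    g/t(x) = p + r * x^n / (q + x^n)

with baseline p (the ratio at x = 0), half-saturation constant q > 0,
saturation increment r (the plateau is p + r) and reaction order n.  Only
the three ratio parameters (p, q, r) are identifiable from the curve; the
underlying rate constants are not.  The reaction order is never fixed by
the equilibrium argument alone, so it defaults to n = 1 and may optionally
be co-fitted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = ["KineticModel", "KineticFitError", "kinetic_gt", "fit_kinetic",
           "convert_ratio_image"]

# gauche/trans ratios of saturated acyl chains stay well under ~1.5 even in
# fully disordered bilayers; bounding p and the plateau p + r there keeps
# noisy fits from diverging.
_RATIO_BOUND = 1.5


class KineticFitError(RuntimeError):
    def __init__(self, message, best_model=None, diagnostics=None):
        super().__init__(message)
        self.best_model = best_model
        self.diagnostics = diagnostics or {}


@dataclass
class KineticModel:
    p: float
    q: float
    r: float
    n: float = 1.0
    rss: float = float("nan")
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("half-saturation constant q must be positive")
        if self.n <= 0:
            raise ValueError("reaction order n must be positive")

    @property
    def plateau(self) -> float:
        return self.p + self.r

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"p": self.p, "q": self.q, "r": self.r, "n": self.n,
                 "rss": self.rss, "identifiable": self.identifiable},
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["p"], d["q"], d["r"], d.get("n", 1.0),
                   d.get("rss", float("nan")), d.get("identifiable", True))


def kinetic_gt(model: KineticModel, x: float | np.ndarray) -> float | np.ndarray:
    """Gauche/trans ratio predicted at mixing ratio x >= 0."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("mixing ratio must be non-negative")
    xn = xa**model.n
    out = model.p + model.r * xn / (model.q + xn)
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def fit_kinetic(
    x: np.ndarray,
    y: np.ndarray,
    fixed_n: float | None = 1.0,
    q_init: float | None = None,
) -> KineticModel:
    """Least-squares fit of (p, q, r) -- and optionally n -- to (x, ratio) points.

    Parametrized internally as (p, plateau, q[, n]) so the physical bounds
    0 <= p, plateau <= 1.5 are simple boxes.  Deterministic given the data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        raise KineticFitError("all x identical: curve not identifiable")
    min_pts = 3 if fixed_n is not None else 4
    if x.size < min_pts or n_distinct < min(3, n_distinct + 1):
        raise ValueError(f"need at least {min_pts} points at >= 3 distinct x")
    if fixed_n is None and n_distinct < 3:
        raise ValueError("need >= 3 distinct x to co-fit the order n")

    order = np.argsort(x)
    p0 = float(np.clip(y[order[:2]].mean(), 0.0, _RATIO_BOUND))
    s0 = float(np.clip(y[order[-2:]].mean(), 0.0, _RATIO_BOUND))
    q0 = q_init if q_init is not None else float(max(np.median(x), 1e-3))

    def unpack(theta):
        if fixed_n is None:
            p, s, q, n = theta
        else:
            p, s, q = theta
            n = fixed_n
        return p, q, s - p, n

    def residuals(theta):
        p, q, r, n = unpack(theta)
        m = KineticModel(p, q, r, n)
        return kinetic_gt(m, x) - y

    if fixed_n is None:
        theta0 = [p0, s0, q0, 1.0]
        lower = [0.0, 0.0, 1e-8, 0.05]
        upper = [_RATIO_BOUND, _RATIO_BOUND, np.inf, 10.0]
    else:
        theta0 = [p0, s0, q0]
        lower = [0.0, 0.0, 1e-8]
        upper = [_RATIO_BOUND, _RATIO_BOUND, np.inf]

    res = least_squares(
        residuals, theta0, bounds=(lower, upper), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
    )
    p, q, r, n = unpack(res.x)
    rss = float(res.fun @ res.fun)
    model = KineticModel(p, q, r, n, rss=rss)
    if not res.success:
        raise KineticFitError(
            f"kinetic fit did not converge: {res.message}",
            best_model=model,
            diagnostics={"result": res},
        )
    # flat data leave q (and n) arbitrary
    y_span = float(y.max() - y.min())
    if abs(r) <= max(1e-10, 1e-6 * max(y_span, 1.0)) or y_span == 0.0:
        model.identifiable = False
        warnings.warn("saturation increment ~0: q is not identifiable")
    return model


def convert_ratio_image(
    x_image: np.ndarray,
    model: KineticModel,
    validity_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pixel-wise conversion of a mixing-ratio image to gauche/trans.

    Invalid pixels are set to NaN.
    """
    x_image = np.asarray(x_image, dtype=float)
    if validity_mask is None:
        validity_mask = np.ones(x_image.shape, dtype=bool)
    if validity_mask.shape != x_image.shape:
        raise ValueError("validity mask shape mismatch")
    out = np.full(x_image.shape, np.nan)
    vals = x_image[validity_mask]
    if vals.size:
        out[validity_mask] = kinetic_gt(model, vals)
    return out
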