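"""Synthetic inputs with known ground truth for the quantification pipeline.

No public dataset accompanies the measurement campaign this package models,
so every input is emulated here: in vitro reference-spectrum families of
phospholipid mixtures, hyperspectral phantom cubes with embedded lipid
droplets and scan-line artifacts, saturating gauche/trans-vs-composition
point sets, and 3-D acyl-chain geometries with prescribed dihedral
sequences.  All generators are pure functions of (spec, seed).

The reference family mimics the reported behaviour of the C-D stretch band
of deuterated palmitoyl lipid: as the unsaturated/saturated mixing ratio x
grows, the ~2100 cm^-1 band top shifts right and widens.  Band shapes are
pseudo-Voigt; physically accurate band simulation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference_builder as rb
from .spectral_core import (
    HyperspectralCube,
    Spectrum,
    WavenumberAxis,
    design_vectors,
    preprocess_normalize,
)

__all__ = [
    "CHANNEL_SPACING",
    "MD_COMPOSITION_RATIOS",
    "MD_BILAYER_COMPOSITIONS",
    "bilayer_composition",
    "make_silent_region_axis",
    "make_window_axis",
    "BandSpec",
    "ReferenceFamilySpec",
    "ReferenceFamily",
    "make_reference_family",
    "default_background_spectrum",
    "PhantomSpec",
    "PhantomGroundTruth",
    "make_phantom_cube",
    "ChainSpec",
    "make_chain_coords",
    "make_random_dihedral_chains",
    "make_kinetic_points",
]

# Channel spacing chosen so that the inclusive 2000-2300 cm^-1 analysis
# window holds exactly 210 channels (the instrument reports ~1.43 cm^-1).
CHANNEL_SPACING = 300.0 / 209.0

# Bilayer compositions used for the model-membrane simulations, as
# (mixing ratio, n unsaturated PC18:1, n saturated PC16:0) molecule counts.
MD_BILAYER_COMPOSITIONS: tuple[tuple[float, int, int], ...] = (
    (0.0, 0, 200),
    (0.125, 24, 192),
    (0.25, 40, 160),
    (0.5, 68, 136),
    (1.0, 100, 100),
    (2.0, 136, 68),
    (3.0, 150, 50),
    (4.0, 160, 40),
    (5.0, 170, 34),
    (6.0, 180, 30),
    (7.0, 182, 26),
    (8.0, 192, 24),
)

MD_COMPOSITION_RATIOS = np.array([c[0] for c in MD_BILAYER_COMPOSITIONS])


def bilayer_composition(ratio: float) -> tuple[int, int]:
    """(n_unsaturated, n_saturated) molecule counts for one model bilayer."""
    for r, n_b, n_a in MD_BILAYER_COMPOSITIONS:
        if r == ratio:
            return n_b, n_a
    raise KeyError(f"no bilayer composition tabulated for ratio {ratio}")


def make_silent_region_axis() -> WavenumberAxis:
    """Full silent-region axis (~1800.5-2499.5 cm^-1) anchored at 2000 cm^-1.

    Grid points are 2000 + k * (300/209) for k = -139 ... 348, so that the
    inclusive windows [2000, 2300], [1800, 2000] and [2300, 2500] contain
    exactly 210, 140 and 140 channels respectively.
    """
    k = np.arange(-139, 349)
    return WavenumberAxis(2000.0 + k * CHANNEL_SPACING)


def make_window_axis() -> WavenumberAxis:
    """The 210-channel 2000-2300 cm^-1 analysis window axis."""
    return WavenumberAxis(2000.0 + np.arange(210) * CHANNEL_SPACING)


@dataclass(frozen=True)
class BandSpec:
    """One pseudo-Voigt band whose parameters drift linearly with x."""

    center0: float
    center_slope: float
    width0: float
    width_slope: float
    amp0: float
    amp_slope: float
    eta: float = 0.5  # Lorentzian fraction


# Default band family: a dominant C-D stretch band near 2100 cm^-1 whose top
# right-shifts and widens with increasing mixing ratio, flanked by two weaker
# symmetric/antisymmetric CD2 features.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(2100.0, 1.2, 18.0, 1.6, 1.00, -0.02, 0.5),
    BandSpec(2070.0, 0.5, 14.0, 0.8, 0.45, 0.01, 0.4),
    BandSpec(2195.0, 0.8, 16.0, 1.0, 0.30, 0.015, 0.4),
)


def _pseudo_voigt(w: np.ndarray, center: float, width: float, eta: float) -> np.ndarray:
    g = np.exp(-0.5 * ((w - center) / width) ** 2)
    l = 1.0 / (1.0 + ((w - center) / width) ** 2)
    return (1 - eta) * g + eta * l


@dataclass
class ReferenceFamilySpec:
    """Study conditions for the in vitro reference family.

    17 mixing-ratio levels (0.0 ... 8.0 step 0.5) with 10 replicate spectra
    each, matching the measurement design; replicate-level nuisance (scale
    jitter, baseline tilt/offset) and i.i.d. Gaussian channel noise emulate
    acquisition variability.
    """

    ratio_levels: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 8.0 + 1e-9, 0.5)
    )
    replicates_per_level: int = 10
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    noise_sd: float = 0.01  # relative to the peak normalized intensity
    scale_jitter: float = 0.05
    baseline_slope_sd: float = 0.0005
    baseline_offset_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.ratio_levels = np.asarray(self.ratio_levels, dtype=float)
        if np.any(self.ratio_levels < 0) or np.any(np.diff(self.ratio_levels) <= 0):
            raise ValueError("ratio_levels must be sorted, non-negative")
        if self.replicates_per_level < 1:
            raise ValueError("need at least one replicate per level")


@dataclass
class ReferenceFamily:
    """Generated family plus its exactly-known channel functions."""

    axis: WavenumberAxis
    records: list[tuple[float, int, Spectrum]]
    truth_knots: np.ndarray
    truth_values: np.ndarray  # (n_channels, n_knots), normalized space

    def truth_spectrum(self, x: float) -> np.ndarray:
        """Noise-free normalized-space spectrum at mixing ratio x."""
        return np.atleast_2d(
            rb.evaluate_pchip(self.truth_knots, self.truth_values, np.array([x]))
        )[:, 0]

    def truth_model(self) -> rb.ReferenceModel:
        fits = [
            rb.ChannelFit(knots=self.truth_knots, values=v) for v in self.truth_values
        ]
        return rb.ReferenceModel(self.axis, fits)


def make_reference_family(spec: ReferenceFamilySpec) -> ReferenceFamily:
    """Generate replicate spectra whose normalized channel functions are
    exactly representable by the 5-knot PCHIP regression.

    The band model is evaluated at the five knot ratios, each knot spectrum
    is detrended/normalized, and the per-channel ground truth is the PCHIP
    interpolant of those normalized knot values.  Replicates then re-dress
    the noise-free curve with scale jitter, an affine baseline and Gaussian
    noise -- exactly the nuisance that preprocessing removes.
    """
    rng = np.random.default_rng(spec.seed)
    axis = make_window_axis()
    w = axis.values

    knot_x = rb.DEFAULT_KNOTS
    knot_spectra = []
    for x in knot_x:
        raw = np.zeros_like(w)
        for b in spec.bands:
            amp = max(b.amp0 + b.amp_slope * x, 0.0)
            raw += amp * _pseudo_voigt(
                w, b.center0 + b.center_slope * x, b.width0 + b.width_slope * x, b.eta
            )
        knot_spectra.append(preprocess_normalize(raw))
    truth_values = np.vstack(knot_spectra).T  # (n_channels, n_knots)

    ramp, ones = design_vectors(len(axis))
    peak = float(np.abs(truth_values).max())
    records: list[tuple[float, int, Spectrum]] = []
    clean = rb.evaluate_pchip(knot_x, truth_values, spec.ratio_levels)  # (S, n_levels)
    for i, ratio in enumerate(spec.ratio_levels):
        base = clean[:, i]
        for rep in range(spec.replicates_per_level):
            scale = 1.0 + spec.scale_jitter * rng.standard_normal()
            scale = abs(scale) if scale != 0 else 1.0
            y = (
                scale * base
                + spec.baseline_slope_sd * rng.standard_normal() * ramp
                + spec.baseline_offset_sd * rng.standard_normal() * ones
                + spec.noise_sd * peak * rng.standard_normal(len(axis))
            )
            records.append((float(ratio), rep, Spectrum(axis, y, f"x{ratio}_N{rep}")))
    return ReferenceFamily(axis, records, knot_x, truth_values)


def default_background_spectrum(axis: WavenumberAxis) -> Spectrum:
    """Smooth broad autofluorescence-like background over the window."""
    w = axis.values
    y = 0.8 * np.exp(-0.5 * ((w - 2150.0) / 180.0) ** 2) + 0.3
    return Spectrum(axis, y, "background")


@dataclass
class PhantomSpec:
    """Ground-truth layout of a hyperspectral cell phantom.

    Cytosol covers the frame at a moderate mixing ratio; bright droplet
    discs carry a saturated-lipid-rich (low x) composition at much higher
    signal amplitude, as lipid droplets do after labeled-palmitate uptake.
    One raster row carries a scan-line gain artifact.  Amplitudes are in
    units of the unit-norm reference spectra.
    """

    height: int = 64
    width: int = 64
    x_cytosol: float = 3.0
    alpha_cytosol: float = 1.0
    # (row, col, radius_px, mixing ratio, signal amplitude); radius ~2 px is
    # a 1.2 um droplet at 0.3 um/px, inside the 2-5 px band the droplet
    # bandpass filter retains
    droplets: tuple[tuple[float, float, float, float, float], ...] = (
        (16.0, 16.0, 2.0, 0.5, 8.0),
        (40.0, 28.0, 2.0, 0.8, 8.0),
        (24.0, 50.0, 2.0, 0.5, 8.0),
    )
    beta_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (-2e-4, 2e-4)
    delta_range: tuple[float, float] = (-0.02, 0.02)
    hla_rows: tuple[int, ...] = (33,)
    hla_gain: float = 3.0
    bg_pixel: tuple[int, int] = (0, 0)
    noise_sd: float = 0.002
    pixel_size_um: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for r, c, rad, _x, _a in self.droplets:
            if not (rad <= r <= self.height - 1 - rad and rad <= c <= self.width - 1 - rad):
                raise ValueError(f"droplet at ({r}, {c}) outside image bounds")
        for row in self.hla_rows:
            if not 0 <= row < self.height:
                raise ValueError(f"HLA row {row} outside image")


@dataclass
class PhantomGroundTruth:
    x_map: np.ndarray
    alpha_map: np.ndarray
    beta_map: np.ndarray
    gamma_map: np.ndarray
    delta_map: np.ndarray
    ld_mask: np.ndarray
    hla_mask: np.ndarray
    bg_pixel: tuple[int, int]
    background: Spectrum


def make_phantom_cube(
    spec: PhantomSpec,
    reference: rb.ReferenceModel,
    background: Spectrum | None = None,
) -> tuple[HyperspectralCube, PhantomGroundTruth]:
    """Forward-compose a phantom cube pixel-by-pixel.

    Each pixel spectrum is alpha * y_x + beta * b + gamma * ramp + delta * 1
    plus Gaussian noise; scan-line rows get their signal amplitude boosted by
    ``hla_gain``; the designated background pixel carries background only.
    """
    rng = np.random.default_rng(spec.seed)
    axis = reference.axis
    S = len(axis)
    b = (background or default_background_spectrum(axis)).intensity
    ramp, ones = design_vectors(S)

    H, W = spec.height, spec.width
    rr, cc = np.mgrid[0:H, 0:W]
    x_map = np.full((H, W), spec.x_cytosol, dtype=float)
    alpha_map = np.full((H, W), spec.alpha_cytosol, dtype=float)
    ld_mask = np.zeros((H, W), dtype=bool)
    for r0, c0, rad, x_d, a_d in spec.droplets:
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        x_map[disc] = x_d
        alpha_map[disc] = a_d
        ld_mask |= disc

    lo, hi = reference.domain
    if np.any(x_map < lo) or np.any(x_map > hi):
        raise ValueError("phantom mixing ratios outside the reference domain")

    beta_map = rng.uniform(*spec.beta_range, size=(H, W))
    gamma_map = rng.uniform(*spec.gamma_range, size=(H, W))
    delta_map = rng.uniform(*spec.delta_range, size=(H, W))

    hla_mask = np.zeros((H, W), dtype=bool)
    for row in spec.hla_rows:
        hla_mask[row, :] = True
    alpha_eff = np.where(hla_mask, alpha_map * spec.hla_gain, alpha_map)

    r_bg, c_bg = spec.bg_pixel
    alpha_eff[r_bg, c_bg] = 0.0
    alpha_map[r_bg, c_bg] = 0.0

    # vectorized signal synthesis: unique ground-truth ratios are few
    data = np.empty((H, W, S))
    for x_val in np.unique(x_map):
        sel = x_map == x_val
        y_x = reference.evaluate_many(np.array([x_val]))[:, 0]
        data[sel] = alpha_eff[sel, None] * y_x[None, :]
    data += (
        beta_map[..., None] * b[None, None, :]
        + gamma_map[..., None] * ramp[None, None, :]
        + delta_map[..., None] * ones[None, None, :]
    )
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)

    cube = HyperspectralCube(data, axis, spec.pixel_size_um)
    truth = PhantomGroundTruth(
        x_map,
        alpha_eff,
        beta_map,
        gamma_map,
        delta_map,
        ld_mask,
        hla_mask,
        spec.bg_pixel,
        Spectrum(axis, b, "background"),
    )
    return cube, truth


@dataclass
class ChainSpec:
    """An n-carbon acyl chain built from internal coordinates.

    ``dihedral_sequence`` prescribes the C-C-C-C dihedral (degrees) at each
    of the n_carbons - 3 rotatable positions; 180 is trans, +/-60 gauche.
    """

    n_carbons: int = 16
    dihedral_sequence: tuple[float, ...] = ()
    bond_length: float = 1.54  # Angstrom, sp3 C-C
    bond_angle: float = 111.0  # degrees, C-C-C

    def __post_init__(self) -> None:
        if self.n_carbons < 4:
            raise ValueError("need at least 4 carbons")
        if not self.dihedral_sequence:
            self.dihedral_sequence = tuple([180.0] * (self.n_carbons - 3))
        if len(self.dihedral_sequence) != self.n_carbons - 3:
            raise ValueError(
                f"expected {self.n_carbons - 3} dihedrals, "
                f"got {len(self.dihedral_sequence)}"
            )


def make_chain_coords(spec: ChainSpec) -> np.ndarray:
    """(n_carbons, 3) Cartesian positions realizing the prescribed dihedrals.

    Atoms are placed successively (natural extension reference frame): each
    new atom sits at the fixed bond length/angle from its two predecessors,
    rotated about the previous bond by the prescribed dihedral.
    """
    n = spec.n_carbons
    b = spec.bond_length
    theta = np.radians(spec.bond_angle)
    coords = np.zeros((n, 3))
    coords[1] = [b, 0.0, 0.0]
    coords[2] = coords[1] + b * np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    for i in range(3, n):
        phi = np.radians(spec.dihedral_sequence[i - 3])
        p1, p2, p3 = coords[i - 3], coords[i - 2], coords[i - 1]
        bc = p3 - p2
        bc /= np.linalg.norm(bc)
        ab = p2 - p1
        nrm = np.cross(ab, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.cross(nrm, bc)
        # local frame (bc, m, nrm); supplement of the bond angle off the bond
        # sign of the out-of-plane component chosen so that the measured
        # signed dihedral (two-plane convention) equals the prescribed phi
        d_local = np.array(
            [
                -b * np.cos(theta),
                b * np.sin(theta) * np.cos(phi),
                -b * np.sin(theta) * np.sin(phi),
            ]
        )
        coords[i] = p3 + d_local[0] * bc + d_local[1] * m + d_local[2] * nrm
    return coords


def make_random_dihedral_chains(
    n_chains: int,
    n_carbons: int,
    gauche_prob: float,
    seed: int,
    jitter_deg: float = 0.0,
) -> tuple[list[np.ndarray], list[tuple[float, ...]]]:
    """Chains with dihedrals drawn trans/gauche i.i.d.; returns coords + truth."""
    rng = np.random.default_rng(seed)
    chains, sequences = [], []
    for _ in range(n_chains):
        n_d = n_carbons - 3
        is_gauche = rng.random(n_d) < gauche_prob
        sign = np.where(rng.random(n_d) < 0.5, 1.0, -1.0)
        angles = np.where(is_gauche, sign * 60.0, 180.0)
        if jitter_deg > 0:
            angles = angles + rng.uniform(-jitter_deg, jitter_deg, n_d)
        seq = tuple(float(a) for a in angles)
        chains.append(make_chain_coords(ChainSpec(n_carbons, seq)))
        sequences.append(seq)
    return chains, sequences


def make_kinetic_points(
    p: float,
    q: float,
    r: float,
    n: float = 1.0,
    x_values: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Saturating gauche/trans-vs-composition points p + r x^n / (q + x^n).

    Defaults to the 12 model-membrane composition ratios.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    x = MD_COMPOSITION_RATIOS.copy() if x_values is None else np.asarray(x_values, float)
    if np.any(x < 0):
        raise ValueError("x_values must be non-negative")
    y = p + r * x**n / (q + x**n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(x.shape)
    return x, y
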