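"""Gauche/trans conformer counting from acyl-chain carbon coordinates.

For every four consecutive backbone carbons A-B-C-D the signed dihedral
between the A-B-C and B-C-D planes classifies the position as trans (near
180 deg) or gauche (near +/-60 deg); a 16-carbon chain has 13 such
positions.  Ratios are pooled counts (sum of gauche over sum of trans
across all chains and frames), since the kinetic model's concentrations
are counts of dihedral positions, not per-chain averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ChainFrame",
    "ConformerCounts",
    "GaucheTransUndefinedError",
    "dihedral_angle",
    "classify_conformer",
    "chain_gt_ratio",
    "ensemble_gt_ratio",
    "read_xyz_frames",
    "write_xyz_frames",
]

GAUCHE_CUTOFF_DEG = 120.0  # symmetric rotamer boundary; gauche iff |phi| <= cutoff


class GaucheTransUndefinedError(ZeroDivisionError):
    """Raised when no trans positions exist; counts are attached."""

    def __init__(self, message: str, counts: "ConformerCounts"):
        super().__init__(message)
        self.counts = counts


@dataclass
class ConformerCounts:
    n_gauche: int = 0
    n_trans: int = 0

    @property
    def total(self) -> int:
        return self.n_gauche + self.n_trans

    def __add__(self, other: "ConformerCounts") -> "ConformerCounts":
        return ConformerCounts(
            self.n_gauche + other.n_gauche, self.n_trans + other.n_trans
        )

    @property
    def ratio(self) -> float:
        if self.n_trans == 0:
            raise GaucheTransUndefinedError("no trans positions: ratio undefined", self)
        return self.n_gauche / self.n_trans


@dataclass
class ChainFrame:
    """One trajectory frame: a list of ordered carbon-position arrays (Angstrom)."""

    chains: list[np.ndarray]
    frame_id: int = 0

    def __post_init__(self) -> None:
        cleaned = []
        for i, chain in enumerate(self.chains):
            arr = np.asarray(chain, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 4:
                raise ValueError(f"chain {i} must be (n>=4, 3) coordinates")
            if np.any(np.linalg.norm(np.diff(arr, axis=0), axis=1) < 1e-9):
                raise ValueError(f"chain {i} has coincident consecutive atoms")
            cleaned.append(arr)
        self.chains = cleaned


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral (degrees, (-180, 180]) of four points; 180 is anti.

    Uses the standard two-plane convention: the angle between the plane of
    (p1, p2, p3) and that of (p2, p3, p4), signed by the chirality of the
    arrangement about the central bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined dihedral: colinear triple")
    b2n = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2n)
    ang = np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def classify_conformer(angle: float, cutoff: float = GAUCHE_CUTOFF_DEG) -> str:
    """'trans' iff |angle| > cutoff (default 120 deg), else 'gauche'.

    The boundary itself counts as gauche.
    """
    if not -180.0 < angle <= 180.0 + 1e-12:
        raise ValueError("angle must lie in (-180, 180]")
    return "trans" if abs(angle) > cutoff else "gauche"


def chain_gt_ratio(
    chain: np.ndarray, cutoff: float = GAUCHE_CUTOFF_DEG
) -> tuple[ConformerCounts, float]:
    """Counts and gauche/trans ratio over all consecutive carbon quadruples."""
    arr = np.asarray(chain, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 4:
        raise ValueError("chain must contain at least 4 carbons")
    counts = ConformerCounts()
    for i in range(arr.shape[0] - 3):
        kind = classify_conformer(
            dihedral_angle(arr[i], arr[i + 1], arr[i + 2], arr[i + 3]), cutoff
        )
        if kind == "gauche":
            counts.n_gauche += 1
        else:
            counts.n_trans += 1
    return counts, counts.ratio


def ensemble_gt_ratio(
    frames: list[ChainFrame],
    selection: list[int] | None = None,
    cutoff: float = GAUCHE_CUTOFF_DEG,
) -> tuple[ConformerCounts, float]:
    """Pooled gauche/trans ratio over selected chains of all frames."""
    if not frames:
        raise ValueError("need at least one frame")
    pooled = ConformerCounts()
    for frame in frames:
        chains = (
            frame.chains
            if selection is None
            else [frame.chains[i] for i in selection]
        )
        for chain in chains:
            counts = ConformerCounts()
            for i in range(chain.shape[0] - 3):
                kind = classify_conformer(
                    dihedral_angle(chain[i], chain[i + 1], chain[i + 2], chain[i + 3]),
                    cutoff,
                )
                if kind == "gauche":
                    counts.n_gauche += 1
                else:
                    counts.n_trans += 1
            pooled = pooled + counts
    return pooled, pooled.ratio


def write_xyz_frames(
    frames: list[ChainFrame], path: str | Path, element: str = "C"
) -> None:
    """Multi-frame XYZ text; chains of a frame are concatenated in order."""
    with open(path, "w") as fh:
        for frame in frames:
            n_atoms = sum(c.shape[0] for c in frame.chains)
            lengths = ",".join(str(c.shape[0]) for c in frame.chains)
            fh.write(f"{n_atoms}\n")
            fh.write(f"frame={frame.frame_id} chain_lengths={lengths}\n")
            for chain in frame.chains:
                for xyz in chain:
                    fh.write(
                        f"{element} {float(xyz[0])!r} {float(xyz[1])!r} "
                        f"{float(xyz[2])!r}\n"
                    )


def read_xyz_frames(path: str | Path) -> list[ChainFrame]:
    """Read multi-frame XYZ written by :func:`write_xyz_frames`.

    The comment line's ``chain_lengths`` field restores chain boundaries;
    without it, all atoms of a frame form one chain.
    """
    frames: list[ChainFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_atoms = int(lines[i].strip())
        comment = lines[i + 1]
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in lines[i + 2 : i + 2 + n_atoms]]
        )
        lengths = None
        for token in comment.split():
            if token.startswith("chain_lengths="):
                lengths = [int(v) for v in token.split("=", 1)[1].split(",")]
        if lengths is None:
            lengths = [n_atoms]
        chains, pos = [], 0
        for ln in lengths:
            chains.append(coords[pos : pos + ln])
            pos += ln
        frames.append(ChainFrame(chains, frame_no))
        frame_no += 1
        i += 2 + n_atoms
    return frames
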