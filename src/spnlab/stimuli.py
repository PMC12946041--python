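"""Parametric octagon stimuli: irregular polygons with or without mirror symmetry.

Stimuli are octagons inscribed in a circle (default radius 0.75 degrees of
visual angle).  Each vertex of the regular-octagon template is rotated about
the origin by an angular jitter drawn uniformly from +-jitter_deg, keeping
radial distance fixed.  Asymmetric stimuli jitter all eight vertices
independently.  Symmetric stimuli jitter two anchor vertices (one from each
reflection orbit of the template) and generate the remaining six by
successive reflections across the object-frame vertical and horizontal
axes; the whole set is then rotated by 45 or 135 degrees so the two
orthogonal mirror axes appear obliquely in display coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "OctagonStimulus",
    "make_octagon",
    "is_mirror_symmetric",
    "elongation_axis",
]

# Template angles (degrees, CCW from screen-right) avoid the mirror axes so
# reflections never map a vertex onto itself.  Under the group
# {identity, reflect-vertical, reflect-horizontal, rotate-180} they split
# into two orbits of four: {22.5, 157.5, 202.5, 337.5} and
# {67.5, 112.5, 247.5, 292.5}.
TEMPLATE_ANGLES_DEG = np.arange(8) * 45.0 + 22.5
_ANCHOR_TEMPLATE = (22.5, 67.5)  # one representative per orbit


@dataclass(frozen=True)
class OctagonStimulus:
    """Eight planar vertices (degrees of visual angle) plus bookkeeping."""

    vertices: np.ndarray  # (8, 2), sorted by polar angle
    condition: str  # "symmetric" | "asymmetric"
    rotation_deg: float  # 45 or 135
    anchor_indices: tuple[int, ...]  # indices into `vertices` of the anchors
    seed: int | None

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.vertices, axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition": self.condition,
                "rotation_deg": self.rotation_deg,
                "seed": self.seed,
                "vertices": self.vertices.tolist(),
            }
        )

    def to_svg(self, path: str | Path, scale: float = 100.0) -> None:
        """Write a minimal SVG of the filled octagon for visual inspection."""
        v = self.vertices * scale
        half = 1.2 * np.abs(v).max()
        pts = " ".join(f"{x:.2f},{-y:.2f}" for x, y in v)
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'viewBox="{-half:.1f} {-half:.1f} {2 * half:.1f} {2 * half:.1f}">'
            f'<polygon points="{pts}" fill="black"/></svg>'
        )
        Path(path).write_text(svg)


def _rot(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _from_polar(angles_deg: np.ndarray, radius: float) -> np.ndarray:
    a = np.deg2rad(angles_deg)
    return radius * np.column_stack([np.cos(a), np.sin(a)])


def make_octagon(
    condition: str = "symmetric",
    rotation_deg: float = 45.0,
    jitter_deg: float = 20.0,
    radius: float = 0.75,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OctagonStimulus:
    """Generate one octagon stimulus.

    Parameters
    ----------
    condition
        ``"symmetric"`` (doubly mirror-symmetric about the axes at
        ``rotation_deg`` and ``rotation_deg + 90``) or ``"asymmetric"``
        (eight independently jittered vertices).
    rotation_deg
        Display rotation of the object frame; must be 45 or 135 so the
        mirror axes are oblique.
    jitter_deg
        Half-range of the uniform angular jitter; must lie in [0, 22.5) so
        jittered vertices cannot swap template sectors.
    radius
        Circumscribed-circle radius in degrees of visual angle.
    seed, rng
        Either a seed (deterministic) or an existing generator.
    """
    if condition not in ("symmetric", "asymmetric"):
        raise ValueError(f"unknown condition {condition!r}")
    if rotation_deg not in (45, 45.0, 135, 135.0):
        raise ValueError("rotation_deg must be 45 or 135")
    if not 0 <= jitter_deg < 22.5:
        raise ValueError("jitter_deg must lie in [0, 22.5)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    for _ in range(100):
        if condition == "asymmetric":
            angles = TEMPLATE_ANGLES_DEG + rng.uniform(-jitter_deg, jitter_deg, 8)
            verts = _from_polar(angles, radius)
            anchor_angles: tuple[float, ...] = ()
        else:
            a1, a2 = (t + rng.uniform(-jitter_deg, jitter_deg) for t in _ANCHOR_TEMPLATE)
            orbit = []
            for a in (a1, a2):
                # reflection across vertical axis: theta -> 180 - theta;
                # across horizontal: theta -> -theta; both: theta + 180
                orbit.extend([a, 180.0 - a, -a, a + 180.0])
            angles = np.asarray(orbit)
            verts = _from_polar(angles, radius)
            anchor_angles = (a1, a2)
        verts = verts @ _rot(rotation_deg).T if condition == "symmetric" else verts
        # near-coincident vertices would make the polygon degenerate; resample
        if cdist(verts, verts)[~np.eye(8, dtype=bool)].min() > 1e-9 * radius:
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not generate non-degenerate octagon")

    display_angles = np.rad2deg(np.arctan2(verts[:, 1], verts[:, 0])) % 360.0
    order = np.argsort(display_angles)
    verts = verts[order]
    if condition == "symmetric":
        rotated = [(a + rotation_deg) % 360.0 for a in anchor_angles]
        sorted_angles = display_angles[order]
        anchor_indices = tuple(
            int(np.argmin(np.abs((sorted_angles - a + 180) % 360 - 180)))
            for a in rotated
        )
    else:
        anchor_indices = tuple(range(8))
    return OctagonStimulus(
        vertices=verts,
        condition=condition,
        rotation_deg=float(rotation_deg),
        anchor_indices=anchor_indices,
        seed=seed,
    )


def is_mirror_symmetric(
    stimulus: OctagonStimulus, axis_deg: float, tol: float = 1e-9
) -> bool:
    """True iff reflecting the vertex set about the axis reproduces it within tol.

    The reflected set is matched to the original by optimal bipartite
    assignment on pairwise distances, so vertex ordering is irrelevant.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    v = stimulus.vertices
    a = np.deg2rad(axis_deg)
    # reflection matrix about the axis through the origin at angle a
    refl = np.array(
        [[np.cos(2 * a), np.sin(2 * a)], [np.sin(2 * a), -np.cos(2 * a)]]
    )
    mirrored = v @ refl.T
    cost = cdist(mirrored, v)
    rows, cols = linear_sum_assignment(cost)
    return bool(cost[rows, cols].max() <= tol)


def elongation_axis(stimulus: OctagonStimulus | np.ndarray) -> tuple[float, float, bool]:
    """Principal axis and anisotropy of the vertex second-moment tensor.

    Returns ``(axis_deg, anisotropy, defined)`` where ``axis_deg`` is the
    orientation (mod 180) of the eigenvector with the larger eigenvalue of
    the centered second-moment tensor, ``anisotropy`` the eigenvalue ratio
    (larger/smaller, >= 1), and ``defined`` False when the tensor is
    isotropic to 1e-9 (axis then reported as nan).
    """
    v = stimulus.vertices if isinstance(stimulus, OctagonStimulus) else np.asarray(stimulus)
    centered = v - v.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("vertices are all coincident")
    tensor = centered.T @ centered / len(v)
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    small, large = evals
    if small <= 0:
        anisotropy = np.inf
    else:
        anisotropy = float(large / small)
    if abs(anisotropy - 1.0) < 1e-9:
        return (float("nan"), 1.0, False)
    major = evecs[:, 1]
    axis = float(np.rad2deg(np.arctan2(major[1], major[0])) % 180.0)
    return (axis, anisotropy, True)
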