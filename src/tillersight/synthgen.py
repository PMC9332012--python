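"""Synthetic rice-hill patch generator with exact ground truth.

Real paddy imagery for this task is a top-down-oblique view of a single hill:
green leaves arcing from a basal clump over a water/soil background, with
occasional leaf overlap, leaves intruding from neighbouring hills, and small
specular reflections on the water surface.  The generator emulates exactly
those features and nothing more (no 3-D plant architecture, no wind blur, no
photorealism) so that every scene carries analytic ground truth: leaf
centerlines, tip coordinates, and the number of tips above the plant-mask
centroid.

Leaves are quadratic Bézier arcs from a basal point, with width tapering
linearly from the base width (drawn from 12–18 px, the minimum leaf width
the pipeline is designed for) to 6 px at the tip.  Control points are chosen
so the arc is monotone in the row coordinate — the leaf tip is the topmost
point of the leaf, as for upright vegetative-stage leaves.

Stress modes mirror the field error taxonomy:

* overlap     — two long leaves share a tip region within 12 px; merged tip
                regions make the detector undercount.
* intrusion   — an extra leaf enters from a side border with its tip above
                the centroid; the detector counts it, overcounting.
* edge        — a long leaf exits through a side border, so its true tip is
                outside the frame and the traced skeleton is clipped.
* elevation   — short (non-main-stem) leaves reach above the centroid, as
                under too-steep shooting elevation; the detector counts them.
* reflections — bright blobs of 100–499 px on the water surface; all are
                below the 500-px area filter and must vanish in preprocessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

__all__ = ["Leaf", "Reflection", "SceneParams", "SyntheticScene", "generate_scene", "render_scene"]

#: Leaf/background colours differ mainly along the green axis, and pixel
#: noise is mostly correlated brightness (illumination), so a decorrelation
#: stretch suppresses the noise while keeping the class difference — the
#: regime the real pipeline operates in.
LEAF_COLOR = np.array([100.0, 152.0, 92.0])
BACKGROUND_COLOR = np.array([112.0, 102.0, 94.0])
REFLECTION_COLOR = np.array([195.0, 215.0, 205.0])
BRIGHTNESS_NOISE_SD = 12.0
LEAF_BRIGHTNESS_NOISE_SD = 12.0
CHANNEL_NOISE_SD = 1.5
TIP_WIDTH = 6.0


@dataclass(frozen=True)
class Leaf:
    """A quadratic Bézier leaf blade with linearly tapering width."""

    base: tuple[float, float]
    ctrl: tuple[float, float]
    tip: tuple[float, float]
    base_width: float
    tip_width: float = TIP_WIDTH

    def point(self, t) -> np.ndarray:
        """Centerline point(s) at parameter t in [0, 1] (t=1 is the tip).
        Returns an (..., 2) array of (row, col)."""
        t = np.asarray(t, dtype=float)[..., None]
        p0 = np.asarray(self.base)
        p1 = np.asarray(self.ctrl)
        p2 = np.asarray(self.tip)
        return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2

    def width_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.base_width + (self.tip_width - self.base_width) * t

    def centerline(self, n: int = 200) -> np.ndarray:
        return self.point(np.linspace(0.0, 1.0, n))

    def arc_length(self) -> float:
        pts = self.centerline(64)
        return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


@dataclass(frozen=True)
class Reflection:
    """A specular blob on the water surface: a rotated ellipse."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float
    area: int  # drawn pixel count


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry and stress-mode controls.

    Defaults describe a clean mid-season hill patch: 560x420 px, 5–17 long
    leaves fanned from a basal point near the bottom centre with tips in the
    upper part of the frame, a few short leaves staying low, no error modes.
    """

    height: int = 420
    width: int = 560
    n_long_leaves: int = 8
    n_short_leaves: int = 4
    leaf_width_range: tuple[float, float] = (12.0, 18.0)
    base_point: tuple[int, int] | None = None
    overlap_prob: float = 0.0
    neighbor_intrusion_prob: float = 0.0
    reflection_count: int = 0
    edge_exit_prob: float = 0.0
    elevated_short_leaves: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("scene must be at least 64 x 64")
        if min(self.leaf_width_range) < 1:
            raise ValueError("leaf width must be >= 1 px")
        for p in (self.overlap_prob, self.neighbor_intrusion_prob, self.edge_exit_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_long_leaves < 0 or self.n_short_leaves < 0 or self.reflection_count < 0:
            raise ValueError("counts must be >= 0")
        bp = self.resolved_base()
        if not (0 <= bp[0] < self.height and 0 <= bp[1] < self.width):
            raise ValueError("base point outside image")

    def resolved_base(self) -> tuple[int, int]:
        if self.base_point is not None:
            return self.base_point
        return int(round(0.92 * self.height)), self.width // 2


@dataclass
class SyntheticScene:
    """A generated scene plus its analytic ground truth.

    ``truth_tip_coords`` are the in-frame hill-leaf tips lying strictly above
    the plant-mask centroid row; ``truth_tips_above_centroid`` is their
    count.  Intruding neighbour leaves contribute mask pixels but never
    ground-truth tips.
    """

    params: SceneParams
    leaves: list[Leaf]
    short_leaves: list[Leaf]
    intruders: list[Leaf]
    reflections: list[Reflection]
    truth_tips_above_centroid: int = 0
    truth_tip_coords: list[tuple[float, float]] = field(default_factory=list)
    centroid_row: float = float("nan")
    _mask: np.ndarray | None = field(default=None, repr=False)

    def plant_mask(self) -> np.ndarray:
        """Analytic occupancy mask of all leaf blades (hill + intruders),
        excluding reflections."""
        if self._mask is None:
            shape = (self.params.height, self.params.width)
            mask = np.zeros(shape, dtype=bool)
            for leaf in [*self.leaves, *self.short_leaves, *self.intruders]:
                _paint_leaf(mask, leaf)
            self._mask = mask
        return self._mask

    def all_hill_tips(self) -> list[tuple[float, float]]:
        return [lf.tip for lf in [*self.leaves, *self.short_leaves]]


def _paint_leaf(mask: np.ndarray, leaf: Leaf) -> None:
    n = max(16, int(leaf.arc_length()))
    ts = np.linspace(0.0, 1.0, n)
    pts = leaf.point(ts)
    widths = leaf.width_at(ts)
    for (r, c), w in zip(pts, widths):
        rr, cc = draw.disk((r, c), max(w / 2.0, 0.5), shape=mask.shape)
        mask[rr, cc] = True


def _clearance_ok(
    tip: tuple[float, float],
    other_lines: list[np.ndarray],
    row_above: float = 16.0,
    row_below: float = 6.0,
    col_half: float = 19.0,
) -> bool:
    """True when no foreign centerline sample encroaches on the detection
    window above ``tip`` (with slack for rendering/tracing jitter)."""
    for line in other_lines:
        near = (
            (line[:, 0] >= tip[0] - row_above)
            & (line[:, 0] <= tip[0] + row_below)
            & (np.abs(line[:, 1] - tip[1]) <= col_half)
        )
        if near.any():
            return False
    return True


def _make_leaf(
    rng: np.random.Generator,
    base: tuple[float, float],
    tip: tuple[float, float],
    width: float,
    bow: float | None = None,
) -> Leaf:
    """Leaf with a monotone-row quadratic arc.

    When ``bow`` is None the control column stays strictly between the tip
    and base columns (the blade bows inward, toward the clump), which keeps
    a leaf's upper centerline on its own side of the fan; otherwise the
    control column is the chord midpoint ± ``bow``.
    """
    span_r = base[0] - tip[0]
    ctrl_r = tip[0] + rng.uniform(0.35, 0.65) * span_r
    if bow is None:
        u = rng.uniform(0.05, 0.45)
        ctrl_c = tip[1] + u * (base[1] - tip[1])
    else:
        mid_c = (base[1] + tip[1]) / 2.0
        ctrl_c = mid_c + rng.uniform(-bow, bow)
    return Leaf(base=base, ctrl=(ctrl_r, ctrl_c), tip=tip, base_width=width)


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Build a scene deterministically from ``params.seed``.

    Long-leaf tips are fanned across the frame with at least ~26 px of
    column separation and individually validated so that, in clean mode, no
    foreign centerline crosses the detection window above any tip.  Raises
    ``ValueError`` when the requested number of leaves cannot be placed at
    that separation (infeasible geometry).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    base = tuple(map(float, params.resolved_base()))
    margin = 40.0
    n_long = params.n_long_leaves

    if n_long > 0 and (w - 2 * margin) / max(n_long - 1, 1) < 26.0:
        raise ValueError(
            f"cannot place {n_long} long leaves at >= 26 px tip separation "
            f"in a {w}-px-wide frame"
        )

    slots = (
        np.linspace(margin, w - margin, n_long)
        if n_long > 1
        else np.array([w / 2.0])[:n_long]
    )

    leaves: list[Leaf] = []
    lines: list[np.ndarray] = []
    for i in range(n_long):  # left to right across the fan
        col = float(slots[i]) + rng.uniform(-2.0, 2.0)
        placed = False
        for _attempt in range(60):
            tip = (rng.uniform(0.12 * h, 0.36 * h), col)
            width = rng.uniform(*params.leaf_width_range)
            leaf = _make_leaf(rng, base, tip, width)
            line = leaf.centerline(160)
            if _clearance_ok(tip, lines) and all(
                _clearance_ok(lf.tip, [line]) for lf in leaves
            ):
                leaves.append(leaf)
                lines.append(line)
                placed = True
                break
        if not placed:
            raise ValueError("infeasible geometry: could not place a long leaf")

    # short leaves: stay low (or rise above the canopy in elevation mode)
    short_leaves: list[Leaf] = []
    for _ in range(params.n_short_leaves):
        if params.elevated_short_leaves:
            tip_r = rng.uniform(0.30 * h, 0.42 * h)
        else:
            # well below the plant-mask centroid (~0.55-0.65 H), so neither
            # the analytic tip nor its traced endpoint can straddle the line
            tip_r = rng.uniform(0.72 * h, 0.82 * h)
        for attempt in range(40):
            tip = (tip_r, base[1] + rng.uniform(-0.28 * w, 0.28 * w))
            width = rng.uniform(*params.leaf_width_range)
            leaf = _make_leaf(rng, base, tip, width, bow=15.0)
            line = leaf.centerline(120)
            if all(_clearance_ok(lf.tip, [line]) for lf in leaves) and (
                not params.elevated_short_leaves
                or _clearance_ok(tip, lines + [s.centerline(120) for s in short_leaves])
            ):
                short_leaves.append(leaf)
                lines.append(line)
                break

    # Error 1: force two adjacent long leaves to share a tip region (< 12 px)
    if len(leaves) >= 2 and rng.random() < params.overlap_prob:
        by_col = sorted(range(len(leaves)), key=lambda i: leaves[i].tip[1])
        j = int(rng.integers(0, len(by_col) - 1))
        a, b = by_col[j], by_col[j + 1]
        host = leaves[a]
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(4.0, 11.0)
        new_tip = (host.tip[0] + rad * math.sin(ang), host.tip[1] + rad * math.cos(ang))
        new_tip = (min(max(new_tip[0], 5.0), base[0] - 50.0), min(max(new_tip[1], 5.0), w - 6.0))
        moved = leaves[b]
        leaves[b] = _make_leaf(rng, base, new_tip, moved.base_width, bow=10.0)

    # Error 2: neighbour leaf entering from a side border
    intruders: list[Leaf] = []
    if rng.random() < params.neighbor_intrusion_prob:
        side = -20.0 if rng.random() < 0.5 else w + 19.0
        ibase = (rng.uniform(0.45 * h, 0.7 * h), side)
        for attempt in range(40):
            tip = (rng.uniform(0.14 * h, 0.36 * h), rng.uniform(0.15 * w, 0.85 * w))
            leaf = _make_leaf(rng, ibase, tip, rng.uniform(*params.leaf_width_range), bow=12.0)
            line = leaf.centerline(160)
            if _clearance_ok(tip, lines) and all(
                _clearance_ok(lf.tip, [line]) for lf in leaves
            ):
                intruders.append(leaf)
                break

    # Error 3: a long leaf exits through a side border (true tip off-frame)
    if leaves and rng.random() < params.edge_exit_prob:
        i = int(rng.integers(0, len(leaves)))
        side = -30.0 if leaves[i].tip[1] < w / 2 else w + 29.0
        tip = (rng.uniform(0.25 * h, 0.45 * h), side)
        leaves[i] = _make_leaf(rng, base, tip, leaves[i].base_width, bow=10.0)

    scene = SyntheticScene(
        params=params,
        leaves=leaves,
        short_leaves=short_leaves,
        intruders=intruders,
        reflections=[],
    )
    plant = scene.plant_mask()
    scene.reflections = _place_reflections(rng, plant, params)

    if plant.any():
        scene.centroid_row = float(np.nonzero(plant)[0].mean())
        tips = [
            t
            for t in scene.all_hill_tips()
            if t[0] < scene.centroid_row and 0 <= t[0] < h and 0 <= t[1] < w
        ]
        scene.truth_tip_coords = tips
        scene.truth_tips_above_centroid = len(tips)
    return scene


def _place_reflections(
    rng: np.random.Generator, plant: np.ndarray, params: SceneParams
) -> list[Reflection]:
    """Sample sub-500-px elliptical blobs clear of the plant and each other."""
    h, w = plant.shape
    occupied = ndimage.binary_dilation(plant, iterations=8)
    out: list[Reflection] = []
    for _ in range(params.reflection_count):
        for _attempt in range(200):
            area = rng.uniform(100.0, 460.0)
            q = rng.uniform(0.45, 0.95)
            r_major = math.sqrt(area / (math.pi * q))
            r_minor = q * r_major
            rot = rng.uniform(0, math.pi)
            cr = rng.uniform(r_major + 4, h - r_major - 4)
            cc = rng.uniform(r_major + 4, w - r_major - 4)
            rr, ccx = draw.ellipse(cr, cc, r_major, r_minor, rotation=rot, shape=(h, w))
            if rr.size < 100 or rr.size > 499 or occupied[rr, ccx].any():
                continue
            blob = np.zeros_like(plant)
            blob[rr, ccx] = True
            occupied |= ndimage.binary_dilation(blob, iterations=8)
            out.append(
                Reflection(center=(cr, cc), axes=(r_major, r_minor), rotation=rot, area=int(rr.size))
            )
            break
    return out


def render_scene(scene: SyntheticScene) -> np.ndarray:
    """Render the scene to an H x W x 3 uint8 image.

    Leaves are filled green curves over a brown/blue-gray background with
    mild per-pixel noise; a light Gaussian blur softens edges (a stand-in
    for optical anti-aliasing).  Deterministic for a fixed scene seed.
    """
    p = scene.params
    rng = np.random.default_rng([p.seed, 101])
    h, w = p.height, p.width
    img = np.empty((h, w, 3))
    img[:] = BACKGROUND_COLOR
    img += rng.normal(0.0, BRIGHTNESS_NOISE_SD, size=(h, w))[..., None]
    plant = scene.plant_mask()
    n_plant = int(plant.sum())
    img[plant] = LEAF_COLOR + rng.normal(
        0.0, LEAF_BRIGHTNESS_NOISE_SD, size=(n_plant, 1)
    )
    for refl in scene.reflections:
        rr, cc = draw.ellipse(
            *refl.center, *refl.axes, rotation=refl.rotation, shape=(h, w)
        )
        img[rr, cc] = REFLECTION_COLOR + rng.normal(0.0, 6.0, size=(rr.size, 1))
    img += rng.normal(0.0, CHANNEL_NOISE_SD, size=(h, w, 3))
    img = ndimage.gaussian_filter(img, sigma=(0.5, 0.5, 0.0))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
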