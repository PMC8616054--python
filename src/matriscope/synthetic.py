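"""Seeded synthetic data: fiber micrographs, AFM force curves, morphometry.

Four microstructure classes emulate the phenotypes of polymerized ECM
hydrogels imaged by collagen-I immunofluorescence:

``long_fiber``
    very long, straight, sparsely placed fibers with essentially no
    crosslinks (polymerized collagen I).
``network_sparse`` / ``network_dense``
    interconnected long strands laid down by correlated random walks with
    branching and crosslinking, forming an intricate fibrous network
    (breast-tissue matrix gels); the dense variant branches and crosslinks
    at a higher rate.
``honeycomb``
    short, variable-thickness edges of a centroidal (Lloyd-relaxed)
    Voronoi tessellation, forming distinguishable honeycomb-like meshes
    (basement-membrane-like matrix).

Every generator is a pure function of its arguments plus an integer seed:
identical calls give bit-identical output.  Each rendered image keeps the
latent :class:`FiberGraph` it was drawn from, so geometric ground truth
(branch points, fiber lengths) is available to tests and analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from skimage.draw import line as draw_line

CLASS_LABELS = ("long_fiber", "network_dense", "network_sparse", "honeycomb")

#: default tile geometry; full frames are exact multiples of this
TILE_SHAPE = (104, 120)
#: default full-frame size: a 10 x 12 grid of 104 x 120 tiles
FRAME_SHAPE = (1040, 1440)


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the image generator.

    ``n_fibers`` means straight fibers for ``long_fiber``, primary walkers
    for the network classes, and is ignored for ``honeycomb`` (which uses
    ``n_cells`` tessellation seeds).  ``None`` fields fall back to the
    class defaults in :data:`CLASS_PARAM_DEFAULTS`.
    """

    height: int = FRAME_SHAPE[0]
    width: int = FRAME_SHAPE[1]
    tile_shape: tuple[int, int] = TILE_SHAPE
    pixel_size_um: float = 0.2
    n_fibers: int | None = None
    fiber_width_px: float | None = None
    fiber_peak: float = 0.85
    background_level: float = 0.02
    noise_sd: float = 0.02
    # correlated-random-walk (network) parameters
    walk_step_px: float = 4.0
    n_steps: int = 200
    sigma_turn_deg: float | None = None
    branch_prob: float | None = None
    crosslink_radius_px: float = 2.0
    crosslink_refractory_steps: int = 6
    # honeycomb parameters
    n_cells: int = 150
    lloyd_iterations: int = 2


#: per-class defaults for the fields left ``None`` in GeneratorParams
CLASS_PARAM_DEFAULTS: dict[str, dict[str, float]] = {
    "long_fiber": {"n_fibers": 25, "fiber_width_px": 2.0},
    "network_sparse": {
        "n_fibers": 40,
        "fiber_width_px": 2.0,
        "sigma_turn_deg": 15.0,
        "branch_prob": 0.005,
    },
    "network_dense": {
        "n_fibers": 55,
        "fiber_width_px": 2.0,
        "sigma_turn_deg": 25.0,
        "branch_prob": 0.02,
    },
    "honeycomb": {"n_fibers": 0, "fiber_width_px": 3.0},
}


@dataclass
class FiberGraph:
    """Latent geometry behind a rendered image.

    ``nodes`` are (row, col) pixel coordinates.  ``edges`` index into
    ``nodes``; network fibers are chains of short edges, straight fibers a
    single long edge.  A *branch point* is any node of degree >= 3 —
    either a branching event or a crosslink junction.
    """

    nodes: np.ndarray  # (n, 2) float
    edges: np.ndarray  # (m, 2) int
    edge_widths: np.ndarray  # (m,) float
    #: per-fiber polylines for rendering: list of (width, (k, 2) points)
    polylines: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=np.int64)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    @property
    def branch_points(self) -> np.ndarray:
        """Indices of nodes with degree >= 3."""
        return np.flatnonzero(self.degrees() >= 3)

    def branch_point_density(self, height: int, width: int) -> float:
        """Branch points per 1e5 px^2."""
        return 1e5 * len(self.branch_points) / float(height * width)

    def edge_lengths(self) -> np.ndarray:
        if not len(self.edges):
            return np.zeros(0)
        a = self.nodes[self.edges[:, 0]]
        b = self.nodes[self.edges[:, 1]]
        return np.linalg.norm(a - b, axis=1)


@dataclass
class FiberImage:
    """RGB raster with intensities in [0, 1]; fiber signal in green."""

    pixels: np.ndarray  # (H, W, 3) float32 in [0, 1]
    class_label: str
    seed: int
    pixel_size_um: float = 0.2
    graph: FiberGraph | None = None
    params: GeneratorParams | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if not self.image_id:
            self.image_id = f"{self.class_label}_s{self.seed}"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class SyntheticForceCurve:
    """Noisy conical-Hertz force curve with known ground-truth modulus."""

    indentation_m: np.ndarray
    force_N: np.ndarray
    true_modulus_Pa: float
    poisson_ratio: float
    tip_half_angle_deg: float
    noise_sd_N: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.indentation_m) != len(self.force_N):
            raise ValueError("indentation and force must have equal length")
        if len(self.indentation_m) < 10:
            raise ValueError("force curve needs at least 10 samples")
        if np.any(np.diff(self.indentation_m) < 0):
            raise ValueError("indentation must be non-decreasing")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent stream for (seed, key): stable under adding more keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _resolve_params(class_label: str, params: GeneratorParams) -> GeneratorParams:
    if class_label not in CLASS_LABELS:
        raise ValueError(
            f"unknown class_label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    overrides = {
        k: v
        for k, v in CLASS_PARAM_DEFAULTS[class_label].items()
        if getattr(params, k) is None
    }
    return replace(params, **overrides)


def _chord_through(
    point: np.ndarray, theta: float, height: int, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints of the full chord through `point` at angle `theta`."""
    d = np.array([math.sin(theta), math.cos(theta)])  # (drow, dcol)
    ts: list[float] = []
    for axis, bound in ((0, height - 1), (1, width - 1)):
        if abs(d[axis]) > 1e-12:
            for edge in (0.0, float(bound)):
                t = (edge - point[axis]) / d[axis]
                p = point + t * d
                o = 1 - axis
                if -1e-9 <= p[o] <= (width - 1 if axis == 0 else height - 1) + 1e-9:
                    ts.append(t)
    if len(ts) < 2:
        return point, point
    t0, t1 = min(ts), max(ts)
    return point + t0 * d, point + t1 * d


def _long_fiber_graph(params: GeneratorParams, seed: int) -> FiberGraph:
    h, w = params.height, params.width
    diag = math.hypot(h, w)
    nodes: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    widths: list[float] = []
    polylines: list[tuple[float, np.ndarray]] = []
    for k in range(int(params.n_fibers)):
        rng = _rng(seed, 0, k)  # per-fiber stream: fiber k is stable under n_fibers
        for _ in range(200):
            p = rng.uniform([0, 0], [h - 1, w - 1])
            theta = rng.uniform(0, math.pi)
            a, b = _chord_through(p, theta, h, w)
            if np.linalg.norm(b - a) >= 0.8 * diag:
                break
        i = len(nodes)
        nodes.extend([a, b])
        edges.append((i, i + 1))
        widths.append(params.fiber_width_px)
        polylines.append((params.fiber_width_px, np.array([a, b])))
    return FiberGraph(
        nodes=np.array(nodes).reshape(-1, 2),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        edge_widths=np.array(widths),
        polylines=polylines,
    )


class _WalkState:
    """Shared bookkeeping for the correlated-random-walk classes."""

    def __init__(self, params: GeneratorParams) -> None:
        self.params = params
        self.nodes: list[tuple[float, float]] = []
        self.edges: list[tuple[int, int]] = []
        self.widths: list[float] = []
        self.polylines: list[tuple[float, np.ndarray]] = []
        self.cell_px = 4.0
        self.grid: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add_node(self, r: float, c: float, walker: int) -> int:
        idx = len(self.nodes)
        self.nodes.append((r, c))
        key = (int(r // self.cell_px), int(c // self.cell_px))
        self.grid.setdefault(key, []).append((idx, walker))
        return idx

    def nearby(self, r: float, c: float, walker: int, radius: float) -> int | None:
        kr, kc = int(r // self.cell_px), int(c // self.cell_px)
        best, best_d = None, radius
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for idx, w in self.grid.get((kr + dr, kc + dc), ()):
                    if w == walker:
                        continue
                    nr, nc = self.nodes[idx]
                    d = math.hypot(nr - r, nc - c)
                    if d <= best_d:
                        best, best_d = idx, d
        return best


def _walk_one(
    state: _WalkState,
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    n_steps: int,
    walker_id: int,
    allow_branch: bool,
    spawn_queue: list[tuple[np.ndarray, float, int]],
) -> None:
    p = state.params
    sigma = math.radians(p.sigma_turn_deg)
    h, w = p.height, p.width
    turns = rng.normal(0.0, sigma, size=n_steps)
    branch_u = rng.random(n_steps)
    cross_cooldown = 0
    pos = start.astype(float)
    node = state.add_node(pos[0], pos[1], walker_id)
    pts = [pos.copy()]
    for s in range(n_steps):
        heading += turns[s]
        pos = pos + p.walk_step_px * np.array([math.sin(heading), math.cos(heading)])
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            break
        nxt = state.add_node(pos[0], pos[1], walker_id)
        state.edges.append((node, nxt))
        state.widths.append(p.fiber_width_px)
        pts.append(pos.copy())
        # crosslink: fuse with a previously laid fiber passing within radius
        if cross_cooldown == 0:
            other = state.nearby(pos[0], pos[1], walker_id, p.crosslink_radius_px)
            if other is not None:
                state.edges.append((nxt, other))
                state.widths.append(p.fiber_width_px)
                cross_cooldown = p.crosslink_refractory_steps
        else:
            cross_cooldown -= 1
        if allow_branch and branch_u[s] < p.branch_prob:
            side = 1.0 if rng.random() < 0.5 else -1.0
            off = side * math.radians(rng.uniform(30.0, 90.0))
            length = int(rng.integers(50, 151))
            spawn_queue.append((pos.copy(), heading + off, length))
        node = nxt
    if len(pts) >= 2:
        state.polylines.append((p.fiber_width_px, np.array(pts)))


def _network_graph(params: GeneratorParams, seed: int) -> FiberGraph:
    state = _WalkState(params)
    rng = _rng(seed, 0)
    spawn: list[tuple[np.ndarray, float, int]] = []
    for k in range(int(params.n_fibers)):
        start = rng.uniform([0, 0], [params.height - 1, params.width - 1])
        heading = rng.uniform(0, 2 * math.pi)
        _walk_one(state, rng, start, heading, params.n_steps, k, True, spawn)
    # side branches walk a shorter distance and do not branch themselves
    for j, (start, heading, length) in enumerate(spawn):
        _walk_one(
            state, rng, start, heading, length, int(params.n_fibers) + j, False, spawn
        )
    return FiberGraph(
        nodes=np.array(state.nodes).reshape(-1, 2),
        edges=np.array(state.edges, dtype=np.int64).reshape(-1, 2),
        edge_widths=np.array(state.widths),
        polylines=state.polylines,
    )


def _empty_graph() -> FiberGraph:
    return FiberGraph(
        nodes=np.zeros((0, 2)),
        edges=np.zeros((0, 2), dtype=np.int64),
        edge_widths=np.zeros(0),
    )


def _honeycomb_graph(params: GeneratorParams, seed: int) -> FiberGraph:
    if params.n_cells < 4:  # Voronoi undefined below 4 generators
        return _empty_graph()
    rng = _rng(seed, 0)
    h, w = float(params.height), float(params.width)
    pts = rng.uniform([0, 0], [h, w], size=(params.n_cells, 2))

    def _voronoi(points: np.ndarray) -> Voronoi:
        # reflect across all four borders so every interior cell is finite
        refl = [
            points,
            points * [-1, 1],
            points * [1, -1],
            [2 * h, 0] + points * [-1, 1],
            [0, 2 * w] + points * [1, -1],
        ]
        return Voronoi(np.vstack(refl))

    for _ in range(params.lloyd_iterations):  # centroidal relaxation
        vor = _voronoi(pts)
        new = pts.copy()
        for i in range(params.n_cells):
            region = vor.regions[vor.point_region[i]]
            if region and -1 not in region:
                new[i] = vor.vertices[region].mean(axis=0)
        pts = np.clip(new, [1, 1], [h - 2, w - 2])

    vor = _voronoi(pts)
    node_index: dict[int, int] = {}
    nodes: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    widths: list[float] = []
    polylines: list[tuple[float, np.ndarray]] = []
    for (p1, p2), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p1 >= params.n_cells and p2 >= params.n_cells:
            continue  # ridge between mirror points only
        if -1 in verts:
            continue
        a, b = verts
        for v in (a, b):
            if v not in node_index:
                node_index[v] = len(nodes)
                nodes.append(np.clip(vor.vertices[v], [0, 0], [h - 1, w - 1]))
        width = float(rng.choice([2.0, 2.5, 3.0, 3.5, 4.0]))
        edges.append((node_index[a], node_index[b]))
        widths.append(width)
        polylines.append((width, np.array([nodes[node_index[a]], nodes[node_index[b]]])))
    return FiberGraph(
        nodes=np.array(nodes).reshape(-1, 2),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        edge_widths=np.array(widths),
        polylines=polylines,
    )


def _render(graph: FiberGraph, params: GeneratorParams, seed: int) -> np.ndarray:
    """Rasterize fibers with a Gaussian transverse profile into green."""
    h, w = params.height, params.width
    green = np.zeros((h, w), dtype=np.float64)
    by_width: dict[float, list[np.ndarray]] = {}
    for width, pts in graph.polylines:
        by_width.setdefault(round(width, 2), []).append(pts)
    for width, polys in by_width.items():
        canvas = np.zeros((h, w), dtype=np.float64)
        for pts in polys:
            pix_r: list[np.ndarray] = []
            pix_c: list[np.ndarray] = []
            ipts = np.round(pts).astype(int)
            for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
                rr, cc = draw_line(r0, c0, r1, c1)
                pix_r.append(rr)
                pix_c.append(cc)
            rr = np.concatenate(pix_r)
            cc = np.concatenate(pix_c)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            flat = np.unique(rr[ok] * w + cc[ok])  # each fiber adds once per pixel
            canvas.flat[flat] += 1.0
        sigma = width / 2.355  # FWHM of the transverse profile = fiber width
        # scale so an isolated fiber peaks near fiber_peak after blurring
        amp = params.fiber_peak * sigma * math.sqrt(2 * math.pi)
        green += gaussian_filter(canvas * amp, sigma)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = params.background_level
    img[:, :, 1] += green
    noise = _rng(seed, 1).normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img + noise, 0.0, 1.0).astype(np.float32)


def generate_image(
    class_label: str, seed: int, params: GeneratorParams | None = None
) -> FiberImage:
    """Render one synthetic immunofluorescence frame of the given class.

    The frame is built in two stages: a latent :class:`FiberGraph` is laid
    down by the class-specific geometric process, then rasterized into the
    green channel with a Gaussian transverse intensity profile plus
    clipped additive Gaussian noise on all channels.  Output dimensions
    must be exact multiples of ``params.tile_shape``.
    """
    params = _resolve_params(class_label, params or GeneratorParams())
    th, tw = params.tile_shape
    if params.height % th or params.width % tw:
        raise ValueError(
            f"image size {params.height}x{params.width} is not divisible by "
            f"tile size {th}x{tw}"
        )
    if class_label == "long_fiber":
        graph = _long_fiber_graph(params, seed)
    elif class_label in ("network_sparse", "network_dense"):
        graph = _network_graph(params, seed)
    else:
        graph = _honeycomb_graph(params, seed)
    pixels = _render(graph, params, seed)
    return FiberImage(
        pixels=pixels,
        class_label=class_label,
        seed=seed,
        pixel_size_um=params.pixel_size_um,
        graph=graph,
        params=params,
    )


def generate_dataset(
    n_images_per_class: int,
    base_seed: int,
    params: GeneratorParams | None = None,
    class_labels: Sequence[str] = CLASS_LABELS,
) -> list[FiberImage]:
    """Balanced image set: ``n_images_per_class`` frames per class.

    Per-image seeds are derived deterministically from ``base_seed`` and
    are unique across the set.
    """
    if n_images_per_class < 1:
        raise ValueError("n_images_per_class must be >= 1")
    images = []
    for ci, label in enumerate(class_labels):
        for i in range(n_images_per_class):
            seed = (base_seed * 1_000_003 + ci * 4099 + i) % (2**31 - 1)
            img = generate_image(label, seed, params)
            img.image_id = f"{label}_{i:03d}"
            images.append(img)
    return images


def hertz_cone_force(
    indentation_m: np.ndarray,
    modulus_Pa: float,
    poisson_ratio: float = 0.5,
    tip_half_angle_deg: float = 18.0,
) -> np.ndarray:
    """Conical-indenter Hertz law F = (2/pi) tan(a) E/(1-nu^2) d^2."""
    alpha = math.radians(tip_half_angle_deg)
    pref = (2.0 / math.pi) * math.tan(alpha) * modulus_Pa / (1.0 - poisson_ratio**2)
    d = np.asarray(indentation_m, dtype=float)
    return pref * d * d


def generate_force_curve(
    true_modulus_Pa: float,
    poisson_ratio: float = 0.5,
    tip_half_angle_deg: float = 18.0,
    max_depth_m: float = 1e-6,
    n_points: int = 100,
    noise_sd_N: float = 0.0,
    seed: int = 0,
) -> SyntheticForceCurve:
    """Hertz force curve with optional additive Gaussian force noise."""
    if true_modulus_Pa <= 0:
        raise ValueError("true_modulus_Pa must be positive")
    if max_depth_m <= 0:
        raise ValueError("max_depth_m must be positive")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    depth = np.linspace(0.0, max_depth_m, n_points)
    force = hertz_cone_force(depth, true_modulus_Pa, poisson_ratio, tip_half_angle_deg)
    if noise_sd_N > 0:
        force = force + _rng(seed, 2).normal(0.0, noise_sd_N, size=n_points)
    return SyntheticForceCurve(
        indentation_m=depth,
        force_N=force,
        true_modulus_Pa=true_modulus_Pa,
        poisson_ratio=poisson_ratio,
        tip_half_angle_deg=tip_half_angle_deg,
        noise_sd_N=noise_sd_N,
        seed=seed,
    )


#: multiplicative size effects of hormone / growth-factor treatment on
#: spheroid volume, relative to untreated control
DEFAULT_FOLD_EFFECTS = {"E2": 1.92, "IGF1": 2.68, "E2+IGF1": 2.74}


def generate_morphometry(
    n_per_group: int = 15,
    control_mean_volume: float = 100.0,
    fold_effects: dict[str, float] | None = None,
    cv: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-structured spheroid measurements.

    Volumes are lognormal with geometric mean ``control_mean_volume x
    fold`` per group and coefficient of variation ``cv``; at ``cv = 0``
    every volume equals its group's mean exactly.  Length and width are
    back-solved so ``(length x width^2) / 2`` reproduces each volume, with
    a random aspect ratio in [1, 1.5] (width <= length).

    Returns a tidy table with columns ``group, length, width, volume``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    folds = dict(DEFAULT_FOLD_EFFECTS if fold_effects is None else fold_effects)
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold effects must be positive")
    rng = _rng(seed, 3)
    sigma = math.sqrt(math.log1p(cv * cv))
    rows = []
    for group, fold in [("control", 1.0), *folds.items()]:
        gm = control_mean_volume * fold
        z = rng.normal(0.0, 1.0, size=n_per_group) if sigma > 0 else np.zeros(n_per_group)
        volumes = gm * np.exp(sigma * z)
        aspect = rng.uniform(1.0, 1.5, size=n_per_group)
        width = np.cbrt(2.0 * volumes / aspect)
        length = aspect * width
        for l, w_, v in zip(length, width, volumes):
            rows.append({"group": group, "length": l, "width": w_, "volume": v})
    return pd.DataFrame(rows)
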