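"""Seeded generator of ground-truthed droplet scenes.

Emulates the statistical structure of brightfield images of surfactant-
stabilized droplet populations encapsulating gut microbes: monodisperse
circular droplets (~55 µm diameter, CV ~5%) with Poisson cell occupancy
(λ ≈ 0.11), each occupied droplet following a lagged-logistic growth
trajectory drawn from a fast/slow-grower mixture.  Rendered scenes show
bright droplet interiors with dark rims on a gray background and biomass as
dark granular blobs, clumps or filaments; per-droplet ground truth (center,
radius, cell count, biomass fraction, grower class) is attached so detection
and quantification can be benchmarked against known answers.

Coordinate convention: (row, col), 0-based, origin top-left, half-open image
bounds — used everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GenerationError

__all__ = [
    "GrowerParams",
    "GrowthModelParams",
    "OpticsParams",
    "SyntheticDroplet",
    "SyntheticScene",
    "sample_occupancy",
    "sample_diameters",
    "simulate_growth",
    "simulate_trajectories",
    "render_scene",
    "generate_scene",
    "generate_series",
]

#: default pixel pitch, µm per pixel (10x objective class imaging)
DEFAULT_PIXEL_SIZE = 0.5
#: default mean droplet diameter, µm
DEFAULT_DIAMETER = 55.0
#: default diameter coefficient of variation
DEFAULT_CV = 0.05
#: default mean cells per droplet
DEFAULT_LAMBDA = 0.11

_STYLES = ("dense", "clumps", "filaments")


@dataclass(frozen=True)
class GrowerParams:
    """Lagged-logistic growth parameters for one grower class.

    ``lag`` hours of no net growth, then logistic increase at ``rate`` per
    hour toward ``capacity`` (maximum biomass area fraction, <= 1).
    """

    lag: float
    rate: float
    capacity: float

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0 h, got {self.lag}")
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0 /h, got {self.rate}")
        if not 0.0 < self.capacity <= 1.0:
            raise ValueError(f"capacity must be in (0, 1], got {self.capacity}")


@dataclass(frozen=True)
class GrowthModelParams:
    """Fast/slow grower mixture generating the bimodal growth distribution.

    Defaults emulate a gut-microbe co-culture: fast growers (lag ~2 h,
    saturating within ~6 h, filling much of the droplet) mixed with slow
    growers that accumulate modest biomass over days.  ``seed_fraction`` is
    the biomass area fraction contributed by one founding cell at t=0;
    ``jitter_sigma`` is the SD of the per-droplet multiplicative log-normal
    jitter applied to rate and capacity.
    """

    fast_fraction: float = 0.5
    fast: GrowerParams = field(default_factory=lambda: GrowerParams(2.0, 2.5, 0.60))
    slow: GrowerParams = field(default_factory=lambda: GrowerParams(4.0, 0.10, 0.25))
    seed_fraction: float = 1e-3
    jitter_sigma: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError(f"fast_fraction must be in [0, 1], got {self.fast_fraction}")
        if 0.0 < self.fast_fraction < 1.0 and self.fast.rate <= self.slow.rate:
            raise ValueError("fast rate must exceed slow rate when both classes present")
        if not 0.0 < self.seed_fraction < 1.0:
            raise ValueError(f"seed_fraction must be in (0, 1), got {self.seed_fraction}")
        if self.jitter_sigma < 0:
            raise ValueError(f"jitter_sigma must be >= 0, got {self.jitter_sigma}")


@dataclass(frozen=True)
class OpticsParams:
    """Rendering intensities (fractions of full scale) and noise level.

    Chosen so the Canny stage responds to droplet rims and biomass texture
    but not to background shot noise: rim and biomass contrasts are an order
    of magnitude above ``noise_sd``.
    """

    background: float = 0.45
    interior: float = 0.58
    rim: float = 0.12
    rim_width: float = 2.5
    biomass: float = 0.18
    biomass_texture_sd: float = 0.04
    biomass_gap_fraction: float = 0.15
    noise_sd: float = 0.012
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        for name in ("background", "interior", "rim", "biomass"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SyntheticDroplet:
    """Ground-truth record for one simulated droplet."""

    center: tuple[float, float]  # (row, col) in pixels
    radius: float  # pixels
    cell_count: int
    true_biomass_fraction: float
    grower_class: str  # 'none' | 'slow' | 'fast'
    style: str = "dense"

    def __post_init__(self) -> None:
        if self.cell_count == 0 and self.true_biomass_fraction != 0.0:
            raise ValueError("empty droplet must have zero biomass fraction")
        if self.grower_class not in ("none", "slow", "fast"):
            raise ValueError(f"unknown grower_class {self.grower_class!r}")


@dataclass(frozen=True)
class SyntheticScene:
    """Rendered image plus the ground truth that produced it."""

    image: np.ndarray
    droplets: tuple[SyntheticDroplet, ...]
    pixel_size: float  # µm per pixel
    seed: int
    timepoint: float  # hours


# ---------------------------------------------------------------------------
# occupancy and geometry sampling
# ---------------------------------------------------------------------------

def sample_occupancy(n_droplets: int, lambda_: float, seed: int) -> np.ndarray:
    """I.i.d. Poisson(λ) cell counts for ``n_droplets`` droplets."""
    if n_droplets < 1:
        raise ValueError(f"n_droplets must be >= 1, got {n_droplets}")
    if lambda_ < 0:
        raise ValueError(f"lambda_ must be >= 0, got {lambda_}")
    rng = np.random.default_rng(seed)
    return rng.poisson(lambda_, size=n_droplets)


def sample_diameters(
    n: int, mean_diameter: float, cv: float, seed: int
) -> np.ndarray:
    """Droplet diameters (µm): normal with given CV, truncated at ±4 SD."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mean_diameter <= 0:
        raise ValueError(f"mean_diameter must be > 0 um, got {mean_diameter}")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    if cv == 0:
        return np.full(n, float(mean_diameter))
    rng = np.random.default_rng(seed)
    sd = cv * mean_diameter
    d = rng.normal(mean_diameter, sd, size=n)
    # resample the rare tails beyond +-4 SD (and any non-positive draw)
    bad = (np.abs(d - mean_diameter) > 4 * sd) | (d <= 0)
    while bad.any():
        d[bad] = rng.normal(mean_diameter, sd, size=int(bad.sum()))
        bad = (np.abs(d - mean_diameter) > 4 * sd) | (d <= 0)
    return d


# ---------------------------------------------------------------------------
# growth model
# ---------------------------------------------------------------------------

def _logistic(b0: float, cap: float, rate: float, lag: float, t: float) -> float:
    """Lagged logistic: flat at b0 until ``lag``, then logistic toward cap."""
    if t <= lag:
        return b0
    # solution of db/dt = rate * b * (1 - b/cap) with b(lag) = b0
    return cap / (1.0 + ((cap - b0) / b0) * np.exp(-rate * (t - lag)))


def _droplet_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _draw_class_and_jitter(
    rng: np.random.Generator, params: GrowthModelParams
) -> tuple[str, GrowerParams]:
    """Grower class plus per-droplet jittered parameters (one draw each)."""
    cls = "fast" if rng.random() < params.fast_fraction else "slow"
    base = params.fast if cls == "fast" else params.slow
    if params.jitter_sigma > 0:
        rate = base.rate * rng.lognormal(0.0, params.jitter_sigma)
        cap = float(np.clip(base.capacity * rng.lognormal(0.0, params.jitter_sigma),
                            params.seed_fraction, 1.0))
    else:
        rate, cap = base.rate, base.capacity
    return cls, GrowerParams(base.lag, rate, cap)


def simulate_growth(
    cell_count: int,
    params: GrowthModelParams,
    t: float,
    seed: int,
    index: int = 0,
) -> tuple[float, str]:
    """Biomass fraction of one droplet at time ``t`` (hours).

    Returns ``(biomass_fraction, grower_class)``.  Empty droplets stay at
    zero.  The grower class and parameter jitter are drawn once per droplet
    from ``(seed, index)``, so evaluating the same droplet at several time
    points yields a consistent trajectory.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0 h, got {t}")
    if cell_count < 0:
        raise ValueError(f"cell_count must be >= 0, got {cell_count}")
    if cell_count == 0:
        return 0.0, "none"
    rng = _droplet_rng(seed, index)
    cls, g = _draw_class_and_jitter(rng, params)
    b0 = min(cell_count * params.seed_fraction, g.capacity)
    return float(_logistic(b0, g.capacity, g.rate, g.lag, t)), cls


def simulate_trajectories(
    cell_counts: Sequence[int],
    params: GrowthModelParams,
    timepoints: Sequence[float],
    seed: int,
) -> tuple[np.ndarray, list[str]]:
    """Biomass fractions for a droplet cohort across time points.

    Returns an ``(n_droplets, n_timepoints)`` array plus per-droplet grower
    classes; droplet identity (class, jitter) is held fixed across time.
    """
    counts = np.asarray(cell_counts)
    out = np.zeros((len(counts), len(timepoints)))
    classes: list[str] = []
    for i, c in enumerate(counts):
        if c == 0:
            classes.append("none")
            continue
        rng = _droplet_rng(seed, i)
        cls, g = _draw_class_and_jitter(rng, params)
        classes.append(cls)
        b0 = min(int(c) * params.seed_fraction, g.capacity)
        for j, t in enumerate(timepoints):
            if t < 0:
                raise ValueError(f"timepoints must be >= 0 h, got {t}")
            out[i, j] = _logistic(b0, g.capacity, g.rate, g.lag, t)
    return out, classes


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _interior_radius(radius: float, optics: OpticsParams) -> float:
    """Radius of the measurable interior inside the dark rim."""
    return radius - optics.rim_width / 2.0 - 1.0


def _paint_biomass(
    canvas: np.ndarray,
    center: tuple[float, float],
    radius: float,
    fraction: float,
    style: str,
    optics: OpticsParams,
    rng: np.random.Generator,
) -> None:
    """Darken ``fraction`` of the droplet interior with a textured pattern.

    Candidate interior pixels are ranked by a style-specific priority
    (distance to a blob center, clump centers, or a filament polyline) and
    exactly the target number of pixels is painted, so rendered coverage
    matches the ground-truth fraction to rounding.
    """
    if fraction <= 0:
        return
    r_in = _interior_radius(radius, optics)
    cy, cx = center
    r_ceil = int(np.ceil(r_in))
    rows = np.arange(int(np.floor(cy)) - r_ceil, int(np.ceil(cy)) + r_ceil + 1)
    cols = np.arange(int(np.floor(cx)) - r_ceil, int(np.ceil(cx)) + r_ceil + 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    dist = np.hypot(rr - cy, cc - cx)
    inside = dist <= r_in
    rr, cc = rr[inside], cc[inside]
    n_interior = rr.size
    target = int(round(fraction * n_interior))
    if target == 0:
        target = 1  # a founding cell is at least one visible pixel
    target = min(target, n_interior)

    if style == "dense":
        # one compact blob, off-center
        off = rng.uniform(-0.3 * r_in, 0.3 * r_in, size=2)
        prio = np.hypot(rr - (cy + off[0]), cc - (cx + off[1]))
        prio = prio + rng.normal(0.0, 0.8, size=prio.shape)  # ragged boundary
    elif style == "clumps":
        k = rng.integers(3, 7)
        ang = rng.uniform(0, 2 * np.pi, size=k)
        rad = rng.uniform(0, 0.75 * r_in, size=k)
        ky = cy + rad * np.sin(ang)
        kx = cx + rad * np.cos(ang)
        prio = np.min(
            np.hypot(rr[:, None] - ky[None, :], cc[:, None] - kx[None, :]), axis=1
        )
        prio = prio + rng.normal(0.0, 0.6, size=prio.shape)
    elif style == "filaments":
        # random-walk polyline through the interior
        n_pts = 12
        pts = np.empty((n_pts, 2))
        pts[0] = (cy + rng.uniform(-0.5, 0.5) * r_in, cx + rng.uniform(-0.5, 0.5) * r_in)
        heading = rng.uniform(0, 2 * np.pi)
        step = 0.35 * r_in
        for i in range(1, n_pts):
            heading += rng.normal(0.0, 0.7)
            nxt = pts[i - 1] + step * np.array([np.sin(heading), np.cos(heading)])
            d = np.hypot(nxt[0] - cy, nxt[1] - cx)
            if d > 0.8 * r_in:  # bounce back toward the center
                heading += np.pi
                nxt = pts[i - 1] + step * np.array([np.sin(heading), np.cos(heading)])
            pts[i] = nxt
        prio = np.full(rr.shape, np.inf)
        for p in pts:
            prio = np.minimum(prio, np.hypot(rr - p[0], cc - p[1]))
        prio = prio + rng.normal(0.0, 0.4, size=prio.shape)
    else:
        raise ValueError(f"unknown biomass style {style!r}")

    order = np.argsort(prio, kind="stable")[:target]
    sel_r, sel_c = rr[order], cc[order]
    # granular texture: mostly dark cell mass with bright inter-cell gaps a
    # few pixels across, so dense biomass carries internal edges that
    # survive the measurement blur, as real cell clumps do
    texture = optics.biomass + rng.normal(
        0.0, optics.biomass_texture_sd, size=target
    )
    if optics.biomass_gap_fraction > 0 and target > 1:
        field = gaussian_filter(
            rng.standard_normal((rows.size, cols.size)), 1.2
        )[inside][order]
        cut = np.quantile(field, 1.0 - optics.biomass_gap_fraction)
        texture[field > cut] = optics.interior
    canvas[sel_r, sel_c] = np.clip(texture, 0.0, 1.0)


def render_scene(
    droplets: Sequence[SyntheticDroplet],
    shape: tuple[int, int],
    optics: OpticsParams = OpticsParams(),
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    timepoint: float = 0.0,
) -> SyntheticScene:
    """Render droplets onto a brightfield-like grayscale image.

    Each droplet is a bright disk with a dark rim on a gray background;
    biomass is painted as dark granular pixels covering the droplet's
    ``true_biomass_fraction`` of the interior.  Additive Gaussian noise is
    applied last, then the image is quantized to the requested bit depth.
    Raises :class:`GenerationError` for out-of-bounds or overlapping
    droplets.
    """
    h, w = shape
    for i, d in enumerate(droplets):
        cy, cx = d.center
        if not (d.radius < cy < h - d.radius and d.radius < cx < w - d.radius):
            raise GenerationError(
                f"droplet {i} at {d.center} r={d.radius:.1f} exceeds image bounds {shape}"
            )
        for j, e in enumerate(droplets[:i]):
            dist = np.hypot(cy - e.center[0], cx - e.center[1])
            if dist < d.radius + e.radius:
                raise GenerationError(f"droplets {j} and {i} overlap")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10B]))
    canvas = np.full(shape, optics.background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for d in droplets:
        cy, cx = d.center
        dist = np.hypot(yy - cy, xx - cx)
        canvas[dist <= d.radius + optics.rim_width / 2] = optics.rim
        canvas[dist <= d.radius - optics.rim_width / 2] = optics.interior
    for d in droplets:
        _paint_biomass(
            canvas, d.center, d.radius, d.true_biomass_fraction, d.style, optics, rng
        )
    canvas = canvas + rng.normal(0.0, optics.noise_sd, size=shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    if optics.bit_depth == 8:
        image = np.round(canvas * 255).astype(np.uint8)
    else:
        image = np.round(canvas * 65535).astype(np.uint16)
    return SyntheticScene(
        image=image,
        droplets=tuple(droplets),
        pixel_size=pixel_size,
        seed=seed,
        timepoint=timepoint,
    )


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _place_droplets(
    radii: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
    margin: float = 3.0,
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Random non-overlapping centers with every droplet fully in bounds."""
    h, w = shape
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        lo_r, hi_r = r + margin, h - r - margin
        lo_c, hi_c = r + margin, w - r - margin
        if lo_r >= hi_r or lo_c >= hi_c:
            raise GenerationError(f"droplet radius {r:.1f} px too large for image {shape}")
        for _ in range(max_tries):
            cy = rng.uniform(lo_r, hi_r)
            cx = rng.uniform(lo_c, hi_c)
            ok = all(
                np.hypot(cy - yc, cx - xc) >= r + radii[j] + margin
                for j, (yc, xc) in enumerate(centers)
            )
            if ok:
                centers.append((cy, cx))
                break
        else:
            raise GenerationError(
                f"could not place droplet {i + 1}/{len(radii)} in image {shape}; "
                "reduce n_droplets or enlarge the image"
            )
    return centers


def generate_scene(
    n_droplets: int,
    seed: int,
    timepoint: float = 0.0,
    lambda_: float = DEFAULT_LAMBDA,
    mean_diameter: float = DEFAULT_DIAMETER,
    cv: float = DEFAULT_CV,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] = (1024, 1024),
    growth: GrowthModelParams = GrowthModelParams(),
    optics: OpticsParams = OpticsParams(),
) -> SyntheticScene:
    """Generate one fully ground-truthed scene at a single time point."""
    return generate_series(
        n_droplets,
        seed,
        [timepoint],
        lambda_=lambda_,
        mean_diameter=mean_diameter,
        cv=cv,
        pixel_size=pixel_size,
        shape=shape,
        growth=growth,
        optics=optics,
    )[0]


def generate_series(
    n_droplets: int,
    seed: int,
    timepoints: Sequence[float],
    lambda_: float = DEFAULT_LAMBDA,
    mean_diameter: float = DEFAULT_DIAMETER,
    cv: float = DEFAULT_CV,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] = (1024, 1024),
    growth: GrowthModelParams = GrowthModelParams(),
    optics: OpticsParams = OpticsParams(),
) -> list[SyntheticScene]:
    """Render one droplet cohort imaged at several incubation time points.

    Droplet identity (position, size, occupancy, grower class) is shared
    across time points — the same physical droplets re-imaged — while the
    biomass fraction follows each droplet's growth trajectory.
    """
    ss = np.random.SeedSequence(seed)
    s_occ, s_dia, s_place, s_style = (int(c.generate_state(1)[0] % 2**31)
                                      for c in ss.spawn(4))
    counts = sample_occupancy(n_droplets, lambda_, s_occ)
    diameters = sample_diameters(n_droplets, mean_diameter, cv, s_dia)
    radii_px = diameters / pixel_size / 2.0
    rng_place = np.random.default_rng(s_place)
    centers = _place_droplets(radii_px, shape, rng_place)
    rng_style = np.random.default_rng(s_style)
    styles = [
        _STYLES[rng_style.integers(len(_STYLES))] if c > 0 else "dense"
        for c in counts
    ]
    traj, classes = simulate_trajectories(counts, growth, timepoints, seed)
    scenes = []
    for j, t in enumerate(timepoints):
        droplets = [
            SyntheticDroplet(
                center=centers[i],
                radius=float(radii_px[i]),
                cell_count=int(counts[i]),
                true_biomass_fraction=float(traj[i, j]),
                grower_class=classes[i],
                style=styles[i],
            )
            for i in range(n_droplets)
        ]
        scenes.append(
            render_scene(
                droplets, shape, optics=optics, seed=seed + 7919 * j,
                pixel_size=pixel_size, timepoint=float(t),
            )
        )
    return scenes
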