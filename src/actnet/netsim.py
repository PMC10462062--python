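"""Synthetic tensed actin-network scenes and TIRF-like rendering.

This module generates ground-truth networks of parallel filament bundles
on micropatterned motor stripes, applies a per-filament-load binding law
for a force-sensitive actin-binding protein (ABP), and renders noisy
two-channel image stacks.  It emulates the reconstitution geometry in
which paired-filament complexes trapped between myosin stripes entangle
into "Y" and "star" shaped networks spanning the passivated gaps.

The binding model
-----------------
Each bundle segment of ``n`` filaments carries a total tension ``F_seg``
shared equally by its filaments, so the per-filament load is ``F_seg/n``.
The per-filament ABP occupancy is

    rho(n) = k0 * (1 + beta * g(F_seg / n))

with ``g`` the load response (identity by default, or the saturating
form ``g(x) = x / (x + x0)``).  ``beta = 0`` encodes a force-insensitive
binder (the C-terminally truncated mutant): occupancy is then constant
and total binding scales purely with bundle size, i.e. mass action.
For ``beta > 0`` and linear ``g`` the expected total ABP on a segment is
``n*k0 + k0*beta*F_seg`` — the force-dependent term is independent of
``n``, which equalizes binder numbers across bundle sizes and enriches
the ABP:actin ratio on small bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa

from .core import ImageStack, ParameterError

__all__ = [
    "StripePattern",
    "BindingParams",
    "NetworkConfig",
    "BundleGroundTruth",
    "SceneGroundTruth",
    "RenderParams",
    "RuptureModel",
    "GenerationError",
    "make_stripe_pattern",
    "binding_density",
    "sample_network",
    "render",
    "sample_rupture_times",
    "rasterize_path",
]


class GenerationError(ParameterError):
    """Scene geometry cannot be realized with the given pattern/config."""


# --------------------------------------------------------------------------
# stripe micropattern
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StripePattern:
    """Periodic motor-stripe geometry rendered on a pixel grid.

    ``stripe_width`` and ``gap_width`` are in micrometres; the first
    stripe starts at column (vertical orientation) or row (horizontal)
    zero.  Pixel intervals are half-open: pixel ``c`` covers
    ``[c*pixel_size, (c+1)*pixel_size)`` and is on-stripe iff its left
    edge falls inside a stripe of the periodic pattern.
    """

    stripe_width: float
    gap_width: float
    pixel_size: float
    image_shape: tuple[int, int]
    orientation: str = "vertical"

    def __post_init__(self) -> None:
        if self.stripe_width < 0 or self.gap_width <= 0:
            raise ParameterError("need stripe_width >= 0 and gap_width > 0")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if len(self.image_shape) != 2 or min(self.image_shape) <= 0:
            raise ParameterError(f"bad image_shape {self.image_shape}")
        if self.orientation not in ("vertical", "horizontal"):
            raise ParameterError(f"bad orientation {self.orientation!r}")

    @property
    def period(self) -> float:
        return self.stripe_width + self.gap_width

    def mask(self) -> np.ndarray:
        """Boolean on-pattern (stripe) mask of shape ``image_shape``."""
        return make_stripe_pattern(
            self.stripe_width,
            self.gap_width,
            self.pixel_size,
            self.image_shape,
            self.orientation,
        )

    def gap_spans(self) -> list[tuple[int, int]]:
        """Half-open pixel index spans of *full* gaps.

        A full gap is a run of off-pattern columns (vertical) or rows
        (horizontal) bounded by stripe pixels on both sides, so a
        structure placed in it can anchor prongs on both stripes.
        """
        m = self.mask()
        axis_profile = m[0, :] if self.orientation == "vertical" else m[:, 0]
        spans: list[tuple[int, int]] = []
        n = axis_profile.size
        i = 0
        while i < n:
            if not axis_profile[i]:
                j = i
                while j < n and not axis_profile[j]:
                    j += 1
                if i > 0 and j < n:  # bounded by stripes on both sides
                    spans.append((i, j))
                i = j
            else:
                i += 1
        return spans


def make_stripe_pattern(
    stripe_width: float,
    gap_width: float,
    pixel_size: float,
    shape: tuple[int, int],
    orientation: str = "vertical",
) -> np.ndarray:
    """Render a periodic stripe mask (True on motor stripes).

    The pattern begins with a stripe at index 0 and repeats with period
    ``stripe_width + gap_width``.  The on-pixel fraction matches
    ``stripe_width / period`` to within one pixel row of rounding.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    if stripe_width < 0 or gap_width <= 0:
        raise ParameterError("need stripe_width >= 0 and gap_width > 0")
    if len(shape) != 2 or min(shape) <= 0:
        raise ParameterError(f"bad shape {shape}")
    if orientation not in ("vertical", "horizontal"):
        raise ParameterError(f"bad orientation {orientation!r}")

    period = stripe_width + gap_width
    n = shape[1] if orientation == "vertical" else shape[0]
    # position of each pixel's leading edge within the period
    pos = (np.arange(n) * pixel_size) % period
    on = pos < stripe_width
    if orientation == "vertical":
        return np.broadcast_to(on[None, :], shape).copy()
    return np.broadcast_to(on[:, None], shape).copy()


# --------------------------------------------------------------------------
# force-activated binding law
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingParams:
    """Parameters of the force-activated occupancy law rho(n).

    k0
        Baseline per-filament ABP occupancy, expressed directly in
        rendered brightness units (photons/pixel/filament), so the ABP
        channel has camera-comparable signal at occupancy 1.
    beta
        Force-activation amplitude; 0 encodes the force-insensitive
        (truncated-mutant-like) binder.
    x0
        Saturation scale of the load response, used when
        ``g_form == "saturating"``.
    g_form
        ``"linear"``: g(x) = x; ``"saturating"``: g(x) = x / (x + x0).
    """

    k0: float = 30.0
    beta: float = 2.0
    x0: float = 1.0
    g_form: str = "linear"

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ParameterError("k0 must be positive")
        if self.beta < 0:
            raise ParameterError("beta must be non-negative")
        if self.g_form not in ("linear", "saturating"):
            raise ParameterError(f"unknown g_form {self.g_form!r}")
        if self.g_form == "saturating" and self.x0 <= 0:
            raise ParameterError("x0 must be positive for saturating g")


def binding_density(params: BindingParams, n, F_seg):
    """Per-filament ABP occupancy rho(n) = k0*(1 + beta*g(F_seg/n)).

    ``n`` (filament count >= 1) and ``F_seg`` (total segment tension,
    arbitrary force units) may be scalars or arrays.  rho is constant in
    ``n`` for beta = 0 and strictly decreasing in ``n`` for beta > 0 and
    F_seg > 0.
    """
    n = np.asarray(n, dtype=float)
    F = np.asarray(F_seg, dtype=float)
    if np.any(n < 1):
        raise ParameterError("filament count n must be >= 1")
    if np.any(F < 0):
        raise ParameterError("segment tension must be non-negative")
    x = F / n
    if params.g_form == "linear":
        g = x
    else:
        g = x / (x + params.x0)
    rho = params.k0 * (1.0 + params.beta * g)
    return rho if rho.ndim else float(rho)


# --------------------------------------------------------------------------
# ground-truth scenes
# --------------------------------------------------------------------------

@dataclass
class BundleGroundTruth:
    """One bundle segment (prong) of a simulated network."""

    segment_id: int
    path: np.ndarray  # (K, 2) float array of (row, col) knots
    n: int
    F_seg: float
    actin_density_per_filament: float
    abp_density_per_filament: float
    structure_id: int = 0
    gap_id: int = 0

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.ndim != 2 or self.path.shape[1] != 2 or len(self.path) < 2:
            raise ParameterError("path must be a (K>=2, 2) polyline")
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.F_seg < 0:
            raise ParameterError("F_seg must be >= 0")


@dataclass
class SceneGroundTruth:
    """A simulated network scene plus everything needed to score recovery."""

    pattern: StripePattern
    segments: list[BundleGroundTruth]
    binding: BindingParams
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.segments)

    def to_frame(self) -> pd.DataFrame:
        """One row per segment; paths serialized as ';'-joined r,c pairs."""
        rows = []
        for s in self.segments:
            rows.append(
                {
                    "segment_id": s.segment_id,
                    "structure_id": s.structure_id,
                    "gap_id": s.gap_id,
                    "n": s.n,
                    "F_seg": s.F_seg,
                    "actin_density_per_filament": s.actin_density_per_filament,
                    "abp_density_per_filament": s.abp_density_per_filament,
                    "path": ";".join(f"{r:.3f},{c:.3f}" for r, c in s.path),
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def segment_mask(self, index: int, width_px: int = 5) -> np.ndarray:
        """Rasterize one segment's path as a ``width_px``-wide mask."""
        return rasterize_path(
            self.segments[index].path, self.pattern.image_shape, width_px
        )


def rasterize_path(path, shape, width_px: int = 1) -> np.ndarray:
    """Rasterize a polyline into a boolean mask of the given width.

    Width is realized as a Euclidean distance threshold at
    ``(width_px - 1) / 2`` around the 1-pixel line, matching the disk
    dilation used when widening skeleton segments.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ParameterError("width_px must be a positive odd integer")
    path = np.asarray(path, dtype=float)
    line = np.zeros(shape, dtype=bool)
    pts = np.rint(path).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, shape[1] - 1)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc, _ = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        line[rr[keep], cc[keep]] = True
    if width_px == 1:
        return line
    radius = (width_px - 1) / 2
    dist = ndimage.distance_transform_edt(~line)
    return dist <= radius


@dataclass
class NetworkConfig:
    """Parameters of the random network generator.

    Structures (one per gap knot) are laid out in non-overlapping
    horizontal bands so prongs of different structures stay separated,
    with at most two prongs anchoring on each bounding stripe and
    guaranteed vertical offsets between same-side anchors so prongs
    diverge quickly from the knot (resolvable by a fixed-width
    segmentation).  ``bundle_sizes``/``bundle_size_weights`` define the
    distribution of filament counts per prong; the default weights ~ 1/n
    reproduce the qualitative prevalence of small bundles.  ``F_seg`` is
    the total tension applied to every embedded segment, reflecting
    motors pulling with similar total magnitude on a network segment
    regardless of its size; arbitrary units (only F/n ratios are
    meaningful).  ``F_seg_cv`` disperses per-segment tension around
    ``F_seg`` (lognormal, mean-preserving): total magnitude is
    independent of bundle size but fluctuates between segments as
    variable numbers of stochastically cycling motors engage each one.
    Set it to 0 for strictly equal tension everywhere.
    """

    n_structures: int = 3
    prongs_min: int = 3
    prongs_max: int = 4
    bundle_sizes: tuple[int, ...] = (1, 2, 3, 4, 6, 8)
    bundle_size_weights: tuple[float, ...] | None = None
    fixed_sizes: tuple[int, ...] | None = None
    F_seg: float = 6.0
    F_seg_cv: float = 1.0
    actin_density: float = 120.0  # a0, photons/pixel/filament before gain
    binding: BindingParams = field(default_factory=BindingParams)
    knot_margin_px: float = 14.0
    band_pad_px: float = 2.0
    min_band_px: float = 40.0

    def size_weights(self) -> np.ndarray:
        if self.bundle_size_weights is not None:
            w = np.asarray(self.bundle_size_weights, dtype=float)
            if len(w) != len(self.bundle_sizes) or np.any(w < 0) or w.sum() == 0:
                raise ParameterError("bad bundle_size_weights")
        else:
            w = 1.0 / np.asarray(self.bundle_sizes, dtype=float)
        return w / w.sum()


def sample_network(
    pattern: StripePattern,
    config: NetworkConfig | None = None,
    seed: int = 0,
) -> SceneGroundTruth:
    """Draw a random scene of Y/star structures spanning the stripe gaps.

    Each structure has one knot placed in a gap interior and 3+ prongs
    that anchor on the stripe pixels bounding that gap, with at least
    one prong on each side so the structure spans the gap.  Prong
    anchor rows are stratified within the structure's band so that
    distinct prongs are well separated away from the knot.  Deterministic
    given (pattern, config, seed).
    """
    config = config or NetworkConfig()
    rng = np.random.default_rng(seed)
    spans = pattern.gap_spans()
    if not spans:
        raise GenerationError("pattern contains no full gap")
    rows = pattern.image_shape[0]
    if pattern.orientation != "vertical":
        raise GenerationError("sample_network supports vertical stripes")

    margin = config.knot_margin_px
    usable = [s for s in spans if (s[1] - s[0]) > 2 * margin]
    if not usable:
        raise GenerationError(
            f"all gaps narrower than minimum prong length (2*{margin} px)"
        )

    band = rows / config.n_structures
    if band < config.min_band_px:
        raise GenerationError(
            f"{config.n_structures} structures need bands of at least "
            f"{config.min_band_px} px; image gives {band:.1f}"
        )

    weights = config.size_weights()
    segments: list[BundleGroundTruth] = []
    seg_id = 0
    for s_idx in range(config.n_structures):
        gap_idx = int(rng.integers(len(usable)))
        g0, g1 = usable[gap_idx]
        r0 = s_idx * band + config.band_pad_px
        r1 = (s_idx + 1) * band - config.band_pad_px
        half = (r1 - r0) / 2
        k = int(rng.integers(config.prongs_min, min(config.prongs_max, 4) + 1))
        knot_r = r0 + half + rng.uniform(-0.1, 0.1) * half
        knot_c = rng.uniform(g0 + margin, g1 - margin)

        # split prongs across the two stripes, at most two per side, so
        # same-side prongs can be given opposite vertical offsets and
        # diverge quickly from the knot
        k = max(2, min(k, 4))
        if k == 2:
            m_left = 1
        elif k == 3:
            m_left = 1 if rng.integers(2) else 2
        else:
            m_left = 2
        m_right = k - m_left
        anchors: list[tuple[float, float]] = []
        for side, m in ((0, m_left), (1, m_right)):
            col = g0 - 1 if side == 0 else g1  # last/first stripe pixel
            if m == 1:
                sign = 1 if rng.integers(2) else -1
                offs = [sign * rng.uniform(0.0, 0.6) * half]
            else:
                offs = [
                    rng.uniform(0.45, 0.8) * half,
                    -rng.uniform(0.45, 0.8) * half,
                ]
            for off in offs:
                anchors.append((knot_r + off, float(col)))

        for (ar, ac) in anchors:
            if config.fixed_sizes is not None:
                n = int(config.fixed_sizes[seg_id % len(config.fixed_sizes)])
            else:
                n = int(rng.choice(config.bundle_sizes, p=weights))
            if config.F_seg_cv > 0:
                sigma = math.sqrt(math.log1p(config.F_seg_cv**2))
                F = config.F_seg * rng.lognormal(-sigma**2 / 2, sigma)
            else:
                F = config.F_seg
            rho = binding_density(config.binding, n, F)
            segments.append(
                BundleGroundTruth(
                    segment_id=seg_id,
                    path=np.array([[knot_r, knot_c], [ar, ac]]),
                    n=n,
                    F_seg=F,
                    actin_density_per_filament=config.actin_density,
                    abp_density_per_filament=rho,
                    structure_id=s_idx,
                    gap_id=gap_idx,
                )
            )
            seg_id += 1
    return SceneGroundTruth(
        pattern=pattern, segments=segments, binding=config.binding, seed=seed
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Camera/optics emulation parameters.

    Signal formation per frame t:
      expected = blur(base * (1-bleach)^t, psf_sigma) * gain + background
      image    = Poisson(expected) + Normal(0, read_noise_sigma)
    with Poisson shot noise skipped when ``shot_noise`` is False.
    ``bleach_rate_per_frame`` may be a scalar (both channels) or a pair
    (actin, abp).
    """

    psf_sigma: float = 1.0
    background: float = 10.0
    gain: float = 1.0
    read_noise_sigma: float = 2.0
    bleach_rate_per_frame: float | tuple[float, float] = 0.002
    shot_noise: bool = True
    frame_interval: float = 2.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ParameterError("psf_sigma must be >= 0")
        if self.background < 0 or self.gain <= 0 or self.read_noise_sigma < 0:
            raise ParameterError("bad background/gain/read_noise_sigma")
        for b in self.bleach_rates():
            if not 0 <= b < 1:
                raise ParameterError("bleach rate must be in [0, 1)")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")

    def bleach_rates(self) -> tuple[float, float]:
        b = self.bleach_rate_per_frame
        return (b, b) if np.isscalar(b) else (b[0], b[1])


def _base_images(scene: SceneGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless pre-optics channel images (photons/px before gain).

    Actin signal along a segment is n * a0; ABP signal is n * rho(n).
    Overlapping segments (e.g. at the knot) add.
    """
    shape = scene.pattern.image_shape
    actin = np.zeros(shape, dtype=float)
    abp = np.zeros(shape, dtype=float)
    for seg in scene.segments:
        amp_actin = seg.n * seg.actin_density_per_filament
        amp_abp = seg.n * seg.abp_density_per_filament
        pts = np.rint(seg.path).astype(int)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc, val = line_aa(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            rr, cc, val = rr[keep], cc[keep], val[keep]
            actin[rr, cc] += amp_actin * val
            abp[rr, cc] += amp_abp * val
    return actin, abp


def render(scene: SceneGroundTruth, params: RenderParams | None = None) -> ImageStack:
    """Render a two-channel (actin, ABP) image stack from a scene.

    Deterministic given (scene, params): all randomness flows from
    ``params.seed``.
    """
    params = params or RenderParams()
    if not scene.segments:
        raise ParameterError("cannot render an empty scene")
    rng = np.random.default_rng(params.seed)
    bases = _base_images(scene)
    bleach = params.bleach_rates()
    frames = []
    for t in range(params.n_frames):
        chans = []
        for ci, base in enumerate(bases):
            signal = base * (1.0 - bleach[ci]) ** t
            if params.psf_sigma > 0:
                signal = ndimage.gaussian_filter(
                    signal, params.psf_sigma, mode="constant"
                )
            expected = signal * params.gain + params.background
            if params.shot_noise:
                img = rng.poisson(np.clip(expected, 0, None)).astype(float)
            else:
                img = expected
            if params.read_noise_sigma > 0:
                img = img + rng.normal(0.0, params.read_noise_sigma, img.shape)
            chans.append(img)
        frames.append(np.stack(chans, axis=-1))
    data = np.stack(frames, axis=0)
    return ImageStack(
        data=data,
        channels=("actin", "abp"),
        pixel_size=scene.pattern.pixel_size,
        frame_interval=params.frame_interval,
    )


# --------------------------------------------------------------------------
# paired-filament-complex lifetimes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RuptureModel:
    """Two-component exponential mixture of times to rupture.

    The bulk of paired filament complexes break after tens of seconds
    (median ``median_main``); a small fraction ``tail_fraction`` belongs
    to a long-lived tail with median ``tail_scale`` (complexes observed
    to persist for many minutes).
    """

    median_main: float = 27.0
    tail_fraction: float = 0.05
    tail_scale: float = 300.0

    def __post_init__(self) -> None:
        if self.median_main <= 0:
            raise ParameterError("median_main must be positive")
        if not 0 <= self.tail_fraction <= 1:
            raise ParameterError("tail_fraction must be a probability")
        if self.tail_fraction > 0 and self.tail_scale <= 0:
            raise ParameterError("tail_scale must be positive")


def sample_rupture_times(
    model: RuptureModel, count: int, seed: int = 0
) -> np.ndarray:
    """Draw ``count`` rupture times (seconds) from the mixture model.

    Exponential components are parameterized by their median, i.e.
    scale = median / ln 2.  Deterministic given (model, count, seed).
    """
    if count < 1:
        raise ParameterError("count must be >= 1")
    rng = np.random.default_rng(seed)
    in_tail = rng.random(count) < model.tail_fraction
    times = rng.exponential(model.median_main / math.log(2), size=count)
    if model.tail_fraction > 0:
        tail = rng.exponential(model.tail_scale / math.log(2), size=count)
        times = np.where(in_tail, tail, times)
    return times
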