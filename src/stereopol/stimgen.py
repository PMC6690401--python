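"""Random-dot stereogram synthesis.

Generates left/right image pairs of square dots on a gray (zero) background,
with full per-pixel provenance (which dot covers which pixel in which eye).
Dots are placed sequentially at uniform random positions; in the no-overlap
mode a candidate dot that would overwrite pixels of an existing dot in either
eye is rejected and redrawn.  Disparity (a uniform mean plus optional per-dot
noise) is applied to the x coordinate before the dot is drawn: a dot with
nominal (cyclopean) position ``x`` and total disparity ``delta`` is drawn at
``x + ceil(delta/2)`` in the left eye and ``x - floor(delta/2)`` in the right
eye.  Disparity is therefore the left-eye minus the right-eye feature
position, matching the receptive-field convention of the energy model (left
RF at +x0/2, right at -x0/2), so a neuron with position disparity x0 is
maximally driven by a stimulus of disparity x0.

Mixed-polarity pairs (dots of luminance +1/-1 with equal probability) are the
primitive: same-polarity and dark/darker stimuli are produced from them by
element-wise conversion, so the identical dot layout underlies every polarity
condition for a given seed.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from .exceptions import (
    DegenerateImageError,
    GeometryError,
    InfeasibleDensityError,
    PackingInfeasibleError,
    SequencingError,
)

#: sentinel used in the id rasters for background pixels
BACKGROUND = -1

#: default cap on consecutive rejected placements before giving up
DEFAULT_MAX_REJECTS = 10_000


class OverlapMode(enum.Enum):
    NO_OVERLAP = "no_overlap"
    OVERLAP = "overlap"


class PolarityMode(enum.Enum):
    MIXED = "mixed"
    WHITE = "white"
    BLACK = "black"
    DARK_DARKER = "dark_darker"


class EyeRestriction(enum.Enum):
    BOTH = "both"
    LEFT_ONLY = "left_only"
    RIGHT_ONLY = "right_only"


class OverlapCheck(enum.Enum):
    """Where the no-overlap test is evaluated.

    SHIFTED: a candidate is rejected if its *drawn* footprint (after the
    disparity shift) would overwrite dot pixels in either eye.  NOMINAL: the
    test uses the nominal (pre-shift) footprint on a cyclopean occupancy grid.
    The published one-sentence description is compatible with both; SHIFTED is
    the default.
    """

    SHIFTED = "shifted"
    NOMINAL = "nominal"


# ---------------------------------------------------------------------------
# noise models (tagged union)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoNoise:
    kind: str = field(default="none", init=False)


@dataclass(frozen=True)
class GaussianNoise:
    """Per-dot disparity noise ~ N(0, sd_px), rounded to integer pixels."""

    sd_px: float
    kind: str = field(default="gaussian", init=False)

    def __post_init__(self):
        if self.sd_px < 0:
            raise ValueError("Gaussian noise sd must be >= 0")


@dataclass(frozen=True)
class TwoPlanes:
    """Half the dots (chosen at random) get disparity offset disp_a_px, half
    disp_b_px, depicting two transparent planes."""

    disp_a_px: int
    disp_b_px: int
    kind: str = field(default="two_planes", init=False)


@dataclass(frozen=True)
class Decorrelate:
    """A fraction of dots is deleted and replaced by independently positioned
    dots in each eye."""

    fraction: float
    kind: str = field(default="decorrelate", init=False)

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("decorrelated fraction must be in [0, 1]")


NoiseModel = Union[NoNoise, GaussianNoise, TwoPlanes, Decorrelate]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusParams:
    """Full specification of a stereogram ensemble."""

    width_px: int = 100
    height_px: int = 100
    dot_size_px: int = 4
    density: float = 0.4
    overlap_mode: OverlapMode = OverlapMode.NO_OVERLAP
    polarity_mode: PolarityMode = PolarityMode.MIXED
    mean_disparity_px: int = 0
    noise_model: NoiseModel = NoNoise()
    seed: int = 0
    #: override the dot count implied by ``density`` (used to compare overlap
    #: modes at the same number of dots, as in the figure-2/7 conventions)
    n_dots_override: Optional[int] = None
    overlap_check: OverlapCheck = OverlapCheck.SHIFTED
    max_rejects: int = DEFAULT_MAX_REJECTS

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise GeometryError("image dimensions must be positive")
        if self.dot_size_px <= 0:
            raise GeometryError("dot size must be positive")
        if self.dot_size_px > min(self.width_px, self.height_px):
            raise GeometryError("dot larger than image")
        if not 0.0 <= self.density < 1.0:
            raise InfeasibleDensityError(
                f"density must be in [0, 1); got {self.density}"
            )

    @property
    def image_area_px(self) -> int:
        return self.width_px * self.height_px

    @property
    def dot_area_px(self) -> int:
        return self.dot_size_px**2

    def n_dots(self) -> int:
        if self.n_dots_override is not None:
            return int(self.n_dots_override)
        return required_dot_count(
            self.density, self.image_area_px, self.dot_area_px, self.overlap_mode
        )

    def to_dict(self) -> dict:
        d = {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "dot_size_px": self.dot_size_px,
            "density": self.density,
            "overlap_mode": self.overlap_mode.value,
            "polarity_mode": self.polarity_mode.value,
            "mean_disparity_px": self.mean_disparity_px,
            "noise_model": _noise_to_dict(self.noise_model),
            "seed": self.seed,
            "n_dots_override": self.n_dots_override,
            "overlap_check": self.overlap_check.value,
        }
        return d


def _noise_to_dict(noise: NoiseModel) -> dict:
    d = {"kind": noise.kind}
    if isinstance(noise, GaussianNoise):
        d["sd_px"] = noise.sd_px
    elif isinstance(noise, TwoPlanes):
        d["disp_a_px"] = noise.disp_a_px
        d["disp_b_px"] = noise.disp_b_px
    elif isinstance(noise, Decorrelate):
        d["fraction"] = noise.fraction
    return d


@dataclass
class DotRecord:
    """One placed dot: nominal position before disparity, pre-normalisation
    luminance, its integer noise disparity and correlation status."""

    x_px: int
    y_px: int
    luminance: float
    noise_disp_px: int = 0
    correlated: bool = True
    eye_restriction: EyeRestriction = EyeRestriction.BOTH


@dataclass
class StereoPair:
    """A left/right raster pair plus per-eye dot-id provenance maps."""

    left: np.ndarray
    right: np.ndarray
    left_ids: np.ndarray
    right_ids: np.ndarray
    dots: List[DotRecord]
    params: StimulusParams
    normalized: bool = False
    uncorrelated: bool = False

    def copy(self) -> "StereoPair":
        return StereoPair(
            left=self.left.copy(),
            right=self.right.copy(),
            left_ids=self.left_ids.copy(),
            right_ids=self.right_ids.copy(),
            dots=list(self.dots),
            params=self.params,
            normalized=self.normalized,
            uncorrelated=self.uncorrelated,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def required_dot_count(
    density: float,
    image_area_px: float,
    dot_area_px: float,
    overlap_mode: OverlapMode,
) -> int:
    """Number of square dots needed so each monocular pixel is covered with
    probability ``density``.

    Without overlap the coverage is additive, N = d * A_im / A_dot.  With
    overlap each dot leaves a pixel uncovered with probability
    (1 - A_dot/A_im), so N = ln(1 - d) / ln(1 - A_dot/A_im).
    """
    if density >= 1.0 or density < 0.0:
        raise InfeasibleDensityError(f"density must be in [0, 1); got {density}")
    if dot_area_px > image_area_px:
        raise GeometryError("dot larger than image")
    if density == 0.0:
        return 0
    if overlap_mode is OverlapMode.NO_OVERLAP:
        n = density * image_area_px / dot_area_px
    else:
        n = math.log(1.0 - density) / math.log(1.0 - dot_area_px / image_area_px)
    return int(round(n))


def _split_disparity(delta: int) -> tuple:
    """Split a total disparity into (left_shift, right_shift): the dot is
    drawn at x + left_shift in the left eye and x - right_shift in the
    right.  The extra pixel of an odd disparity goes to the left eye."""
    left = math.ceil(delta / 2)
    right = delta - left
    return left, right


def _rngs_for_pair(seed: int, pair_index: int):
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(pair_index,))
    place_ss, noise_ss = ss.spawn(2)
    return np.random.default_rng(place_ss), np.random.default_rng(noise_ss)


def _draw_noise_disparities(
    noise: NoiseModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer per-dot disparity offsets.  Drawn from a stream separate from
    dot placement so that e.g. GaussianNoise(0) is raster-identical to
    NoNoise for equal seeds."""
    if isinstance(noise, (NoNoise, Decorrelate)):
        return np.zeros(n, dtype=np.int64)
    if isinstance(noise, GaussianNoise):
        return np.rint(rng.normal(0.0, noise.sd_px, size=n)).astype(np.int64)
    if isinstance(noise, TwoPlanes):
        offsets = np.empty(n, dtype=np.int64)
        half = (n + 1) // 2
        offsets[:half] = noise.disp_a_px
        offsets[half:] = noise.disp_b_px
        rng.shuffle(offsets)
        return offsets
    raise TypeError(f"unknown noise model {noise!r}")


def _decorrelated_mask(noise: NoiseModel, n: int, rng: np.random.Generator):
    if isinstance(noise, Decorrelate) and n > 0:
        n_dec = int(round(noise.fraction * n))
        mask = np.zeros(n, dtype=bool)
        mask[rng.permutation(n)[:n_dec]] = True
        return mask
    return np.zeros(n, dtype=bool)


def _footprint(x: int, y: int, size: int, width: int, height: int):
    """Clipped slice of a dot anchored (top-left) at (x, y)."""
    x0, x1 = max(x, 0), min(x + size, width)
    y0, y1 = max(y, 0), min(y + size, height)
    if x0 >= x1 or y0 >= y1:
        return None
    return slice(y0, y1), slice(x0, x1)


def generate_pair(params: StimulusParams, pair_index: int = 0) -> StereoPair:
    """Generate one (unnormalised) stereogram pair.

    Dots are drawn sequentially.  In NO_OVERLAP mode a candidate whose drawn
    footprint would overwrite existing dot pixels (in either eye, under the
    default SHIFTED check) is abandoned and redrawn; more than
    ``params.max_rejects`` consecutive failures raises
    :class:`PackingInfeasibleError`.
    """
    W, H, s = params.width_px, params.height_px, params.dot_size_px
    place_rng, noise_rng = _rngs_for_pair(params.seed, pair_index)

    n = params.n_dots()
    noise_disp = _draw_noise_disparities(params.noise_model, n, noise_rng)
    decorrelated = _decorrelated_mask(params.noise_model, n, noise_rng)

    left = np.zeros((H, W))
    right = np.zeros((H, W))
    left_ids = np.full((H, W), BACKGROUND, dtype=np.int64)
    right_ids = np.full((H, W), BACKGROUND, dtype=np.int64)
    nominal_ids = (
        np.full((H, W), BACKGROUND, dtype=np.int64)
        if params.overlap_check is OverlapCheck.NOMINAL
        else None
    )

    no_overlap = params.overlap_mode is OverlapMode.NO_OVERLAP
    dots: List[DotRecord] = []

    def place_one(dot_id, lum, delta, eyes, record_kwargs):
        """Rejection-sample one dot; draw it and append its record."""
        sl, sr = _split_disparity(delta)
        rejects = 0
        while True:
            x = int(place_rng.integers(0, W))
            y = int(place_rng.integers(0, H))
            fl = _footprint(x + sl, y, s, W, H) if "L" in eyes else None
            fr = _footprint(x - sr, y, s, W, H) if "R" in eyes else None
            if no_overlap:
                if nominal_ids is not None:
                    fn = _footprint(x, y, s, W, H)
                    occupied = fn is not None and (nominal_ids[fn] != BACKGROUND).any()
                else:
                    occupied = (
                        fl is not None and (left_ids[fl] != BACKGROUND).any()
                    ) or (fr is not None and (right_ids[fr] != BACKGROUND).any())
                if occupied:
                    rejects += 1
                    if rejects > params.max_rejects:
                        achieved = (left_ids != BACKGROUND).mean()
                        raise PackingInfeasibleError(
                            f"gave up after {rejects} consecutive rejected "
                            f"placements (dot {dot_id + 1} of {n}); achieved "
                            f"left-eye coverage {achieved:.3f}",
                            achieved_density=float(achieved),
                        )
                    continue
            if fl is not None:
                left[fl] = lum
                left_ids[fl] = dot_id
            if fr is not None:
                right[fr] = lum
                right_ids[fr] = dot_id
            if nominal_ids is not None:
                fn = _footprint(x, y, s, W, H)
                if fn is not None:
                    nominal_ids[fn] = dot_id
            dots.append(DotRecord(x_px=x, y_px=y, luminance=lum, **record_kwargs))
            return

    for i in range(n):
        if decorrelated[i]:
            # replacement dots, independent position (and luminance) per eye
            for eyes, restriction in (
                ("L", EyeRestriction.LEFT_ONLY),
                ("R", EyeRestriction.RIGHT_ONLY),
            ):
                lum = 1.0 if place_rng.integers(0, 2) else -1.0
                place_one(
                    len(dots),
                    lum,
                    0,
                    eyes,
                    dict(noise_disp_px=0, correlated=False, eye_restriction=restriction),
                )
        else:
            lum = 1.0 if place_rng.integers(0, 2) else -1.0
            delta = params.mean_disparity_px + int(noise_disp[i])
            place_one(
                len(dots),
                lum,
                delta,
                "LR",
                dict(
                    noise_disp_px=int(noise_disp[i]),
                    correlated=True,
                    eye_restriction=EyeRestriction.BOTH,
                ),
            )

    pair = StereoPair(
        left=left,
        right=right,
        left_ids=left_ids,
        right_ids=right_ids,
        dots=dots,
        params=params,
        normalized=False,
    )
    if params.polarity_mode is not PolarityMode.MIXED:
        pair = to_same_polarity(pair, params.polarity_mode)
    return pair


def to_same_polarity(pair: StereoPair, target: PolarityMode) -> StereoPair:
    """Convert a mixed-polarity pair to a same-polarity stimulus.

    WHITE takes the absolute value (all dots +1 on 0), BLACK negates it, and
    DARK_DARKER maps white dots to dark-gray (-0.5) while black dots stay at
    -1, giving two same-sign contrasts in equal numbers.  Dot layout and
    provenance are untouched, so the identical pattern underlies every
    polarity condition.  Must precede normalisation.
    """
    if pair.normalized:
        raise SequencingError("polarity conversion must precede normalisation")
    if target is PolarityMode.MIXED:
        return pair

    def convert(r: np.ndarray) -> np.ndarray:
        if target is PolarityMode.WHITE:
            return np.abs(r)
        if target is PolarityMode.BLACK:
            return -np.abs(r)
        if target is PolarityMode.DARK_DARKER:
            return np.where(r > 0, -0.5, r)
        raise ValueError(f"unsupported polarity target {target}")

    def convert_lum(v: float) -> float:
        if target is PolarityMode.WHITE:
            return abs(v)
        if target is PolarityMode.BLACK:
            return -abs(v)
        return -0.5 if v > 0 else v

    out = pair.copy()
    out.left = convert(pair.left)
    out.right = convert(pair.right)
    out.dots = [replace(d, luminance=convert_lum(d.luminance)) for d in pair.dots]
    out.params = replace(pair.params, polarity_mode=target)
    return out


def normalize(pair: StereoPair) -> StereoPair:
    """Normalise each monocular image to zero mean and unit variance,
    modelling low-level luminance/contrast adaptation."""

    def norm(r: np.ndarray) -> np.ndarray:
        mu = r.mean()
        sd = r.std()
        if sd < 1e-12:
            raise DegenerateImageError("constant image cannot be normalised")
        return (r - mu) / sd

    out = pair.copy()
    out.left = norm(pair.left)
    out.right = norm(pair.right)
    out.normalized = True
    return out


def generate_uncorrelated_pair(params: StimulusParams, pair_index: int = 0) -> StereoPair:
    """Two independent monocular patterns with identical parameters, packaged
    as one pair: the baseline stimulus for tuning-curve normalisation."""
    a = generate_pair(params, pair_index=2 * pair_index)
    b = generate_pair(params, pair_index=2 * pair_index + 1)
    offset = len(a.dots)
    right_ids = np.where(b.right_ids == BACKGROUND, BACKGROUND, b.right_ids + offset)
    dots = [
        replace(d, eye_restriction=EyeRestriction.LEFT_ONLY, correlated=False)
        for d in a.dots
    ] + [
        replace(d, eye_restriction=EyeRestriction.RIGHT_ONLY, correlated=False)
        for d in b.dots
    ]
    return StereoPair(
        left=a.left,
        right=b.right,
        left_ids=a.left_ids,
        right_ids=right_ids,
        dots=dots,
        params=params,
        normalized=False,
        uncorrelated=True,
    )


def generate_ensemble(
    params: StimulusParams, n_patterns: int, uncorrelated: bool = False
) -> List[StereoPair]:
    """Generate ``n_patterns`` pairs with per-pair derived RNG streams."""
    gen = generate_uncorrelated_pair if uncorrelated else generate_pair
    return [gen(params, pair_index=i) for i in range(n_patterns)]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def save_pair_png(pair: StereoPair, path_prefix: str) -> None:
    """Write 8-bit grayscale PNGs (one per eye) plus a JSON parameter sidecar."""
    from PIL import Image

    lo = min(pair.left.min(), pair.right.min())
    hi = max(pair.left.max(), pair.right.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    for name, raster in (("left", pair.left), ("right", pair.right)):
        img = ((raster - lo) * scale).round().astype(np.uint8)
        Image.fromarray(img, mode="L").save(f"{path_prefix}_{name}.png")
    with open(f"{path_prefix}_params.json", "w") as fh:
        json.dump(pair.params.to_dict(), fh, indent=2)
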