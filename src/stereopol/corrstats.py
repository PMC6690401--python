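"""Empirical interocular correlation statistics.

The central quantity is the sample Pearson correlation coefficient between
the left and right images,

    r = (<LR> - <L><R>) / sqrt((<L^2> - <L>^2)(<R^2> - <R>^2)),

evaluated over all pixels, or — for the cross-correlation profile — over the
region where the two images overlap after displacing one of them.  Shifted
comparisons truncate to the overlap region; there is no wraparound and no
zero padding (padding biases r toward 0, wraparound fabricates structure).

Provenance-based pixel-pair bookkeeping divides aligned left/right pixel
pairs into "matched" pairs (forced equal: background in both eyes, or the two
images of the same correlated, zero-noise dot) and "unmatched" pairs (all
pairs disrupted by disparity noise or decorrelation), yielding the
probabilities that feed the closed-form expected-correlation theory in
:mod:`stereopol.analytic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateImageError, ProvenanceError, RangeError
from .stimgen import BACKGROUND, StereoPair


@dataclass
class CorrelationProfile:
    """Mean +/- SD correlation versus horizontal displacement, aggregated
    across an ensemble of patterns.  SD is the across-pattern SD, not SEM."""

    displacements_px: List[int]
    mean_r: List[float]
    sd_r: List[float]
    n_patterns: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "displacement_px": self.displacements_px,
                "mean_r": self.mean_r,
                "sd_r": self.sd_r,
                "n": self.n_patterns,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def se_r(self) -> np.ndarray:
        return np.asarray(self.sd_r) / np.sqrt(self.n_patterns)


@dataclass
class PixelPairStats:
    """Pixel-pair probabilities of one ensemble (or one pair).

    d    — probability a monocular pixel is covered by a dot
    m, u — probability an aligned pixel pair is matched / unmatched (u = 1-m)
    d_m  — P(dot | matched pair)
    d_u  — P(dot in one eye | unmatched pair)
    x    — P(dot in the other eye | unmatched pair with a dot in one eye)

    The fields satisfy d = m*d_m + u*d_u and x*d_u = 2*d_u - 1 exactly on the
    symmetrised counts.
    """

    d: float
    m: float
    u: float
    d_m: float
    d_u: float
    x: float
    n_pixel_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "m": self.m,
            "u": self.u,
            "d_m": self.d_m,
            "d_u": self.d_u,
            "x": self.x,
            "n_pixel_pairs": self.n_pixel_pairs,
        }


# ---------------------------------------------------------------------------


def pearson_r(left: np.ndarray, right: np.ndarray) -> float:
    """Sample Pearson correlation coefficient between two equally shaped
    rasters, invariant under independent positive affine rescaling of each."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("rasters must share shape")
    l = left.ravel()
    r = right.ravel()
    lc = l - l.mean()
    rc = r - r.mean()
    denom = np.sqrt((lc**2).sum() * (rc**2).sum())
    if denom < 1e-300 or l.std() < 1e-12 or r.std() < 1e-12:
        raise DegenerateImageError("zero-variance raster in correlation")
    return float((lc * rc).sum() / denom)


def _shifted_views(a: np.ndarray, b: np.ndarray, k: int):
    """Overlap-region views pairing a[:, x] with b[:, x - k], i.e. testing
    the hypothesis that image a is displaced k pixels rightward of b — the
    same left-minus-right sign convention as stimulus disparity."""
    W = a.shape[1]
    if abs(k) >= W:
        raise RangeError(f"displacement {k} leaves no overlap (width {W})")
    if k >= 0:
        return a[:, k:], b[:, : W - k]
    return a[:, : W + k], b[:, -k:]


def _profile(
    image_pairs: Sequence, displacements: Sequence[int]
) -> CorrelationProfile:
    displacements = [int(k) for k in displacements]
    rs = np.empty((len(image_pairs), len(displacements)))
    for i, (a, b) in enumerate(image_pairs):
        for j, k in enumerate(displacements):
            av, bv = _shifted_views(a, b, k)
            rs[i, j] = pearson_r(av, bv)
    return CorrelationProfile(
        displacements_px=displacements,
        mean_r=rs.mean(axis=0).tolist(),
        sd_r=rs.std(axis=0, ddof=1).tolist() if len(image_pairs) > 1 else [0.0] * len(displacements),
        n_patterns=len(image_pairs),
    )


def cross_correlation_profile(
    ensemble: Sequence[StereoPair], displacement_range: Sequence[int]
) -> CorrelationProfile:
    """Pearson r between left and displaced right images, per displacement,
    aggregated over the ensemble.  Peaks at the stimulus disparity for
    noise-free uniform-disparity patterns."""
    return _profile([(p.left, p.right) for p in ensemble], displacement_range)


def monocular_autocorrelation(
    ensemble: Sequence[StereoPair], lag_range: Sequence[int], eye: str = "left"
) -> CorrelationProfile:
    """Horizontal autocorrelation of one eye's image."""
    img = [(getattr(p, eye), getattr(p, eye)) for p in ensemble]
    return _profile(img, lag_range)


# ---------------------------------------------------------------------------
# provenance-based pixel-pair classification
# ---------------------------------------------------------------------------


def _pair_counts(pair: StereoPair) -> np.ndarray:
    """Raw counts [n, matched, matched_dot, unm_both, unm_left, unm_right]
    over aligned pixel pairs (alignment at the mean disparity)."""
    if pair.left_ids is None or pair.right_ids is None or pair.dots is None:
        raise ProvenanceError("pixel-pair classification requires provenance maps")
    D = pair.params.mean_disparity_px
    lid, rid = _shifted_views(pair.left_ids, pair.right_ids, D)

    n_dots = len(pair.dots)
    if n_dots:
        ok = np.array(
            [d.correlated and d.noise_disp_px == 0 for d in pair.dots], dtype=bool
        )
    else:
        ok = np.zeros(0, dtype=bool)

    ldot = lid != BACKGROUND
    rdot = rid != BACKGROUND
    both_bg = ~ldot & ~rdot
    same_dot = ldot & rdot & (lid == rid)
    if n_dots and not pair.uncorrelated:
        matched_dot = same_dot & ok[np.where(same_dot, lid, 0)]
    else:
        matched_dot = np.zeros_like(same_dot)
    matched = both_bg | matched_dot
    unmatched = ~matched

    return np.array(
        [
            matched.size,
            matched.sum(),
            matched_dot.sum(),
            (unmatched & ldot & rdot).sum(),
            (unmatched & ldot & ~rdot).sum(),
            (unmatched & ~ldot & rdot).sum(),
        ],
        dtype=np.int64,
    )


def _stats_from_counts(c: np.ndarray) -> PixelPairStats:
    n, n_m, n_md, n_bb, n_l, n_r = (int(v) for v in c)
    m = n_m / n
    u = 1.0 - m
    d_m = n_md / n_m if n_m else 0.0
    n_u = n - n_m
    if n_u:
        p_bb = n_bb / n_u
        p_l = n_l / n_u
        p_r = n_r / n_u
        # symmetrise over the two eyes so that x*d_u = 2*d_u - 1 holds exactly
        d_u = p_bb + 0.5 * (p_l + p_r)
        x = p_bb / d_u if d_u else 0.0
    else:
        # no unmatched pairs: d_u conventionally at its theoretical floor
        d_u, x = 0.5, 0.0
    d = m * d_m + u * d_u
    return PixelPairStats(d=d, m=m, u=u, d_m=d_m, d_u=d_u, x=x, n_pixel_pairs=n)


def classify_pixel_pairs(pair: StereoPair) -> PixelPairStats:
    """Classify aligned pixel pairs of one stereogram as matched/unmatched
    and return the empirical pixel-pair probabilities.

    A pair is matched iff both pixels are background or both are covered by
    the same correlated dot with zero noise disparity; every other pair is
    unmatched.  A dot displaced by (rounded) nonzero noise contributes only
    unmatched pairs, even where its two footprints happen to overlap — this
    mirrors the dichotomy of the closed-form theory, which is exact for
    decorrelation noise.
    """
    return _stats_from_counts(_pair_counts(pair))


def pooled_pixel_pair_stats(ensemble: Sequence[StereoPair]) -> PixelPairStats:
    """Pixel-pair probabilities pooled (count-wise) over an ensemble."""
    counts = np.sum([_pair_counts(p) for p in ensemble], axis=0)
    return _stats_from_counts(counts)
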