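"""Depth-resolved immunofluorescence profiles of the inner plexiform layer.

The IPL is a laminated synaptic layer whose depth is expressed as a
percentage, 0% at the inner-nuclear-layer border and 100% at the
ganglion-cell-layer border.  The dendrites of OFF and ON starburst
amacrine cells (the "ChAT bands") stratify at ~28% and ~63% depth and
serve as fiducial markers: each image's depth axis is warped so its two
reference-channel peaks land exactly on those anchors, which lets
profiles from sections with different IPL thicknesses be averaged and
compared.

Workflow: maximum-project the central slices of a confocal z-stack,
extract the mean-gray-value profile across a rectangular ROI spanning
the IPL, detect the reference-band peaks on the smoothed profile,
piecewise-linearly warp depth so the peaks sit at the anchors (applying
the identical warp to the co-registered target channel), then average
hierarchically (images -> animal -> group), normalise to the wild-type
session peak, and form group difference profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats as sstats

__all__ = [
    "ImageStack", "DepthProfile", "BandComparison",
    "project_stack", "extract_profile", "find_band_peaks",
    "reference_band_peaks", "align_profile", "average_profiles",
    "normalize_to_reference", "difference_profile", "compare_at_bands",
    "CHAT_ANCHORS",
]

#: fiducial anchor depths (% IPL) for the OFF and ON ChAT bands
CHAT_ANCHORS = (28.0, 63.0)

#: common aligned depth grid: 0..100% in 1% steps
ALIGNED_GRID = np.linspace(0.0, 100.0, 101)

DEFAULT_SMOOTHING_PCT = 2.0   # Gaussian SD for peak detection, % of IPL depth


@dataclass
class ImageStack:
    """A small two-channel confocal z-stack.

    ``pixels`` has shape (z, y, x, channel); the y axis runs from the
    outer (INL) to the inner (GCL) side of the section.  Exactly one
    channel is the stratification reference (ChAT or calretinin).
    """

    pixels: np.ndarray
    channel_names: Tuple[str, ...]
    reference_channel: str
    pixel_size: float = 1.0   # um
    z_step: float = 0.38      # um

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (z, y, x, channel)")
        if self.pixels.shape[0] < 1:
            raise ValueError("need >= 1 z-slice")
        if self.pixels.shape[3] != len(self.channel_names):
            raise ValueError("channel_names does not match channel axis")
        if self.reference_channel not in self.channel_names:
            raise ValueError("reference_channel must be one of channel_names")

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class DepthProfile:
    """Mean gray value versus normalised IPL depth for one channel."""

    depth: np.ndarray        # % IPL, strictly increasing over [0, 100]
    intensity: np.ndarray
    channel: str = ""
    group: str = ""
    animal: Optional[str] = None
    image: Optional[str] = None
    reference_peaks: Optional[Tuple[float, float]] = None  # (outer %, inner %)
    aligned: bool = False
    normalization: Optional[Tuple[str, float]] = None      # (mode, peak value)
    n_source_images: int = 1
    sem: Optional[np.ndarray] = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.depth.size != self.intensity.size:
            raise ValueError("depth and intensity differ in length")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth must be strictly increasing")

    def value_at(self, depth_pct: float) -> float:
        """Linearly interpolated intensity at a depth (%)."""
        return float(np.interp(depth_pct, self.depth, self.intensity))


# ---------------------------------------------------------------------------
# image -> profile

def project_stack(stack: ImageStack, k: int = 3,
                  n: Optional[int] = None) -> Dict[str, np.ndarray]:
    """Maximum-intensity projection of the central ``k`` of ``n`` slices.

    Returns one 2-D (y, x) image per channel, keyed by channel name.
    """
    z = stack.pixels.shape[0]
    if n is None:
        n = z
    if not (1 <= k <= n <= z):
        raise ValueError(f"need 1 <= k ({k}) <= n ({n}) <= z-slices ({z})")
    start = (n - k) // 2
    sub = stack.pixels[start:start + k]
    proj = sub.max(axis=0)
    return {name: proj[..., i] for i, name in enumerate(stack.channel_names)}


def extract_profile(image: np.ndarray,
                    roi: Tuple[int, int, int, int],
                    ipl_bounds: Tuple[int, int],
                    channel: str = "", group: str = "",
                    animal: Optional[str] = None,
                    image_id: Optional[str] = None) -> DepthProfile:
    """Mean gray value per depth row, rescaled to percent of IPL.

    ``roi`` is (row0, row1, col0, col1) with rows running outer->inner;
    ``ipl_bounds`` gives the (outer, inner) pixel rows of the IPL
    borders inside the image.  The returned depth axis spans 0-100%
    between the bounds.
    """
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError("ROI outside the image or degenerate")
    outer, inner = ipl_bounds
    if not (r0 <= outer < inner <= r1):
        raise ValueError("ipl_bounds must lie inside the ROI, outer < inner")
    rows = image[outer:inner + 1, c0:c1]
    intensity = rows.mean(axis=1)
    depth = np.linspace(0.0, 100.0, intensity.size)
    return DepthProfile(depth=depth, intensity=intensity, channel=channel,
                        group=group, animal=animal, image=image_id)


# ---------------------------------------------------------------------------
# peaks and alignment

def _band_peak_candidates(profile: DepthProfile, smoothing_pct: float):
    """Peak candidates as (smoothed index, refined index, prominence).

    Candidates come from the smoothed first/second derivatives; the
    prominence is measured on the smoothed profile (robust to pixel
    noise) while the refined index is the raw-profile maximum within
    the smoothing window (unbiased on warp-asymmetrised bands).
    """
    y = profile.intensity
    n = y.size
    sigma = smoothing_pct / 100.0 * n
    if n <= max(3, int(sigma)):
        raise ValueError("profile shorter than the smoothing window")
    ys = ndimage.gaussian_filter1d(y, sigma=sigma, mode="nearest")
    d1 = np.gradient(ys)
    d2 = np.gradient(d1)
    # downward zero crossings of d1 with concavity
    idx = np.flatnonzero((d1[:-1] > 0) & (d1[1:] <= 0))
    peaks = [i if ys[i] >= ys[i + 1] else i + 1 for i in idx]
    peaks = sorted({i for i in peaks if d2[i] < 0})
    if not peaks:
        return []
    half = max(1, int(np.ceil(2 * sigma)))
    out = []
    for i in peaks:
        # snap to the local maximum of the smoothed profile so the
        # prominence measure is well defined
        lo_s, hi_s = max(0, i - 2), min(n, i + 3)
        i_s = lo_s + int(np.argmax(ys[lo_s:hi_s]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prom = float(signal.peak_prominences(ys, [i_s])[0][0])
        lo, hi = max(0, i - half), min(n, i + half + 1)
        i_r = lo + int(np.argmax(y[lo:hi]))
        out.append((i_s, i_r, prom))
    # merge candidates that snapped/refined to the same position
    seen = {}
    for i_s, i_r, prom in out:
        if i_r not in seen or prom > seen[i_r][2]:
            seen[i_r] = (i_s, i_r, prom)
    return sorted(seen.values(), key=lambda c: c[1])


def find_band_peaks(profile: DepthProfile,
                    smoothing_pct: float = DEFAULT_SMOOTHING_PCT,
                    ) -> np.ndarray:
    """Depths (%) of local intensity maxima, by smoothed-derivative analysis.

    The profile is Gaussian-smoothed (SD = ``smoothing_pct`` of the IPL
    depth), and peaks are taken where the smoothed first derivative
    crosses zero downward while the smoothed second derivative is
    negative; each is refined to the raw-profile maximum within the
    smoothing window.  Flat or monotone profiles return an empty array.
    """
    cands = _band_peak_candidates(profile, smoothing_pct)
    if not cands:
        return np.array([])
    return profile.depth[np.array([c[1] for c in cands])]


def reference_band_peaks(profile: DepthProfile,
                         mode: str = "chat",
                         smoothing_pct: float = DEFAULT_SMOOTHING_PCT,
                         ) -> Tuple[float, float]:
    """The two fiducial peaks of a reference-channel profile.

    ``chat`` mode keeps the two most prominent peaks (the profile should
    show exactly the two SAC bands); ``calretinin`` keeps the outermost
    and innermost of the detected bands, which correspond to the OFF
    and ON SACs.
    """
    cands = _band_peak_candidates(profile, smoothing_pct)
    if len(cands) < 2:
        raise ValueError("reference profile must show at least two bands")
    if mode == "calretinin":
        sel = profile.depth[[cands[0][1], cands[-1][1]]]
    elif mode == "chat":
        top = sorted(cands, key=lambda c: c[2])[-2:]
        sel = np.sort(profile.depth[[c[1] for c in top]])
    else:
        raise ValueError("mode must be 'chat' or 'calretinin'")
    outer, inner = float(sel[0]), float(sel[1])
    if not outer < inner:
        raise ValueError("reference peaks out of order")
    return (outer, inner)


def _warp_knots(reference_peaks: Tuple[float, float],
                anchors: Tuple[float, float]) -> Tuple[np.ndarray, np.ndarray]:
    outer, inner = reference_peaks
    a_out, a_in = anchors
    if not (0.0 < outer < inner < 100.0):
        raise ValueError("reference peaks must be ordered inside (0, 100)")
    if not (0.0 < a_out < a_in < 100.0):
        raise ValueError("anchors must be ordered inside (0, 100)")
    x = np.array([0.0, outer, inner, 100.0])   # measured depth
    y = np.array([0.0, a_out, a_in, 100.0])    # aligned depth
    return x, y


def align_profile(profile: DepthProfile,
                  reference_peaks: Tuple[float, float],
                  anchors: Tuple[float, float] = CHAT_ANCHORS,
                  grid: np.ndarray = ALIGNED_GRID) -> DepthProfile:
    """Warp the depth axis so the reference peaks land on the anchors.

    The warp is piecewise linear with pinned endpoints (0 -> 0,
    100 -> 100) and interior knots (outer peak -> outer anchor, inner
    peak -> inner anchor); it is strictly monotone for any valid peak
    pair.  Intensities are resampled onto the uniform aligned grid by
    linear interpolation.  Apply with the *reference channel's* peaks
    to every co-registered channel of the same image, so all channels
    share one warp.
    """
    x, y = _warp_knots(reference_peaks, anchors)
    # resample: intensity at aligned depth g came from measured depth
    # warp^-1(g) (the inverse warp swaps the knot roles)
    src = np.interp(grid, y, x)
    intensity = np.interp(src, profile.depth, profile.intensity)
    return replace(profile,
                   depth=np.asarray(grid, float).copy(),
                   intensity=intensity,
                   reference_peaks=tuple(anchors),
                   aligned=True,
                   sem=None)


# ---------------------------------------------------------------------------
# group statistics

def average_profiles(profiles: Sequence[DepthProfile]) -> DepthProfile:
    """Pointwise mean +/- SEM of aligned profiles on a common grid."""
    if not profiles:
        raise ValueError("no profiles to average")
    states = {p.aligned for p in profiles}
    if len(states) != 1:
        raise ValueError("mixed alignment states")
    grid = profiles[0].depth
    for p in profiles[1:]:
        if p.depth.size != grid.size or not np.allclose(p.depth, grid):
            raise ValueError("profiles are not on a common depth grid")
    mat = np.stack([p.intensity for p in profiles])
    mean = mat.mean(axis=0)
    sem = (mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
           if mat.shape[0] > 1 else np.zeros_like(mean))
    first = profiles[0]
    return DepthProfile(depth=grid.copy(), intensity=mean,
                        channel=first.channel, group=first.group,
                        reference_peaks=first.reference_peaks,
                        aligned=first.aligned,
                        normalization=first.normalization,
                        n_source_images=sum(p.n_source_images for p in profiles),
                        sem=sem)


def hierarchical_average(profiles: Sequence[DepthProfile]) -> DepthProfile:
    """Average images within each animal, then animals within the group.

    Mirrors the acquisition design in which each animal contributes
    several images; the group mean and SEM are computed over animals,
    not over pooled images.
    """
    by_animal: Dict[str, List[DepthProfile]] = {}
    for p in profiles:
        by_animal.setdefault(p.animal or "unknown", []).append(p)
    per_animal = [average_profiles(ps) for ps in by_animal.values()]
    out = average_profiles(per_animal)
    return out


def normalize_to_reference(profile: DepthProfile,
                           reference_peak_value: float,
                           mode: str = "wt_session_peak") -> DepthProfile:
    """Divide intensities by the wild-type session peak intensity."""
    if reference_peak_value <= 0:
        raise ValueError("reference peak value must be > 0")
    if profile.normalization is not None:
        raise ValueError("profile is already normalized")
    return replace(profile,
                   intensity=profile.intensity / reference_peak_value,
                   sem=(profile.sem / reference_peak_value
                        if profile.sem is not None else None),
                   normalization=(mode, float(reference_peak_value)))


def difference_profile(a: DepthProfile, b: DepthProfile) -> DepthProfile:
    """Pointwise a - b (e.g. wild type minus mutant)."""
    if a.depth.size != b.depth.size or not np.allclose(a.depth, b.depth):
        raise ValueError("profiles are not on a common depth grid")
    return DepthProfile(depth=a.depth.copy(),
                        intensity=a.intensity - b.intensity,
                        channel=a.channel,
                        group=f"{a.group}-{b.group}",
                        reference_peaks=a.reference_peaks,
                        aligned=a.aligned and b.aligned)


@dataclass
class BandComparison:
    """Unpaired t test between groups at one band depth."""

    t_statistic: float
    p_value: float
    alpha_adjusted: float
    significant: bool
    mean_difference: float
    ci95: Tuple[float, float]
    n_a: int
    n_b: int
    degenerate: bool = False


def compare_at_bands(group_a: Sequence[float], group_b: Sequence[float],
                     n_comparisons: int = 1,
                     alpha: float = 0.05) -> BandComparison:
    """Unpaired t test of per-animal band intensities, Bonferroni-adjusted.

    Significance is judged at alpha / n_comparisons.  The mean
    difference (a - b) and its 95% CI are reported alongside p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 animals per group")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    alpha_adj = alpha / n_comparisons
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return BandComparison(np.nan, np.nan, alpha_adj, a.mean() != b.mean(),
                              diff, (diff, diff), a.size, b.size,
                              degenerate=True)
    t, p = sstats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                 / df)
    se = sp * np.sqrt(1 / a.size + 1 / b.size)
    tcrit = sstats.t.ppf(0.975, df)
    return BandComparison(float(t), float(p), alpha_adj,
                          bool(p < alpha_adj), diff,
                          (diff - tcrit * se, diff + tcrit * se),
                          a.size, b.size)


# ---------------------------------------------------------------------------
# TIFF ingestion

def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF, pages ordered z-major then
    channel (z0c0, z0c1, z1c0, ...)."""
    import tifffile

    z, y, x, c = stack.pixels.shape
    pages = stack.pixels.transpose(0, 3, 1, 2).reshape(z * c, y, x)
    tifffile.imwrite(path, pages.astype(np.float32),
                     metadata={"axes": "QYX",
                               "channel_names": ",".join(stack.channel_names),
                               "reference_channel": stack.reference_channel})


def read_stack(path, channel_names: Tuple[str, ...],
               reference_channel: str,
               pixel_size: float = 1.0, z_step: float = 0.38) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack` (or any
    stack with z-major, channel-minor page order)."""
    import tifffile

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    c = len(channel_names)
    if pages.shape[0] % c:
        raise ValueError("page count is not a multiple of the channel count")
    z = pages.shape[0] // c
    pixels = pages.reshape(z, c, *pages.shape[1:]).transpose(0, 2, 3, 1)
    return ImageStack(pixels=pixels, channel_names=tuple(channel_names),
                      reference_channel=reference_channel,
                      pixel_size=pixel_size, z_step=z_step)


# ---------------------------------------------------------------------------
# tidy-table serialisation

def profiles_to_frame(profiles: Sequence[DepthProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for d, v in zip(p.depth, p.intensity):
            rows.append({"depth_pct": d, "intensity": v,
                         "channel": p.channel, "group": p.group,
                         "animal": p.animal, "image": p.image,
                         "aligned": p.aligned})
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> List[DepthProfile]:
    keys = ["channel", "group", "animal", "image"]
    out = []
    for vals, sub in df.groupby(keys, dropna=False, sort=False):
        sub = sub.sort_values("depth_pct")
        meta = dict(zip(keys, vals))
        out.append(DepthProfile(
            depth=sub["depth_pct"].to_numpy(),
            intensity=sub["intensity"].to_numpy(),
            channel=meta["channel"] or "",
            group=meta["group"] or "",
            animal=None if pd.isna(meta["animal"]) else meta["animal"],
            image=None if pd.isna(meta["image"]) else meta["image"],
            aligned=bool(sub["aligned"].iloc[0]) if "aligned" in sub else False))
    return out
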