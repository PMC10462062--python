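"""Per-segment ratiometric quantification and statistics.

The canonical per-segment statistic is the ratio of means: the mean ABP
intensity over a segment mask divided by the mean actin intensity over
the same mask.  Per-pixel ratio heatmaps are provided for display and
diagnostics only.  Also here: state-window time averaging, cross-state
segment matching and fold-change tracking, per-trial normalization,
median-quadrant enrichment fractions, OLS fits, Welch's t-test, paired
pre/post comparisons, line-scan bundle counting, fixed-box ROI means,
and census/survival summaries of paired-filament-complex lifetimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import DataError, ImageStack, ParameterError

__all__ = [
    "StateWindow",
    "time_average",
    "detect_transitions",
    "measure",
    "estimate_background",
    "ratio_image",
    "match_segments",
    "max_fold_change",
    "normalize_per_trial",
    "quadrant_fraction",
    "linfit",
    "welch_test",
    "paired_compare",
    "count_peaks_linescan",
    "measure_roi",
    "pfc_census",
]


# --------------------------------------------------------------------------
# states and time averaging
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateWindow:
    """A half-open frame range [start, stop) of stable network geometry."""

    state_id: int
    start: int
    stop: int
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.stop <= self.start or self.start < 0:
            raise ParameterError(f"bad state window [{self.start}, {self.stop})")


def time_average(stack: ImageStack, window: StateWindow) -> np.ndarray:
    """Per-pixel mean of a stack over a state window; returns (Y, X, C)."""
    if window.stop > stack.n_frames:
        raise ParameterError(
            f"window [{window.start}, {window.stop}) exceeds {stack.n_frames} frames"
        )
    return stack.data[window.start : window.stop].astype(float).mean(axis=0)


def detect_transitions(
    stack: ImageStack, channel: str | int = "actin", z_threshold: float = 3.0
) -> list[StateWindow]:
    """Automatic state splitting from frame-to-frame intensity change.

    The mean absolute difference between consecutive frames of the
    chosen channel is computed; frames where it exceeds
    mean + z_threshold * sd are taken as state boundaries.  The
    returned windows are non-overlapping and tile [0, T).  This is a
    convenience stand-in for the manual identification of substantive
    rearrangements; user-supplied windows remain the primary path.
    """
    if stack.n_frames < 3:
        raise ParameterError("need at least 3 frames to detect transitions")
    ci = stack.channel_index(channel) if isinstance(channel, str) else channel
    frames = stack.data[..., ci].astype(float)
    diffs = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    cut = diffs.mean() + z_threshold * diffs.std()
    boundaries = [0] + [t + 1 for t in range(len(diffs)) if diffs[t] > cut]
    boundaries.append(stack.n_frames)
    boundaries = sorted(set(boundaries))
    return [
        StateWindow(state_id=i, start=a, stop=b, provenance="auto")
        for i, (a, b) in enumerate(zip(boundaries[:-1], boundaries[1:]))
        if b > a
    ]


# --------------------------------------------------------------------------
# per-segment measurement
# --------------------------------------------------------------------------

def measure(
    masks: np.ndarray,
    actin_img: np.ndarray,
    abp_img: np.ndarray,
    state_id: int = 0,
    region_id: int = 0,
    background: tuple[float, float] | None = None,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean intensities and ABP:actin ratio per labeled segment mask.

    ``masks`` is an integer label image (0 = background).  Optional
    ``background`` (actin, abp) is subtracted from the means before the
    ratio.  An optional ``exclude`` mask removes pixels from every
    segment before averaging (e.g. junction neighborhoods, where the
    blur of crossing bundles mixes signals); segments left with no
    pixels are dropped.  Segments whose (background-corrected) mean
    actin intensity is not positive get ``ratio = NaN`` and
    ``ratio_valid = False`` and are excluded from downstream ratio
    statistics.
    """
    masks = np.asarray(masks)
    actin_img = np.asarray(actin_img, dtype=float)
    abp_img = np.asarray(abp_img, dtype=float)
    if actin_img.shape != abp_img.shape or actin_img.shape != masks.shape:
        raise DataError("masks and channel images must share one shape")
    bg_a, bg_b = background if background is not None else (0.0, 0.0)
    if exclude is not None:
        exclude = np.asarray(exclude).astype(bool)
        if exclude.shape != masks.shape:
            raise DataError("exclude mask shape mismatch")
    rows = []
    for lbl in [int(v) for v in np.unique(masks) if v > 0]:
        sel = masks == lbl
        if exclude is not None:
            sel = sel & ~exclude
            if not sel.any():
                continue
        mean_a = float(actin_img[sel].mean()) - bg_a
        mean_b = float(abp_img[sel].mean()) - bg_b
        valid = mean_a > 0
        rows.append(
            {
                "segment_id": lbl,
                "state_id": state_id,
                "region_id": region_id,
                "area_px": int(sel.sum()),
                "mean_actin": mean_a,
                "mean_abp": mean_b,
                "ratio": mean_b / mean_a if valid else np.nan,
                "ratio_valid": valid,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "segment_id",
            "state_id",
            "region_id",
            "area_px",
            "mean_actin",
            "mean_abp",
            "ratio",
            "ratio_valid",
        ],
    )


def estimate_background(image: np.ndarray, foreground: np.ndarray) -> float:
    """Mean intensity outside the generously dilated foreground mask.

    The dilation (6 px) keeps PSF tails of the foreground out of the
    estimate; the mean (not the median) is used because the shot-noise
    distribution is skewed and its median underestimates the true
    background level.
    """
    from scipy import ndimage

    image = np.asarray(image, dtype=float)
    fg = ndimage.binary_dilation(
        np.asarray(foreground).astype(bool), iterations=6
    )
    off = image[~fg]
    if off.size == 0:
        raise DataError("foreground covers the whole image")
    return float(np.mean(off))


def ratio_image(
    actin_img: np.ndarray,
    abp_img: np.ndarray,
    mask: np.ndarray | None = None,
    actin_floor: float = 0.0,
) -> np.ndarray:
    """Per-pixel ABP:actin ratio heatmap (display/diagnostic).

    Pixels outside ``mask`` or with actin intensity <= ``actin_floor``
    are NaN and excluded from display statistics.
    """
    actin_img = np.asarray(actin_img, dtype=float)
    abp_img = np.asarray(abp_img, dtype=float)
    if actin_img.shape != abp_img.shape:
        raise DataError("channel images must share one shape")
    out = np.full(actin_img.shape, np.nan)
    ok = actin_img > actin_floor
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != actin_img.shape:
            raise DataError("mask shape mismatch")
        ok &= mask
    out[ok] = abp_img[ok] / actin_img[ok]
    return out


# --------------------------------------------------------------------------
# cross-state tracking
# --------------------------------------------------------------------------

def match_segments(
    labels_a: np.ndarray, labels_b: np.ndarray, min_iou: float = 0.5
) -> pd.DataFrame:
    """Greedy maximum-IoU matching between two label images.

    Pairs are accepted in order of descending intersection-over-union;
    each label participates in at most one match and pairs below
    ``min_iou`` are discarded.  Columns: label_a, label_b, iou.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise DataError("label images must share one shape")
    ids_a = [int(v) for v in np.unique(labels_a) if v > 0]
    ids_b = [int(v) for v in np.unique(labels_b) if v > 0]
    cands = []
    for la in ids_a:
        sel_a = labels_a == la
        area_a = sel_a.sum()
        overlap_labels = labels_b[sel_a]
        for lb in [int(v) for v in np.unique(overlap_labels) if v > 0]:
            inter = int((overlap_labels == lb).sum())
            union = int(area_a + (labels_b == lb).sum() - inter)
            iou = inter / union
            if iou >= min_iou:
                cands.append((iou, la, lb))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for iou, la, lb in cands:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        rows.append({"label_a": la, "label_b": lb, "iou": iou})
    return pd.DataFrame(rows, columns=["label_a", "label_b", "iou"])


def max_fold_change(series: Sequence[float]) -> float:
    """Maximal fold change of a per-state intensity series vs its first value.

    Returns NaN (a flagged, unusable measurement) when the baseline is
    not positive.
    """
    vals = np.asarray(list(series), dtype=float)
    if vals.size == 0:
        raise ParameterError("series is empty")
    if vals[0] <= 0:
        return float("nan")
    return float(np.max(vals) / vals[0])


# --------------------------------------------------------------------------
# population statistics
# --------------------------------------------------------------------------

def normalize_per_trial(
    table: pd.DataFrame,
    channels: Sequence[str] = ("mean_actin", "mean_abp"),
    trial_col: str = "trial",
) -> pd.DataFrame:
    """Divide each channel by its per-trial median segment intensity.

    Makes trials with different illumination/gain comparable; after
    normalization every trial's median is 1 in each channel.
    """
    if trial_col not in table.columns:
        raise DataError(f"table lacks a {trial_col!r} column")
    out = table.copy()
    for _, idx in table.groupby(trial_col).groups.items():
        for ch in channels:
            med = table.loc[idx, ch].median()
            if not np.isfinite(med) or med == 0:
                raise DataError(f"trial median of {ch} is zero or undefined")
            out.loc[idx, ch] = table.loc[idx, ch] / med
    return out


class QuadrantResult(NamedTuple):
    fraction: float
    subset: pd.DataFrame
    actin_median: float
    abp_median: float


def quadrant_fraction(
    table: pd.DataFrame,
    actin_col: str = "mean_actin",
    abp_col: str = "mean_abp",
) -> QuadrantResult:
    """Fraction of segments in the small-bundle/high-binding quadrant.

    The quadrant is (ABP strictly above the table's median ABP
    intensity) and (actin strictly below the median actin intensity);
    medians are computed over the analyzed table, i.e. per condition.
    Under independent symmetric scatter the expected fraction is 0.25;
    force-activated binding shifts it upward.
    """
    if len(table) < 2:
        raise ParameterError("need at least 2 segments")
    med_a = float(table[actin_col].median())
    med_b = float(table[abp_col].median())
    sel = (table[abp_col] > med_b) & (table[actin_col] < med_a)
    return QuadrantResult(
        fraction=float(sel.mean()),
        subset=table[sel],
        actin_median=med_a,
        abp_median=med_b,
    )


class LinFit(NamedTuple):
    slope: float
    intercept: float
    r: float


def linfit(x, y) -> LinFit:
    """Ordinary least squares line y = slope*x + intercept with Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need >= 3 paired points")
    if np.var(x) == 0:
        raise ParameterError("x has zero variance")
    if np.var(y) == 0:
        # constant response: flat fit, correlation conventionally zero
        return LinFit(slope=0.0, intercept=float(y.mean()), r=0.0)
    res = stats.linregress(x, y)
    return LinFit(slope=float(res.slope), intercept=float(res.intercept),
                  r=float(res.rvalue))


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_test(group_a, group_b) -> WelchResult:
    """Unpaired two-sided Welch's t-test (unequal variances).

    Degrees of freedom follow the Welch–Satterthwaite approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ParameterError("both groups are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def paired_compare(
    pre_table: pd.DataFrame,
    post_table: pd.DataFrame,
    key: str = "region_id",
) -> tuple[pd.DataFrame, dict]:
    """Per-region deltas of mean ratio and mean actin, pre vs post.

    Mirrors the paired before/after-ATP comparison: tables are averaged
    per region, joined on ``key``, and per-region differences
    (post - pre) of the mean ratio and mean actin intensity are
    returned together with paired summary statistics.  Keys present on
    one side only are listed in the summary and excluded.
    """
    def per_region(t: pd.DataFrame) -> pd.DataFrame:
        valid = t[t["ratio_valid"]] if "ratio_valid" in t.columns else t
        return valid.groupby(key).agg(
            mean_ratio=("ratio", "mean"), mean_actin=("mean_actin", "mean")
        )

    pre = per_region(pre_table)
    post = per_region(post_table)
    common = pre.index.intersection(post.index)
    unmatched = sorted(
        set(pre.index.symmetric_difference(post.index))
    )
    if len(common) == 0:
        raise DataError("no matching region keys between pre and post")
    delta = pd.DataFrame(
        {
            "delta_ratio": post.loc[common, "mean_ratio"]
            - pre.loc[common, "mean_ratio"],
            "delta_actin": post.loc[common, "mean_actin"]
            - pre.loc[common, "mean_actin"],
        }
    )
    summary = {
        "n_regions": int(len(common)),
        "unmatched_keys": unmatched,
        "mean_delta_ratio": float(delta["delta_ratio"].mean()),
        "mean_delta_actin": float(delta["delta_actin"].mean()),
    }
    if len(common) >= 2 and delta["delta_ratio"].std(ddof=1) > 0:
        tt = stats.ttest_rel(
            post.loc[common, "mean_ratio"], pre.loc[common, "mean_ratio"]
        )
        summary["paired_t"] = float(tt.statistic)
        summary["paired_p"] = float(tt.pvalue)
    return delta.reset_index(), summary


# --------------------------------------------------------------------------
# line scans, ROIs, census
# --------------------------------------------------------------------------

def count_peaks_linescan(profile, min_prominence: float) -> int:
    """Number of bundles crossing a line scan = prominent local maxima."""
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ParameterError("profile too short")
    peaks, _ = signal.find_peaks(profile, prominence=min_prominence)
    return int(len(peaks))


def measure_roi(
    image: np.ndarray, center: tuple[int, int], box_shape: tuple[int, int]
) -> float:
    """Mean intensity in an axis-aligned box (half-open pixel ranges).

    The box of shape (height, width) is anchored so that ``center``
    is its integer center: rows [cr - h//2, cr - h//2 + h), and
    likewise for columns.  Boxes extending outside the image are an
    error.
    """
    image = np.asarray(image, dtype=float)
    h, w = box_shape
    if h < 1 or w < 1:
        raise ParameterError("box_shape must be positive")
    r0 = center[0] - h // 2
    c0 = center[1] - w // 2
    if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise ParameterError(
            f"box {box_shape} at {center} extends outside image {image.shape}"
        )
    return float(image[r0 : r0 + h, c0 : c0 + w].mean())


def pfc_census(
    annotations: pd.DataFrame | Sequence[dict],
    frame_interval: float = 2.0,
    reference_frame: int = 10,
) -> dict:
    """Census and rupture-time summary for paired filament complexes.

    ``annotations`` records one object per row with columns ``type``
    ("single" or "paired"), ``first_frame``, ``last_intact_frame`` and
    optional ``censored`` (True when the object outlived the recording).
    Rupture time is (last_intact_frame - reference_frame) *
    frame_interval; observation conventionally starts at frame 10.
    Survival is summarized Kaplan-Meier style over censored records.
    """
    table = pd.DataFrame(annotations)
    required = {"type", "last_intact_frame"}
    if not required <= set(table.columns):
        raise DataError(f"annotations need columns {sorted(required)}")
    if "censored" not in table.columns:
        table = table.assign(censored=False)

    n_total = int(len(table))
    n_paired = int((table["type"] == "paired").sum())
    paired = table[table["type"] == "paired"]
    result: dict = {
        "n_total": n_total,
        "n_paired": n_paired,
        "paired_fraction": n_paired / n_total if n_total else float("nan"),
    }
    if len(paired):
        times = (
            paired["last_intact_frame"].to_numpy(dtype=float) - reference_frame
        ) * frame_interval
        if np.any(times < 0):
            raise DataError("negative rupture times; check reference_frame")
        observed = ~paired["censored"].to_numpy(dtype=bool)

        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter()
        km.fit(times, event_observed=observed)
        surv = km.survival_function_
        result.update(
            {
                "n_ruptures": int(observed.sum()),
                "median_rupture_s": float(km.median_survival_time_),
                "survival": pd.DataFrame(
                    {
                        "time_s": surv.index.to_numpy(dtype=float),
                        "survival": surv.iloc[:, 0].to_numpy(dtype=float),
                    }
                ),
            }
        )
    return result
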