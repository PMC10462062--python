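"""Reproducible in-silico validation studies.

Each function here defines one complete simulated study — scene
generation, rendering, segmentation, measurement, and the summary
statistic — with the study conditions fixed as defaults, so the same
computation backs both the test suite and the reproduction script.
All randomness is controlled by the ``seed`` argument.

Study conventions
-----------------
* Pattern: 2.5 um stripes with 17.5 um gaps at 0.267 um/px on a
  192 x 160 px field (two full gaps), the micropattern geometry used
  for the ABP experiments.
* Noiseless studies render without shot/read noise and with zero
  background; noisy studies use the default camera emulation (Poisson
  shot noise, 2 e- read noise, 10 photons/px background).
* Segmentation for recovery scoring uses a fixed threshold (15 photons
  noiseless; background + 20 noisy) and a 10 px minimum segment size:
  the bundle-size range spans ~20x in brightness, which makes a global
  Otsu threshold sit between brightness classes and drop single
  filaments, while junction fragments are shorter than ~10 px and true
  prongs are longer than ~18 px.
* Measurements exclude pixels within 6 px of skeleton branch points,
  where the PSF mixes the signals of crossing bundles.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import bundleseg, netquant, netsim

__all__ = [
    "STUDY_PATTERN",
    "quantify_scene",
    "segmentation_recovery",
    "binding_recovery",
    "beta0_linearity",
    "quadrant_comparison",
    "welch_calibration",
    "rupture_roundtrip",
]

STUDY_PATTERN = netsim.StripePattern(
    stripe_width=2.5,
    gap_width=17.5,
    pixel_size=0.267,
    image_shape=(192, 160),
    orientation="vertical",
)

_JUNCTION_EXCLUDE_RADIUS_PX = 6.0
_NOISELESS_THRESHOLD = 15.0
_NOISY_THRESHOLD_ABOVE_BG = 20.0
_MIN_SEGMENT_PX = 10


def _render_params(noisy: bool, seed: int) -> netsim.RenderParams:
    if noisy:
        return netsim.RenderParams(seed=seed)
    return netsim.RenderParams(
        shot_noise=False, read_noise_sigma=0.0, background=0.0, seed=seed
    )


def _seg_config(noisy: bool, rp: netsim.RenderParams) -> bundleseg.SegConfig:
    thr = (
        rp.background + _NOISY_THRESHOLD_ABOVE_BG
        if noisy
        else _NOISELESS_THRESHOLD
    )
    return bundleseg.SegConfig(
        threshold_method="fixed", threshold=thr,
        min_segment_px=_MIN_SEGMENT_PX,
    )


def _junction_exclusion(res: bundleseg.SegmentationResult) -> np.ndarray | None:
    if not len(res.branch_pts):
        return None
    pts = np.zeros(res.masks.shape, dtype=bool)
    pts[res.branch_pts[:, 0], res.branch_pts[:, 1]] = True
    return ndimage.distance_transform_edt(~pts) <= _JUNCTION_EXCLUDE_RADIUS_PX


def quantify_scene(
    scene: netsim.SceneGroundTruth,
    noisy: bool,
    seed: int,
    match_truth: bool = False,
) -> tuple[pd.DataFrame, bundleseg.SegmentationResult]:
    """Render, segment and measure one scene under the study conditions.

    With ``match_truth`` the returned table gains an ``n`` column with
    the ground-truth filament count of the best-overlapping true prong
    (IoU >= 0.3 greedy matching); unmatched segments are dropped.
    """
    rp = _render_params(noisy, seed)
    stack = netsim.render(scene, rp)
    actin = stack.data[0, ..., 0]
    abp = stack.data[0, ..., 1]
    res = bundleseg.segment_pipeline(actin, _seg_config(noisy, rp))
    if res.n_segments == 0:
        return pd.DataFrame(), res
    background = None
    if noisy:
        fg = res.masks > 0
        background = (
            netquant.estimate_background(actin, fg),
            netquant.estimate_background(abp, fg),
        )
    table = netquant.measure(
        res.masks, actin, abp,
        background=background, exclude=_junction_exclusion(res),
    )
    if match_truth:
        truth = np.zeros(scene.pattern.image_shape, dtype=int)
        for i in range(len(scene)):
            m = scene.segment_mask(i, 5)
            truth[m & (truth == 0)] = i + 1
        matches = netquant.match_segments(res.masks, truth, min_iou=0.3)
        n_map = {
            row.label_a: scene.segments[row.label_b - 1].n
            for row in matches.itertuples()
        }
        table["n"] = table["segment_id"].map(n_map)
        table = table.dropna(subset=["n"])
    return table, res


def segmentation_recovery(n_scenes: int = 100, seed: int = 0) -> dict:
    """Segment-count and mask-overlap recovery on noiseless scenes.

    For each seeded scene (random bundle sizes), the automated pipeline
    is run on the noiseless actin channel and compared with ground
    truth: exact segment-count agreement, and per-mask IoU against the
    5-px-wide rasterized true prongs under greedy matching.
    """
    cfg = netsim.NetworkConfig()
    exact = 0
    all_ious: list[float] = []
    scenes_all_ok = 0
    for i in range(n_scenes):
        scene_seed = seed * 100_003 + i
        scene = netsim.sample_network(STUDY_PATTERN, cfg, seed=scene_seed)
        rp = _render_params(False, scene_seed)
        stack = netsim.render(scene, rp)
        res = bundleseg.segment_pipeline(
            stack.data[0, ..., 0], _seg_config(False, rp)
        )
        truth = np.zeros(STUDY_PATTERN.image_shape, dtype=int)
        for j in range(len(scene)):
            m = scene.segment_mask(j, 5)
            truth[m & (truth == 0)] = j + 1
        matches = netquant.match_segments(res.masks, truth, min_iou=0.0)
        ious = matches["iou"].to_numpy()
        all_ious.extend(ious)
        count_ok = res.n_segments == len(scene)
        overlap_ok = len(matches) == res.n_segments and (ious >= 0.5).all()
        exact += count_ok
        scenes_all_ok += count_ok and overlap_ok
    return {
        "n_scenes": n_scenes,
        "count_exact_rate": exact / n_scenes,
        "all_masks_iou_ok_rate": scenes_all_ok / n_scenes,
        "median_iou": float(np.median(all_ious)) if all_ious else float("nan"),
        "min_iou": float(np.min(all_ious)) if all_ious else float("nan"),
    }


def binding_recovery(
    noisy: bool, n_scenes: int | None = None, seed: int = 0
) -> dict:
    """Recover the binding-law parameters by regressing ratio on 1/n.

    Scenes use a fixed calibration grid of bundle sizes (1,2,3,4,6,8)
    and strictly equal segment tension (F_seg_cv = 0) so the expected
    per-segment ratio is exactly k0/a0 + (k0*beta*F/a0)/n.  An OLS fit
    of measured segment ratio against 1/n then estimates slope
    k0*beta*F/a0 and intercept k0/a0; relative errors against the
    configured truth are reported.
    """
    if n_scenes is None:
        n_scenes = 20 if noisy else 6
    binding = netsim.BindingParams()
    cfg = netsim.NetworkConfig(
        binding=binding, fixed_sizes=(1, 2, 3, 4, 6, 8), F_seg_cv=0.0
    )
    a0 = cfg.actin_density
    expected_slope = binding.k0 * binding.beta * cfg.F_seg / a0
    expected_intercept = binding.k0 / a0
    tables = []
    for i in range(n_scenes):
        scene_seed = seed * 100_003 + 50_000 + i
        scene = netsim.sample_network(STUDY_PATTERN, cfg, seed=scene_seed)
        table, _ = quantify_scene(scene, noisy, scene_seed, match_truth=True)
        if len(table):
            tables.append(table)
    t = pd.concat(tables, ignore_index=True)
    t = t[t["ratio_valid"]]
    fit = netquant.linfit(1.0 / t["n"], t["ratio"])
    return {
        "n_segments": int(len(t)),
        "slope": fit.slope,
        "intercept": fit.intercept,
        "expected_slope": expected_slope,
        "expected_intercept": expected_intercept,
        "slope_rel_err": abs(fit.slope - expected_slope) / expected_slope,
        "intercept_rel_err": abs(fit.intercept - expected_intercept)
        / expected_intercept,
        "r": fit.r,
    }


def beta0_linearity(n_scenes: int = 8, seed: int = 0) -> dict:
    """Pearson r of ABP vs actin intensity for force-insensitive scenes.

    With beta = 0 the occupancy law is constant, so noiseless ABP
    intensity is strictly proportional to actin intensity across
    segments — the linear mass-action regime of the no-force and
    truncated-mutant conditions.
    """
    cfg = netsim.NetworkConfig(
        binding=netsim.BindingParams(beta=0.0)
    )
    tables = []
    for i in range(n_scenes):
        scene_seed = seed * 100_003 + 80_000 + i
        scene = netsim.sample_network(STUDY_PATTERN, cfg, seed=scene_seed)
        table, _ = quantify_scene(scene, False, scene_seed)
        if len(table):
            tables.append(table)
    t = pd.concat(tables, ignore_index=True)
    t = t[t["ratio_valid"]]
    fit = netquant.linfit(t["mean_actin"], t["mean_abp"])
    return {"n_segments": int(len(t)), "r": fit.r, "slope": fit.slope}


def quadrant_comparison(
    n_replicates: int = 100, scenes_per_condition: int = 8, seed: int = 0
) -> dict:
    """Paired force vs no-force comparison of the quadrant fraction.

    Each replicate renders the same seeded scenes once with the
    force-activated binder (default beta) and once with beta = 0, under
    realistic noise, and computes the fraction of segments in the
    (above-median ABP, below-median actin) quadrant per condition.
    Reported: the rate of replicates where the force condition has the
    strictly larger fraction, and the mean fractions.
    """
    frac_force = []
    frac_noforce = []
    for rep in range(n_replicates):
        fractions = {}
        for beta in (netsim.BindingParams().beta, 0.0):
            cfg = netsim.NetworkConfig(
                binding=netsim.BindingParams(beta=beta)
            )
            tables = []
            for i in range(scenes_per_condition):
                scene_seed = (
                    seed * 100_003 + 200_000 + rep * scenes_per_condition + i
                )
                scene = netsim.sample_network(
                    STUDY_PATTERN, cfg, seed=scene_seed
                )
                table, _ = quantify_scene(scene, True, scene_seed)
                if len(table):
                    tables.append(table)
            t = pd.concat(tables, ignore_index=True)
            t = t[t["ratio_valid"]]
            fractions[beta] = netquant.quadrant_fraction(t).fraction
        frac_force.append(fractions[netsim.BindingParams().beta])
        frac_noforce.append(fractions[0.0])
    frac_force_arr = np.asarray(frac_force)
    frac_noforce_arr = np.asarray(frac_noforce)
    return {
        "n_replicates": n_replicates,
        "win_rate": float((frac_force_arr > frac_noforce_arr).mean()),
        "mean_fraction_force": float(frac_force_arr.mean()),
        "mean_fraction_noforce": float(frac_noforce_arr.mean()),
    }


def welch_calibration(
    n_simulations: int = 2000, n_per_group: int = 50, seed: int = 0
) -> dict:
    """Type-I error of the two-sided Welch test under the null.

    Both groups are drawn from the same standard normal; the rejection
    rate at alpha = 0.05 should be close to 0.05.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_simulations, n_per_group))
    b = rng.standard_normal((n_simulations, n_per_group))
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return {
        "n_simulations": n_simulations,
        "rejection_rate": float((res.pvalue < 0.05).mean()),
    }


def rupture_roundtrip(n_samples: int = 10_000, seed: int = 0) -> dict:
    """Simulate rupture times and recover the median through the census.

    Times are drawn from the single-component lifetime model (median
    27 s, no long-lived tail), converted to frame annotations, and
    summarized by the census; the recovered Kaplan-Meier median should
    match the configured median.
    """
    model = netsim.RuptureModel(median_main=27.0, tail_fraction=0.0)
    frame_interval = 2.0
    reference_frame = 10
    times = netsim.sample_rupture_times(model, n_samples, seed=seed)
    records = pd.DataFrame(
        {
            "type": "paired",
            "first_frame": reference_frame,
            "last_intact_frame": reference_frame + times / frame_interval,
        }
    )
    census = netquant.pfc_census(records, frame_interval, reference_frame)
    return {
        "n_samples": n_samples,
        "configured_median_s": model.median_main,
        "recovered_median_s": census["median_rupture_s"],
        "rel_err": abs(census["median_rupture_s"] - model.median_main)
        / model.median_main,
    }
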