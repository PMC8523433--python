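"""Reproducible validation experiments on synthetic mosaics.

Each function builds its own inputs with the synthetic generator, runs the
pipeline, and returns the measured quantities.  They exist so the package's
validation claims — closed-form lattice recovery, preset parameter
recovery, test–retest repeatability, statistical calibration — are a
single function call away for tests, scripts and documentation alike.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Sequence

import numpy as np

from .detection import DetectionParams, crop_cones, detect_cones, to_16bit_sharpened
from .geometry import ROISpec, radius_for_eccentricity
from .io import RunConfig
from .metrics import delaunay_icd, metrics_from_cones
from .stats import friedman_test, wilcoxon_signed_rank
from .study import repeatability_analysis, simulate_cohort
from .synthetic import (
    SyntheticMosaicSpec,
    eccentricity_preset,
    generate_mosaic,
    pathology_preset,
    render_image,
)


def lattice_closed_form(
    spacing_um: float = 10.0,
    region_um: float = 300.0,
    margin_um: float = 30.0,
    pixel_scale_um: float = 0.25,
    radius_um: float = 2.63,
    seed: int = 0,
) -> Dict[str, float]:
    """Run the full pipeline on a noise-free rendered triangular lattice.

    The lattice is rendered on a supersampled grid (default 0.25 µm/px) so
    pixel quantization does not confound the geometric closed forms, then
    cones are detected and metrics taken on an interior window (half-open,
    ``margin_um`` in from every side) where boundary censoring is absent.
    Closed forms: density 2/(√3·s²), hexagonality 100%, ICD = NND = s.
    """
    spec = SyntheticMosaicSpec(
        spacing_um=spacing_um, jitter_frac=0.0, dropout_frac=0.0,
        reflectivity_cv=0.0, background_sd=0.0, region_um=region_um,
        pixel_scale_um=pixel_scale_um, seed=seed,
    )
    truth = generate_mosaic(spec)
    image = render_image(truth)
    det = detect_cones(to_16bit_sharpened(image), DetectionParams(radius_um=radius_um))
    hi = region_um - margin_um
    sub = crop_cones(det, margin_um, margin_um, hi, hi)
    side = region_um - 2 * margin_um
    m = metrics_from_cones(sub, ROISpec(2.0, "temporal", side))
    return {
        "n_cones": float(m.n_cones),
        "density_cones_per_mm2": m.density_cones_per_mm2,
        "hexagonality_pct": m.hexagonality_pct,
        "icd_um": delaunay_icd(sub, exclude_hull=True),
        "nnd_um": m.nnd_um,
    }


def preset_recovery(
    ecc_deg: float,
    seeds: Sequence[int],
    region_um: float = 240.0,
    margin_um: float = 9.0,
) -> Dict[str, object]:
    """Detected-vs-truth recovery at a healthy-eccentricity preset.

    For each seed a mosaic is generated at the preset density, rendered and
    analyzed; detected and ground-truth cones are compared on the same
    interior window (``margin_um`` clear of the borders, beyond the
    detector's edge-exclusion band) so both densities share one footprint.
    """
    radius = radius_for_eccentricity(ecc_deg)
    params = DetectionParams(radius_um=radius)
    d_ratio, n_ratio, det_density, hex_pct = [], [], [], []
    side = region_um - 2 * margin_um
    roi = ROISpec(ecc_deg, "temporal", side)
    for seed in seeds:
        spec = eccentricity_preset(ecc_deg, seed=int(seed), region_um=region_um)
        truth = generate_mosaic(spec)
        det = detect_cones(to_16bit_sharpened(render_image(truth)), params)
        hi = region_um - margin_um
        md = metrics_from_cones(crop_cones(det, margin_um, margin_um, hi, hi), roi)
        mg = metrics_from_cones(crop_cones(truth.cones, margin_um, margin_um, hi, hi), roi)
        d_ratio.append(md.density_cones_per_mm2 / mg.density_cones_per_mm2)
        n_ratio.append(md.nnd_um / mg.nnd_um)
        det_density.append(md.density_cones_per_mm2)
        hex_pct.append(md.hexagonality_pct)
    return {
        "density_ratio_mean": float(np.mean(d_ratio)),
        "nnd_ratio_mean": float(np.mean(n_ratio)),
        "density_ratios": d_ratio,
        "nnd_ratios": n_ratio,
        "detected_density_mean": float(np.mean(det_density)),
        "hexagonality_mean": float(np.mean(hex_pct)),
    }


def mean_detected_density(
    ecc_deg: float, seeds: Sequence[int], region_um: float = 480.0
) -> float:
    """Mean whole-field analyzed density at a preset (larger fields damp
    the Monte-Carlo noise of the estimate)."""
    from .metrics import analyze_roi

    params = DetectionParams(radius_um=radius_for_eccentricity(ecc_deg))
    roi = ROISpec(ecc_deg, "temporal", region_um)
    vals = []
    for seed in seeds:
        spec = eccentricity_preset(ecc_deg, seed=int(seed), region_um=region_um)
        vals.append(
            analyze_roi(render_image(generate_mosaic(spec)), roi, params).density_cones_per_mm2
        )
    return float(np.mean(vals))


def repeatability_experiment(seed: int = 0, n_subjects: int = 10) -> Dict[str, object]:
    """Test–retest harness: each synthetic subject's retina (ground-truth
    mosaic at 2°) is rendered twice with independent reflectivity/noise
    draws; per-metric ICC(2,1) across the two sessions is returned."""
    cfg = RunConfig(seed=seed, eccentricities_deg=(2.0,), meridians=("temporal",))
    baseline = simulate_cohort(cfg, n_subjects=n_subjects, session=0)
    followup = simulate_cohort(cfg, n_subjects=n_subjects, session=1, renoise_only=True)
    return repeatability_analysis(baseline, followup)


def null_calibration(n_reps: int = 2000, seed: int = 0, n: int = 10, k: int = 5,
                     alpha: float = 0.05) -> Dict[str, float]:
    """Empirical type-I error of the Friedman and Wilcoxon tests under
    i.i.d. Gaussian nulls."""
    rng = np.random.default_rng([seed, 42])
    rej_f = rej_w = 0
    for _ in range(n_reps):
        rej_f += friedman_test(rng.normal(size=(n, k))).p_value < alpha
        rej_w += wilcoxon_signed_rank(rng.normal(size=12), rng.normal(size=12)).p_value < alpha
    return {
        "friedman_type1": rej_f / n_reps,
        "wilcoxon_type1": rej_w / n_reps,
        "n_reps": float(n_reps),
    }


def pathology_metrics(scenario: str, seeds: Sequence[int]) -> Dict[str, float]:
    """Seed-averaged analyzed metrics for a pathology preset."""
    roi = ROISpec(2.0, "temporal", 240.0)
    params = DetectionParams(radius_um=radius_for_eccentricity(2.0))
    dens, nnds, hexs, icds = [], [], [], []
    for seed in seeds:
        truth = generate_mosaic(pathology_preset(scenario, seed=int(seed)))
        det = detect_cones(to_16bit_sharpened(render_image(truth)), params)
        m = metrics_from_cones(det, roi)
        dens.append(m.density_cones_per_mm2)
        nnds.append(m.nnd_um)
        hexs.append(m.hexagonality_pct)
        icds.append(m.icd_um)
    return {
        "density_cones_per_mm2": float(np.mean(dens)),
        "nnd_um": float(np.mean(nnds)),
        "hexagonality_pct": float(np.mean(hexs)),
        "icd_um": float(np.mean(icds)),
    }
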