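"""The three study arms: metrics survey, repeatability, validation.

* **metrics** — a cohort of per-ROI mosaic metrics is summarized across
  eccentricity: a Friedman test for an overall eccentricity effect per
  metric (blocks = subject × meridian), Wilcoxon signed-rank tests between
  consecutive eccentricities, and Holm–Bonferroni correction across the
  post-hoc family.
* **repeatability** — baseline and follow-up metric tables matched by
  (subject, ecc_deg, meridian) yield one ICC(2,1) per metric.
* **validation** — paired automated vs manual cone densities are compared
  by Bland–Altman analysis with a proportional-bias regression.

``simulate_cohort`` builds a fully synthetic cohort (subjects ×
eccentricities × meridians) so all three arms run end-to-end without any
acquired images.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detection import DetectionParams
from .geometry import RadiusTable, ROISpec, radius_for_eccentricity
from .io import RunConfig
from .metrics import analyze_roi
from .stats import (
    AgreementResult,
    RepeatabilityResult,
    TestResult,
    bland_altman,
    friedman_test,
    holm_bonferroni,
    icc_2way_random_single_absolute,
    wilcoxon_signed_rank,
)
from .synthetic import eccentricity_preset, generate_mosaic, render_image, with_seed

METRIC_NAMES = ("density", "hex_pct", "icd_um", "nnd_um")


def _derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31 from integer parts."""
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_synthetic_roi(
    ecc_deg: float,
    seed: int,
    config: Optional[RunConfig] = None,
    density_factor: float = 1.0,
    noise_seed: Optional[int] = None,
):
    """Generate, render and analyze one synthetic ROI at an eccentricity.

    Returns (MosaicMetrics, GroundTruth).  ``density_factor`` scales the
    preset target density (inter-subject variation); ``noise_seed``
    re-noises the rendering independently of the mosaic seed.
    """
    config = config or RunConfig()
    spec = eccentricity_preset(
        ecc_deg,
        seed=seed,
        region_um=config.roi_side_um,
        pixel_scale_um=config.pixel_scale_um,
    )
    if density_factor != 1.0:
        from dataclasses import replace

        spec = replace(
            spec,
            target_density_cones_per_mm2=spec.target_density_cones_per_mm2 * density_factor,
            spacing_um=None,
        )
    truth = generate_mosaic(spec)
    image = render_image(truth, noise_seed=noise_seed)
    radius = radius_for_eccentricity(ecc_deg, RadiusTable(config.radius_table))
    params = DetectionParams(radius_um=radius, noise_threshold=config.noise_threshold)
    roi = ROISpec(eccentricity_deg=ecc_deg, meridian="temporal", side_um=config.roi_side_um)
    return analyze_roi(image, roi, params), truth


def simulate_cohort(
    config: Optional[RunConfig] = None,
    n_subjects: int = 10,
    session: int = 0,
    subject_cv: float = 0.12,
    renoise_only: bool = False,
) -> pd.DataFrame:
    """Per-ROI metric table for a synthetic cohort.

    Each subject carries a lognormal density factor (CV ``subject_cv``)
    shared across all their ROIs, emulating inter-individual variation.
    With ``renoise_only=True`` a later session reuses session 0's ground
    truth and only the rendering noise changes — the test–retest design
    where the retina is the same but the acquisition differs.
    """
    config = config or RunConfig()
    rows: List[Dict] = []
    for subj in range(n_subjects):
        factor_rng = np.random.default_rng([config.seed, 101, subj])
        sig2 = np.log(1.0 + subject_cv**2)
        factor = float(factor_rng.lognormal(-sig2 / 2.0, np.sqrt(sig2)))
        for ie, ecc in enumerate(config.eccentricities_deg):
            for im, meridian in enumerate(config.meridians):
                mosaic_session = 0 if renoise_only else session
                seed = _derive_seed(config.seed, subj, ie, im, mosaic_session)
                noise_seed = _derive_seed(config.seed, subj, ie, im, session, 7)
                m, _ = analyze_synthetic_roi(
                    ecc, seed, config, density_factor=factor, noise_seed=noise_seed
                )
                row = {"subject": subj, "ecc_deg": ecc, "meridian": meridian}
                row.update(m.as_row())
                rows.append(row)
    return pd.DataFrame(rows)


def metrics_survey(
    df: pd.DataFrame, metrics: Sequence[str] = METRIC_NAMES, alpha: float = 0.05
) -> Dict[str, Dict]:
    """Eccentricity-effect summary per metric.

    For each metric: a Friedman test across eccentricities with blocks =
    (subject, meridian), Wilcoxon signed-rank tests between consecutive
    eccentricities, and Holm–Bonferroni adjusted p-values across that
    post-hoc family.
    """
    eccs = sorted(df["ecc_deg"].unique())
    out: Dict[str, Dict] = {}
    for metric in metrics:
        wide = df.pivot_table(
            index=["subject", "meridian"], columns="ecc_deg", values=metric
        )[eccs].dropna()
        fr = friedman_test(wide.to_numpy())
        pairs: List[Tuple[float, float]] = list(zip(eccs[:-1], eccs[1:]))
        wtests = [
            wilcoxon_signed_rank(wide[a].to_numpy(), wide[b].to_numpy()) for a, b in pairs
        ]
        reject, adjusted = holm_bonferroni([t.p_value for t in wtests], alpha=alpha)
        out[metric] = {
            "friedman": fr,
            "pairs": pairs,
            "wilcoxon": wtests,
            "holm_adjusted_p": adjusted,
            "holm_reject": reject,
        }
    return out


def repeatability_analysis(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    metrics: Sequence[str] = METRIC_NAMES,
    keys: Sequence[str] = ("subject", "ecc_deg", "meridian"),
) -> Dict[str, RepeatabilityResult]:
    """Per-metric ICC(2,1) from matched baseline/follow-up tables."""
    keys = list(keys)
    merged = baseline.merge(followup, on=keys, suffixes=("_b", "_f"), how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        missing = unmatched[keys].to_dict("records")
        raise ValueError(f"unmatched records between sessions: {missing}")
    out = {}
    for metric in metrics:
        table = merged[[f"{metric}_b", f"{metric}_f"]].to_numpy()
        out[metric] = icc_2way_random_single_absolute(table)
    return out


def validation_agreement(
    auto_density: Sequence[float], manual_density: Sequence[float]
) -> AgreementResult:
    """Bland–Altman agreement of automated vs manual cone densities."""
    return bland_altman(np.asarray(auto_density), np.asarray(manual_density))


def run_study_arm(config: RunConfig, arm: str, **kwargs):
    """Dispatch one of the three study arms.

    ``metrics`` simulates (or accepts ``df=``) a cohort and returns
    (per-ROI table, survey summary); ``repeatability`` needs ``baseline``
    and ``followup`` tables (or simulates a re-noised pair) and returns a
    per-metric ICC dict; ``validation`` needs ``auto`` and ``manual``
    density sequences and returns an AgreementResult.
    """
    if arm == "metrics":
        df = kwargs.get("df")
        if df is None:
            df = simulate_cohort(config, n_subjects=kwargs.get("n_subjects", 10))
        return df, metrics_survey(df)
    if arm == "repeatability":
        baseline = kwargs.get("baseline")
        followup = kwargs.get("followup")
        if baseline is None or followup is None:
            n = kwargs.get("n_subjects", 10)
            baseline = simulate_cohort(config, n_subjects=n, session=0)
            followup = simulate_cohort(config, n_subjects=n, session=1, renoise_only=True)
        return repeatability_analysis(baseline, followup)
    if arm == "validation":
        return validation_agreement(kwargs["auto"], kwargs["manual"])
    raise ValueError(f"unknown study arm {arm!r}; expected metrics|repeatability|validation")
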