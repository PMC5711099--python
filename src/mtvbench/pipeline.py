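"""End-to-end study orchestration on a synthetic phantom cohort.

Three experiments mirror how a delineation-algorithm comparison is run in
practice:

1. **Segmentation comparison** — all configured arms on each case's native
   PET grid: per-arm volumes and SUV statistics, pairwise conformity-index
   summaries, an ICC table, and a Friedman test with post-hoc pairwise
   comparisons.
2. **Resampling study** — threshold arms run on the native PET grid and
   again after resampling onto a planning-CT grid, quantifying how grid
   choice alone moves the reference uptake and the delineated volume.
3. **Transfer study** — each arm's mask exported as planar contours and
   re-rasterized under the configured (dialect, rule) scenarios,
   quantifying the volume change a DICOM-RT transfer between workstations
   induces (Bland-Altman per scenario).

One seed controls the cohort and thereby the whole report; re-running with
the same configuration reproduces byte-identical CSV tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contours import (
    ANY_OVERLAP,
    CENTER_INSIDE,
    VOXEL_CENTER,
    VOXEL_EDGE,
    round_trip_volume_change,
)
from .metrics import (
    bland_altman,
    ci_summary,
    conformity_index,
    friedman_test,
    icc_agreement,
    paired_tests,
    relative_volume_variation,
)
from .phantom import CohortRanges, PhantomCase, generate_cohort, make_ct_grid
from .segmentation import (
    MAX_VOXEL,
    NEIGHBORHOOD_MEAN5,
    GbmParams,
    SegMethodConfig,
    reference_uptake,
    run_arm,
    segment_fixed_threshold,
    segment_relative_threshold,
)
from .volumes import mask_volume_ml, resample_suv, suv_stats

log = logging.getLogger(__name__)


def default_arms(psf_fwhm: float = 7.0) -> list[SegMethodConfig]:
    """The six standard arms: absolute and relative thresholds under both
    reference-uptake dialects, plus the FLAB and gradient-based methods.

    Labels follow the two-software nomenclature used in comparison tables:
    ``OA*`` arms use the single-hottest-voxel reference and ``PH*`` arms the
    five-voxel-average reference.
    """
    return [
        SegMethodConfig("fixed_threshold", label="OA2.5", dialect=MAX_VOXEL),
        SegMethodConfig("fixed_threshold", label="PH2.5", dialect=NEIGHBORHOOD_MEAN5),
        SegMethodConfig("relative_threshold", label="OA45", dialect=MAX_VOXEL),
        SegMethodConfig("relative_threshold", label="PH45", dialect=NEIGHBORHOOD_MEAN5),
        SegMethodConfig("flab", label="FLAB"),
        SegMethodConfig("gbm", label="GBM", gbm_params=GbmParams(psf_fwhm=psf_fwhm)),
    ]


DEFAULT_SCENARIOS: tuple[tuple[str, str], ...] = (
    (VOXEL_CENTER, CENTER_INSIDE),  # shrinking convention pair
    (VOXEL_EDGE, ANY_OVERLAP),      # expanding convention pair
)


@dataclass
class StudyConfig:
    n: int = 31
    seed: int = 0
    ranges: CohortRanges = field(default_factory=CohortRanges)
    arms: list[SegMethodConfig] = field(default_factory=list)
    ct_kind: str = "fine"
    scenarios: tuple[tuple[str, str], ...] = DEFAULT_SCENARIOS

    def __post_init__(self) -> None:
        if not self.arms:
            self.arms = default_arms(self.ranges.psf_fwhm)
        if self.n < 2:
            raise ValueError("a comparison study needs n >= 2 cases")
        if len(self.arms) < 2:
            raise ValueError("a comparison study needs >= 2 arms")
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValueError("arm labels must be unique")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "ranges": self.ranges.__dict__ | {
                "volume_bounds_ml": list(self.ranges.volume_bounds_ml),
                "contrast_range": list(self.ranges.contrast_range),
            },
            "arms": [
                {
                    "method": a.method, "label": a.label,
                    "absolute_suv": a.absolute_suv, "fraction": a.fraction,
                    "dialect": a.dialect,
                }
                for a in self.arms
            ],
            "ct_kind": self.ct_kind,
            "scenarios": [list(s) for s in self.scenarios],
        }


@dataclass
class StudyReport:
    volumes: pd.DataFrame
    ci_pairs: pd.DataFrame
    icc: pd.DataFrame
    friedman_p: float
    posthoc: pd.DataFrame
    resampling: pd.DataFrame
    resampling_tests: pd.DataFrame
    transfer: pd.DataFrame
    transfer_summary: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# Experiment 1: segmentation comparison
# ---------------------------------------------------------------------------

def run_segmentation_comparison(
    cases: list[PhantomCase], arms: list[SegMethodConfig]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, float, pd.DataFrame]:
    """All arms on all cases: volumes, CI summaries, ICC table, Friedman.

    A failure in one case is logged and that case is skipped from the
    aggregate tables rather than aborting the run.
    """
    vol_rows = []
    masks: dict[str, dict[str, object]] = {}
    kept_cases = []
    for case in cases:
        try:
            case_masks = {}
            for cfg in arms:
                res = run_arm(case.pet, case.roi, cfg)
                case_masks[cfg.label] = res.mask
                vol_rows.append(
                    {
                        "case_id": case.case_id,
                        "arm": cfg.label,
                        "volume_ml": res.volume_ml,
                        "suv_max": res.suv_max,
                        "suv_mean": res.suv_mean,
                        "truth_volume_ml": mask_volume_ml(case.truth),
                    }
                )
        except Exception:
            log.exception("case %s failed; skipping", case.case_id)
            vol_rows = [r for r in vol_rows if r["case_id"] != case.case_id]
            continue
        masks[case.case_id] = case_masks
        kept_cases.append(case)

    volumes = pd.DataFrame(vol_rows)
    labels = [a.label for a in arms]

    ci_rows = []
    pair_names = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    for a, b in pair_names:
        cis = [
            conformity_index(masks[c.case_id][a], masks[c.case_id][b])
            for c in kept_cases
            if masks[c.case_id][a].member.any() or masks[c.case_id][b].member.any()
        ]
        s = ci_summary(np.asarray(cis), pair=f"{a} vs {b}")
        ci_rows.append(s.__dict__)
    for a in labels:
        cis = [
            conformity_index(masks[c.case_id][a], c.truth) for c in kept_cases
        ]
        s = ci_summary(np.asarray(cis), pair=f"truth vs {a}")
        ci_rows.append(s.__dict__)
    ci_pairs = pd.DataFrame(ci_rows)

    pivot = volumes.pivot(index="case_id", columns="arm", values="volume_ml")[labels]
    truth_vols = volumes.groupby("case_id")["truth_volume_ml"].first()
    matrix = pd.concat([truth_vols.rename("truth"), pivot], axis=1)

    icc_rows = []
    overall = icc_agreement(matrix.to_numpy())
    icc_rows.append({"pair": "overall", "icc": overall.icc, "ci95_lower": overall.ci95_lower})
    cols = list(matrix.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            sub = matrix[[cols[i], cols[j]]].to_numpy()
            try:
                r = icc_agreement(sub)
                icc_rows.append(
                    {"pair": f"{cols[i]} vs {cols[j]}", "icc": r.icc, "ci95_lower": r.ci95_lower}
                )
            except ValueError:
                icc_rows.append(
                    {"pair": f"{cols[i]} vs {cols[j]}", "icc": np.nan, "ci95_lower": np.nan}
                )
    icc = pd.DataFrame(icc_rows)

    fr_p, posthoc = friedman_test(pivot.to_numpy())
    ph = pd.DataFrame(
        [
            {
                "pair": f"{labels[d['i']]} vs {labels[d['j']]}",
                "p_raw": d["p_raw"],
                "p_holm": d["p_holm"],
            }
            for d in posthoc
        ]
    )
    return volumes, ci_pairs, icc, fr_p, ph


# ---------------------------------------------------------------------------
# Experiment 2: PET resampling onto the planning-CT grid
# ---------------------------------------------------------------------------

def run_resampling_study(
    cases: list[PhantomCase], ct_kind: str = "fine"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold arms on native vs CT-resampled PET grids.

    Emits, per case and arm, the native and resampled volume, the relative
    volume variation (percent), the extracted SUVmax, and the reference
    uptake under both dialects; plus paired tests per arm across cases.
    """
    rows = []
    for case in cases:
        ct = make_ct_grid(ct_kind, case.spec.pet_grid)
        res = resample_suv(case.pet, ct)
        for dialect, tag in ((MAX_VOXEL, "OA"), (NEIGHBORHOOD_MEAN5, "PH")):
            ref0 = reference_uptake(case.pet, case.roi, dialect)
            ref1 = reference_uptake(res, case.roi, dialect)
            for arm, seg in (
                (f"{tag}45", lambda v, d=dialect: segment_relative_threshold(v, case.roi, 0.45, d)),
                (f"{tag}2.5", lambda v: segment_fixed_threshold(v, case.roi, 2.5)),
            ):
                m0 = seg(case.pet)
                m1 = seg(res)
                v0, v1 = mask_volume_ml(m0), mask_volume_ml(m1)
                smax0 = suv_stats(case.pet, m0)[0] if m0.member.any() else np.nan
                smax1 = suv_stats(res, m1)[0] if m1.member.any() else np.nan
                rows.append(
                    {
                        "case_id": case.case_id,
                        "arm": arm,
                        "dialect": dialect,
                        "vol_native_ml": v0,
                        "vol_resampled_ml": v1,
                        "rel_variation_pct": relative_volume_variation(v0, v1)
                        if v0 > 0
                        else np.nan,
                        "suvmax_native": smax0,
                        "suvmax_resampled": smax1,
                        "ref_native": ref0,
                        "ref_resampled": ref1,
                    }
                )
    df = pd.DataFrame(rows)

    test_rows = []
    for arm, sub in df.groupby("arm", sort=True):
        for quantity, c0, c1 in (
            ("volume_ml", "vol_native_ml", "vol_resampled_ml"),
            ("suvmax", "suvmax_native", "suvmax_resampled"),
        ):
            x = sub[c0].to_numpy()
            y = sub[c1].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            try:
                t_p, w_p = paired_tests(x[ok], y[ok])
            except ValueError:
                t_p = w_p = np.nan
            test_rows.append(
                {
                    "arm": arm,
                    "quantity": quantity,
                    "mean_native": float(np.mean(x[ok])),
                    "mean_resampled": float(np.mean(y[ok])),
                    "t_p": t_p,
                    "wilcoxon_p": w_p,
                }
            )
    return df, pd.DataFrame(test_rows)


# ---------------------------------------------------------------------------
# Experiment 3: DICOM-RT transfer round trip
# ---------------------------------------------------------------------------

def run_transfer_study(
    cases: list[PhantomCase],
    arms: list[SegMethodConfig],
    scenarios: tuple[tuple[str, str], ...] = DEFAULT_SCENARIOS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Round-trip volume change per case, arm and (dialect, rule) scenario."""
    rows = []
    for case in cases:
        for cfg in arms:
            try:
                res = run_arm(case.pet, case.roi, cfg)
            except Exception:
                log.exception("case %s arm %s failed; skipping", case.case_id, cfg.label)
                continue
            if not res.mask.member.any():
                continue
            for dialect, rule in scenarios:
                try:
                    v0, v1, delta = round_trip_volume_change(res.mask, dialect, rule)
                except ValueError:
                    continue
                rows.append(
                    {
                        "case_id": case.case_id,
                        "arm": cfg.label,
                        "dialect": dialect,
                        "rule": rule,
                        "v_before_ml": v0,
                        "v_after_ml": v1,
                        "delta_ml": delta,
                    }
                )
    df = pd.DataFrame(rows)
    summary_rows = []
    for (arm, dialect, rule), sub in df.groupby(["arm", "dialect", "rule"], sort=True):
        ba = bland_altman(sub["v_before_ml"].to_numpy(), sub["v_after_ml"].to_numpy())
        summary_rows.append(
            {
                "arm": arm,
                "dialect": dialect,
                "rule": rule,
                "n": len(sub),
                "mean_diff_ml": ba.mean_diff,
                "sd_diff_ml": ba.sd_diff,
                "loa_low_ml": ba.loa_low,
                "loa_high_ml": ba.loa_high,
            }
        )
    return df, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def run_study(cfg: StudyConfig) -> StudyReport:
    """Generate the cohort and run all three experiments."""
    cases = generate_cohort(cfg.n, cfg.ranges, cfg.seed)
    volumes, ci_pairs, icc, fr_p, posthoc = run_segmentation_comparison(cases, cfg.arms)
    resampling, res_tests = run_resampling_study(cases, cfg.ct_kind)
    transfer, transfer_summary = run_transfer_study(cases, cfg.arms, cfg.scenarios)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "seed": cfg.seed,
        "n_cases": cfg.n,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "package_version": __version__,
    }
    return StudyReport(
        volumes=volumes,
        ci_pairs=ci_pairs,
        icc=icc,
        friedman_p=fr_p,
        posthoc=posthoc,
        resampling=resampling,
        resampling_tests=res_tests,
        transfer=transfer,
        transfer_summary=transfer_summary,
        manifest=manifest,
    )


_CSV_TABLES = (
    ("volumes.csv", "volumes"),
    ("ci_pairs.csv", "ci_pairs"),
    ("icc.csv", "icc"),
    ("posthoc.csv", "posthoc"),
    ("resampling.csv", "resampling"),
    ("resampling_tests.csv", "resampling_tests"),
    ("transfer.csv", "transfer"),
    ("transfer_summary.csv", "transfer_summary"),
)


def write_report(report: StudyReport, outdir) -> list[Path]:
    """Write all report tables as CSV plus a JSON run manifest.

    Floats are serialized with a fixed repr so re-running an identical
    configuration reproduces byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fname, attr in _CSV_TABLES:
        path = out / fname
        getattr(report, attr).to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    manifest = dict(report.manifest)
    manifest["friedman_p"] = report.friedman_p
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(path)
    return written
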