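"""End-to-end study driver: synthetic cohort -> three segmentations by two
observers -> texture features -> index selection -> agreement reports.

Mirrors the structure of a segmentation-robustness study: patients whose
VOI falls below the 64-voxel floor under a method are excluded from that
method's analysis, and the statistical tables are computed on the
complete-case subset analyzable under all three methods by both observers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import (
    BlandAltmanResult,
    MethodVariabilityResult,
    ReproducibilityResult,
    bland_altman,
    extract_correlated_groups,
    friedman_test,
    icc_agreement,
    landis_koch_label,
    pearson_matrix,
    select_independent_indices,
    wilcoxon_signed_rank,
    CorrelationGroup,
)
from .phantom import PhantomCase, PhantomSpec, generate_cohort, simulate_observer
from .segmentation import (
    SegmentationConfig,
    calibrate_adaptive_thresholds,
    segment_adaptive_sbr,
    segment_fixed_threshold,
    segment_gradient_edge,
)
from .texture import (
    DiscretizationConfig,
    IneligibleVOIError,
    TEXTURE_FEATURES,
    extract_features,
)
from .volumes import SegmentationMethod, check_min_volume

METHODS = [SegmentationMethod.FIXED40, SegmentationMethod.ADAPTIVE_SBR,
           SegmentationMethod.GRADIENT_EDGE]
METHOD_PAIRS = [
    (SegmentationMethod.GRADIENT_EDGE, SegmentationMethod.FIXED40),
    (SegmentationMethod.ADAPTIVE_SBR, SegmentationMethod.FIXED40),
    (SegmentationMethod.GRADIENT_EDGE, SegmentationMethod.ADAPTIVE_SBR),
]

#: Calibration phantom grid for the adaptive threshold law.
CALIBRATION_VOLUMES_ML = [6.0, 12.0, 20.0, 32.0]
CALIBRATION_SBRS = [8.0, 15.0, 25.0, 40.0]


@dataclass
class StudyConfig:
    """Everything needed to run the seeded synthetic study end to end."""

    n_patients: int = 43
    base_spec: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(heterogeneity_amp=0.4, noise_sd=0.1)
    )
    size_range_ml: tuple[float, float] = (3.0, 60.0)
    small_fraction: float = 0.3
    jitter_mm: float = 4.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    correlation_threshold: float = 0.8
    seed: int = 0
    output_dir: str | Path | None = None


@dataclass
class StudyReport:
    """All study outputs: exclusion accounting and the four report tables."""

    n_patients: int
    exclusion_counts: dict[str, int]
    n_complete: int
    complete_patients: list[str]
    features: pd.DataFrame  # long format: patient, method, observer, feature, value
    groups: list[CorrelationGroup]
    selected: list[str]
    r_with_standard: dict[str, tuple[float, float]]
    variability: list[MethodVariabilityResult]
    reproducibility: list[ReproducibilityResult]
    bland_altman: dict[tuple[str, str], BlandAltmanResult]
    adaptive_coeffs: tuple[float, float]
    log: list[dict] = field(default_factory=list)


def _segment(method: SegmentationMethod, volume, seed_point,
             seg_config: SegmentationConfig, observer: str):
    if method is SegmentationMethod.FIXED40:
        return segment_fixed_threshold(volume, seed_point, seg_config, observer)
    if method is SegmentationMethod.ADAPTIVE_SBR:
        return segment_adaptive_sbr(volume, seed_point, seg_config, observer)
    return segment_gradient_edge(volume, seed_point, seg_config, observer)


def segment_cohort(
    cases: list[PhantomCase], config: StudyConfig,
    seg_config: SegmentationConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Segment every case with 3 methods x 2 observers and extract features.

    Returns a long-format feature table plus a structured log of exclusions
    and per-stage failures (a failed stage excludes the patient from that
    method's analysis; it never aborts the run)."""
    rows: list[dict] = []
    log: list[dict] = []
    for p_idx, case in enumerate(cases):
        support = case.true_mask.mask
        actions = [
            simulate_observer(
                case.seed_point, config.jitter_mm,
                np.random.SeedSequence([config.seed, 7919, p_idx, o_idx]),
                support, case.volume.spacing, observer=f"obs{o_idx + 1}",
            )
            for o_idx in range(2)
        ]
        for action in actions:
            for method in METHODS:
                entry = {"patient": case.patient_id, "method": method.value,
                         "observer": action.observer}
                try:
                    mask = _segment(method, case.volume, action.seed_point,
                                    seg_config, action.observer)
                    elig = check_min_volume(mask)
                    if not elig.eligible:
                        log.append({**entry, "event": "excluded_too_small",
                                    "n_voxels": elig.n_voxels})
                        continue
                    fv = extract_features(case.volume, mask,
                                          config.discretization,
                                          patient=case.patient_id)
                    for name, value in fv.values.items():
                        rows.append({**entry, "feature": name, "value": value})
                    flagged = [k for k, v in fv.values.items() if not np.isfinite(v)]
                    if flagged:
                        log.append({**entry, "event": "degenerate_indices",
                                    "features": flagged})
                except IneligibleVOIError as exc:
                    log.append({**entry, "event": "excluded_too_small",
                                "detail": str(exc)})
                except Exception as exc:  # noqa: BLE001 - exclusion, not abort
                    log.append({**entry, "event": "stage_error",
                                "detail": f"{type(exc).__name__}: {exc}"})
    features = pd.DataFrame(
        rows, columns=["patient", "method", "observer", "feature", "value"]
    )
    return features, log


def _wide(features: pd.DataFrame, method: str | None = None,
          observer: str | None = None) -> pd.DataFrame:
    sub = features
    if method is not None:
        sub = sub[sub["method"] == method]
    if observer is not None:
        sub = sub[sub["observer"] == observer]
    return sub.pivot_table(index=["patient", "method", "observer"],
                           columns="feature", values="value", aggfunc="first")


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full seeded study and assemble all report tables."""
    seg_config = config.segmentation
    if seg_config.adaptive_coeffs is None:
        coeffs = calibrate_adaptive_thresholds(
            CALIBRATION_VOLUMES_ML, CALIBRATION_SBRS,
            blur_fwhm_mm=config.base_spec.blur_fwhm_mm,
            spacing=config.base_spec.spacing,
            grid_shape=config.base_spec.grid_shape,
            config=seg_config,
        )
        seg_config = replace(seg_config, adaptive_coeffs=coeffs)

    cases = generate_cohort(
        config.n_patients, config.base_spec,
        size_range_ml=config.size_range_ml,
        small_fraction=config.small_fraction,
        seed=config.seed,
    )
    features, log = segment_cohort(cases, config, seg_config)

    # a patient counts as analyzable under a method only if both observers
    # produced an eligible VOI
    ok: dict[str, set[str]] = {m.value: set() for m in METHODS}
    for case in cases:
        sub = features[features["patient"] == case.patient_id]
        for m in METHODS:
            n_obs = sub[sub["method"] == m.value]["observer"].nunique()
            if n_obs == 2:
                ok[m.value].add(case.patient_id)
    all_ids = [c.patient_id for c in cases]
    exclusion_counts = {m: len(all_ids) - len(ok[m]) for m in ok}
    complete = sorted(set.intersection(*ok.values())) if ok else []

    cc = features[features["patient"].isin(complete)]

    # correlation analysis: observer-1 values, the three methods pooled
    wide = _wide(cc, observer="obs1")
    texture_cols = [f for f in TEXTURE_FEATURES if f in wide.columns]
    missing_frac = wide[texture_cols].isna().mean()
    usable = [f for f in texture_cols if missing_frac[f] <= 0.5]
    dropped = sorted(set(texture_cols) - set(usable))
    if dropped:
        log.append({"event": "features_dropped_missing", "features": dropped})
    r = pearson_matrix(wide[usable + ["SUVmax", "MTV"]])
    groups = extract_correlated_groups(r.loc[usable, usable],
                                       threshold=config.correlation_threshold,
                                       order=usable)
    r_with_standard = {
        f: (float(r.loc[f, "SUVmax"]), float(r.loc[f, "MTV"])) for f in usable
    }
    selected = select_independent_indices(groups, r_with_standard,
                                          threshold=config.correlation_threshold)

    # Bland-Altman on MTV between methods (observer 1, complete cases)
    mtv = {
        m.value: _wide(cc, method=m.value, observer="obs1")["MTV"]
        .droplevel(["method", "observer"]).loc[complete]
        for m in METHODS
    }
    ba = {
        (a.value, b.value): bland_altman(mtv[a.value].values, mtv[b.value].values)
        for a, b in METHOD_PAIRS
    }

    # inter-method variability (Friedman over 3 methods + pairwise Wilcoxon)
    report_feats = ["SUVmax", "MTV"] + [f for f in selected]
    variability = []
    for feat in report_feats:
        cols = []
        for m in METHODS:
            w = _wide(cc, method=m.value, observer="obs1")
            cols.append(w[feat].droplevel(["method", "observer"]).loc[complete].values)
        table = np.column_stack(cols)
        table = table[np.all(np.isfinite(table), axis=1)]
        if table.shape[0] < 2:
            log.append({"event": "variability_skipped", "feature": feat})
            continue
        _, fr_p = friedman_test(table)
        pw = {}
        for ai, bi in [(0, 2), (0, 1), (2, 1)]:  # fixed-gradient, fixed-adaptive, gradient-adaptive
            a, b = table[:, ai], table[:, bi]
            try:
                _, wp = wilcoxon_signed_rank(a, b)
            except ValueError:
                wp = float("nan")
            pw[(METHODS[ai].value, METHODS[bi].value)] = wp
        variability.append(MethodVariabilityResult(feature=feat, friedman_p=fr_p,
                                                   pairwise_wilcoxon_p=pw))

    # inter-observer reproducibility (ICC per feature x method)
    reproducibility = []
    for feat in report_feats:
        for m in METHODS:
            w1 = _wide(cc, method=m.value, observer="obs1")
            w2 = _wide(cc, method=m.value, observer="obs2")
            y1 = w1[feat].droplevel(["method", "observer"]).loc[complete].values
            y2 = w2[feat].droplevel(["method", "observer"]).loc[complete].values
            both = np.isfinite(y1) & np.isfinite(y2)
            if both.sum() < 3:
                icc = float("nan")
            elif np.allclose(y1[both], y2[both], rtol=0, atol=0):
                icc = 1.0
            else:
                icc = icc_agreement(y1[both], y2[both])
            reproducibility.append(ReproducibilityResult(
                feature=feat, method=m.value, icc=icc,
                label=landis_koch_label(icc)))

    report = StudyReport(
        n_patients=config.n_patients,
        exclusion_counts=exclusion_counts,
        n_complete=len(complete),
        complete_patients=complete,
        features=features,
        groups=groups,
        selected=selected,
        r_with_standard=r_with_standard,
        variability=variability,
        reproducibility=reproducibility,
        bland_altman=ba,
        adaptive_coeffs=seg_config.adaptive_coeffs,
        log=log,
    )
    if config.output_dir is not None:
        report_tables(report, config.output_dir)
    return report


def report_tables(report: StudyReport, output_dir: str | Path) -> dict[str, Path]:
    """Write CSV analogues of the four report tables plus Bland-Altman
    plots; rerunning on the same report reproduces identical files."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for g in report.groups:
        rows.append({
            "members": ", ".join(g.members),
            "mean_abs_r": "-" if g.mean_abs_r is None else f"{g.mean_abs_r:.3f}",
            "sd_abs_r": "-" if g.sd_abs_r is None else f"{g.sd_abs_r:.3f}",
        })
    paths["groups"] = out / "groups.csv"
    pd.DataFrame(rows, columns=["members", "mean_abs_r", "sd_abs_r"]).to_csv(
        paths["groups"], index=False)

    paths["selected"] = out / "selected.csv"
    sel_rows = [
        {"feature": f,
         "r_SUVmax": report.r_with_standard.get(f, (np.nan, np.nan))[0],
         "r_MTV": report.r_with_standard.get(f, (np.nan, np.nan))[1]}
        for f in report.selected
    ]
    pd.DataFrame(sel_rows, columns=["feature", "r_SUVmax", "r_MTV"]).to_csv(
        paths["selected"], index=False)

    var_rows = []
    for v in report.variability:
        row = {"feature": v.feature, "friedman_p": v.friedman_p}
        for (a, b), p in v.pairwise_wilcoxon_p.items():
            row[f"wilcoxon_{a}_vs_{b}"] = p
        var_rows.append(row)
    paths["variability"] = out / "variability.csv"
    pd.DataFrame(var_rows).to_csv(paths["variability"], index=False)

    paths["reproducibility"] = out / "reproducibility.csv"
    pd.DataFrame(
        [{"feature": r.feature, "method": r.method, "icc": r.icc, "label": r.label}
         for r in report.reproducibility]
    ).to_csv(paths["reproducibility"], index=False)

    paths["bland_altman"] = out / "bland_altman.csv"
    pd.DataFrame(
        [{"method_a": a, "method_b": b, "bias_ml": res.bias,
          "sd_diff_ml": res.sd_diff, "loa_low_ml": res.loa_low,
          "loa_high_ml": res.loa_high, "n": res.n}
         for (a, b), res in report.bland_altman.items()]
    ).to_csv(paths["bland_altman"], index=False)

    paths["exclusions"] = out / "exclusions.csv"
    pd.DataFrame(
        [{"method": m, "n_excluded": c} for m, c in report.exclusion_counts.items()]
    ).to_csv(paths["exclusions"], index=False)

    paths["features"] = out / "features_long.csv"
    report.features.to_csv(paths["features"], index=False)

    for m in report.features["method"].unique():
        for obs in report.features["observer"].unique():
            wide = _wide(report.features, method=m, observer=obs)
            key = f"features_{m}_{obs}"
            paths[key] = out / f"{key}.csv"
            wide.droplevel(["method", "observer"]).to_csv(paths[key])

    paths["log"] = out / "study_log.jsonl"
    with open(paths["log"], "w") as fh:
        for entry in report.log:
            fh.write(json.dumps(entry, default=str) + "\n")

    _bland_altman_plots(report, out, paths)
    return paths


def _bland_altman_plots(report: StudyReport, out: Path, paths: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mtv = report.features[
        (report.features["feature"] == "MTV") & (report.features["observer"] == "obs1")
        & report.features["patient"].isin(report.complete_patients)
    ].pivot_table(index="patient", columns="method", values="value")
    for (a, b), res in report.bland_altman.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        mean_ab = (mtv[a] + mtv[b]) / 2
        diff_ab = mtv[a] - mtv[b]
        ax.scatter(mean_ab, diff_ab, s=18, color="tab:blue")
        ax.axhline(res.bias, color="tab:blue", lw=1.5)
        ax.axhline(res.loa_low, color="tab:red", ls="--", lw=1.2)
        ax.axhline(res.loa_high, color="tab:red", ls="--", lw=1.2)
        ax.set_xlabel("mean MTV (ml)")
        ax.set_ylabel(f"MTV {a} - {b} (ml)")
        ax.set_title(f"{a} vs {b}")
        fig.tight_layout()
        p = out / f"bland_altman_{a}_vs_{b}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths[f"plot_{a}_{b}"] = p
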