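"""Six-study measurement-stability harness for retinal fractal dimensions.

The studies probe how fragile the fractal dimension of the retinal
vasculature is to each link of the measurement chain, using seeded
phantoms in place of clinical images:

1. **Inter/intra-group variation** — phantom groups of differing branching
   complexity; per-group mean/SD/RSD and Tukey-corrected pairwise
   one-way-ANOVA comparisons, on the full field of view and a 5x ODr ROI.
2. **Observer disagreement** — ground truth versus an emulated second
   observer who misses the thinnest vessels; relative errors and Pearson
   association.
3. **Segmentation method** — three vesselness parameterizations, each
   thresholded at its dataset-optimal MCC; relative errors vs truth.
4. **Region of interest** — ROIs at 4/5/6x ODr with 6x as reference.
5. **Segmentation quality** — a threshold sweep 0.15-0.35 (step 0.01)
   trading over- against under-segmentation; per-threshold MCC and mean
   FD relative error.
6. **Cameras and repeatability** — several camera profiles, five
   acquisitions each; between-camera differences and per-subject
   repeatability (RSD over acquisitions).

Statistics follow the usual conventions: sample (n-1) standard
deviations; RSD = SD/mean (the coefficient of variation); relative error
``|D_x - D_r| / D_r`` against a declared reference; Tukey HSD for the
pairwise group comparisons so the simultaneous confidence intervals agree
with the adjusted p-values; two-sided Pearson tests for association.

Every study is a pure function of ``(config, seed)``; reports serialize to
deterministic CSV + JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import synthetic
from .fractal import BoxScheduleConfig, compute_fd
from .preprocess import normalize_luminosity_contrast
from .roi import ROISpec, circular_roi_mask
from .segmentation import (
    FrangiParams,
    frangi_vesselness,
    segmentation_quality,
    threshold_map,
    threshold_sweep,
)
from .synthetic import CameraProfile, PhantomSpec

__all__ = [
    "RelativeErrorStat",
    "GroupDispersion",
    "RepeatabilityStat",
    "StabilityReport",
    "relative_error",
    "rsd",
    "repeatability",
    "pairwise_anova",
    "pearson_test",
    "default_study_config",
    "run_study",
]


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def relative_error(d_x: float, d_r: float) -> float:
    """|D_x - D_r| / D_r against the reference value D_r."""
    if d_r == 0:
        raise ZeroDivisionError("reference dimension is zero")
    return abs(d_x - d_r) / abs(d_r)


def rsd(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    return float(v.std(ddof=1) / mean)


@dataclass
class RelativeErrorStat:
    reference_id: str
    per_subject: list[float]

    @property
    def max_re(self) -> float:
        return float(np.max(self.per_subject))

    @property
    def mean_re(self) -> float:
        return float(np.mean(self.per_subject))


@dataclass
class GroupDispersion:
    label: str
    mean: float
    sd: float

    @property
    def rsd(self) -> float:
        if self.mean == 0:
            raise ZeroDivisionError("RSD undefined for zero mean")
        return self.sd / self.mean


@dataclass
class RepeatabilityStat:
    """Per-subject RSD over repeated acquisitions, summarized across subjects."""

    per_subject: dict[str, float]

    @property
    def max_rsd(self) -> float:
        return float(np.max(list(self.per_subject.values())))

    @property
    def mean_rsd(self) -> float:
        return float(np.mean(list(self.per_subject.values())))


def repeatability(per_subject_fds: Mapping[str, Sequence[float]]) -> RepeatabilityStat:
    """RSD of each subject's repeated measurements; max/mean across subjects."""
    out = {}
    for subject, vals in per_subject_fds.items():
        vals = list(vals)
        if len(vals) < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 acquisitions")
        out[str(subject)] = rsd(vals)
    return RepeatabilityStat(per_subject=out)


def pairwise_anova(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise group comparisons after a one-way ANOVA (Tukey HSD).

    Returns one row per unordered pair with the mean difference, its
    standard error, the family-corrected p-value and the simultaneous 95%
    confidence interval; the CI excludes 0 exactly when p < 0.05.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("at least 2 groups are required")
    for lab in labels:
        if len(groups[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    values = np.concatenate([np.asarray(groups[lab], dtype=float) for lab in labels])
    codes = np.concatenate([[lab] * len(groups[lab]) for lab in labels])
    if np.ptp(values) == 0:
        rows = [
            {"group_a": a, "group_b": b, "mean_diff": 0.0, "std_err": 0.0,
             "p_value": 1.0, "ci_low": 0.0, "ci_high": 0.0}
            for i, a in enumerate(labels) for b in labels[i + 1:]
        ]
        return pd.DataFrame(rows)
    res = pairwise_tukeyhsd(values, codes, alpha=0.05)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )
    return pd.DataFrame(
        {
            "group_a": frame["group1"],
            "group_b": frame["group2"],
            "mean_diff": res.meandiffs,
            "std_err": res.std_pairs,
            "p_value": res.pvalues,
            "ci_low": res.confint[:, 0],
            "ci_high": res.confint[:, 1],
        }
    )


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p under the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Study orchestration
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Per-condition FD table, summary statistics and test results."""

    study_id: int
    condition_table: pd.DataFrame
    statistics: dict
    tests: pd.DataFrame | None
    config: dict
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.condition_table.to_csv(
            outdir / "report.csv", index=False, float_format="%.12g",
            lineterminator="\n",
        )
        payload = {
            "study_id": self.study_id,
            "seed": self.seed,
            "config": self.config,
            "statistics": self.statistics,
            "tests": None
            if self.tests is None
            else json.loads(self.tests.to_json(orient="records", double_precision=12)),
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        if self.tests is not None:
            self.tests.to_csv(outdir / "tests.csv", index=False,
                              float_format="%.12g", lineterminator="\n")


def _phantom(seed: int, **overrides) -> synthetic.PhantomBundle:
    return synthetic.make_vascular_phantom(PhantomSpec(seed=int(seed), **overrides))


def _fovea_roi(bundle: synthetic.PhantomBundle, k: float) -> np.ndarray:
    spec = ROISpec(center=bundle.fovea_center, k=k,
                   od_radius=bundle.od_geometry.od_radius, anchor="fovea")
    return circular_roi_mask(spec, bundle.truth_vessels.shape)


def _od_roi(bundle: synthetic.PhantomBundle, k: float) -> np.ndarray:
    spec = ROISpec(center=bundle.od_geometry.center, k=k,
                   od_radius=bundle.od_geometry.od_radius, anchor="od_center")
    return circular_roi_mask(spec, bundle.truth_vessels.shape)


def _fd_triplet(vessels, roi_mask, cfg) -> dict:
    res = compute_fd(vessels, roi_mask, cfg)
    return {"D_B": res.d_b, "D_I": res.d_i, "D_C": res.d_c}


def _segment(bundle: synthetic.PhantomBundle, params: FrangiParams) -> np.ndarray:
    norm, _ = normalize_luminosity_contrast(bundle.image)
    norm = np.where(bundle.fov_mask, norm, 0.0)
    vp = frangi_vesselness(norm, params)
    values = np.where(bundle.fov_mask, np.asarray(vp), 0.0)
    return values


def default_study_config(study_id: int) -> dict:
    """Desk-scale default configuration for each study."""
    fd_cfg = {"min_box_px": 2, "max_box_fraction": 0.25, "base": 2}
    common = {"fd": fd_cfg, "phantom": {}}
    if study_id == 1:
        return {
            **common,
            "groups": {
                "sparse": {"branch_prob": 0.60, "n_roots": 5},
                "medium": {"branch_prob": 0.78, "n_roots": 6},
                "dense": {"branch_prob": 0.92, "n_roots": 7},
            },
            "n_per_group": 6,
        }
    if study_id == 2:
        return {**common, "n_subjects": 12, "min_caliber_px": 2.0}
    if study_id == 3:
        return {
            **common,
            "n_subjects": 8,
            "methods": {
                "vesselness-a": {"scales": (1.0, 2.0, 4.0, 8.0), "alpha": 0.5, "beta": 5.0},
                "vesselness-b": {"scales": (2.0, 4.0), "alpha": 0.8, "beta": 3.0},
                "vesselness-c": {"scales": (1.0, 2.0, 4.0), "alpha": 0.3, "beta": 8.0,
                                 "variant": "original-frangi"},
            },
            "sweep": {"t_min": 0.05, "t_max": 0.60, "t_step": 0.025},
        }
    if study_id == 4:
        # offset-averaged scans: the ROI comparison is a translation-robustness
        # question, and grid-placement noise would otherwise dominate the
        # small 5x-vs-6x contrast
        return {
            **common,
            "fd": {**fd_cfg, "offset_averaging": True},
            "n_subjects": 20, "roi_ks": (4.0, 5.0, 6.0), "reference_k": 6.0,
        }
    if study_id == 5:
        return {
            **common,
            "n_subjects": 5,
            "method": {"scales": (1.0, 2.0, 4.0, 8.0), "alpha": 0.5, "beta": 5.0},
            "sweep": {"t_min": 0.15, "t_max": 0.35, "t_step": 0.01},
        }
    if study_id == 6:
        return {
            **common,
            "n_subjects": 6,
            "n_acquisitions": 5,
            "threshold": 0.25,
            "method": {"scales": (1.0, 2.0, 4.0, 8.0), "alpha": 0.5, "beta": 5.0},
            "cameras": {
                "wide": {"resolution_scale": 1.0, "contrast_gain": 1.1,
                         "gamma": 1.0, "noise_sigma": 0.015, "acquisition_jitter_px": 1.0},
                "compact": {"resolution_scale": 0.75, "contrast_gain": 0.9,
                            "gamma": 1.1, "noise_sigma": 0.02, "acquisition_jitter_px": 2.0},
                "laser": {"resolution_scale": 1.0, "contrast_gain": 1.0,
                          "gamma": 0.9, "noise_sigma": 0.01, "acquisition_jitter_px": 1.0},
            },
        }
    raise ValueError(f"unknown study id {study_id}; expected 1..6")


def _merge_config(study_id: int, config: dict | None) -> dict:
    cfg = default_study_config(study_id)
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key] = {**cfg[key], **val}
            else:
                cfg[key] = val
    return cfg


def _fd_config(cfg: dict) -> BoxScheduleConfig:
    return BoxScheduleConfig(**cfg.get("fd", {}))


def _subject_seeds(seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream])
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def _study1(cfg: dict, seed: int) -> StabilityReport:
    fd_cfg = _fd_config(cfg)
    rows = []
    groups_full: dict[str, list[float]] = {}
    groups_roi: dict[str, list[float]] = {}
    for gi, (label, overrides) in enumerate(sorted(cfg["groups"].items())):
        seeds = _subject_seeds(seed, cfg["n_per_group"], 100 + gi)
        for s in seeds:
            bundle = _phantom(s, **{**cfg["phantom"], **overrides})
            fd_full = compute_fd(bundle.truth_vessels, bundle.fov_mask, fd_cfg).d_b
            fd_roi = compute_fd(bundle.truth_vessels, _fovea_roi(bundle, 5.0), fd_cfg).d_b
            groups_full.setdefault(label, []).append(fd_full)
            groups_roi.setdefault(label, []).append(fd_roi)
            rows.append({"group": label, "seed": s, "D_B_full_fov": fd_full,
                         "D_B_roi5": fd_roi})
    stats = {}
    for roi_name, data in (("full_fov", groups_full), ("roi5", groups_roi)):
        stats[roi_name] = {
            lab: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                  "rsd": rsd(v)}
            for lab, v in sorted(data.items())
        }
    tests = pd.concat(
        [pairwise_anova(groups_full).assign(roi="full_fov"),
         pairwise_anova(groups_roi).assign(roi="roi5")],
        ignore_index=True,
    )
    return StabilityReport(1, pd.DataFrame(rows), stats, tests, cfg, seed)


def _study2(cfg: dict, seed: int) -> StabilityReport:
    fd_cfg = _fd_config(cfg)
    seeds = _subject_seeds(seed, cfg["n_subjects"], 200)
    rows = []
    for s in seeds:
        bundle = _phantom(s, **cfg["phantom"])
        roi = _fovea_roi(bundle, 5.0)
        obs = synthetic.emulate_observer(bundle.truth_vessels, cfg["min_caliber_px"])
        ref = _fd_triplet(bundle.truth_vessels, roi, fd_cfg)
        alt = _fd_triplet(obs, roi, fd_cfg)
        row = {"seed": s}
        for dim in ("D_B", "D_I", "D_C"):
            row[f"{dim}_truth"] = ref[dim]
            row[f"{dim}_observer2"] = alt[dim]
            row[f"{dim}_re"] = relative_error(alt[dim], ref[dim])
        rows.append(row)
    table = pd.DataFrame(rows)
    stats, tests_rows = {}, []
    for dim in ("D_B", "D_I", "D_C"):
        res = RelativeErrorStat("truth", table[f"{dim}_re"].tolist())
        stats[dim] = {"max_re": res.max_re, "mean_re": res.mean_re}
        if table[f"{dim}_observer2"].nunique() > 1:
            r, p = pearson_test(table[f"{dim}_truth"], table[f"{dim}_observer2"])
        else:
            r, p = float("nan"), float("nan")
        tests_rows.append({"dimension": dim, "pearson_r": r, "p_value": p})
    return StabilityReport(2, table, stats, pd.DataFrame(tests_rows), cfg, seed)


def _optimal_threshold(prob_maps, truths, fovs, sweep_cfg) -> float:
    """Dataset-optimal threshold: maximizes the mean MCC over all images."""
    agg: dict[float, list[float]] = {}
    for values, truth, fov in zip(prob_maps, truths, fovs):
        sweep = threshold_sweep(values, truth, fov, sweep_cfg["t_min"],
                                sweep_cfg["t_max"], sweep_cfg["t_step"])
        for t, mcc in zip(sweep["t"], sweep["MCC"]):
            agg.setdefault(float(t), []).append(float(mcc))
    means = {t: np.mean(v) for t, v in agg.items()}
    return max(sorted(means), key=lambda t: means[t])


def _study3(cfg: dict, seed: int) -> StabilityReport:
    fd_cfg = _fd_config(cfg)
    seeds = _subject_seeds(seed, cfg["n_subjects"], 300)
    bundles = [_phantom(s, **cfg["phantom"]) for s in seeds]
    rois = [_fovea_roi(b, 5.0) for b in bundles]
    refs = [compute_fd(b.truth_vessels, roi, fd_cfg).d_b for b, roi in zip(bundles, rois)]
    rows = []
    tests_rows = []
    stats = {}
    for method, p in sorted(cfg["methods"].items()):
        params = FrangiParams(**{**p, "scales": tuple(p["scales"])})
        maps = [_segment(b, params) for b in bundles]
        t_opt = _optimal_threshold(maps, [b.truth_vessels for b in bundles],
                                   [b.fov_mask for b in bundles], cfg["sweep"])
        fds, res = [], []
        for b, roi, m, ref in zip(bundles, rois, maps, refs):
            fd = compute_fd(threshold_map(m, t_opt), roi, fd_cfg).d_b
            fds.append(fd)
            res.append(relative_error(fd, ref))
            rows.append({"method": method, "seed": b.spec.seed, "threshold": t_opt,
                         "D_B": fd, "D_B_truth": ref, "re": res[-1]})
        stat = RelativeErrorStat("truth", res)
        stats[method] = {"threshold": t_opt, "max_re": stat.max_re,
                         "mean_re": stat.mean_re}
        r, pval = pearson_test(refs, fds)
        tests_rows.append({"method": method, "pearson_r": r, "p_value": pval})
    return StabilityReport(3, pd.DataFrame(rows), stats, pd.DataFrame(tests_rows), cfg, seed)


def _study4(cfg: dict, seed: int) -> StabilityReport:
    fd_cfg = _fd_config(cfg)
    seeds = _subject_seeds(seed, cfg["n_subjects"], 400)
    ks = tuple(cfg["roi_ks"])
    ref_k = float(cfg["reference_k"])
    rows = []
    per_k: dict[float, list[float]] = {k: [] for k in ks}
    for s in seeds:
        bundle = _phantom(s, **cfg["phantom"])
        row = {"seed": s}
        for k in ks:
            fd = compute_fd(bundle.truth_vessels, _fovea_roi(bundle, k), fd_cfg).d_b
            row[f"D_B_roi{int(k)}"] = fd
            per_k[k].append(fd)
        rows.append(row)
    stats = {}
    tests_rows = []
    for k in ks:
        if k == ref_k:
            stats[f"roi{int(k)}"] = {"reference": True}
            continue
        res = [relative_error(x, r) for x, r in zip(per_k[k], per_k[ref_k])]
        stat = RelativeErrorStat(f"roi{int(ref_k)}", res)
        stats[f"roi{int(k)}"] = {"max_re": stat.max_re, "mean_re": stat.mean_re}
        r, p = pearson_test(per_k[k], per_k[ref_k])
        tests_rows.append({"roi_k": k, "reference_k": ref_k, "pearson_r": r,
                           "p_value": p})
    stats["mean_by_k"] = {f"roi{int(k)}": float(np.mean(per_k[k])) for k in ks}
    return StabilityReport(4, pd.DataFrame(rows), stats, pd.DataFrame(tests_rows), cfg, seed)


def _study5(cfg: dict, seed: int) -> StabilityReport:
    fd_cfg = _fd_config(cfg)
    sweep_cfg = cfg["sweep"]
    seeds = _subject_seeds(seed, cfg["n_subjects"], 500)
    params = FrangiParams(**{**cfg["method"], "scales": tuple(cfg["method"]["scales"])})
    bundles = [_phantom(s, **cfg["phantom"]) for s in seeds]
    rois = [_fovea_roi(b, 5.0) for b in bundles]
    refs = [compute_fd(b.truth_vessels, roi, fd_cfg).d_b for b, roi in zip(bundles, rois)]
    maps = [_segment(b, params) for b in bundles]
    n = int(round((sweep_cfg["t_max"] - sweep_cfg["t_min"]) / sweep_cfg["t_step"]))
    ts = [round(sweep_cfg["t_min"] + i * sweep_cfg["t_step"], 10) for i in range(n + 1)]
    rows = []
    for t in ts:
        mccs, res, fds = [], [], []
        for b, roi, m, ref in zip(bundles, rois, maps, refs):
            binary = threshold_map(m, t)
            q = segmentation_quality(binary, b.truth_vessels, b.fov_mask, threshold=t)
            fd = compute_fd(binary, roi, fd_cfg).d_b
            mccs.append(q.mcc)
            fds.append(fd)
            res.append(relative_error(fd, ref))
        rows.append({"t": t, "mean_MCC": float(np.mean(mccs)),
                     "mean_D_B": float(np.mean(fds)),
                     "mean_FD_re": float(np.mean(res))})
    table = pd.DataFrame(rows)
    best_t = float(table.loc[table["mean_MCC"].idxmax(), "t"])
    rho = float(sps.spearmanr(table["mean_MCC"], table["mean_FD_re"]).statistic)
    stats = {
        "argmax_mcc_threshold": best_t,
        "max_mean_mcc": float(table["mean_MCC"].max()),
        "re_at_best_t": float(table.loc[table["mean_MCC"].idxmax(), "mean_FD_re"]),
        "min_mean_re": float(table["mean_FD_re"].min()),
        "spearman_mcc_re": rho,
    }
    return StabilityReport(5, table, stats, None, cfg, seed)


def _study6(cfg: dict, seed: int) -> StabilityReport:
    fd_cfg = _fd_config(cfg)
    seeds = _subject_seeds(seed, cfg["n_subjects"], 600)
    params = FrangiParams(**{**cfg["method"], "scales": tuple(cfg["method"]["scales"])})
    rows = []
    per_camera: dict[str, dict[str, list[float]]] = {}
    for cam_name, cam_cfg in sorted(cfg["cameras"].items()):
        profile = CameraProfile(name=cam_name, **cam_cfg)
        per_camera[cam_name] = {}
        for si, s in enumerate(seeds):
            bundle = _phantom(s, **cfg["phantom"])
            for acq in range(1, cfg["n_acquisitions"] + 1):
                shot = synthetic.emulate_camera(bundle, profile, acq)
                values = _segment(shot, params)
                binary = threshold_map(values, cfg["threshold"])
                roi = _od_roi(shot, 4.0)
                fd = compute_fd(binary, roi, fd_cfg).d_b
                per_camera[cam_name].setdefault(f"subject{si}", []).append(fd)
                rows.append({"camera": cam_name, "subject": f"subject{si}",
                             "acquisition": acq, "D_B": fd})
    stats = {}
    cam_means = {}
    for cam_name, per_subject in sorted(per_camera.items()):
        rep = repeatability(per_subject)
        stats[cam_name] = {"max_rsd": rep.max_rsd, "mean_rsd": rep.mean_rsd}
        cam_means[cam_name] = float(np.mean([np.mean(v) for v in per_subject.values()]))
    stats["overall_mean_rsd"] = float(np.mean([stats[c]["mean_rsd"]
                                               for c in per_camera]))
    labels = sorted(cam_means)
    diffs = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            avg = 0.5 * (cam_means[a] + cam_means[b])
            diffs.append({"camera_a": a, "camera_b": b,
                          "mean_relative_difference": abs(cam_means[a] - cam_means[b]) / avg})
    return StabilityReport(6, pd.DataFrame(rows), stats, pd.DataFrame(diffs), cfg, seed)


_STUDIES: dict[int, Callable[[dict, int], StabilityReport]] = {
    1: _study1, 2: _study2, 3: _study3, 4: _study4, 5: _study5, 6: _study6,
}


def run_study(study_id: int, config: dict | None = None, seed: int = 0) -> StabilityReport:
    """Run one of the six stability studies at desk scale.

    ``config`` entries override the defaults from
    :func:`default_study_config`; nested dicts merge shallowly.  Identical
    ``(config, seed)`` produce byte-identical reports.
    """
    if study_id not in _STUDIES:
        raise ValueError(f"unknown study id {study_id}; expected 1..6")
    cfg = _merge_config(study_id, config)
    return _STUDIES[study_id](cfg, int(seed))
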