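"""Group-level comparison of ASL, GE-BOLD and SE-BOLD CVR maps.

Implements the cohort analyses: gray-matter summary CVRs under ASL
confidence (z-score) thresholding, across-subject and spatial correlations,
per-ROI Fisher-z correlation maps with a venous-density stratification,
bootstrap spatial-correlation-vs-n curves, second-level t-maps, and the
coefficient of variation.  The ASL map acts as the physiological reference;
the guiding question is whether SE-BOLD, being less sensitive to
macrovascular veins, tracks it more closely than GE-BOLD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cvr_mapping import CVRMap

log = logging.getLogger(__name__)

PAIRS = (("ge", "asl"), ("se", "asl"), ("se", "ge"))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilising transform atanh(r)."""
    return np.arctanh(r)


def inverse_fisher_z(z: float | np.ndarray) -> float | np.ndarray:
    return np.tanh(z)


def coefficient_of_variation(values: np.ndarray) -> float:
    """SD/mean (sample SD, n-1 denominator); unitless fraction."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / m)


def across_subject_correlation(
    a: np.ndarray, b: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation of per-subject summary values with two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or a.size != b.size:
        raise ValueError("need matched vectors of length >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("undefined correlation: zero variance")
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SubjectCVRSet:
    """Cohort of per-subject (ASL, GE, SE) CVR maps on a common grid.

    maps : list over subjects of dicts weighting -> CVRMap
    gm_mask : boolean gray-matter mask
    roi_labels : integer label image (0 = background)
    venous_density : per-ROI macrovascular venous density (roi id -> value,
        arbitrary units from an SWI-derived atlas)
    """

    maps: list[dict[str, CVRMap]]
    gm_mask: np.ndarray
    roi_labels: np.ndarray | None = None
    venous_density: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.gm_mask = np.asarray(self.gm_mask, dtype=bool)
        for subj in self.maps:
            for w, m in subj.items():
                if m.beta.shape != self.gm_mask.shape:
                    raise ValueError("all maps must share the gm_mask grid")
        if self.roi_labels is not None and self.venous_density is not None:
            ids = {int(i) for i in np.unique(self.roi_labels)} - {0}
            missing = sorted(ids - set(self.venous_density))
            if missing:
                raise ValueError(f"venous_density missing ROI ids: {missing}")

    @property
    def n_subjects(self) -> int:
        return len(self.maps)


@dataclass
class ThresholdCurve:
    """Group summaries as a function of the ASL z-score threshold."""

    z_thresholds: np.ndarray
    group_mean: pd.DataFrame  # index threshold, columns weightings
    group_sd: pd.DataFrame
    correlations: pd.DataFrame  # columns like "ge_vs_asl", Pearson r
    n_subjects_used: np.ndarray = field(default=None)


def gm_summary(
    cvr_set: SubjectCVRSet, z_thr: float = -np.inf
) -> pd.DataFrame:
    """Per-subject GM mean CVR per weighting under an ASL-z voxel mask.

    The voxel set {GM, ASL z > z_thr} is defined per subject on the ASL
    confidence map and applied identically to all three weightings.
    Subjects with an empty surviving set get NaN rows (logged).
    """
    rows = []
    for i, subj in enumerate(cvr_set.maps):
        zmap = subj["asl"].z
        sel = cvr_set.gm_mask & np.isfinite(zmap) & (zmap > z_thr)
        if not sel.any():
            log.info("gm_summary: subject %d empty at z_thr=%g", i, z_thr)
            rows.append({w: np.nan for w in subj})
            continue
        rows.append({w: float(np.nanmean(subj[w].beta[sel])) for w in subj})
    return pd.DataFrame(rows)


def threshold_curves(
    cvr_set: SubjectCVRSet, z_grid: np.ndarray
) -> ThresholdCurve:
    """gm_summary plus pairwise across-subject Pearson r per z threshold."""
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.size and np.any(np.diff(z_grid) < 0):
        raise ValueError("z_grid must be sorted ascending")
    means, sds, corrs, n_used = [], [], [], []
    for z_thr in z_grid:
        df = gm_summary(cvr_set, z_thr)
        valid = df.dropna()
        n_used.append(len(valid))
        means.append(valid.mean())
        sds.append(valid.std(ddof=1))
        row = {}
        for a, b in PAIRS:
            key = f"{a}_vs_{b}"
            if len(valid) >= 3 and valid[a].std() > 0 and valid[b].std() > 0:
                row[key], _ = across_subject_correlation(valid[a], valid[b])
            else:
                row[key] = np.nan
        corrs.append(row)
    return ThresholdCurve(
        z_thresholds=z_grid,
        group_mean=pd.DataFrame(means, index=z_grid),
        group_sd=pd.DataFrame(sds, index=z_grid),
        correlations=pd.DataFrame(corrs, index=z_grid),
        n_subjects_used=np.asarray(n_used),
    )


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def steiger_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent overlapping correlations.

    Tests r12 = r13 where variable 1 (here CVR_ASL) is shared.  Returns
    (Z, two-sided p).
    """
    rm2 = (r12**2 + r13**2) / 2.0
    f = min((1.0 - r23) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (np.arctanh(r12) - np.arctanh(r13)) * np.sqrt(
        (n - 3) / (2.0 * (1.0 - r23) * h)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def roi_fisher_maps(
    cvr_set: SubjectCVRSet, z_thr: float = -np.inf, q: float = 0.05
) -> pd.DataFrame:
    """Per-ROI Fisher-z across-subject correlations and their difference.

    For every atlas ROI: subject-level ROI-mean CVRs (GM voxels surviving
    the ASL z threshold) -> Pearson r for GE-vs-ASL and SE-vs-ASL -> atanh.
    The difference (SE-vs-ASL minus GE-vs-ASL) is tested with Steiger's
    dependent-correlation test; all p-vectors are BH-FDR corrected across
    ROIs at level q.  Includes a high_venous flag from the 50th-percentile
    binarisation of the venous-density table.
    """
    if cvr_set.roi_labels is None:
        raise ValueError("roi_labels required")
    roi_ids = sorted(set(np.unique(cvr_set.roi_labels)) - {0})
    rows = []
    for roi in roi_ids:
        in_roi = (cvr_set.roi_labels == roi) & cvr_set.gm_mask
        per_subj = {w: [] for w in ("asl", "ge", "se")}
        for subj in cvr_set.maps:
            zmap = subj["asl"].z
            sel = in_roi & np.isfinite(zmap) & (zmap > z_thr)
            for w in per_subj:
                per_subj[w].append(
                    float(np.nanmean(subj[w].beta[sel])) if sel.any() else np.nan
                )
        df = pd.DataFrame(per_subj).dropna()
        row = {"roi": roi, "n_subjects": len(df)}
        if len(df) < 3:
            log.info("roi_fisher_maps: ROI %d has %d valid subjects", roi, len(df))
            rows.append(row)
            continue
        r_ge, p_ge = across_subject_correlation(df["ge"], df["asl"])
        r_se, p_se = across_subject_correlation(df["se"], df["asl"])
        r_geSe, _ = across_subject_correlation(df["se"], df["ge"])
        _, p_diff = steiger_test(r_se, r_ge, r_geSe, len(df))
        row.update(
            r_ge_asl=r_ge,
            r_se_asl=r_se,
            fisher_ge_asl=float(fisher_z(r_ge)),
            fisher_se_asl=float(fisher_z(r_se)),
            fisher_diff=float(fisher_z(r_se) - fisher_z(r_ge)),
            p_ge_asl=p_ge,
            p_se_asl=p_se,
            p_diff=p_diff,
        )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("roi")
    for col in ("p_ge_asl", "p_se_asl", "p_diff"):
        flags = np.zeros(len(out), dtype=bool)
        ok = out[col].notna().to_numpy() if col in out else np.zeros(len(out), bool)
        if ok.any():
            flags[ok] = bh_fdr(out[col].to_numpy()[ok], q)
        out[col.replace("p_", "sig_")] = flags
    if cvr_set.venous_density is not None:
        dens = np.array([cvr_set.venous_density[r] for r in out.index])
        out["venous_density"] = dens
        out["high_venous"] = dens > np.percentile(dens, 50)
    return out


def second_level_tmap(maps: list[CVRMap]) -> np.ndarray:
    """One-sample t of voxel CVR across subjects against zero.

    Zero across-subject variance with nonzero mean gives a signed infinite
    t (perfect agreement); zero variance with zero mean gives the NaN
    sentinel; all-NaN voxels stay NaN.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    stack = np.stack([m.beta for m in maps], axis=0)
    n = stack.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    t[(sd == 0) & (mean == 0)] = np.nan
    return t


def spatial_correlation(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray
) -> float:
    """Pearson r between two maps over mask voxels finite in both."""
    sel = mask & np.isfinite(map_a) & np.isfinite(map_b)
    a, b = map_a[sel], map_b[sel]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def spatial_correlation_vs_n(
    cvr_set: SubjectCVRSet,
    n_iters: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bootstrap spatial correlation of group-average maps vs subjects averaged.

    For each k = 1..N, n_iters bootstrap draws of k subjects (with
    replacement, including k = N) are averaged per weighting and the GM
    voxelwise Pearson r is computed for each map pair.  Returns a tidy frame
    with mean and SD over iterations per (k, pair).
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    rng = np.random.default_rng(seed)
    n = cvr_set.n_subjects
    stacks = {
        w: np.stack([subj[w].beta for subj in cvr_set.maps], axis=0)
        for w in ("asl", "ge", "se")
    }
    rows = []
    for k in range(1, n + 1):
        r_acc = {f"{a}_vs_{b}": [] for a, b in PAIRS}
        for _ in range(n_iters):
            idx = rng.integers(0, n, size=k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
                avg = {w: np.nanmean(stacks[w][idx], axis=0) for w in stacks}
            for a, b in PAIRS:
                r_acc[f"{a}_vs_{b}"].append(
                    spatial_correlation(avg[a], avg[b], cvr_set.gm_mask)
                )
        for pair, vals in r_acc.items():
            vals = np.asarray(vals)
            rows.append(
                {
                    "k": k,
                    "pair": pair,
                    "r_mean": float(np.nanmean(vals)),
                    "r_sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
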