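"""Univariate GLM feature selection for the d-SA and d-MR voxel masks.

The attentional (d-SA) mask is defined by voxels whose BOLD response scales
more strongly with reaction time on deceased-related than on colour-congruent
Stroop words — a parametric-modulation contrast (deceased x RT) - (congruent
x RT) with a trial on/off regressor controlling semantic processing.  The
representational (d-MR) mask is the minimum-statistic conjunction of
deceased-vs-controls contrasts for pictures and for stories, each controlling
for block-level valence and arousal ratings, thresholded leniently because it
serves only as feature selection for the subsequent MVPA.

Cluster-level correction uses a subject-level sign-flip permutation null on
the maximum cluster size (26-connectivity), which is self-contained and valid
at small volumes, in place of smoothness-based random-field corrections.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from . import designgen as dg
from .boldsim import BoldSeries, _hrf_fine, _FINE_DT
from .exceptions import (DesignError, InsufficientDataError, ParameterError,
                         ShapeError)

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Named per-TR regressors: task columns, nuisance columns, drifts."""
    frame: pd.DataFrame
    task_columns: list[str]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def _convolve_boxcar(onsets, durations, amplitudes, schedule) -> np.ndarray:
    n_fine = int(round(schedule.duration / _FINE_DT))
    course = np.zeros(n_fine)
    for o, d, a in zip(onsets, durations, amplitudes):
        i0 = int(round(o / _FINE_DT))
        i1 = min(n_fine, int(round((o + d) / _FINE_DT)))
        course[i0:i1] += a
    conv = np.convolve(course, _hrf_fine(_FINE_DT))[:n_fine]
    idx = (np.arange(schedule.n_volumes) * schedule.tr / _FINE_DT).round().astype(int)
    return conv[np.clip(idx, 0, n_fine - 1)]


def _collinear_columns(X: np.ndarray, names: list[str], tol=1e-8) -> list[str]:
    """Names of columns nearly in the span of the preceding ones."""
    bad, basis = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        col = X[:, j:j + 1]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) < tol * max(1.0, np.linalg.norm(col)):
            bad.append(name)
        else:
            basis = np.hstack([basis, col])
    return bad


def build_design_matrix(events: pd.DataFrame, schedule: dg.TrSchedule,
                        modulators: list[tuple[str, str]] = (),
                        confounds: pd.DataFrame | None = None,
                        drift_order: int = 2,
                        modulator_only: tuple[str, ...] = ()) -> DesignMatrix:
    """GLM design: HRF-convolved condition boxcars, mean-centered parametric
    modulators, motion confounds, Legendre drifts and an intercept.

    ``modulators`` lists (condition, value_column) pairs; modulator values
    are centered within their condition *before* convolution, so a constant
    modulator yields an all-zero column.  Conditions in ``modulator_only``
    contribute no on/off column of their own (used for block-level nuisance
    ratings).  Raises :class:`DesignError` naming collinear columns if the
    result is rank deficient.
    """
    cols: dict[str, np.ndarray] = {}
    task_cols: list[str] = []
    for cond in pd.unique(events["trial_type"]):
        ev = events[events["trial_type"] == cond]
        if cond in modulator_only:
            continue
        if len(ev) == 0:
            logger.warning("condition %s has no events; column omitted", cond)
            continue
        cols[cond] = _convolve_boxcar(ev["onset"], ev["duration"],
                                      np.ones(len(ev)), schedule)
        task_cols.append(cond)
    for cond, value_col in modulators:
        ev = events[events["trial_type"] == cond]
        if len(ev) == 0:
            logger.warning("modulator parent %s has no events; omitted", cond)
            continue
        vals = ev[value_col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ParameterError(f"modulator {value_col} has missing values "
                                 f"for condition {cond}")
        name = f"{cond}_x_{value_col}"
        cols[name] = _convolve_boxcar(ev["onset"], ev["duration"],
                                      vals - vals.mean(), schedule)
        task_cols.append(name)

    if confounds is not None:
        if len(confounds) != schedule.n_volumes:
            raise ParameterError("confound rows must equal n_volumes")
        for c in confounds.columns:
            cols[f"conf_{c}"] = confounds[c].to_numpy(dtype=float)
    tt = np.linspace(-1, 1, schedule.n_volumes)
    for k in range(1, drift_order + 1):
        cols[f"drift_{k}"] = np.polynomial.legendre.Legendre.basis(k)(tt)
    cols["intercept"] = np.ones(schedule.n_volumes)

    frame = pd.DataFrame(cols)
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, list(frame.columns))
        raise DesignError(f"design matrix is rank deficient; collinear "
                          f"columns: {bad}")
    return DesignMatrix(frame=frame, task_columns=task_cols)


# --------------------------------------------------------------------------
# first level
# --------------------------------------------------------------------------

def _contrast_vector(X: DesignMatrix, contrast) -> np.ndarray:
    if isinstance(contrast, dict):
        missing = [k for k in contrast if k not in X.columns]
        if missing:
            raise DesignError(f"contrast names {missing} not in design")
        c = np.zeros(len(X.columns))
        for k, v in contrast.items():
            c[X.columns.index(k)] = v
        return c
    c = np.asarray(contrast, dtype=float)
    if c.size != len(X.columns):
        raise DesignError("contrast length does not match design columns")
    return c


def fit_first_level(bold: BoldSeries, X: DesignMatrix, contrast,
                    prewhiten: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel least-squares contrast effect and its sampling variance.

    Optional AR(1) prewhitening estimates a single pooled lag-1 residual
    autocorrelation and refits on whitened data.  Returns 3D effect and
    variance maps (zero outside the brain mask).
    """
    mat = X.matrix
    n_t, p = mat.shape
    if bold.n_volumes != n_t:
        raise ShapeError("design rows do not match BOLD volumes")
    if n_t <= p:
        raise InsufficientDataError("fewer time points than regressors")
    c = _contrast_vector(X, contrast)
    Y = bold.masked().T.astype(float)           # (t, v)

    def ols(Xm, Ym):
        XtXinv = np.linalg.pinv(Xm.T @ Xm)
        beta = XtXinv @ Xm.T @ Ym
        resid = Ym - Xm @ beta
        dof = n_t - np.linalg.matrix_rank(Xm)
        sigma2 = (resid ** 2).sum(axis=0) / dof
        eff = c @ beta
        var = float(c @ XtXinv @ c) * sigma2
        return eff, var, resid

    eff, var, resid = ols(mat, Y)
    if prewhiten:
        num = (resid[1:] * resid[:-1]).sum()
        den = (resid ** 2).sum()
        phi = float(np.clip(num / den if den > 0 else 0.0, -0.95, 0.95))
        W_first = np.sqrt(1 - phi ** 2)
        Yw = np.vstack([W_first * Y[:1], Y[1:] - phi * Y[:-1]])
        Xw = np.vstack([W_first * mat[:1], mat[1:] - phi * mat[:-1]])
        eff, var, _ = ols(Xw, Yw)

    eff_map = np.zeros(bold.shape)
    var_map = np.zeros(bold.shape)
    eff_map[bold.brain_mask] = eff
    var_map[bold.brain_mask] = var
    return eff_map, var_map


def combine_runs(effects: list[np.ndarray], variances: list[np.ndarray],
                 mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effects (inverse-variance) combination of per-run estimates."""
    w = np.stack([1.0 / np.maximum(v[mask], 1e-12) for v in variances])
    e = np.stack([eff[mask] for eff in effects])
    wsum = w.sum(axis=0)
    eff_map = np.zeros(mask.shape)
    var_map = np.zeros(mask.shape)
    eff_map[mask] = (w * e).sum(axis=0) / wsum
    var_map[mask] = 1.0 / wsum
    return eff_map, var_map


# --------------------------------------------------------------------------
# group level
# --------------------------------------------------------------------------

@dataclass
class StatMap:
    """3D group statistic (z) with its provenance."""
    data: np.ndarray
    df: int
    contrast: str
    mask: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.data[self.mask]).all():
            raise ShapeError("statistic non-finite inside brain mask")


def _group_z(effects: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Inverse-variance-weighted one-sample z with a DerSimonian-Laird
    method-of-moments between-subject variance; vectorized over voxels.

    ``effects``/``variances``: (k_subjects, n_voxels).
    """
    k = effects.shape[0]
    w = 1.0 / np.maximum(variances, 1e-12)
    wsum = w.sum(axis=0)
    mu_fe = (w * effects).sum(axis=0) / wsum
    q = (w * (effects - mu_fe) ** 2).sum(axis=0)
    cval = wsum - (w ** 2).sum(axis=0) / wsum
    tau2 = np.maximum(0.0, (q - (k - 1)) / np.maximum(cval, 1e-12))
    w_star = 1.0 / (variances + tau2)
    ws_sum = w_star.sum(axis=0)
    mu = (w_star * effects).sum(axis=0) / ws_sum
    z = mu * np.sqrt(ws_sum)
    degenerate = ws_sum <= 0
    z[degenerate] = 0.0
    return z


def fit_group_level(effects: list[np.ndarray], variances: list[np.ndarray],
                    mask: np.ndarray, contrast: str = "") -> StatMap:
    """One-sample random-effects test across subjects at every voxel."""
    if len(effects) < 3:
        raise InsufficientDataError("group level requires >= 3 subjects")
    e = np.stack([eff[mask] for eff in effects])
    v = np.stack([var[mask] for var in variances])
    z = _group_z(e, v)
    out = np.zeros(mask.shape)
    out[mask] = z
    return StatMap(data=out, df=len(effects) - 1, contrast=contrast, mask=mask)


def conjunction_min(map_a: StatMap, map_b: StatMap) -> StatMap:
    """Minimum-statistic conjunction: significant only where both effects are."""
    if map_a.data.shape != map_b.data.shape:
        raise ShapeError("conjunction inputs on different grids")
    data = np.minimum(map_a.data, map_b.data)
    return StatMap(data=data, df=min(map_a.df, map_b.df),
                   contrast=f"min({map_a.contrast}, {map_b.contrast})",
                   mask=map_a.mask & map_b.mask)


# --------------------------------------------------------------------------
# permutation cluster correction
# --------------------------------------------------------------------------

class SignFlipNull:
    """Subject-level sign-flip permutation scheme for group cluster nulls.

    Holds per-subject effect/variance maps for one or more contrasts; each
    permutation flips the sign of every map belonging to a subject jointly
    and recomputes the group statistic (minimum over contrasts when more
    than one, matching a conjunction).
    """

    def __init__(self, effects_per_contrast, variances_per_contrast, mask):
        if not isinstance(effects_per_contrast[0], (list, tuple)):
            effects_per_contrast = [effects_per_contrast]
            variances_per_contrast = [variances_per_contrast]
        self.mask = mask
        self._e = [np.stack([eff[mask] for eff in effs])
                   for effs in effects_per_contrast]
        self._v = [np.stack([var[mask] for var in vs])
                   for vs in variances_per_contrast]
        self.n_subjects = self._e[0].shape[0]

    def stat(self, signs: np.ndarray | None = None) -> np.ndarray:
        """Flattened (in-mask) group z, minimum over contrasts."""
        z = None
        for e, v in zip(self._e, self._v):
            es = e if signs is None else signs[:, None] * e
            zi = _group_z(es, v)
            z = zi if z is None else np.minimum(z, zi)
        return z


def _cluster_sizes(supra_flat: np.ndarray, mask: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    vol = np.zeros(mask.shape, dtype=bool)
    vol[mask] = supra_flat
    labels, n = ndimage.label(vol, structure=_STRUCT26)
    if n == 0:
        return labels, np.array([], dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


@dataclass
class FeatureMask:
    """Boolean voxel set plus the thresholds/statistics that produced it."""
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), np.eye(4)),
                 str(path))
        sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
        with open(sidecar, "w") as fh:
            json.dump(self.provenance, fh, indent=2)

    @classmethod
    def load(cls, path) -> "FeatureMask":
        img = nib.load(str(path))
        sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
        try:
            with open(sidecar) as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {}
        return cls(mask=np.asarray(img.dataobj).astype(bool), provenance=prov)


def cluster_correct(stat_map: StatMap, voxel_p: float, cluster_alpha: float,
                    null: SignFlipNull, n_perm: int = 500,
                    seed: int = 0) -> FeatureMask:
    """Retain suprathreshold clusters exceeding the sign-flip max-size null.

    Voxels with z above the one-sided ``voxel_p`` threshold are grouped by
    26-connectivity; a cluster survives if its size exceeds the
    (1 - cluster_alpha) quantile of the maximum-cluster-size distribution
    under subject sign flipping.  ``cluster_alpha >= 1`` keeps every
    suprathreshold cluster (threshold-only limit).
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    zthr = float(norm.isf(voxel_p))
    mask = stat_map.mask
    labels, sizes = _cluster_sizes(stat_map.data[mask] > zthr, mask)
    if sizes.size == 0:
        warnings.warn("no suprathreshold voxels; returning empty mask")
        return FeatureMask(mask=np.zeros(mask.shape, dtype=bool),
                           provenance={"voxel_p": voxel_p,
                                       "cluster_alpha": cluster_alpha,
                                       "contrast": stat_map.contrast,
                                       "n_voxels": 0, "cluster_sizes": []})
    if cluster_alpha >= 1.0:
        size_thr = 0.0
    else:
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=null.n_subjects)
            _, psizes = _cluster_sizes(null.stat(signs) > zthr, mask)
            null_max[i] = psizes.max() if psizes.size else 0
        size_thr = float(np.quantile(null_max, 1.0 - cluster_alpha))
    keep_labels = np.flatnonzero(sizes > size_thr) + 1
    keep = np.isin(labels, keep_labels)
    prov = {"voxel_p": voxel_p, "cluster_alpha": cluster_alpha,
            "z_threshold": zthr, "cluster_size_threshold": size_thr,
            "contrast": stat_map.contrast, "n_voxels": int(keep.sum()),
            "cluster_sizes": sizes[keep_labels - 1].tolist(),
            "n_perm": n_perm}
    return FeatureMask(mask=keep, provenance=prov)


# --------------------------------------------------------------------------
# end-to-end mask pipelines
# --------------------------------------------------------------------------

def _schedule_of(bold: BoldSeries) -> dg.TrSchedule:
    return dg.TrSchedule(tr=bold.tr, n_volumes=bold.n_volumes)


def _dsa_subject_effect(sub) -> tuple[np.ndarray, np.ndarray]:
    """First-level (deceased x RT) - (congruent x RT) effect for one subject,
    runs combined by fixed effects."""
    des = sub.stroop_design
    effs, vars_ = [], []
    for run_idx, (bold, motion) in enumerate(sub.stroop_runs, start=1):
        ev = des.events[des.events["run"] == run_idx]
        X = build_design_matrix(ev, _schedule_of(bold),
                                modulators=[("deceased", "rt"),
                                            ("congruent", "rt")],
                                confounds=motion)
        eff, var = fit_first_level(
            bold, X, {"deceased_x_rt": 1.0, "congruent_x_rt": -1.0})
        effs.append(eff)
        vars_.append(var)
    return combine_runs(effs, vars_, sub.stroop_runs[0][0].brain_mask)


def make_dsa_mask(cohort, voxel_p: float = 0.01, cluster_alpha: float = 0.05,
                  n_perm: int = 500, seed: int = 0) -> FeatureMask:
    """Feature mask for deceased-related selective attention.

    RT-modulation contrast (deceased x RT - congruent x RT) per subject,
    random-effects group test, then permutation cluster correction at
    voxel-P < 0.01, cluster-P < 0.05 (an intentionally inclusive mask).
    """
    effs, vars_ = zip(*(_dsa_subject_effect(s) for s in cohort.subjects))
    mask = cohort.subjects[0].stroop_runs[0][0].brain_mask
    gmap = fit_group_level(list(effs), list(vars_), mask,
                           contrast="deceased_x_rt - congruent_x_rt")
    null = SignFlipNull(list(effs), list(vars_), mask)
    return cluster_correct(gmap, voxel_p, cluster_alpha, null,
                           n_perm=n_perm, seed=seed)


def _dmr_events(design: dg.RepresentationDesign) -> pd.DataFrame:
    """Event frame for the d-MR GLM: condition-by-modality stimulus events
    (think and rating probes as nuisance), plus per-block rows carrying the
    valence/arousal ratings for parametric nuisance regressors."""
    ev = design.events.copy()
    stim = ev[ev["modality"].isin(["picture", "story"])].copy()
    stim["trial_type"] = stim["trial_type"] + "_" + stim["modality"]
    think = ev[ev["modality"] == "think"].copy()
    think["trial_type"] = "think"
    probes = ev[ev["modality"].str.startswith("probe")].copy()
    probes["trial_type"] = "rating_probe"
    block_rows = []
    for block, grp in ev.groupby("block"):
        onset = grp["onset"].min()
        end = grp.loc[grp["modality"] == "think", "onset"].iloc[0] + \
            grp.loc[grp["modality"] == "think", "duration"].iloc[0]
        block_rows.append({"onset": onset, "duration": end - onset,
                           "trial_type": "blockmod",
                           "valence": grp["valence"].iloc[0],
                           "arousal": grp["arousal"].iloc[0]})
    return pd.concat([stim, think, probes, pd.DataFrame(block_rows)],
                     ignore_index=True)


_DMR_CONTRASTS = {
    "picture": {"deceased_picture": 1.0, "living_picture": -0.5,
                "demographic_picture": -0.5},
    "story": {"deceased_story": 1.0, "living_story": -0.5,
              "demographic_story": -0.5},
}


def _dmr_subject_effects(sub) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    bold, motion = sub.rep_run
    ev = _dmr_events(sub.rep_design)
    X = build_design_matrix(ev, _schedule_of(bold),
                            modulators=[("blockmod", "valence"),
                                        ("blockmod", "arousal")],
                            confounds=motion, modulator_only=("blockmod",))
    return {name: fit_first_level(bold, X, con)
            for name, con in _DMR_CONTRASTS.items()}


def make_dmr_mask(cohort, voxel_p: float = 0.001, cluster_alpha: float = 0.1,
                  n_perm: int = 500, seed: int = 0) -> FeatureMask:
    """Feature mask for the deceased-related mental representation.

    Separate group tests for deceased-vs-controls pictures and stories (each
    with block-level valence/arousal nuisance modulators), combined by a
    minimum-statistic conjunction and cluster-corrected at voxel-P < 0.001,
    cluster-P < 0.1; the think modality carries no d-MR label and enters
    only as a nuisance regressor.
    """
    per_sub = [_dmr_subject_effects(s) for s in cohort.subjects]
    mask = cohort.subjects[0].rep_run[0].brain_mask
    group_maps = []
    eff_lists, var_lists = [], []
    for name in ("picture", "story"):
        effs = [d[name][0] for d in per_sub]
        vars_ = [d[name][1] for d in per_sub]
        group_maps.append(fit_group_level(effs, vars_, mask, contrast=name))
        eff_lists.append(effs)
        var_lists.append(vars_)
    conj = conjunction_min(*group_maps)
    null = SignFlipNull(eff_lists, var_lists, mask)
    return cluster_correct(conj, voxel_p, cluster_alpha, null,
                           n_perm=n_perm, seed=seed)
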