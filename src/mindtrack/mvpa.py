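"""Multivariate pattern training within the pre-selected feature masks.

Two decoders are trained per subject, mirroring the labels the tasks
provide:

* **d-MR classifier** — L2-regularized logistic regression separating
  deceased-related picture/story events from the two control persons,
  evaluated by leave-one-run-out cross-validated AUC;
* **d-SA regressor** — ridge regression predicting per-trial response time
  to deceased-related Stroop words, evaluated by out-of-fold predictive
  Pearson correlation.

The learned voxel weighting vector ``w`` (the decoding pattern W) is the
average of the fold weight vectors; significance of the cross-validated
performance is assessed by a within-run label-permutation test.  These are
declared modelling choices (regularization family, CV scheme, fold
averaging) and each is configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score

from . import designgen as dg
from .boldsim import BoldSeries
from .exceptions import (DataError, DesignError, ParameterError, RangeError,
                         ShapeError)


@dataclass
class SampleSet:
    """Event-level feature patterns with labels and run structure."""
    X: np.ndarray                # (n_samples, n_mask_voxels)
    y: np.ndarray                # class (0/1) or continuous RT label
    runs: np.ndarray             # run id per sample
    mask: np.ndarray             # 3D boolean feature mask

    def __post_init__(self):
        if not np.isfinite(self.X).all():
            raise DataError("non-finite feature values")
        if self.X.shape[1] != int(self.mask.sum()):
            raise ShapeError("feature width does not match mask voxel count")

    def __len__(self):
        return self.X.shape[0]


@dataclass
class PatternModel:
    """Trained voxel weighting pattern W plus its training metadata.

    ``w`` is the decoding (backward-model) weight vector that is applied to
    new data; ``w_activation`` is the corresponding forward-model activation
    pattern cov(X) @ w, the interpretable spatial image of the decoded
    process (decoding weights themselves diverge from the generative
    pattern as SNR grows, since ridge-type solutions suppress
    high-variance signal directions).
    """
    w: np.ndarray                # decoding weight per mask voxel
    mask: np.ndarray             # 3D boolean
    family: str                  # "logistic" | "ridge"
    regularization: float
    cv_scheme: str
    performance: float           # AUC (classifier) or Pearson r (regressor)
    permutation_p: float | None = None
    w_activation: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.w).all():
            raise DataError("non-finite weights")
        if self.w.size != int(self.mask.sum()):
            raise ShapeError("weight length does not match mask voxel count")

    def weight_map(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.w
        return vol

    def activation_map(self) -> np.ndarray:
        if self.w_activation is None:
            raise DataError("model has no activation pattern")
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.w_activation
        return vol

    def save(self, path) -> None:
        """Weight map (and activation pattern) as a 4D NIfTI + JSON sidecar."""
        vols = [self.weight_map()]
        if self.w_activation is not None:
            vols.append(self.activation_map())
        nib.save(nib.Nifti1Image(np.stack(vols, axis=-1).astype(np.float32),
                                 np.eye(4)), str(path))
        sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
        mask_idx = np.flatnonzero(self.mask.ravel())
        meta = {"family": self.family, "regularization": self.regularization,
                "cv_scheme": self.cv_scheme, "performance": self.performance,
                "permutation_p": self.permutation_p,
                "mask_flat_indices": mask_idx.tolist(),
                "mask_shape": list(self.mask.shape), **self.meta}
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "PatternModel":
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        mask = np.zeros(int(np.prod(meta["mask_shape"])), dtype=bool)
        mask[meta.pop("mask_flat_indices")] = True
        mask = mask.reshape(meta.pop("mask_shape"))
        if vol.ndim == 3:
            vol = vol[..., None]
        w = vol[..., 0][mask]
        act = vol[..., 1][mask] if vol.shape[-1] > 1 else None
        return cls(w=w, mask=mask, family=meta.pop("family"),
                   regularization=meta.pop("regularization"),
                   cv_scheme=meta.pop("cv_scheme"),
                   performance=meta.pop("performance"),
                   permutation_p=meta.pop("permutation_p"),
                   w_activation=act, meta=meta)


# --------------------------------------------------------------------------
# sample extraction
# --------------------------------------------------------------------------

def extract_samples(bold: BoldSeries, events: pd.DataFrame, mask: np.ndarray,
                    schedule: dg.TrSchedule, label_col: str | None = None,
                    run_col: str | None = "run",
                    hrf_offset: int = 4) -> SampleSet:
    """Per-event feature vectors: mean standardized BOLD over the event's
    hemodynamically delayed TR window.

    Each voxel's series is z-scored over time, then averaged over TRs
    ``[onset_tr + hrf_offset, onset_tr + hrf_offset + duration)`` (at least
    one TR).  The 4-TR offset matches the delay convention used when the
    trained patterns are later applied to the mindwandering tasks.
    """
    if not mask.any():
        raise ParameterError("feature mask is empty")
    data = bold.data[mask].astype(float)           # (v, t)
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (data - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    feats, labels, runs = [], [], []
    for _, ev in events.iterrows():
        start = dg.events_to_tr_index(float(ev["onset"]), schedule) + hrf_offset
        n_trs = max(1, int(np.ceil(float(ev["duration"]) / schedule.tr)))
        stop = start + n_trs - 1
        if stop > schedule.n_volumes:
            raise RangeError("event window extends past the series")
        feats.append(z[:, start - 1:stop].mean(axis=1))
        labels.append(ev[label_col] if label_col else np.nan)
        runs.append(ev[run_col] if run_col and run_col in ev else 1)
    return SampleSet(X=np.asarray(feats), y=np.asarray(labels, dtype=float),
                     runs=np.asarray(runs), mask=mask)


# --------------------------------------------------------------------------
# cross-validated training
# --------------------------------------------------------------------------

def _activation_pattern(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Forward-model pattern cov(X) @ w without forming the full covariance."""
    Xc = X - X.mean(axis=0)
    return Xc.T @ (Xc @ w) / max(1, X.shape[0] - 1)


def _run_folds(runs: np.ndarray):
    uniq = np.unique(runs)
    if uniq.size < 2:
        raise DesignError("leave-one-run-out CV requires >= 2 runs")
    for r in uniq:
        yield runs != r, runs == r


def train_dmr_classifier(samples: SampleSet,
                         grid=(1e-3, 0.01, 0.1, 1.0, 10.0),
                         seed: int = 0) -> PatternModel:
    """Leave-one-run-out L2 logistic classification of deceased vs control.

    The ridge penalty C is chosen by inner leave-one-run-out AUC on each
    training set; the reported performance is the mean out-of-fold AUC and
    the final pattern is the average of fold weight vectors.
    """
    y = samples.y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise DesignError("classifier labels must contain both classes")

    def fit_eval(X, yy, runs):
        """Mean out-of-fold AUC over runs for each C; also fold weights."""
        aucs = {c: [] for c in grid}
        for tr, te in _run_folds(runs):
            if len(np.unique(yy[tr])) < 2 or len(np.unique(yy[te])) < 2:
                raise DesignError("a CV fold contains a single class")
            for c in grid:
                clf = LogisticRegression(C=c, max_iter=2000)
                clf.fit(X[tr], yy[tr])
                aucs[c].append(roc_auc_score(yy[te], clf.decision_function(X[te])))
        return {c: float(np.mean(v)) for c, v in aucs.items()}

    fold_aucs, fold_ws, fold_cs = [], [], []
    for tr, te in _run_folds(samples.runs):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise DesignError("a CV fold contains a single class")
        inner = fit_eval(samples.X[tr], y[tr], samples.runs[tr]) \
            if len(grid) > 1 and np.unique(samples.runs[tr]).size >= 2 \
            else {grid[0]: 0.0}
        best_c = max(grid, key=lambda c: inner.get(c, -np.inf))
        clf = LogisticRegression(C=best_c, max_iter=2000)
        clf.fit(samples.X[tr], y[tr])
        fold_aucs.append(roc_auc_score(y[te], clf.decision_function(samples.X[te])))
        fold_ws.append(clf.coef_.ravel())
        fold_cs.append(best_c)
    w = np.mean(fold_ws, axis=0)
    return PatternModel(w=w, mask=samples.mask,
                        family="logistic",
                        regularization=float(np.median(fold_cs)),
                        cv_scheme="leave-one-run-out",
                        performance=float(np.mean(fold_aucs)),
                        w_activation=_activation_pattern(samples.X, w),
                        meta={"fold_auc": [float(a) for a in fold_aucs]})


def train_dsa_regressor(samples: SampleSet,
                        grid=(1.0, 10.0, 100.0, 1e3, 1e4),
                        seed: int = 0) -> PatternModel:
    """Leave-one-run-out ridge regression of deceased-word RT on patterns.

    Performance is the mean over folds of the Pearson correlation between
    out-of-fold predictions and observed RTs (per-fold correlation avoids
    the fold-intercept bias of pooled out-of-fold correlations); alpha is
    chosen by inner CV mean squared error and the final pattern averages
    the fold weight vectors.
    """
    if not np.isfinite(samples.y).all():
        raise DataError("RT labels must be finite")

    def inner_mse(X, yy, runs):
        mses = {a: [] for a in grid}
        for tr, te in _run_folds(runs):
            for a in grid:
                reg = Ridge(alpha=a)
                reg.fit(X[tr], yy[tr])
                mses[a].append(np.mean((reg.predict(X[te]) - yy[te]) ** 2))
        return {a: float(np.mean(v)) for a, v in mses.items()}

    fold_rs, fold_ws, fold_as = [], [], []
    for tr, te in _run_folds(samples.runs):
        inner = inner_mse(samples.X[tr], samples.y[tr], samples.runs[tr]) \
            if len(grid) > 1 and np.unique(samples.runs[tr]).size >= 2 \
            else {grid[0]: 0.0}
        best_a = min(grid, key=lambda a: inner.get(a, np.inf))
        reg = Ridge(alpha=best_a)
        reg.fit(samples.X[tr], samples.y[tr])
        pred = reg.predict(samples.X[te])
        if np.std(pred) == 0 or np.std(samples.y[te]) == 0:
            warnings.warn("degenerate fold predictions; fold r set to 0")
            fold_rs.append(0.0)
        else:
            fold_rs.append(float(pearsonr(pred, samples.y[te])[0]))
        fold_ws.append(reg.coef_.ravel())
        fold_as.append(best_a)
    r = float(np.mean(fold_rs))
    w = np.mean(fold_ws, axis=0)
    return PatternModel(w=w, mask=samples.mask,
                        family="ridge", regularization=float(np.median(fold_as)),
                        cv_scheme="leave-one-run-out", performance=r,
                        w_activation=_activation_pattern(samples.X, w))


def permutation_pvalue(model_fit_fn, samples: SampleSet, n_perm: int = 100,
                       seed: int = 0) -> float:
    """Permutation p-value of cross-validated performance.

    Labels are permuted within run; ``p = (1 + #{null >= observed}) /
    (1 + n_perm)``, so p is 1/(1+n_perm) when the observed performance beats
    every null draw and 1 when it beats none.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    observed = model_fit_fn(samples).performance
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = samples.y.copy()
        for r in np.unique(samples.runs):
            sel = samples.runs == r
            y_perm[sel] = rng.permutation(y_perm[sel])
        perm_set = SampleSet(X=samples.X, y=y_perm, runs=samples.runs,
                             mask=samples.mask)
        if model_fit_fn(perm_set).performance >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


# --------------------------------------------------------------------------
# task-specific sample assembly
# --------------------------------------------------------------------------

def dmr_samples(sub, mask: np.ndarray) -> SampleSet:
    """Picture and story events, deceased (1) vs both controls (0); think
    events are excluded.  Person blocks serve as CV folds ("runs") since the
    task is a single acquisition."""
    bold, _ = sub.rep_run
    ev = sub.rep_design.events
    ev = ev[ev["modality"].isin(["picture", "story"])].copy()
    ev["label"] = (ev["trial_type"] == "deceased").astype(float)
    # fold by block triplet (each fold holds one block of each person)
    ev["fold"] = (ev["block"].astype(int) - 1) // 3 + 1
    schedule = dg.TrSchedule(tr=bold.tr, n_volumes=bold.n_volumes)
    return extract_samples(bold, ev, mask, schedule, label_col="label",
                           run_col="fold")


def dsa_samples(sub, mask: np.ndarray) -> SampleSet:
    """Deceased-word Stroop trials with their RT labels, by run."""
    sets = []
    des = sub.stroop_design
    for run_idx, (bold, _) in enumerate(sub.stroop_runs, start=1):
        ev = des.events[(des.events["run"] == run_idx)
                        & (des.events["trial_type"] == "deceased")]
        schedule = dg.TrSchedule(tr=bold.tr, n_volumes=bold.n_volumes)
        sets.append(extract_samples(bold, ev, mask, schedule, label_col="rt",
                                    run_col="run"))
    return SampleSet(X=np.vstack([s.X for s in sets]),
                     y=np.concatenate([s.y for s in sets]),
                     runs=np.concatenate([s.runs for s in sets]),
                     mask=mask)
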