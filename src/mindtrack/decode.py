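"""Pattern expression: projecting trained W patterns onto SART time series.

Expression at TR t is the voxelwise product of the pattern weights with the
cleaned, standardized BOLD values, summed over the feature mask — a
unitless time-resolved proxy of the trained mental process.  Block and
whole-task averages use hemodynamically delayed windows (start 4 TRs after
the preceding boundary, end 2 TRs past the following one) and pooled
expression values are winsorized at Tukey fences before inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import designgen as dg
from .boldsim import BoldSeries, MOTION_COLUMNS
from .exceptions import InsufficientDataError, ParameterError, ShapeError
from .mvpa import PatternModel


@dataclass
class ExpressionSeries:
    """TR-by-TR expression of one pattern for one subject."""
    values: np.ndarray
    pattern_id: str = ""
    subject_id: str = ""

    def __len__(self):
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tr_index": np.arange(1, len(self) + 1),
                             "value": self.values})


def clean_standardize(bold: BoldSeries, motion: pd.DataFrame) -> BoldSeries:
    """Regress out six motion parameters, then z-score each voxel's series.

    Mirrors the standard cleaning applied before pattern application:
    per-voxel residualization on [intercept, 6 motion columns] followed by
    standardization to mean 0, s.d. 1.  Zero-variance voxels become all
    zeros.
    """
    if bold.n_volumes < 8:
        raise InsufficientDataError("need at least 8 time points")
    if len(motion) != bold.n_volumes:
        raise ParameterError("motion rows must equal n_volumes")
    cols = [c for c in MOTION_COLUMNS if c in motion.columns]
    mot = motion[cols] if len(cols) == 6 else motion.iloc[:, :6]
    X = np.column_stack([np.ones(bold.n_volumes), mot.to_numpy(dtype=float)])
    Y = bold.masked().T.astype(float)                       # (t, v)
    resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
    sd = resid.std(axis=0)
    # voxels fully explained by the confounds (or constant) become all-zero
    # rather than z-scored numerical noise
    keep = sd > 1e-6 * np.maximum(Y.std(axis=0), 1.0)
    z = np.where(keep, resid / np.where(keep, sd, 1.0), 0.0)
    data = np.zeros_like(bold.data, dtype=np.float32)
    data[bold.brain_mask] = z.T.astype(np.float32)
    return BoldSeries(data=data, tr=bold.tr, affine=bold.affine,
                      brain_mask=bold.brain_mask)


def apply_pattern(model: PatternModel, bold: BoldSeries,
                  pattern_id: str = "", subject_id: str = "") -> ExpressionSeries:
    """expression(t) = sum_v w_v * bold_v(t) over the pattern's mask."""
    if model.mask.shape != bold.shape:
        raise ShapeError("pattern mask grid does not match BOLD grid")
    series = model.w @ bold.data[model.mask].astype(float)
    return ExpressionSeries(values=series, pattern_id=pattern_id or model.family,
                            subject_id=subject_id)


def block_average(expr: ExpressionSeries, design: dg.SartDesign,
                  schedule: dg.TrSchedule, hrf_offset: int = 4,
                  tail: int = 2) -> np.ndarray:
    """Per-block mean expression over the delayed probe-to-probe windows."""
    if len(expr) != schedule.n_volumes:
        raise ShapeError("expression length does not match schedule")
    means = []
    for lo, hi in dg.block_windows(design, schedule, hrf_offset, tail):
        if hi < lo:
            warnings.warn("empty block window after clipping; mean is NaN")
            means.append(np.nan)
        else:
            means.append(float(expr.values[lo - 1:hi].mean()))
    return np.asarray(means)


def task_average(expr: ExpressionSeries, design: dg.SartDesign,
                 schedule: dg.TrSchedule, hrf_offset: int = 4,
                 tail: int = 2) -> float:
    """Whole-task mean expression for the continuous SART."""
    lo, hi = dg.task_window(design, schedule, hrf_offset, tail)
    full_hi = dg._last_tr_overlapping(design.duration, schedule) + tail
    if full_hi > schedule.n_volumes:
        warnings.warn("series ends before 2 TRs past task end; window clipped")
    return float(expr.values[lo - 1:hi].mean())


def winsorize_iqr(values, factor: float = 1.5) -> tuple[np.ndarray, int]:
    """Censor Tukey-fence outliers to the nearest in-fence observed value.

    Fences are ``[Q1 - factor*IQR, Q3 + factor*IQR]`` with linearly
    interpolated quartiles.  Values outside the fences are replaced by the
    nearest observed value inside them (order preserved).  Returns the
    winsorized array and the number of changed values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ParameterError("need at least 4 values to winsorize")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    lo_fence = q1 - factor * (q3 - q1)
    hi_fence = q3 + factor * (q3 - q1)
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    out = x.copy()
    low = x < lo_fence
    high = x > hi_fence
    if inside.size:
        out[low] = inside.min()
        out[high] = inside.max()
    return out, int(low.sum() + high.sum())


# --------------------------------------------------------------------------
# block-record assembly
# --------------------------------------------------------------------------

def build_block_records(sub, dsa_model: PatternModel, dmr_model: PatternModel,
                        winsorize: bool = False) -> pd.DataFrame:
    """Decode one subject's probed SART into a 16-row block table.

    Cleans and standardizes the BOLD, applies both patterns, averages over
    the delayed block windows, and joins the behavioural probe responses and
    error flags.  Error blocks are flagged here but only excluded at the
    inference stage.
    """
    bold, motion = sub.probes_run
    design = sub.probes_design
    schedule = dg.TrSchedule(tr=bold.tr, n_volumes=bold.n_volumes)
    clean = clean_standardize(bold, motion)
    out = sub.probes_blocks[["subject_id", "block", "probe_deceased",
                             "probe_living", "probe_self", "error"]].copy()
    for name, model in (("sa", dsa_model), ("mr", dmr_model)):
        expr = apply_pattern(model, clean, pattern_id=name,
                             subject_id=sub.record.subject_id)
        vals = block_average(expr, design, schedule)
        if winsorize:
            vals, _ = winsorize_iqr(vals)
        out[name] = vals
    return out


def cohort_block_records(cohort, dsa_models: dict, dmr_models: dict,
                         winsorize: bool = True) -> pd.DataFrame:
    """Decoded block table across subjects; expression values winsorized
    across the pooled sample per pattern (as the outlier counts are assessed
    on the pooled expression output)."""
    tabs = [build_block_records(s, dsa_models[s.record.subject_id],
                                dmr_models[s.record.subject_id])
            for s in cohort.subjects]
    blocks = pd.concat(tabs, ignore_index=True)
    if winsorize:
        for name in ("sa", "mr"):
            blocks[name], _ = winsorize_iqr(blocks[name].to_numpy())
    return blocks
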