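"""End-to-end orchestration: cohort -> masks -> patterns -> expression -> model.

Chains the full analysis on a (typically simulated) cohort: univariate
feature selection, per-subject pattern training, pattern-expression decoding
of the probed SART, and the factorial mixed logistic model.  Used by the
integration tests, the acceptance script and the ``mindtrack run`` command.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decode, designgen as dg, featselect, inference, mvpa
from .boldsim import CohortDataset
from .exceptions import DataError


@dataclass
class PipelineResult:
    dsa_mask: featselect.FeatureMask
    dmr_mask: featselect.FeatureMask
    dsa_models: dict
    dmr_models: dict
    blocks: pd.DataFrame
    table: pd.DataFrame
    three_way: inference.ModelResult
    split: tuple | None = None
    extras: dict = field(default_factory=dict)


def train_subject_models(cohort: CohortDataset, dsa_mask, dmr_mask
                         ) -> tuple[dict, dict]:
    dsa_models, dmr_models = {}, {}
    for sub in cohort.subjects:
        sid = sub.record.subject_id
        dsa_models[sid] = mvpa.train_dsa_regressor(
            mvpa.dsa_samples(sub, dsa_mask.mask))
        dmr_models[sid] = mvpa.train_dmr_classifier(
            mvpa.dmr_samples(sub, dmr_mask.mask))
    return dsa_models, dmr_models


def run_pipeline(cohort: CohortDataset, n_perm: int = 200, seed: int = 0,
                 median_split: bool = False) -> PipelineResult:
    """Run feature selection, pattern training, decoding and inference."""
    dsa_mask = featselect.make_dsa_mask(cohort, n_perm=n_perm, seed=seed)
    dmr_mask = featselect.make_dmr_mask(cohort, n_perm=n_perm, seed=seed + 1)
    if dsa_mask.n_voxels == 0 or dmr_mask.n_voxels == 0:
        raise DataError("a feature mask is empty; cannot train patterns "
                        "(low SNR or too few subjects)")
    dsa_models, dmr_models = train_subject_models(cohort, dsa_mask, dmr_mask)
    blocks = decode.cohort_block_records(cohort, dsa_models, dmr_models)
    table = inference.standardize_predictors(blocks, cohort.clinical)
    three_way = inference.fit_three_way_mixed_logit(table)
    split = inference.median_split_models(table) if median_split else None
    return PipelineResult(dsa_mask=dsa_mask, dmr_mask=dmr_mask,
                          dsa_models=dsa_models, dmr_models=dmr_models,
                          blocks=blocks, table=table, three_way=three_way,
                          split=split)


def sart_subject_table(cohort: CohortDataset, dsa_models: dict,
                       dmr_models: dict) -> pd.DataFrame:
    """Subject-level continuous-SART table: task-average expressions,
    avoidance and the post-task loss-thought report."""
    rows = []
    for sub in cohort.subjects:
        if sub.sart_run is None:
            continue
        sid = sub.record.subject_id
        bold, motion = sub.sart_run
        schedule = dg.TrSchedule(tr=bold.tr, n_volumes=bold.n_volumes)
        clean = decode.clean_standardize(bold, motion)
        row = {"subject_id": sid, "avoidance": sub.record.avoidance,
               "report": sub.sart_report}
        for name, model in (("sa", dsa_models[sid]), ("mr", dmr_models[sid])):
            expr = decode.apply_pattern(model, clean)
            row[name] = decode.task_average(expr, sub.sart_design, schedule)
        rows.append(row)
    return pd.DataFrame(rows)
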