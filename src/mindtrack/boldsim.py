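"""Synthetic 4D BOLD with embedded ground-truth mental-state patterns.

The simulator is the package's test bed: it embeds two disjoint spatial
weight maps — a "basal-ganglia-like" deceased-related mental-representation
(d-MR) pattern and a "frontotemporoparietal-like" deceased-related
selective-attention (d-SA) pattern — into noisy AR(1) BOLD, and couples
their latent states to yes/no thought-probe responses through an
avoidance-moderated full-factorial logistic model.  Every downstream stage
(feature selection, pattern training, decoding, inference) can therefore be
checked against a known truth.

Signal model per voxel v and TR t::

    bold(v, t) = snr * [w_dsa(v) * s_sa(t) + w_dmr(v) * s_mr(t)]
                 + drift(v, t) + motion-coupled nuisance + AR(1) noise

with unit-variance HRF-convolved states ``s`` and unit-RMS weight maps, so
``snr`` is the signal/noise amplitude ratio at a typical pattern voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from . import designgen as dg
from .exceptions import DataError, ParameterError, RangeError

_FINE_DT = 0.1   # resolution (s) for neural-state construction / convolution

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class BoldSeries:
    """4D voxel time series plus its sampling grid and brain mask."""
    data: np.ndarray                  # (x, y, z, t)
    tr: float
    affine: np.ndarray
    brain_mask: np.ndarray            # (x, y, z) boolean

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ParameterError("data must be 4D with at least one volume")
        if not self.brain_mask.any():
            raise ParameterError("brain mask is empty")
        if not np.isfinite(self.data).all():
            raise DataError("BOLD contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def masked(self) -> np.ndarray:
        """(n_mask_voxels, t) view of in-mask time series."""
        return self.data[self.brain_mask]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))
        mask_path = str(path).replace(".nii", "_mask.nii")
        nib.save(nib.Nifti1Image(self.brain_mask.astype(np.uint8), self.affine),
                 mask_path)

    @classmethod
    def load(cls, path) -> "BoldSeries":
        img = nib.load(str(path))
        mask_img = nib.load(str(path).replace(".nii", "_mask.nii"))
        tr = float(img.header.get_zooms()[3])
        return cls(data=np.asarray(img.dataobj, dtype=np.float32), tr=tr,
                   affine=img.affine,
                   brain_mask=np.asarray(mask_img.dataobj).astype(bool))


@dataclass
class GroundTruth:
    """True spatial patterns and SNR used to generate a dataset."""
    w_true_dsa: np.ndarray
    w_true_dmr: np.ndarray
    brain_mask: np.ndarray
    snr: float

    def save(self, path) -> None:
        np.savez(path, w_true_dsa=self.w_true_dsa, w_true_dmr=self.w_true_dmr,
                 brain_mask=self.brain_mask, snr=self.snr)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        z = np.load(path)
        return cls(w_true_dsa=z["w_true_dsa"], w_true_dmr=z["w_true_dmr"],
                   brain_mask=z["brain_mask"].astype(bool), snr=float(z["snr"]))


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical covariates entering the inference stage."""
    subject_id: str
    avoidance: float          # IES-A mean item score
    icg: float                # Inventory of Complicated Grief total
    cesd: float               # CES-D mean item score
    age: float
    months_since_loss: float
    loss_type: str            # "suicide" | "other"
    medication: bool
    education_years: float = 16.0

    def __post_init__(self):
        if self.avoidance < 0:
            raise ParameterError("avoidance score must be non-negative")
        if not 3 <= self.months_since_loss <= 14:
            raise ParameterError("months_since_loss must lie in [3, 14]")


@dataclass(frozen=True)
class NoiseParams:
    ar1_phi: float = 0.3
    sigma: float = 1.0
    drift_amplitude: float = 0.5
    motion_amplitude: float = 0.5

    def validate(self):
        if not abs(self.ar1_phi) < 1:
            raise ParameterError("|ar1_phi| must be < 1")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


@dataclass(frozen=True)
class RtParams:
    """Generative response-time model for the Stroop task (seconds)."""
    base: tuple = (("deceased", 0.68), ("living", 0.65),
                   ("congruent", 0.62), ("incongruent", 0.72))
    coupling: float = 0.08      # s of deceased-trial RT per s.d. of latent attention
    noise_sd: float = 0.05
    floor: float = 0.2


#: Fixed-effect coefficients of the generative probe-response model, on the
#: per-standard-deviation scale.  Interaction structure mirrors the full
#: factorial of d-MR, d-SA and avoidance.  The intercept is calibrated so
#: that the *marginal* rate of loss-thought reports is 85/275 (~31%) under
#: standard-normal states/avoidance and a 0.5-s.d. random intercept — the
#: nonlinear interactions raise the marginal rate above expit(b0), so b0
#: sits below logit(0.309).
DEFAULT_COEFFS = {
    "b0": -1.5355,
    "b_mr": 0.33, "b_sa": 0.72, "b_av": 1.0,
    "b_mrsa": 2.21, "b_mrav": -0.25, "b_saav": 1.11,
    "b_three": -2.37,
}


@dataclass
class CohortParams:
    n_subjects: int = 27
    coeffs: dict = field(default_factory=lambda: dict(DEFAULT_COEFFS))
    noise: NoiseParams = field(default_factory=NoiseParams)
    snr: float = 1.0
    shape: tuple = (20, 20, 12)
    tr: float = 2.0
    p_error_block: float = 1.0 - 275 / 432   # matches 275 error-free of 27*16 blocks
    random_intercept_sd: float = 0.5
    state_phi: float = 0.85      # smoothness of latent SART state fluctuations
    rt_coupling: float | None = None     # None -> RtParams default
    dmr_modalities: tuple = ("picture", "story")
    seed: int = 0
    tasks: tuple = ("stroop", "representation", "sart", "sart_probes")

    def validate(self):
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        self.noise.validate()


# --------------------------------------------------------------------------
# hemodynamic response
# --------------------------------------------------------------------------

def _hrf_fine(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF on a dt grid, unit peak.

    Response gamma peaks at 6 s, undershoot gamma at 16 s, undershoot ratio
    1/6 (the standard canonical shape).
    """
    t = np.arange(0, duration + dt / 2, dt)
    peak = gamma_dist.pdf(t, a=7.0, scale=1.0)       # mode (a-1)*scale = 6 s
    under = gamma_dist.pdf(t, a=17.0, scale=1.0)     # mode 16 s
    h = peak - under / 6.0
    return h / h.max()


def hrf_kernel(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds, unit peak."""
    if tr <= 0:
        raise ParameterError("tr must be positive")
    fine = _hrf_fine(_FINE_DT, duration)
    step = int(round(tr / _FINE_DT))
    h = fine[::step]
    return h / h.max()


def _convolve_to_trs(fine_course: np.ndarray, schedule: dg.TrSchedule) -> np.ndarray:
    """HRF-convolve a fine-resolution neural course and sample at TR onsets."""
    hrf = _hrf_fine(_FINE_DT)
    conv = np.convolve(fine_course, hrf)[:fine_course.size]
    idx = (np.arange(schedule.n_volumes) * schedule.tr / _FINE_DT).round().astype(int)
    idx = np.clip(idx, 0, conv.size - 1)
    return conv[idx]


def _fine_grid_len(schedule: dg.TrSchedule) -> int:
    return int(round(schedule.duration / _FINE_DT))


def _events_to_fine_course(onsets, durations, amplitudes, schedule) -> np.ndarray:
    course = np.zeros(_fine_grid_len(schedule))
    for o, d, a in zip(onsets, durations, amplitudes):
        i0 = int(round(o / _FINE_DT))
        i1 = int(round((o + d) / _FINE_DT))
        if i1 > course.size:
            raise RangeError("event extends past the acquisition schedule")
        course[i0:i1] += a
    return course


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def make_ground_truth(shape=(20, 20, 12), snr: float = 1.0, seed: int = 0,
                      smooth_vox: float = 1.5) -> GroundTruth:
    """Smoothed random Gaussian-field patterns on two disjoint regions.

    The volume is split along x into two slabs standing in for the two
    anatomically distinct systems (d-MR vs d-SA); each pattern is a smoothed
    white-noise field restricted to a central blob of its slab, normalised
    to unit RMS over its support.  Disjoint supports make pattern-leakage
    checks meaningful.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    brain = np.zeros(shape, dtype=bool)
    brain[1:-1, 1:-1, 1:-1] = True

    def field(x_lo, x_hi):
        support = np.zeros(shape, dtype=bool)
        support[x_lo:x_hi, 2:-2, 2:-2] = True
        support &= brain
        w = gaussian_filter(rng.standard_normal(shape), smooth_vox)
        w[~support] = 0.0
        # zero-mean over the support: the pattern is a contrast between
        # voxels, invisible to the region-mean BOLD signal
        w[support] -= w[support].mean()
        rms = np.sqrt(np.mean(w[support] ** 2))
        return w / rms

    gap = max(1, nx // 10)
    w_dmr = field(1, nx // 2 - gap)
    w_dsa = field(nx // 2 + gap, nx - 1)
    return GroundTruth(w_true_dsa=w_dsa, w_true_dmr=w_dmr, brain_mask=brain,
                       snr=snr)


# --------------------------------------------------------------------------
# neural states per design
# --------------------------------------------------------------------------

def neural_states(design, schedule: dg.TrSchedule, seed: int = 0,
                  state_phi: float = 0.85,
                  dmr_modalities: tuple = ("picture", "story")) -> dict:
    """Fine-grid latent neural courses for d-SA and d-MR implied by a design.

    Stroop: the d-SA state fires on each deceased word with amplitude given
    by the trial's latent attention capture (standardized), which the RT
    model couples into that trial's RT excess; if the latent column is
    absent (measured data), the standardized RT itself is used.
    Representation: the d-MR state is a boxcar over deceased events of the
    requested modalities.  SART variants: both states are smooth latent
    AR(1) fluctuations at TR resolution, held constant within each TR.
    """
    n_fine = _fine_grid_len(schedule)
    out = {"sa": np.zeros(n_fine), "mr": np.zeros(n_fine)}
    if isinstance(design, dg.StroopDesign):
        ev = design.events
        dec = ev[ev["trial_type"] == "deceased"]
        if "latent_attention" in dec.columns and dec["latent_attention"].notna().all():
            amps = _standardize(dec["latent_attention"].to_numpy())
        elif dec["rt"].notna().all():
            amps = _standardize(dec["rt"].to_numpy())
        else:
            raise DataError("Stroop design has unfilled RTs; run simulate_rts first")
        out["sa"] = _events_to_fine_course(dec["onset"], dec["duration"], amps,
                                           schedule)
    elif isinstance(design, dg.RepresentationDesign):
        ev = design.events
        sel = (ev["trial_type"] == "deceased") & ev["modality"].isin(dmr_modalities)
        out["mr"] = _events_to_fine_course(ev.loc[sel, "onset"],
                                           ev.loc[sel, "duration"],
                                           np.ones(int(sel.sum())), schedule)
    elif isinstance(design, dg.SartDesign):
        rng = np.random.default_rng(seed)
        reps = int(round(schedule.tr / _FINE_DT))
        for key in ("sa", "mr"):
            x = np.empty(schedule.n_volumes)
            x[0] = rng.standard_normal()
            innov = rng.standard_normal(schedule.n_volumes - 1)
            s = np.sqrt(1 - state_phi ** 2)
            for t in range(1, schedule.n_volumes):
                x[t] = state_phi * x[t - 1] + s * innov[t - 1]
            out[key] = np.repeat(x, reps)[:n_fine]
    else:
        raise TypeError(f"unknown design type {type(design).__name__}")
    return out


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------

def _ar1_noise(rng, n_vox, n_t, phi, sigma):
    eps = rng.standard_normal((n_vox, n_t))
    if phi == 0:
        return sigma * eps
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0]
    s = np.sqrt(1 - phi ** 2)
    for t in range(1, n_t):
        out[:, t] = phi * out[:, t - 1] + s * eps[:, t]
    return sigma * out


def simulate_motion(rng, n_t: int, amplitude: float = 1.0) -> pd.DataFrame:
    """Random-walk six-parameter head motion (mm / rad)."""
    steps = rng.standard_normal((n_t, 6))
    steps[:, :3] *= 0.02 * amplitude
    steps[:, 3:] *= 0.0005 * amplitude
    return pd.DataFrame(np.cumsum(steps, axis=0), columns=MOTION_COLUMNS)


def simulate_bold(design, truth: GroundTruth, noise: NoiseParams,
                  schedule: dg.TrSchedule, seed: int,
                  states: dict | None = None,
                  dmr_modalities: tuple = ("picture", "story"),
                  state_phi: float = 0.85) -> tuple[BoldSeries, pd.DataFrame]:
    """Simulate one acquisition of any task design.

    Returns the BOLD series and its six-column motion table.  ``states``
    may carry precomputed fine-grid latent courses (as from
    :func:`neural_states`); otherwise they are derived from the design.
    """
    noise.validate()
    rng = np.random.default_rng(seed)
    if states is None:
        states = neural_states(design, schedule, seed=rng.integers(2 ** 31),
                               state_phi=state_phi, dmr_modalities=dmr_modalities)
    end_time = getattr(design, "duration", None)
    if end_time is not None and end_time > schedule.duration:
        raise RangeError("schedule too short for the design")

    mask = truth.brain_mask
    n_vox = int(mask.sum())
    n_t = schedule.n_volumes

    s_sa = _standardize(_convolve_to_trs(states["sa"], schedule)) \
        if np.any(states["sa"]) else np.zeros(n_t)
    s_mr = _standardize(_convolve_to_trs(states["mr"], schedule)) \
        if np.any(states["mr"]) else np.zeros(n_t)

    sig = truth.snr * (np.outer(truth.w_true_dsa[mask], s_sa)
                       + np.outer(truth.w_true_dmr[mask], s_mr))

    # nuisance: slow polynomial drift + motion-coupled component + AR(1) noise
    tt = np.linspace(-1, 1, n_t)
    drift_basis = np.vstack([tt, 3 * tt ** 2 - 1])
    drift = noise.drift_amplitude * rng.standard_normal((n_vox, 2)) @ drift_basis
    motion = simulate_motion(rng, n_t, 1.0)
    mot_z = (motion - motion.mean()) / (motion.std() + 1e-12)
    mot_sig = noise.motion_amplitude * rng.standard_normal((n_vox, 6)) @ mot_z.to_numpy().T
    eps = _ar1_noise(rng, n_vox, n_t, noise.ar1_phi, noise.sigma)

    data = np.zeros((*mask.shape, n_t), dtype=np.float32)
    data[mask] = (sig + drift + mot_sig + eps).astype(np.float32)
    bold = BoldSeries(data=data, tr=schedule.tr, affine=np.eye(4),
                      brain_mask=mask)
    return bold, motion


def simulate_rts(design: dg.StroopDesign, params: RtParams | None = None,
                 seed: int = 0, coupling: float | None = None) -> dg.StroopDesign:
    """Fill per-trial RTs: condition base + latent attention coupling + noise.

    Deceased-word trials carry a latent attention-capture value whose
    coupling into RT makes response time the behavioural label of the d-SA
    pattern.  RTs are floored at a 0.2 s physiological minimum.  Returns a
    new design with the ``rt`` (and ``latent_attention``) columns filled.
    """
    params = params or RtParams()
    rng = np.random.default_rng(seed)
    ev = design.events.copy()
    base = dict(params.base)
    c = params.coupling if coupling is None else coupling
    latent = rng.standard_normal(len(ev))
    rt = ev["trial_type"].map(base).to_numpy(dtype=float)
    rt += params.noise_sd * rng.standard_normal(len(ev))
    is_dec = (ev["trial_type"] == "deceased").to_numpy()
    rt[is_dec] += c * latent[is_dec]
    ev["latent_attention"] = latent
    ev["rt"] = np.maximum(rt, params.floor)
    return dg.StroopDesign(events=ev, params=design.params)


def simulate_probe_responses(block_states: pd.DataFrame, subject_av: float,
                             coeffs: dict, seed: int = 0,
                             random_intercept: float = 0.0) -> np.ndarray:
    """Bernoulli yes/no loss-thought reports from the factorial logistic model.

    ``block_states`` must carry within-subject standardized per-block mean
    expressions ``mr`` and ``sa``; ``subject_av`` is the subject's
    standardized avoidance.  The linear predictor is the full factorial
    b0 + b_mr*mr + b_sa*sa + b_av*av + b_mrsa*mr*sa + b_mrav*mr*av
    + b_saav*sa*av + b_three*mr*sa*av (+ a subject random intercept).
    """
    mr = np.asarray(block_states["mr"], dtype=float)
    sa = np.asarray(block_states["sa"], dtype=float)
    if not (np.isfinite(mr).all() and np.isfinite(sa).all()
            and np.isfinite(subject_av)):
        raise DataError("non-finite states or avoidance")
    av = subject_av
    eta = (coeffs["b0"] + random_intercept
           + coeffs["b_mr"] * mr + coeffs["b_sa"] * sa + coeffs["b_av"] * av
           + coeffs["b_mrsa"] * mr * sa + coeffs["b_mrav"] * mr * av
           + coeffs["b_saav"] * sa * av + coeffs["b_three"] * mr * sa * av)
    rng = np.random.default_rng(seed)
    return rng.random(mr.size) < expit(eta)


def simulate_clinical(n_subjects: int, seed: int = 0) -> list[SubjectRecord]:
    """Clinical covariate table emulating a bereaved cohort (3-14 months
    post-loss, mostly suicide-bereaved, moderate-to-severe grief)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        records.append(SubjectRecord(
            subject_id=f"sub-{i + 1:02d}",
            avoidance=float(np.clip(rng.normal(1.71, 0.59), 0.05, 4.0)),
            icg=float(np.clip(rng.normal(26.14, 12.84), 0, 76)),
            cesd=float(np.clip(rng.normal(1.63, 0.43), 0.1, 3.0)),
            age=float(np.clip(rng.normal(44.06, 13.65), 18, 65)),
            months_since_loss=float(rng.uniform(3, 14)),
            loss_type="suicide" if rng.random() < 20 / 29 else "other",
            medication=bool(rng.random() < 10 / 29),
            education_years=float(np.clip(rng.normal(16.43, 1.9), 10, 22)),
        ))
    return records


def clinical_table(records: list[SubjectRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    return df.set_index("subject_id", drop=False)


RATING_MEANS = {  # (valence, arousal) population means per person condition
    "deceased": (2.0, 3.5), "living": (4.0, 2.8), "demographic": (3.0, 2.5),
}


def simulate_ratings(design: dg.RepresentationDesign, seed: int = 0
                     ) -> dg.RepresentationDesign:
    """Fill per-block valence/arousal ratings (1-5) on all rows of each block."""
    rng = np.random.default_rng(seed)
    ev = design.events.copy()
    for block, grp in ev.groupby("block"):
        cond = grp["trial_type"].iloc[0]
        v_mu, a_mu = RATING_MEANS[cond]
        v = int(np.clip(np.round(rng.normal(v_mu, 0.8)), 1, 5))
        a = int(np.clip(np.round(rng.normal(a_mu, 0.8)), 1, 5))
        ev.loc[grp.index, "valence"] = v
        ev.loc[grp.index, "arousal"] = a
    return dg.RepresentationDesign(events=ev, params=design.params)


# --------------------------------------------------------------------------
# whole-cohort orchestration
# --------------------------------------------------------------------------

@dataclass
class SubjectData:
    """All simulated acquisitions and labels for one subject."""
    record: SubjectRecord
    stroop_design: dg.StroopDesign | None = None
    stroop_runs: list = field(default_factory=list)      # (BoldSeries, motion) per run
    rep_design: dg.RepresentationDesign | None = None
    rep_run: tuple | None = None
    sart_design: dg.SartDesign | None = None
    sart_run: tuple | None = None
    sart_report: float | None = None                     # post-task 1-4 rating
    probes_design: dg.SartDesign | None = None
    probes_run: tuple | None = None
    probes_blocks: pd.DataFrame | None = None            # ground-truth block table


@dataclass
class CohortDataset:
    params: CohortParams
    truth: GroundTruth
    clinical: pd.DataFrame
    subjects: list[SubjectData]

    def block_table(self) -> pd.DataFrame:
        """Ground-truth per-block table across subjects (generative states)."""
        return pd.concat([s.probes_blocks for s in self.subjects
                          if s.probes_blocks is not None], ignore_index=True)

    # -- directory round-trip ------------------------------------------------
    def save(self, root) -> None:
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        self.truth.save(root / "ground_truth.npz")
        self.clinical.to_csv(root / "clinical.tsv", sep="\t", index=False)
        meta = {"n_subjects": self.params.n_subjects, "tr": self.params.tr,
                "snr": self.params.snr, "shape": list(self.params.shape),
                "coeffs": self.params.coeffs, "seed": self.params.seed,
                "tasks": list(self.params.tasks)}
        (root / "params.json").write_text(json.dumps(meta, indent=2))
        for s in self.subjects:
            sd = root / s.record.subject_id
            sd.mkdir(exist_ok=True)
            if s.stroop_design is not None:
                dg.write_events_tsv(s.stroop_design, sd / "stroop_events.tsv")
                for r, (bold, motion) in enumerate(s.stroop_runs, start=1):
                    bold.save(sd / f"stroop_run-{r}.nii.gz")
                    motion.to_csv(sd / f"stroop_run-{r}_motion.tsv", sep="\t",
                                  index=False)
            for name, des, run in (("rep", s.rep_design, s.rep_run),
                                   ("sart", s.sart_design, s.sart_run),
                                   ("probes", s.probes_design, s.probes_run)):
                if des is None:
                    continue
                dg.write_events_tsv(des, sd / f"{name}_events.tsv")
                if run is not None:
                    run[0].save(sd / f"{name}.nii.gz")
                    run[1].to_csv(sd / f"{name}_motion.tsv", sep="\t", index=False)
            if s.probes_blocks is not None:
                s.probes_blocks.to_csv(sd / "probes_blocks.tsv", sep="\t",
                                       index=False)


def _probe_block_table(subject_id, design, schedule, states, rng,
                       av_z, coeffs, ri_sd, p_error) -> pd.DataFrame:
    """Ground-truth block table: windowed state means drive probe responses."""
    windows = dg.block_windows(design, schedule)
    s = {k: _standardize(_convolve_to_trs(states[k], schedule))
         for k in ("sa", "mr")}
    rows = []
    for b, (lo, hi) in enumerate(windows, start=1):
        rows.append({"block": b,
                     "sa": float(s["sa"][lo - 1:hi].mean()),
                     "mr": float(s["mr"][lo - 1:hi].mean())})
    tab = pd.DataFrame(rows)
    for k in ("sa", "mr"):
        tab[k] = _standardize(tab[k].to_numpy())
    ri = ri_sd * rng.standard_normal()
    tab["probe_deceased"] = simulate_probe_responses(
        tab, av_z, coeffs, seed=int(rng.integers(2 ** 31)), random_intercept=ri)
    tab["probe_living"] = rng.random(len(tab)) < 0.3
    tab["probe_self"] = rng.random(len(tab)) < 0.6
    tab["error"] = rng.random(len(tab)) < p_error
    tab.insert(0, "subject_id", subject_id)
    return tab


def simulate_cohort(params: CohortParams | None = None) -> CohortDataset:
    """Simulate a full bereaved cohort: clinical table, task designs, BOLD
    with embedded ground-truth patterns, RT labels, ratings, probe responses
    and post-task reports — everything the pipeline consumes end to end."""
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = make_ground_truth(params.shape, snr=params.snr,
                              seed=int(rng.integers(2 ** 31)))
    records = simulate_clinical(params.n_subjects, seed=int(rng.integers(2 ** 31)))
    clin = clinical_table(records)
    av = clin["avoidance"].to_numpy()
    av_z = (av - av.mean()) / av.std()

    subjects = []
    for i, rec in enumerate(records):
        sub = SubjectData(record=rec)
        sseed = int(rng.integers(2 ** 31))
        srng = np.random.default_rng(sseed)

        if "stroop" in params.tasks:
            des = dg.generate_stroop_design(int(srng.integers(2 ** 31)))
            des = simulate_rts(des, seed=int(srng.integers(2 ** 31)),
                               coupling=params.rt_coupling)
            sub.stroop_design = des
            for run in sorted(des.events["run"].unique()):
                run_des = dg.StroopDesign(
                    events=des.events[des.events["run"] == run].reset_index(drop=True),
                    params=des.params)
                sched = dg.schedule_for(run_des.run_duration, params.tr)
                bold, motion = simulate_bold(run_des, truth, params.noise, sched,
                                             seed=int(srng.integers(2 ** 31)))
                sub.stroop_runs.append((bold, motion))

        if "representation" in params.tasks:
            des = dg.generate_representation_design(int(srng.integers(2 ** 31)))
            des = simulate_ratings(des, seed=int(srng.integers(2 ** 31)))
            sub.rep_design = des
            sched = dg.schedule_for(des.duration, params.tr)
            sub.rep_run = simulate_bold(des, truth, params.noise, sched,
                                        seed=int(srng.integers(2 ** 31)),
                                        dmr_modalities=params.dmr_modalities)

        if "sart" in params.tasks:
            des = dg.generate_sart_design(int(srng.integers(2 ** 31)), "continuous")
            sub.sart_design = des
            sched = dg.schedule_for(des.duration, params.tr)
            states = neural_states(des, sched, seed=int(srng.integers(2 ** 31)),
                                   state_phi=params.state_phi)
            sub.sart_run = simulate_bold(des, truth, params.noise, sched,
                                         seed=int(srng.integers(2 ** 31)),
                                         states=states)
            lo, hi = dg.task_window(des, sched)
            mr_mean = float(_standardize(
                _convolve_to_trs(states["mr"], sched))[lo - 1:hi].mean())
            sub.sart_report = float(np.clip(
                1.67 - 1.5 * mr_mean + 0.4 * srng.standard_normal(), 1, 4))

        if "sart_probes" in params.tasks:
            des = dg.generate_sart_design(int(srng.integers(2 ** 31)), "probed")
            sub.probes_design = des
            sched = dg.schedule_for(des.duration, params.tr)
            states = neural_states(des, sched, seed=int(srng.integers(2 ** 31)),
                                   state_phi=params.state_phi)
            sub.probes_run = simulate_bold(des, truth, params.noise, sched,
                                           seed=int(srng.integers(2 ** 31)),
                                           states=states)
            sub.probes_blocks = _probe_block_table(
                rec.subject_id, des, sched, states, srng, av_z[i],
                params.coeffs, params.random_intercept_sd, params.p_error_block)
        subjects.append(sub)
    return CohortDataset(params=params, truth=truth, clinical=clin,
                         subjects=subjects)


def simulate_block_table(n_subjects: int = 27, n_blocks: int = 16,
                         coeffs: dict | None = None, seed: int = 0,
                         p_error: float = 1.0 - 275 / 432,
                         random_intercept_sd: float = 0.5) -> pd.DataFrame:
    """Block-level generative data without BOLD: per-block standard-normal
    d-MR/d-SA states and factorial probe responses, joined to a clinical
    table.  The fast substrate for inference calibration and recovery."""
    coeffs = coeffs or DEFAULT_COEFFS
    rng = np.random.default_rng(seed)
    records = simulate_clinical(n_subjects, seed=int(rng.integers(2 ** 31)))
    av = np.array([r.avoidance for r in records])
    av_z = (av - av.mean()) / av.std()
    tabs = []
    for i, rec in enumerate(records):
        tab = pd.DataFrame({"block": np.arange(1, n_blocks + 1),
                            "mr": rng.standard_normal(n_blocks),
                            "sa": rng.standard_normal(n_blocks)})
        ri = random_intercept_sd * rng.standard_normal()
        tab["probe_deceased"] = simulate_probe_responses(
            tab, av_z[i], coeffs, seed=int(rng.integers(2 ** 31)),
            random_intercept=ri)
        tab["probe_living"] = rng.random(n_blocks) < 0.3
        tab["probe_self"] = rng.random(n_blocks) < 0.6
        tab["error"] = rng.random(n_blocks) < p_error
        tab.insert(0, "subject_id", rec.subject_id)
        tabs.append(tab)
    blocks = pd.concat(tabs, ignore_index=True)
    blocks.attrs["clinical"] = clinical_table(records)
    return blocks
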