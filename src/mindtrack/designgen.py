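"""Generators for the four fMRI task designs.

Four paradigms feed the pipeline:

* a modified (grief) **Stroop** task indexing deceased-related selective
  attention (d-SA) through colour-naming response times,
* a multimodal **person-representation** task (pictures / stories / think
  blocks for deceased, living-control and demographic-control persons)
  indexing deceased-related mental representation (d-MR),
* a continuous 8-minute **SART** (go/no-go digit task) that promotes
  mindwandering, and
* a blocked **SART-PROBES** variant with three yes/no thought probes
  after each of 16 blocks.

All generators are deterministic given ``(seed, params)`` and emit
BIDS-events-style tables (``onset``, ``duration``, ``trial_type`` plus
task-specific columns).  Onsets are in seconds from the start of the run.
TR bookkeeping uses 1-based indices with half-open intervals: TR ``i``
covers ``[(i-1)*tr, i*tr)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, RangeError

STROOP_CONDITIONS = ("deceased", "living", "congruent", "incongruent")
PERSON_CONDITIONS = ("deceased", "living", "demographic")
PROBE_ORDER = ("deceased", "living", "self")
STROOP_COLORS = ("red", "green", "blue")

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "modality", "rt", "valence",
    "arousal", "block", "probe_deceased", "probe_living", "probe_self",
    "error",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StroopParams:
    n_runs: int = 4
    words_per_block: int = 15
    word_duration: float = 1.5
    iti_mean: float = 2.0
    iti_halfwidth: float = 1.0      # jitter uniform on mean +/- halfwidth
    interblock_fixation: float = 10.0
    initial_fixation: float = 10.0

    def validate(self) -> None:
        for name in ("word_duration", "iti_mean", "interblock_fixation"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.iti_halfwidth < 0 or self.iti_halfwidth >= self.iti_mean:
            raise ParameterError("iti jitter must keep ITIs positive")
        if self.n_runs < 2:
            raise ParameterError("at least two runs are required for run-wise CV")


@dataclass(frozen=True)
class RepParams:
    blocks_per_condition: int = 3
    picture_duration: float = 7.5
    story_line_duration: float = 5.0
    n_story_lines: int = 3
    think_duration: float = 15.0
    modality_fixation: float = 0.5
    rating_probe_duration: float = 4.0
    interblock_fixation: float = 5.0
    initial_fixation: float = 10.0

    def validate(self) -> None:
        for name in ("picture_duration", "story_line_duration", "think_duration",
                     "modality_fixation", "rating_probe_duration"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def block_stim_duration(self) -> float:
        """Stimulus + fixation span of one person block (46.5 s at defaults)."""
        return (2 * self.picture_duration + self.n_story_lines * self.story_line_duration
                + self.think_duration + 3 * self.modality_fixation)


@dataclass(frozen=True)
class SartParams:
    trial_duration: float = 1.5
    iti_mean: float = 2.0
    iti_halfwidth: float = 1.0
    no_go_fraction: float = 0.11
    continuous_duration: float = 480.0          # 8 min of trials
    n_blocks: int = 16
    block_duration_range: tuple[int, int] = (25, 35)
    probe_duration: float = 3.0
    initial_fixation: float = 4.0

    def validate(self) -> None:
        if self.trial_duration <= 0 or self.iti_mean <= 0:
            raise ParameterError("timings must be positive")
        if self.iti_halfwidth < 0 or self.iti_halfwidth >= self.iti_mean:
            raise ParameterError("iti jitter must keep ITIs positive")
        if not 0 < self.no_go_fraction < 0.5:
            raise ParameterError("no_go_fraction must be in (0, 0.5)")


# --------------------------------------------------------------------------
# design containers
# --------------------------------------------------------------------------

@dataclass
class StroopDesign:
    """Event table for the grief Stroop task.

    ``events`` columns: run (1-based), block (1-based within run),
    trial_type, onset, duration, color, rt (NaN until simulated/measured).
    """
    events: pd.DataFrame
    params: StroopParams

    @property
    def run_duration(self) -> float:
        ends = self.events.groupby("run").apply(
            lambda g: g["onset"].iloc[-1] + g["duration"].iloc[-1],
            include_groups=False)
        return float(ends.max()) + self.params.interblock_fixation


@dataclass
class RepresentationDesign:
    """Event table for the person-representation (d-MR) task.

    One fMRI run; blocks of picture/story/think events per person condition
    followed by valence and arousal rating probes (ratings NaN until filled).
    """
    events: pd.DataFrame
    params: RepParams

    @property
    def duration(self) -> float:
        last = self.events.iloc[-1]
        return float(last["onset"] + last["duration"]) + self.params.interblock_fixation


@dataclass
class SartDesign:
    """Go/no-go digit task, continuous or probed variant.

    ``trials``: digit trials (onset, duration, digit, is_no_go, block).
    ``probes``: probe events for the probed variant (block, probe, onset,
    duration), empty otherwise.
    ``blocks``: per-block boundaries (block, t_start, t_end, probe_start,
    probe_end) for the probed variant; single row for continuous.
    """
    variant: str
    trials: pd.DataFrame
    probes: pd.DataFrame
    blocks: pd.DataFrame
    params: SartParams

    @property
    def duration(self) -> float:
        if self.variant == "probed":
            return float(self.blocks["probe_end"].iloc[-1])
        return float(self.trials["onset"].iloc[-1] + self.trials["duration"].iloc[-1])

    @property
    def task_onset(self) -> float:
        return float(self.trials["onset"].iloc[0])


@dataclass(frozen=True)
class TrSchedule:
    """Sampling grid of the acquisition: TR in seconds and volume count."""
    tr: float
    n_volumes: int

    def __post_init__(self):
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.n_volumes < 1:
            raise ParameterError("n_volumes must be >= 1")

    @property
    def duration(self) -> float:
        return self.tr * self.n_volumes


def events_to_tr_index(event_time: float, schedule: TrSchedule) -> int:
    """1-based TR containing ``event_time``; TR i covers [(i-1)*tr, i*tr)."""
    if not 0 <= event_time < schedule.duration:
        raise RangeError(
            f"event time {event_time} outside acquisition [0, {schedule.duration})")
    return int(event_time // schedule.tr) + 1


def schedule_for(duration: float, tr: float = 2.0, pad_trs: int = 8) -> TrSchedule:
    """Schedule covering ``duration`` seconds plus ``pad_trs`` trailing TRs."""
    return TrSchedule(tr=tr, n_volumes=int(np.ceil(duration / tr)) + pad_trs)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _jitters(rng: np.random.Generator, n: int, mean: float, halfwidth: float) -> np.ndarray:
    return rng.uniform(mean - halfwidth, mean + halfwidth, size=n)


def _distinct_permutations(rng: np.random.Generator, n_items: int, n_perms: int) -> list[tuple]:
    """Sample ``n_perms`` pairwise-distinct permutations of range(n_items)."""
    seen: list[tuple] = []
    while len(seen) < n_perms:
        p = tuple(rng.permutation(n_items))
        if p not in seen:
            seen.append(p)
    return seen


def generate_stroop_design(seed: int, params: StroopParams | None = None) -> StroopDesign:
    """Four-run Stroop design: each run holds one block per word condition.

    Block order is a permutation of the four conditions that differs across
    runs; words last 1.5 s with a jittered ITI averaging 2 s; 10 s fixations
    separate blocks.  RTs are left NaN (filled by the simulator or by data).
    """
    params = params or StroopParams()
    params.validate()
    rng = np.random.default_rng(seed)
    orders = _distinct_permutations(rng, len(STROOP_CONDITIONS), params.n_runs)

    rows = []
    for run_i, order in enumerate(orders, start=1):
        t = params.initial_fixation
        for block_i, cond_i in enumerate(order, start=1):
            cond = STROOP_CONDITIONS[cond_i]
            itis = _jitters(rng, params.words_per_block, params.iti_mean,
                            params.iti_halfwidth)
            colors = rng.choice(STROOP_COLORS, size=params.words_per_block)
            for w in range(params.words_per_block):
                rows.append({"run": run_i, "block": block_i, "trial_type": cond,
                             "onset": t, "duration": params.word_duration,
                             "color": colors[w], "rt": np.nan})
                t += params.word_duration + itis[w]
            t += params.interblock_fixation
    events = pd.DataFrame(rows)
    return StroopDesign(events=events, params=params)


def generate_representation_design(seed: int, params: RepParams | None = None
                                   ) -> RepresentationDesign:
    """Person-representation design with picture, story and think modalities.

    Blocks cycle through the person conditions in a random order without
    immediate repeats; within each condition the three stories are assigned
    so that no story repeats between consecutive blocks of the same person.
    Each block spans exactly ``params.block_stim_duration`` seconds of
    stimulus + fixation (46.5 s at defaults) and is followed by valence and
    arousal rating probes.
    """
    params = params or RepParams()
    params.validate()
    rng = np.random.default_rng(seed)

    n_cond = len(PERSON_CONDITIONS)
    # condition sequence: shuffled batches with no repeat across the seam
    seq: list[str] = []
    for _ in range(params.blocks_per_condition):
        batch = list(rng.permutation(n_cond))
        while seq and batch[0] == seq[-1]:
            batch = list(rng.permutation(n_cond))
        seq.extend(batch)
    # cyclic story assignment with a random per-condition offset: each story
    # appears once per condition and consecutive same-person blocks differ
    offsets = {c: int(rng.integers(3)) for c in range(n_cond)}
    story_counter = {c: 0 for c in range(n_cond)}

    rows = []
    t = params.initial_fixation
    for block_i, cond_i in enumerate(seq, start=1):
        cond = PERSON_CONDITIONS[cond_i]
        story_id = (story_counter[cond_i] + offsets[cond_i]) % 3 + 1
        story_counter[cond_i] += 1
        t0 = t
        for _ in range(2):
            rows.append({"block": block_i, "trial_type": cond, "modality": "picture",
                         "onset": t, "duration": params.picture_duration,
                         "story_id": np.nan, "valence": np.nan, "arousal": np.nan})
            t += params.picture_duration
        t += params.modality_fixation
        for _ in range(params.n_story_lines):
            rows.append({"block": block_i, "trial_type": cond, "modality": "story",
                         "onset": t, "duration": params.story_line_duration,
                         "story_id": story_id, "valence": np.nan, "arousal": np.nan})
            t += params.story_line_duration
        t += params.modality_fixation
        rows.append({"block": block_i, "trial_type": cond, "modality": "think",
                     "onset": t, "duration": params.think_duration,
                     "story_id": np.nan, "valence": np.nan, "arousal": np.nan})
        t += params.think_duration + params.modality_fixation
        assert abs((t - t0) - params.block_stim_duration) < 1e-9
        for probe in ("valence", "arousal"):
            rows.append({"block": block_i, "trial_type": cond,
                         "modality": f"probe_{probe}", "onset": t,
                         "duration": params.rating_probe_duration,
                         "story_id": np.nan, "valence": np.nan, "arousal": np.nan})
            t += params.rating_probe_duration
        t += params.interblock_fixation
    return RepresentationDesign(events=pd.DataFrame(rows), params=params)


def _place_no_go(rng: np.random.Generator, n_trials: int, n_no_go: int) -> np.ndarray:
    """Random no-go positions, no two consecutive."""
    if n_no_go > (n_trials + 1) // 2:
        raise ParameterError("cannot place that many non-adjacent no-go trials")
    while True:
        pos = np.sort(rng.choice(n_trials, size=n_no_go, replace=False))
        if n_no_go < 2 or np.all(np.diff(pos) > 1):
            mask = np.zeros(n_trials, dtype=bool)
            mask[pos] = True
            return mask


def _digits(rng: np.random.Generator, no_go: np.ndarray) -> np.ndarray:
    go_digits = np.array([d for d in range(10) if d != 3])
    digits = rng.choice(go_digits, size=no_go.size)
    digits[no_go] = 3
    return digits


def generate_sart_design(seed: int, variant: str = "probed",
                         params: SartParams | None = None) -> SartDesign:
    """SART design: continuous (8 min of trials) or probed (16 blocks).

    11% of trials show the no-go digit 3, placed at random with no two
    consecutive no-go trials.  In the probed variant every block is followed
    by three yes/no thought probes in fixed order (deceased, living, self)
    whose period boundaries are recorded explicitly in ``blocks``.
    """
    params = params or SartParams()
    params.validate()
    if variant not in ("continuous", "probed"):
        raise ParameterError(f"unknown SART variant {variant!r}")
    rng = np.random.default_rng(seed)

    def fill_trials(t_start: float, span: float) -> tuple[list[float], float]:
        onsets, t = [], t_start
        while t + params.trial_duration <= t_start + span:
            onsets.append(t)
            t += params.trial_duration + float(
                _jitters(rng, 1, params.iti_mean, params.iti_halfwidth)[0])
        return onsets, t

    if variant == "continuous":
        onsets, _ = fill_trials(params.initial_fixation, params.continuous_duration)
        onsets = np.asarray(onsets)
        n = onsets.size
        no_go = _place_no_go(rng, n, int(round(params.no_go_fraction * n)))
        trials = pd.DataFrame({"onset": onsets, "duration": params.trial_duration,
                               "digit": _digits(rng, no_go), "is_no_go": no_go,
                               "block": 1})
        blocks = pd.DataFrame({"block": [1], "t_start": [onsets[0]],
                               "t_end": [onsets[-1] + params.trial_duration],
                               "probe_start": [np.nan], "probe_end": [np.nan]})
        return SartDesign(variant=variant, trials=trials, probes=pd.DataFrame(),
                          blocks=blocks, params=params)

    lo, hi = params.block_duration_range
    trial_rows, probe_rows, block_rows = [], [], []
    t = params.initial_fixation
    for b in range(1, params.n_blocks + 1):
        span = float(rng.integers(lo, hi + 1))
        onsets, _ = fill_trials(t, span)
        onsets = np.asarray(onsets)
        no_go = _place_no_go(rng, onsets.size,
                             int(round(params.no_go_fraction * onsets.size)))
        digits = _digits(rng, no_go)
        for o, d, g in zip(onsets, digits, no_go):
            trial_rows.append({"onset": o, "duration": params.trial_duration,
                               "digit": d, "is_no_go": g, "block": b})
        # block spans exactly the drawn duration; time after the last whole
        # trial is fixation, then the probe period begins
        t_end = t + span
        probe_start = t_end
        tp = probe_start
        for probe in PROBE_ORDER:
            probe_rows.append({"block": b, "probe": probe, "onset": tp,
                               "duration": params.probe_duration})
            tp += params.probe_duration
        block_rows.append({"block": b, "t_start": float(onsets[0]), "t_end": t_end,
                           "probe_start": probe_start, "probe_end": tp})
        t = tp + 1.0      # 1 s gap before next block's first trial
    return SartDesign(variant=variant, trials=pd.DataFrame(trial_rows),
                      probes=pd.DataFrame(probe_rows),
                      blocks=pd.DataFrame(block_rows), params=params)


# --------------------------------------------------------------------------
# averaging windows (hemodynamic-delay bookkeeping)
# --------------------------------------------------------------------------

def _last_tr_overlapping(t: float, schedule: TrSchedule) -> int:
    """1-based index of the last TR overlapping an interval ending at ``t``."""
    return max(1, int(np.ceil(t / schedule.tr)))


def block_windows(design: SartDesign, schedule: TrSchedule,
                  hrf_offset: int = 4, tail: int = 2) -> list[tuple[int, int]]:
    """Per-block TR windows for the probed SART (1-based, inclusive).

    Block k is averaged from ``hrf_offset`` TRs after the end of the previous
    probe period through ``tail`` TRs into its own probe period; the window
    preceding block 1 is anchored at the TR containing the first trial onset.
    The 4-TR lead compensates the hemodynamic delay.  Windows are clipped to
    the acquisition.
    """
    if design.variant != "probed":
        raise ParameterError("block windows require the probed variant")
    prev_end = events_to_tr_index(design.task_onset, schedule)
    windows = []
    for _, row in design.blocks.iterrows():
        end_tr = _last_tr_overlapping(row["probe_end"], schedule)
        lo = max(1, prev_end + hrf_offset)
        hi = min(schedule.n_volumes, end_tr + tail)
        windows.append((lo, hi))
        prev_end = end_tr
    return windows


def task_window(design: SartDesign, schedule: TrSchedule,
                hrf_offset: int = 4, tail: int = 2) -> tuple[int, int]:
    """Whole-task TR window for the continuous SART (1-based, inclusive)."""
    start_tr = events_to_tr_index(design.task_onset, schedule)
    end_tr = _last_tr_overlapping(design.duration, schedule)
    return (max(1, start_tr + hrf_offset), min(schedule.n_volumes, end_tr + tail))


# --------------------------------------------------------------------------
# event-table export
# --------------------------------------------------------------------------

def _standard_table(rows: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=rows.index, columns=EVENT_COLUMNS, dtype=object)
    for col in EVENT_COLUMNS:
        if col in rows.columns:
            out[col] = rows[col]
    out["onset"] = rows["onset"].astype(float)
    out["duration"] = rows["duration"].astype(float)
    return out


def design_events_table(design) -> pd.DataFrame:
    """Standard-column event table (onset, duration, trial_type, ...) for any design."""
    if isinstance(design, StroopDesign):
        rows = design.events.copy()
        rows["modality"] = "word"
        return _standard_table(rows)
    if isinstance(design, RepresentationDesign):
        return _standard_table(design.events)
    if isinstance(design, SartDesign):
        trials = design.trials.copy()
        trials["trial_type"] = np.where(trials["is_no_go"], "no_go", "go")
        trials["modality"] = "digit"
        parts = [trials]
        if len(design.probes):
            probes = design.probes.copy()
            probes["trial_type"] = "probe_" + probes["probe"]
            probes["modality"] = "probe"
            parts.append(probes)
        rows = pd.concat(parts, ignore_index=True).sort_values("onset")
        return _standard_table(rows.reset_index(drop=True))
    raise TypeError(f"unknown design type {type(design).__name__}")


def write_events_tsv(design, path) -> None:
    design_events_table(design).to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])
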