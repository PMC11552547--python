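"""Session/trial data model, condition labeling, trial selection, and HDF5 I/O.

The experiment is a cued orientation-change detection task recorded with
bilateral microelectrode arrays in area V4.  Two counterphasing Gabor stimuli
(one per hemifield) are shown; at a random time one of them changes
orientation (the target) and the animal is rewarded for a prompt saccade to
it.  Trials are characterised by the cue type (valid / neutral / invalid),
which side was cued or where the target appeared, and the behavioral outcome
(hit / miss).  Each electrode's receptive field lies in one hemifield, so a
given trial is "attend-in" for one array and "attend-out" for the other.

All analyses are target-locked: the window of interest is the 500 ms
immediately preceding target onset, [-500, 0) ms, which at the 2 kHz sampling
rate is exactly 1000 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger("lfpdisc")

SAMPLING_RATE_HZ = 2000
SCHEMA_VERSION = 1

#: Analysis window relative to target onset, half-open [start, end) in ms.
WINDOW_START_MS = -500
WINDOW_END_MS = 0
WINDOW_N_SAMPLES = 1000

CUE_TYPES = ("valid", "neutral", "invalid")
SIDES = ("left", "right")

#: The eight analysis conditions.  Valid-cue trials are labeled by the cued
#: side relative to the electrode's receptive field (Attend-In / Attend-Out);
#: neutral-cue trials by the side where the target eventually appeared
#: (Target-In / Target-Out); both crossed with hit / miss.
CONDITIONS = ("AIVH", "AOVH", "AIVM", "AOVM", "TINH", "TONH", "TINM", "TONM")

VALID_CONDITIONS = ("AIVH", "AOVH", "AIVM", "AOVM")
NEUTRAL_CONDITIONS = ("TINH", "TONH", "TINM", "TONM")


class ExcludedConditionError(ValueError):
    """Raised when a trial cannot be assigned to an analysis condition."""


class SchemaError(IOError):
    """Raised when an HDF5 session file does not match the expected layout."""


@dataclass
class TrialInfo:
    """Per-trial task variables.

    ``target_onset_ms`` is the target (orientation change) time measured from
    stimulus onset; for non-catch trials it lies in [500, 5500].
    ``change_rank`` orders the six orientation-change magnitudes from 1
    (smallest) to 6.
    """

    cue_type: str
    cue_side: str
    target_side: str
    outcome: str
    target_onset_ms: float
    change_rank: int
    is_instruction: bool = False
    is_catch: bool = False

    def __post_init__(self) -> None:
        if self.cue_type not in CUE_TYPES:
            raise ValueError(f"unknown cue_type {self.cue_type!r}")
        if (self.cue_type == "neutral") != (self.cue_side == "both"):
            raise ValueError("cue_side must be 'both' iff cue_type is 'neutral'")
        if not self.is_catch and not 500 <= self.target_onset_ms <= 5500:
            raise ValueError(
                f"target_onset_ms {self.target_onset_ms} outside [500, 5500]"
            )


@dataclass
class SessionRecording:
    """One recording session: LFP tensor, spike trains, and trial metadata.

    lfp
        float32 array, trials x electrodes x samples, in microvolts, sampled
        at 2 kHz.  By convention the stored samples are the pretarget window
        [-500, 0) ms of each trial.
    spikes
        ``spikes[t][e]`` is a float64 array of spike times in ms relative to
        target onset for trial ``t``, electrode ``e``.
    electrode_rf_side
        Hemifield ('left'/'right') containing each electrode's receptive
        field.  Electrodes implanted in the left hemisphere have right
        hemifield RFs and vice versa.
    """

    lfp: np.ndarray
    spikes: list
    electrode_rf_side: list
    trials: list
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        if self.lfp.ndim != 3:
            raise ValueError("lfp must be trials x electrodes x samples")
        n_trials, n_elec, _ = self.lfp.shape
        if len(self.trials) != n_trials:
            raise ValueError("trial metadata count does not match lfp")
        if len(self.spikes) != n_trials:
            raise ValueError("spikes must have one entry per trial")
        if len(self.electrode_rf_side) != n_elec:
            raise ValueError("electrode_rf_side length must match electrodes")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.lfp.shape[1]

    def electrodes_with_rf(self, side: str) -> np.ndarray:
        """Indices of electrodes whose receptive field is in ``side`` hemifield."""
        return np.flatnonzero(np.asarray(self.electrode_rf_side) == side)


# ---------------------------------------------------------------------------
# Condition labeling and trial selection
# ---------------------------------------------------------------------------

def label_condition(trial: TrialInfo, rf_side: str) -> str:
    """Assign a trial to one of the eight analysis conditions.

    Valid-cue trials are labeled by cue side relative to ``rf_side`` (the
    electrode's receptive-field hemifield) plus outcome; neutral-cue trials by
    target side relative to ``rf_side`` plus outcome.  Invalid-cue,
    instruction, and catch trials are not analyzed and raise
    :class:`ExcludedConditionError`.
    """
    if rf_side not in SIDES:
        raise ValueError(f"rf_side must be one of {SIDES}")
    if trial.is_instruction or trial.is_catch:
        raise ExcludedConditionError("instruction/catch trials are excluded")
    if trial.cue_type == "invalid":
        raise ExcludedConditionError("invalidly cued trials are excluded")
    outcome_code = {"hit": "H", "miss": "M"}[trial.outcome]
    if trial.cue_type == "valid":
        in_out = "I" if trial.cue_side == rf_side else "O"
        return f"A{in_out}V{outcome_code}"
    # neutral: label by where the target appeared
    in_out = "I" if trial.target_side == rf_side else "O"
    return f"T{in_out}N{outcome_code}"


def select_analysis_trials(
    session: SessionRecording,
    rf_side: str,
    change_ranks: tuple = (2, 3),
    min_trials: int = 10,
) -> dict:
    """Per-condition trial index sets for one array (one RF side).

    Drops instruction, catch, and invalid-cue trials; keeps only the stated
    orientation-change ranks (second and third smallest by default, where
    behavioral performance is near 50%).  A cue type (valid or neutral) is
    retained only if all four of its conditions have strictly more than
    ``min_trials`` trials; otherwise that cue type is excluded entirely for
    the session.
    """
    by_condition: dict = {c: [] for c in CONDITIONS}
    for idx, trial in enumerate(session.trials):
        if trial.is_instruction or trial.is_catch:
            continue
        if trial.change_rank not in change_ranks:
            continue
        try:
            cond = label_condition(trial, rf_side)
        except ExcludedConditionError:
            continue
        by_condition[cond].append(idx)

    result: dict = {}
    for cue_conditions in (VALID_CONDITIONS, NEUTRAL_CONDITIONS):
        counts = {c: len(by_condition[c]) for c in cue_conditions}
        if all(n > min_trials for n in counts.values()):
            for c in cue_conditions:
                result[c] = np.asarray(sorted(by_condition[c]), dtype=np.intp)
        else:
            logger.info(
                "cue type of conditions %s excluded (counts %s, need >%d each)",
                cue_conditions, counts, min_trials,
            )
    if session.n_trials == 0:
        logger.warning("empty session: no analysis trials selected")
    return result


def extract_pretarget_segment(
    lfp_trial: np.ndarray,
    target_onset_ms: float,
    trace_start_ms: float = 0.0,
    fs: float = SAMPLING_RATE_HZ,
) -> np.ndarray:
    """Slice the [-500, 0) ms pretarget window out of a longer LFP trace.

    ``lfp_trial`` may be 1-D (samples) or 2-D (electrodes x samples) with the
    first sample at ``trace_start_ms`` relative to stimulus onset.  Returns
    exactly 1000 samples (at 2 kHz); raises if the trace does not cover the
    window.  No detrending or re-referencing is applied.
    """
    onset_idx = int(round((target_onset_ms - trace_start_ms) * fs / 1000.0))
    start = onset_idx - WINDOW_N_SAMPLES
    if start < 0 or onset_idx > lfp_trial.shape[-1]:
        raise ValueError(
            "trial does not contain the full [-500, 0) ms pretarget window "
            f"(need samples [{start}, {onset_idx}) of {lfp_trial.shape[-1]})"
        )
    return lfp_trial[..., start:onset_idx]


# ---------------------------------------------------------------------------
# HDF5 session I/O
# ---------------------------------------------------------------------------

_TRIAL_DTYPE = np.dtype([
    ("cue_type", "S8"),
    ("cue_side", "S8"),
    ("target_side", "S8"),
    ("outcome", "S8"),
    ("target_onset_ms", "f8"),
    ("change_rank", "i8"),
    ("is_instruction", "i1"),
    ("is_catch", "i1"),
])


def save_session(session: SessionRecording, path) -> None:
    """Write a session to HDF5.

    Layout: ``/lfp`` (float32, trials x electrodes x samples),
    ``/spikes/trial{t}/elec{e}`` (float64 ms relative to target onset),
    ``/trials`` (structured table), ``/meta`` attributes
    (``sampling_rate_hz``, ``electrode_rf_side``, ``schema_version``).
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp.astype(np.float32))
        spikes_grp = f.create_group("spikes")
        for t, per_elec in enumerate(session.spikes):
            tg = spikes_grp.create_group(f"trial{t}")
            for e, times in enumerate(per_elec):
                tg.create_dataset(f"elec{e}", data=np.asarray(times, dtype=np.float64))
        table = np.empty(len(session.trials), dtype=_TRIAL_DTYPE)
        for i, tr in enumerate(session.trials):
            table[i] = (
                tr.cue_type.encode(), tr.cue_side.encode(),
                tr.target_side.encode(), tr.outcome.encode(),
                tr.target_onset_ms, tr.change_rank,
                int(tr.is_instruction), int(tr.is_catch),
            )
        f.create_dataset("trials", data=table)
        meta = f.create_group("meta")
        meta.attrs["sampling_rate_hz"] = float(session.sampling_rate_hz)
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["electrode_rf_side"] = [s.encode() for s in session.electrode_rf_side]


def load_session(path) -> SessionRecording:
    """Read a session written by :func:`save_session`; validates the schema."""
    with h5py.File(path, "r") as f:
        if "meta" not in f or "schema_version" not in f["meta"].attrs:
            raise SchemaError(
                "meta group with schema_version attribute required "
                "(expected layout: /lfp, /spikes, /trials, /meta)"
            )
        version = int(f["meta"].attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {version} not supported; expected "
                f"{SCHEMA_VERSION} with layout /lfp (trials x electrodes x "
                "samples), /spikes/trial{t}/elec{e}, /trials, /meta"
            )
        if "spikes" not in f:
            raise SchemaError("spikes group required")
        if "lfp" not in f or "trials" not in f:
            raise SchemaError("lfp dataset and trials table required")
        lfp = f["lfp"][()]
        table = f["trials"][()]
        trials = [
            TrialInfo(
                cue_type=row["cue_type"].decode(),
                cue_side=row["cue_side"].decode(),
                target_side=row["target_side"].decode(),
                outcome=row["outcome"].decode(),
                target_onset_ms=float(row["target_onset_ms"]),
                change_rank=int(row["change_rank"]),
                is_instruction=bool(row["is_instruction"]),
                is_catch=bool(row["is_catch"]),
            )
            for row in table
        ]
        spikes = []
        spikes_grp = f["spikes"]
        n_elec = lfp.shape[1]
        for t in range(lfp.shape[0]):
            tg = spikes_grp[f"trial{t}"]
            spikes.append([tg[f"elec{e}"][()] for e in range(n_elec)])
        rf_side = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["meta"].attrs["electrode_rf_side"]]
        fs = float(f["meta"].attrs["sampling_rate_hz"])
    return SessionRecording(
        lfp=lfp, spikes=spikes, electrode_rf_side=rf_side, trials=trials,
        sampling_rate_hz=fs,
    )
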