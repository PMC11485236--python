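"""Session data model, on-disk format, and firing-rate matrix construction.

A recording session couples sorted spike trains (one per neuron, seconds
from session start) with a trial table describing an odour block of
16 stimuli x 8 presentation cycles (stimulus 0 is the odourless control)
and, optionally, a matched 16-image x 8 visual block.

Time conventions used throughout the package:

* all times are in seconds,
* analysis windows are half-open ``[start, end)`` relative to trial onset,
* trial indices are 0-based and presentation cycles run 1..8.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("PC", "AMY", "EC", "HIP", "PHC")
MODALITIES = ("odour", "image")
PHASES = ("rating", "identification", "visual")
RATINGS = ("liked", "disliked")

N_STIMULI = 16
N_CYCLES = 8
CONTROL_STIMULUS = 0

FORMAT_VERSION = "1.0"

_NA = "NA"


class SessionFormatError(ValueError):
    """Raised when session files are missing or malformed."""


class SessionValidationError(ValueError):
    """Raised when a session violates a structural invariant."""


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time window ``[start_s, end_s)`` relative to trial onset."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"window end {self.end_s} must exceed start {self.start_s}")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


# Default analysis windows: response vs pre-onset baseline.
ODOUR_RESPONSE_WINDOW = TimeWindow(0.0, 2.0)
ODOUR_BASELINE_WINDOW = TimeWindow(-5.0, 0.0)
IMAGE_RESPONSE_WINDOW = TimeWindow(0.0, 1.0)
IMAGE_BASELINE_WINDOW = TimeWindow(-0.5, 0.0)


@dataclass
class NeuronRecord:
    neuron_id: str
    region: str
    spike_times: np.ndarray  # seconds from session start, sorted ascending

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)


@dataclass
class TrialRecord:
    trial_idx: int
    modality: str  # 'odour' | 'image'
    stimulus_id: int  # 0..15; 0 = odourless control / grey screen
    onset_s: float
    presentation_cycle: int  # 1..8
    phase: str  # 'rating' | 'identification' | 'visual'
    rating: str | None = None  # 'liked' | 'disliked'
    chosen_stimulus_id: int | None = None
    correct: bool | None = None


@dataclass
class SessionData:
    session_id: str
    participant_id: str
    neurons: list[NeuronRecord]
    trials: list[TrialRecord]
    ground_truth: dict | None = None

    # ---- convenience accessors -------------------------------------------------

    def neuron(self, neuron_id: str) -> NeuronRecord:
        for n in self.neurons:
            if n.neuron_id == neuron_id:
                return n
        raise KeyError(neuron_id)

    def neurons_in_region(self, region: str) -> list[NeuronRecord]:
        return [n for n in self.neurons if n.region == region]

    def odour_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.modality == "odour"]

    def image_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.modality == "image"]

    @property
    def has_image_block(self) -> bool:
        return any(t.modality == "image" for t in self.trials)

    @property
    def has_control_stimulus(self) -> bool:
        return any(
            t.stimulus_id == CONTROL_STIMULUS for t in self.odour_trials()
        )

    def trial_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])


@dataclass
class RateMatrix:
    """Neurons x trials firing rates for a named window.

    ``values[i, j]`` is the rate of neuron ``neuron_ids[i]`` on trial
    ``trial_idxs[j]`` — spikes per second if ``normalization == 'raw'``,
    a dimensionless baseline z-score if ``normalization == 'zscored'``.
    """

    values: np.ndarray
    window: TimeWindow
    normalization: str  # 'raw' | 'zscored'
    neuron_ids: list[str]
    trial_idxs: list[int]
    baseline_window: TimeWindow | None = None
    excluded_neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.neuron_ids), len(self.trial_idxs)):
            raise ValueError("rate matrix shape inconsistent with id lists")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_trials(self) -> int:
        return len(self.trial_idxs)

    def subset_neurons(self, neuron_ids: Sequence[str]) -> "RateMatrix":
        index = {nid: i for i, nid in enumerate(self.neuron_ids)}
        rows = [index[nid] for nid in neuron_ids]
        return RateMatrix(
            values=self.values[rows, :],
            window=self.window,
            normalization=self.normalization,
            neuron_ids=list(neuron_ids),
            trial_idxs=list(self.trial_idxs),
            baseline_window=self.baseline_window,
            excluded_neuron_ids=list(self.excluded_neuron_ids),
        )


@dataclass(frozen=True)
class Violation:
    code: str
    message: str


# ---------------------------------------------------------------------------
# Rate computation
# ---------------------------------------------------------------------------


def window_spike_counts(
    spike_times: np.ndarray, onsets: np.ndarray, window: TimeWindow
) -> np.ndarray:
    """Spike counts per trial in the half-open window [onset+start, onset+end).

    Spikes exactly at the end boundary are excluded (half-open rule).
    """
    onsets = np.asarray(onsets, dtype=float)
    lo = np.searchsorted(spike_times, onsets + window.start_s, side="left")
    hi = np.searchsorted(spike_times, onsets + window.end_s, side="left")
    return (hi - lo).astype(float)


def compute_rate_matrix(
    session: SessionData,
    trials: Sequence[TrialRecord] | None = None,
    window: TimeWindow = ODOUR_RESPONSE_WINDOW,
    normalization: str = "raw",
    baseline: TimeWindow | None = None,
    neurons: Sequence[NeuronRecord] | None = None,
    sd_ddof: int = 1,
) -> RateMatrix:
    """Build a neurons x trials rate matrix.

    ``raw``: spike count in the window divided by window length (Hz).

    ``zscored``: each trial's response rate is normalised per neuron as
    ``z_t = (r_t - mu_b) / sigma_b`` where ``mu_b`` and ``sigma_b`` are the
    mean and sample standard deviation (``ddof=sd_ddof``) of the per-trial
    baseline-window rates across the selected trials.  Neurons whose
    baseline rates have zero variance are excluded from the output (their
    ids are recorded in ``excluded_neuron_ids`` and a warning is logged).
    """
    if normalization not in ("raw", "zscored"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "zscored" and baseline is None:
        raise ValueError("zscored normalization requires a baseline window")
    if trials is None:
        trials = session.odour_trials()
    if neurons is None:
        neurons = session.neurons
    onsets = np.array([t.onset_s for t in trials], dtype=float)
    trial_idxs = [t.trial_idx for t in trials]

    rows = []
    for neuron in neurons:
        counts = window_spike_counts(neuron.spike_times, onsets, window)
        rows.append(counts / window.length_s)
    rates = np.array(rows, dtype=float).reshape(len(neurons), len(trials))

    if normalization == "raw":
        return RateMatrix(
            values=rates,
            window=window,
            normalization="raw",
            neuron_ids=[n.neuron_id for n in neurons],
            trial_idxs=trial_idxs,
            baseline_window=baseline,
        )

    base_rows = []
    for neuron in neurons:
        counts = window_spike_counts(neuron.spike_times, onsets, baseline)
        base_rows.append(counts / baseline.length_s)
    base = np.array(base_rows, dtype=float).reshape(len(neurons), len(trials))

    mu = base.mean(axis=1)
    sigma = base.std(axis=1, ddof=sd_ddof)
    keep = sigma > 0
    excluded = [n.neuron_id for n, k in zip(neurons, keep) if not k]
    if excluded:
        logger.warning(
            "excluding %d neuron(s) with zero baseline variance: %s",
            len(excluded),
            ", ".join(excluded[:10]),
        )
    z = (rates[keep] - mu[keep, None]) / sigma[keep, None]
    return RateMatrix(
        values=z,
        window=window,
        normalization="zscored",
        neuron_ids=[n.neuron_id for n, k in zip(neurons, keep) if k],
        trial_idxs=trial_idxs,
        baseline_window=baseline,
        excluded_neuron_ids=excluded,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_session(session: SessionData) -> list[Violation]:
    """Check structural invariants; returns an empty list iff all hold."""
    out: list[Violation] = []

    neuron_ids = [n.neuron_id for n in session.neurons]
    if len(set(neuron_ids)) != len(neuron_ids):
        out.append(Violation("DUPLICATE_NEURON_ID", "neuron_id values not unique"))
    for n in session.neurons:
        if n.region not in REGIONS:
            out.append(
                Violation("UNKNOWN_REGION", f"neuron {n.neuron_id}: region {n.region!r}")
            )
        if n.spike_times.size and not np.all(np.isfinite(n.spike_times)):
            out.append(
                Violation("NONFINITE_SPIKE_TIME", f"neuron {n.neuron_id}")
            )
            continue
        if n.spike_times.size and n.spike_times.min() < 0:
            out.append(
                Violation(
                    "NEGATIVE_SPIKE_TIME",
                    f"neuron {n.neuron_id}: min spike time {n.spike_times.min():g}",
                )
            )
        if n.spike_times.size > 1 and np.any(np.diff(n.spike_times) < 0):
            out.append(
                Violation("UNSORTED_SPIKE_TIMES", f"neuron {n.neuron_id}")
            )

    idxs = [t.trial_idx for t in session.trials]
    if len(set(idxs)) != len(idxs):
        out.append(Violation("DUPLICATE_TRIAL_IDX", "trial_idx values not unique"))

    for t in session.trials:
        if t.modality not in MODALITIES:
            out.append(Violation("UNKNOWN_MODALITY", f"trial {t.trial_idx}"))
        if not (0 <= t.stimulus_id < N_STIMULI):
            out.append(Violation("STIMULUS_ID_RANGE", f"trial {t.trial_idx}"))
        if not (1 <= t.presentation_cycle <= N_CYCLES):
            out.append(Violation("CYCLE_RANGE", f"trial {t.trial_idx}"))
        if t.phase not in PHASES:
            out.append(Violation("UNKNOWN_PHASE", f"trial {t.trial_idx}"))
        if t.phase == "rating" and t.rating not in RATINGS:
            out.append(
                Violation("MISSING_RATING", f"trial {t.trial_idx}: rating phase without rating")
            )
        if t.phase == "identification":
            if t.chosen_stimulus_id is None:
                out.append(
                    Violation(
                        "MISSING_CHOICE",
                        f"trial {t.trial_idx}: identification phase without chosen_stimulus_id",
                    )
                )
            elif t.correct is None or t.correct != (t.chosen_stimulus_id == t.stimulus_id):
                out.append(
                    Violation("INCONSISTENT_CORRECT", f"trial {t.trial_idx}")
                )

    for modality in MODALITIES:
        block = [t for t in session.trials if t.modality == modality]
        if not block:
            continue
        counts: dict[int, int] = {}
        for t in block:
            counts[t.stimulus_id] = counts.get(t.stimulus_id, 0) + 1
        # The odourless control may be absent; every presented stimulus
        # must appear exactly once per presentation cycle.
        bad = {s: c for s, c in counts.items() if c != N_CYCLES}
        if bad:
            out.append(
                Violation(
                    "UNBALANCED_BLOCK",
                    f"{modality} block: stimulus counts != {N_CYCLES}: {bad}",
                )
            )
        n_stim = len(counts)
        if n_stim not in (N_STIMULI, N_STIMULI - 1):
            out.append(
                Violation(
                    "STIMULUS_SET_SIZE",
                    f"{modality} block has {n_stim} distinct stimuli",
                )
            )
        onsets = [t.onset_s for t in sorted(block, key=lambda t: t.trial_idx)]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            out.append(
                Violation("NON_INCREASING_ONSETS", f"{modality} block onsets not strictly increasing")
            )

    return out


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_idx",
    "modality",
    "stimulus_id",
    "onset_s",
    "presentation_cycle",
    "phase",
    "rating",
    "chosen_stimulus_id",
    "correct",
]


def _fmt(x) -> str:
    if x is None:
        return _NA
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return repr(float(x))
    return str(x)


def write_session(session: SessionData, path: str | Path) -> None:
    """Write a session as neurons.tsv / spikes.tsv / trials.tsv / session.json.

    The format round-trips exactly: ``write -> read -> write`` produces
    byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "neurons.tsv", "w") as fh:
        fh.write("neuron_id\tregion\tn_spikes\n")
        for n in session.neurons:
            fh.write(f"{n.neuron_id}\t{n.region}\t{n.spike_times.size}\n")

    with open(path / "spikes.tsv", "w") as fh:
        fh.write("neuron_id\tspike_time_s\n")
        for n in session.neurons:
            for t in n.spike_times:
                fh.write(f"{n.neuron_id}\t{float(t)!r}\n")

    with open(path / "trials.tsv", "w") as fh:
        fh.write("\t".join(_TRIAL_COLUMNS) + "\n")
        for t in sorted(session.trials, key=lambda t: t.trial_idx):
            fh.write(
                "\t".join(
                    _fmt(getattr(t, col)) for col in _TRIAL_COLUMNS
                )
                + "\n"
            )

    meta = {
        "session_id": session.session_id,
        "participant_id": session.participant_id,
        "format_version": FORMAT_VERSION,
    }
    if session.ground_truth is not None:
        meta["ground_truth"] = session.ground_truth
    with open(path / "session.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _parse_optional_int(x: str) -> int | None:
    return None if x == _NA else int(x)


def _parse_optional_bool(x: str) -> bool | None:
    if x == _NA:
        return None
    if x not in ("true", "false"):
        raise SessionFormatError(f"bad boolean value {x!r}")
    return x == "true"


def read_session(path: str | Path) -> SessionData:
    """Read a session directory written by :func:`write_session`.

    Unknown columns are ignored with a logged warning; invariant violations
    raise :class:`SessionValidationError` naming the offending row.
    """
    path = Path(path)
    for fname in ("neurons.tsv", "spikes.tsv", "trials.tsv", "session.json"):
        if not (path / fname).exists():
            raise SessionFormatError(f"missing required file {fname} in {path}")

    with open(path / "session.json") as fh:
        meta = json.load(fh)

    neurons_df = pd.read_csv(path / "neurons.tsv", sep="\t", dtype=str)
    spikes_df = pd.read_csv(
        path / "spikes.tsv",
        sep="\t",
        dtype={"neuron_id": str, "spike_time_s": float},
        float_precision="round_trip",
    )
    trials_df = pd.read_csv(path / "trials.tsv", sep="\t", dtype=str, keep_default_na=False)

    for name, df, expected in (
        ("neurons.tsv", neurons_df, ["neuron_id", "region", "n_spikes"]),
        ("trials.tsv", trials_df, _TRIAL_COLUMNS),
    ):
        extra = [c for c in df.columns if c not in expected]
        if extra:
            logger.warning("%s: ignoring unknown columns %s", name, extra)
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise SessionFormatError(f"{name}: missing columns {missing}")

    spikes_by_neuron = {
        nid: grp["spike_time_s"].to_numpy()
        for nid, grp in spikes_df.groupby("neuron_id", sort=False)
    }
    known_ids = set(neurons_df["neuron_id"])
    orphans = set(spikes_by_neuron) - known_ids
    if orphans:
        raise SessionValidationError(
            f"spikes.tsv references unknown neuron_id(s): {sorted(orphans)[:5]}"
        )

    neurons = []
    for _, row in neurons_df.iterrows():
        st = spikes_by_neuron.get(row["neuron_id"], np.empty(0))
        if st.size != int(row["n_spikes"]):
            raise SessionValidationError(
                f"neuron {row['neuron_id']}: n_spikes={row['n_spikes']} but "
                f"{st.size} spikes found"
            )
        neurons.append(
            NeuronRecord(row["neuron_id"], row["region"], st)
        )

    trials = []
    for _, row in trials_df.iterrows():
        trials.append(
            TrialRecord(
                trial_idx=int(row["trial_idx"]),
                modality=row["modality"],
                stimulus_id=int(row["stimulus_id"]),
                onset_s=float(row["onset_s"]),
                presentation_cycle=int(row["presentation_cycle"]),
                phase=row["phase"],
                rating=None if row["rating"] == _NA else row["rating"],
                chosen_stimulus_id=_parse_optional_int(row["chosen_stimulus_id"]),
                correct=_parse_optional_bool(row["correct"]),
            )
        )

    session = SessionData(
        session_id=meta["session_id"],
        participant_id=meta["participant_id"],
        neurons=neurons,
        trials=trials,
        ground_truth=meta.get("ground_truth"),
    )
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(
            "; ".join(f"{v.code}: {v.message}" for v in violations[:5])
        )
    return session
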