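"""Seeded synthetic recording sessions with known ground truth.

The generator emulates the statistical structure of a human
piriform-cortex / medial-temporal-lobe odour session: an odour block of
16 stimuli (15 odours + 1 odourless control) x 8 presentation cycles in
pseudorandom order, an optional matched visual block, region-specific
fractions of stimulus-tuned neurons, multiplicative repetition
suppression, valence-modulated gain in the amygdala, and like/dislike
ratings plus 4-alternative identification choices.

Each neuron is an inhomogeneous Poisson process with a piecewise-constant
rate: a log-normal baseline, stepping to a response plateau between
``latency`` and ``latency + duration`` after the onset of a preferred
stimulus.  On presentation cycle ``c`` of a preferred odour the plateau is

    baseline * (1 + gain * v_mod) * d**(c - 1)

with ``v_mod = 1 + beta_v * v_k`` for amygdala neurons (``v_k`` the
odour's valence score in [-1, 1]) and 1 elsewhere, ``d`` the per-cycle
repetition-suppression decay, and an extra first-cycle boost for piriform
neurons.  Odourless-control trials evoke a weaker response,
``baseline * (1 + gain * control_response_factor)``, in odour-tuned
neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .session import (
    CONTROL_STIMULUS,
    N_CYCLES,
    N_STIMULI,
    REGIONS,
    NeuronRecord,
    SessionData,
    TrialRecord,
)

N_ODOURS = N_STIMULI - 1  # 15 true odours; stimulus 0 is the control


def _default_neuron_counts() -> dict[str, int]:
    # Roughly one session's yield, apportioned like the recorded totals
    # (amygdala/hippocampus richest, piriform sampled in fewer sessions).
    return {"PC": 20, "AMY": 26, "EC": 18, "HIP": 24, "PHC": 16}


def _default_tuned_fraction() -> dict[str, float]:
    return {"PC": 0.40, "AMY": 0.20, "EC": 0.14, "HIP": 0.12, "PHC": 0.05}


def _default_tuning_breadth() -> dict[str, float]:
    # Mean number of preferred odours: piriform broad, amygdala and
    # hippocampus essentially one-hot.
    return {"PC": 4.0, "AMY": 1.0, "EC": 1.5, "HIP": 1.0, "PHC": 1.5}


def _default_latency() -> dict[str, float]:
    return {"PC": 0.2, "AMY": 0.2, "EC": 0.8, "HIP": 0.8, "PHC": 0.8}


def _default_gain_mean() -> dict[str, float]:
    # Broad-but-moderate piriform responses versus sparse, strong MTL
    # responses; the contrast is what makes the piriform population code
    # measurably less sparse than amygdala/hippocampus.
    return {"PC": 5.0, "AMY": 16.0, "EC": 8.0, "HIP": 24.0, "PHC": 4.0}


def _default_off_preferred_factor() -> dict[str, float]:
    # Graded tuning: a tuned neuron's response to a non-preferred odour,
    # as a fraction of its preferred-odour gain.  Nonzero only in the
    # piriform cortex, whose odour code is distributed rather than
    # one-hot; medial-temporal responses are all-or-none.
    return {"PC": 0.4, "AMY": 0.0, "EC": 0.0, "HIP": 0.0, "PHC": 0.0}


def _default_nonspecific_gain() -> dict[str, float]:
    # Sniff-driven odour-nonspecific response gain, applied to every
    # neuron of the region and identical across all 16 stimuli including
    # the odourless control, so it carries no identity information.
    # Present only in the piriform cortex (which responds to sniffing
    # itself); absent downstream, where responses are purely selective.
    return {"PC": 1.5, "AMY": 0.0, "EC": 0.0, "HIP": 0.0, "PHC": 0.0}


@dataclass
class SynthConfig:
    """Parameters of the synthetic session generator (all rates in Hz)."""

    neuron_counts: dict[str, int] = field(default_factory=_default_neuron_counts)
    tuned_fraction: dict[str, float] = field(default_factory=_default_tuned_fraction)
    tuning_breadth: dict[str, float] = field(default_factory=_default_tuning_breadth)
    response_latency_s: dict[str, float] = field(default_factory=_default_latency)
    response_duration_s: float = 1.5

    baseline_rate_median_hz: float = 2.0
    baseline_rate_log_sd: float = 0.5

    gain_mean: dict[str, float] = field(default_factory=_default_gain_mean)
    gain_shape: float = 4.0
    off_preferred_factor: dict[str, float] = field(
        default_factory=_default_off_preferred_factor
    )
    nonspecific_gain: dict[str, float] = field(
        default_factory=_default_nonspecific_gain
    )

    control_response_factor: float = 0.3  # in [0, 1)
    suppression_decay: float = 0.95  # d in (0, 1], per presentation cycle
    pc_first_trial_boost: float = 1.5  # >= 1, piriform cycle-1 multiplier

    valence_gain: float = 0.5  # beta_v, amygdala only
    valence_scores: list[float] | None = None  # per odour 1..15, in [-1, 1]

    identification_accuracy: float = 0.75

    include_control: bool = True
    include_image_block: bool = True
    cross_modal_overlap: float = 0.2  # rho: odour-tuned neurons also image-tuned
    image_only_tuned_fraction: float = 0.05

    mean_iti_s: float = 19.4
    iti_jitter_s: float = 0.4
    image_exposure_s: float = 1.0
    image_iti_s: float = 3.0
    pre_block_padding_s: float = 6.0

    def validate(self) -> None:
        for region in self.neuron_counts:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
        for region, f in self.tuned_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"tuned_fraction[{region}] = {f} outside [0, 1]")
        if not 0.0 <= self.control_response_factor < 1.0:
            raise ValueError("control_response_factor must be in [0, 1)")
        if not 0.0 < self.suppression_decay <= 1.0:
            raise ValueError("suppression_decay must be in (0, 1]")
        if self.pc_first_trial_boost < 1.0:
            raise ValueError("pc_first_trial_boost must be >= 1")
        if self.baseline_rate_median_hz <= 0:
            raise ValueError("baseline rate must be positive")
        if not 0.0 <= self.cross_modal_overlap <= 1.0:
            raise ValueError("cross_modal_overlap must be in [0, 1]")
        if not 0.0 <= self.identification_accuracy <= 1.0:
            raise ValueError("identification_accuracy must be in [0, 1]")
        if self.valence_scores is not None:
            if len(self.valence_scores) != N_ODOURS:
                raise ValueError(f"valence_scores must have length {N_ODOURS}")
            if any(abs(v) > 1 for v in self.valence_scores):
                raise ValueError("valence scores must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic session, for recovery tests."""

    neurons: dict[str, dict]  # neuron_id -> tuning parameters
    valence: list[float]  # per odour 1..15
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)

    def tuned_neuron_ids(self, region: str | None = None) -> list[str]:
        return [
            nid
            for nid, info in self.neurons.items()
            if info["tuned"] and (region is None or info["region"] == region)
        ]


# ---------------------------------------------------------------------------
# Poisson simulation
# ---------------------------------------------------------------------------


def simulate_inhomogeneous_poisson(
    edges: np.ndarray, rates: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Sample an inhomogeneous Poisson spike train with piecewise-constant rate.

    ``rates[i]`` (Hz) applies on ``[edges[i], edges[i+1])``.  Within each
    segment the spike count is Poisson(rate * length) and spike times are
    uniform; segments are independent.  Returns sorted spike times.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    edges = np.asarray(edges, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if edges.ndim != 1 or rates.ndim != 1 or edges.size != rates.size + 1:
        raise ValueError("need len(edges) == len(rates) + 1")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    if not np.all(np.isfinite(rates)) or np.any(rates < 0):
        raise ValueError("rates must be finite and non-negative")

    lengths = np.diff(edges)
    counts = rng.poisson(rates * lengths)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    u = rng.random(total)
    seg = np.repeat(np.arange(rates.size), counts)
    times = edges[seg] + u * lengths[seg]
    return np.sort(times)


def _piecewise_profile(
    base_rate: float, overrides: list[tuple[float, float, float]], t_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Edges/rates arrays for a baseline with non-overlapping rate overrides."""
    edges = [0.0]
    rates = []
    t = 0.0
    for start, end, rate in sorted(overrides):
        if start < t:
            raise ValueError("overlapping rate overrides")
        if start > t:
            edges.append(start)
            rates.append(base_rate)
        edges.append(min(end, t_end))
        rates.append(rate)
        t = end
        if t >= t_end:
            break
    if t < t_end:
        edges.append(t_end)
        rates.append(base_rate)
    return np.array(edges), np.array(rates)


# ---------------------------------------------------------------------------
# Trial schedule and behaviour
# ---------------------------------------------------------------------------


def _pseudorandom_order(
    stimuli: list[int], n_cycles: int, rng: np.random.Generator
) -> list[list[int]]:
    """Per-cycle permutations with no stimulus repeated back to back."""
    cycles: list[list[int]] = []
    prev_last: int | None = None
    for _ in range(n_cycles):
        order = list(rng.permutation(stimuli))
        if order[0] == prev_last:
            # swap the clashing first element with a later one
            j = int(rng.integers(1, len(order)))
            order[0], order[j] = order[j], order[0]
        cycles.append([int(s) for s in order])
        prev_last = order[-1]
    return cycles


def _make_odour_trials(
    config: SynthConfig, valence: np.ndarray, rng: np.random.Generator
) -> list[TrialRecord]:
    stimuli = list(range(N_STIMULI)) if config.include_control else list(range(1, N_STIMULI))
    cycles = _pseudorandom_order(stimuli, N_CYCLES, rng)
    trials: list[TrialRecord] = []
    onset = config.pre_block_padding_s
    idx = 0
    for cycle_i, order in enumerate(cycles, start=1):
        phase = "rating" if cycle_i <= 4 else "identification"
        for stim in order:
            rating = None
            chosen = None
            correct = None
            if phase == "rating":
                v_k = 0.0 if stim == CONTROL_STIMULUS else valence[stim - 1]
                rating = "liked" if rng.random() < expit(2.0 * v_k) else "disliked"
            else:
                if rng.random() < config.identification_accuracy:
                    chosen = stim
                else:
                    others = [s for s in stimuli if s != stim]
                    chosen = int(others[rng.integers(len(others))])
                correct = chosen == stim
            trials.append(
                TrialRecord(
                    trial_idx=idx,
                    modality="odour",
                    stimulus_id=stim,
                    onset_s=float(onset),
                    presentation_cycle=cycle_i,
                    phase=phase,
                    rating=rating,
                    chosen_stimulus_id=chosen,
                    correct=correct,
                )
            )
            idx += 1
            onset += max(5.0, rng.normal(config.mean_iti_s, config.iti_jitter_s))
    return trials


def _make_image_trials(
    config: SynthConfig, start_idx: int, start_time: float, rng: np.random.Generator
) -> list[TrialRecord]:
    stimuli = list(range(N_STIMULI))
    cycles = _pseudorandom_order(stimuli, N_CYCLES, rng)
    trials: list[TrialRecord] = []
    onset = start_time
    idx = start_idx
    for cycle_i, order in enumerate(cycles, start=1):
        for stim in order:
            trials.append(
                TrialRecord(
                    trial_idx=idx,
                    modality="image",
                    stimulus_id=stim,
                    onset_s=float(onset),
                    presentation_cycle=cycle_i,
                    phase="visual",
                )
            )
            idx += 1
            onset += config.image_exposure_s + config.image_iti_s
    return trials


# ---------------------------------------------------------------------------
# Neuron population
# ---------------------------------------------------------------------------


def _draw_neuron_params(
    config: SynthConfig, session_id: str, rng: np.random.Generator
) -> dict[str, dict]:
    params: dict[str, dict] = {}
    for region in REGIONS:
        count = config.neuron_counts.get(region, 0)
        breadth = config.tuning_breadth.get(region, 1.5)
        for i in range(count):
            nid = f"{session_id}-{region}-{i:03d}"
            baseline = float(
                np.exp(rng.normal(np.log(config.baseline_rate_median_hz), config.baseline_rate_log_sd))
            )
            tuned = bool(rng.random() < config.tuned_fraction.get(region, 0.0))
            preferred: list[int] = []
            gain = 0.0
            if tuned:
                n_pref = int(min(N_ODOURS, 1 + rng.poisson(max(0.0, breadth - 1.0))))
                preferred = sorted(
                    int(s) for s in rng.choice(np.arange(1, N_STIMULI), size=n_pref, replace=False)
                )
                gain = float(
                    rng.gamma(config.gain_shape, config.gain_mean.get(region, 2.0) / config.gain_shape)
                )
            image_tuned = False
            image_preferred: list[int] = []
            image_gain = 0.0
            if config.include_image_block:
                if tuned and rng.random() < config.cross_modal_overlap:
                    image_tuned = True
                    image_preferred = list(preferred)  # congruent tuning
                    image_gain = gain
                elif not tuned and rng.random() < config.image_only_tuned_fraction:
                    image_tuned = True
                    n_pref = int(min(N_ODOURS, 1 + rng.poisson(max(0.0, breadth - 1.0))))
                    image_preferred = sorted(
                        int(s)
                        for s in rng.choice(np.arange(1, N_STIMULI), size=n_pref, replace=False)
                    )
                    image_gain = float(
                        rng.gamma(config.gain_shape, config.gain_mean.get(region, 2.0) / config.gain_shape)
                    )
            params[nid] = {
                "region": region,
                "baseline_hz": baseline,
                "tuned": tuned,
                "preferred": preferred,
                "gain": gain,
                "image_tuned": image_tuned,
                "image_preferred": image_preferred,
                "image_gain": image_gain,
            }
    return params


def _response_overrides(
    info: dict,
    trials: list[TrialRecord],
    config: SynthConfig,
    valence: np.ndarray,
) -> list[tuple[float, float, float]]:
    region = info["region"]
    base = info["baseline_hz"]
    latency = config.response_latency_s.get(region, 0.2)
    overrides: list[tuple[float, float, float]] = []
    off_factor = config.off_preferred_factor.get(region, 0.0)
    nonspecific = config.nonspecific_gain.get(region, 0.0)
    for t in trials:
        if t.modality == "odour":
            rate = None
            if info["tuned"] and t.stimulus_id != CONTROL_STIMULUS:
                strength = (
                    1.0 if t.stimulus_id in info["preferred"] else off_factor
                )
                v_mod = 1.0
                if region == "AMY":
                    v_mod = 1.0 + config.valence_gain * valence[t.stimulus_id - 1]
                total_gain = nonspecific + info["gain"] * strength * v_mod
                if total_gain > 0:
                    rate = (
                        base
                        * (1.0 + total_gain)
                        * config.suppression_decay ** (t.presentation_cycle - 1)
                    )
                    if region == "PC" and t.presentation_cycle == 1:
                        rate *= config.pc_first_trial_boost
            elif info["tuned"] and t.stimulus_id == CONTROL_STIMULUS:
                # the sniff-driven component responds to the odourless
                # control at full strength; the selective component at
                # the (weaker) control factor
                rate = base * (
                    1.0 + nonspecific + info["gain"] * config.control_response_factor
                )
            elif not info["tuned"] and nonspecific > 0:
                # untuned neurons carry only the stimulus-independent
                # sniff response: identical for all 16 stimuli including
                # the control, constant across cycles
                rate = base * (1.0 + nonspecific)
            if rate is not None:
                overrides.append(
                    (t.onset_s + latency, t.onset_s + latency + config.response_duration_s, rate)
                )
        else:  # image
            if info["image_tuned"] and t.stimulus_id in info["image_preferred"]:
                rate = base * (1.0 + info["image_gain"])
                overrides.append(
                    (t.onset_s + latency, t.onset_s + latency + config.image_exposure_s, rate)
                )
    return overrides


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------


def generate_session(
    config: SynthConfig | None = None,
    seed: int | None = None,
    session_id: str | None = None,
    participant_id: str | None = None,
) -> tuple[SessionData, GroundTruth]:
    """Generate one synthetic session; identical (config, seed) pairs are
    reproduced exactly."""
    if seed is None:
        raise ValueError("a seed is required: synthetic sessions must be reproducible")
    if config is None:
        config = SynthConfig()
    config.validate()
    session_id = session_id or f"synth-{seed}"
    participant_id = participant_id or f"p-{seed}"
    rng = np.random.default_rng(seed)

    if config.valence_scores is not None:
        valence = np.asarray(config.valence_scores, dtype=float)
    else:
        valence = rng.uniform(-1.0, 1.0, size=N_ODOURS)

    trials = _make_odour_trials(config, valence, rng)
    if config.include_image_block:
        gap = 15.0
        start = trials[-1].onset_s + config.mean_iti_s + gap
        trials += _make_image_trials(config, len(trials), start, rng)
    t_end = trials[-1].onset_s + config.mean_iti_s

    params = _draw_neuron_params(config, session_id, rng)
    neurons = []
    for nid, info in params.items():
        overrides = _response_overrides(info, trials, config, valence)
        edges, rates = _piecewise_profile(info["baseline_hz"], overrides, t_end)
        spikes = simulate_inhomogeneous_poisson(edges, rates, rng)
        neurons.append(NeuronRecord(nid, info["region"], spikes))

    gt = GroundTruth(neurons=params, valence=[float(v) for v in valence], seed=int(seed))
    session = SessionData(
        session_id=session_id,
        participant_id=participant_id,
        neurons=neurons,
        trials=trials,
        ground_truth=gt.to_dict(),
    )
    return session, gt


def generate_cohort(
    n_sessions: int,
    config: SynthConfig | None = None,
    seed: int | None = None,
) -> tuple[list[SessionData], list[GroundTruth]]:
    """Generate several sessions with independent child seeds of ``seed``.

    Valence scores are shared across the cohort (an odour's valence is a
    property of the odour, not of the session): if the config does not fix
    them they are drawn once from the cohort seed.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if config is None:
        config = SynthConfig()
    ss = np.random.SeedSequence(seed)
    if config.valence_scores is None:
        rng = np.random.default_rng(ss.spawn(1)[0])
        import dataclasses

        config = dataclasses.replace(
            config,
            valence_scores=[float(v) for v in rng.uniform(-1, 1, N_ODOURS)],
        )
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sessions)]
    sessions, gts = [], []
    for i, s in enumerate(child_seeds):
        sess, gt = generate_session(
            config, seed=s, session_id=f"synth-{seed}-{i:02d}", participant_id=f"p-{i:02d}"
        )
        sessions.append(sess)
        gts.append(gt)
    return sessions, gts
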