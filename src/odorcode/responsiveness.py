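"""Detection of stimulus-modulated neurons, PSTHs, and response tests.

A neuron is called odour-modulated (image-modulated) when a one-way ANOVA
of its baseline-z-scored response rates across stimulus identities is
significant at ``alpha`` over all trials of the block.  Selection is
per-neuron at fixed alpha with no multiple-testing correction across
neurons; by construction this flags ~alpha of untuned neurons, which is
the chance level all population fractions are compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .session import (
    RateMatrix,
    SessionData,
    TimeWindow,
    window_spike_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class ModulationResult:
    neuron_id: str
    F: float
    p: float
    df_between: int
    df_within: int
    modulated: bool
    modality: str = "odour"


@dataclass
class Psth:
    """Baseline-z-scored peri-stimulus time histogram, averaged over a group."""

    bin_edges: np.ndarray  # seconds relative to onset, len n_bins + 1
    mean_z: np.ndarray
    sem_z: np.ndarray
    n_neurons: int
    group: str = ""
    excluded_neuron_ids: list[str] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ContrastResult:
    """Per-neuron odour-minus-control mean z differences with a population test."""

    neuron_ids: list[str]
    differences: np.ndarray
    statistic: float
    p: float


def one_way_anova(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Row-wise one-way ANOVA of ``values`` (rows x trials) grouped by ``labels``.

    Rows with zero total variance get F = 0, p = 1 (no effect by
    definition rather than an undefined ratio).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    groups = [values[:, labels == g] for g in np.unique(labels)]
    n_groups = len(groups)
    if n_groups < 2 or any(g.shape[1] < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 trials each")
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups, axis=1)
    F = np.atleast_1d(np.asarray(F, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    flat = values.var(axis=1) == 0
    F[flat] = 0.0
    p[flat] = 1.0
    df_between = n_groups - 1
    df_within = values.shape[1] - n_groups
    return F, p, df_between, df_within


def detect_modulated_neurons(
    rates: RateMatrix,
    labels: np.ndarray,
    alpha: float = 0.05,
    modality: str = "odour",
) -> list[ModulationResult]:
    """One-way ANOVA of z-scored rates across stimulus identities, per neuron.

    ``labels`` gives the stimulus_id of each column of ``rates``.  Neurons
    already excluded by the zero-baseline-variance rule are simply absent
    from ``rates`` (and hence from the output).
    """
    labels = np.asarray(labels)
    if labels.size != rates.n_trials:
        raise ValueError("labels length must match number of trials")
    F, p, dfb, dfw = one_way_anova(rates.values, labels)
    return [
        ModulationResult(
            neuron_id=nid,
            F=float(F[i]),
            p=float(p[i]),
            df_between=dfb,
            df_within=dfw,
            modulated=bool(p[i] < alpha),
            modality=modality,
        )
        for i, nid in enumerate(rates.neuron_ids)
    ]


def modulated_fraction(results: list[ModulationResult]) -> float:
    if not results:
        return float("nan")
    return sum(r.modulated for r in results) / len(results)


def compute_psth(
    session: SessionData,
    neuron_ids: list[str],
    onsets: np.ndarray,
    bin_width_s: float = 0.05,
    window: TimeWindow = TimeWindow(-1.0, 2.0),
    baseline: TimeWindow = TimeWindow(-5.0, 0.0),
    group: str = "",
) -> Psth:
    """Group-average baseline-z-scored PSTH.

    For each neuron, spiking is binned (``bin_width_s``) relative to every
    onset and averaged over trials; all bins are z-scored by the mean and
    sample sd of the bins falling in the baseline window.  Neurons whose
    baseline bins have zero variance are excluded (logged).  The returned
    PSTH covers ``window``; the baseline bins are used for normalisation
    only.
    """
    onsets = np.asarray(onsets, dtype=float)
    lo = min(window.start_s, baseline.start_s)
    hi = max(window.end_s, baseline.end_s)
    n_bins = int(round((hi - lo) / bin_width_s))
    edges = lo + bin_width_s * np.arange(n_bins + 1)

    base_mask = (edges[:-1] >= baseline.start_s) & (edges[1:] <= baseline.end_s)
    if base_mask.sum() < 2:
        raise ValueError("baseline window must contain >= 2 bins")
    disp_mask = (edges[:-1] >= window.start_s) & (edges[1:] <= window.end_s + 1e-12)

    z_rows = []
    excluded = []
    for nid in neuron_ids:
        neuron = session.neuron(nid)
        # trials x bins counts, then trial-average rate per bin
        rel = neuron.spike_times[None, :] - onsets[:, None]
        counts = np.stack([np.histogram(r, bins=edges)[0] for r in rel])
        mean_rate = counts.mean(axis=0) / bin_width_s
        mu = mean_rate[base_mask].mean()
        sd = mean_rate[base_mask].std(ddof=1)
        if sd == 0:
            excluded.append(nid)
            continue
        z_rows.append((mean_rate - mu) / sd)
    if excluded:
        logger.warning("PSTH: excluded %d neuron(s) with zero baseline variance", len(excluded))
    if not z_rows:
        raise ValueError("no neurons with nonzero baseline variance")
    Z = np.array(z_rows)[:, disp_mask]
    disp_edges = np.append(edges[:-1][disp_mask], edges[1:][disp_mask][-1])
    return Psth(
        bin_edges=disp_edges,
        mean_z=Z.mean(axis=0),
        sem_z=Z.std(axis=0, ddof=1) / np.sqrt(Z.shape[0]) if Z.shape[0] > 1 else np.zeros(Z.shape[1]),
        n_neurons=Z.shape[0],
        group=group,
        excluded_neuron_ids=excluded,
    )


def odour_vs_control_contrast(
    rates: RateMatrix,
    labels: np.ndarray,
    neuron_ids: list[str] | None = None,
    control_id: int = 0,
) -> ContrastResult:
    """Mean z over odour trials minus mean z over odourless-control trials.

    Computed per neuron (restricted to ``neuron_ids``, typically the
    odour-modulated set), followed by a two-sided Wilcoxon signed-rank
    test on the paired differences.  With a single neuron the population
    p is NaN.  Raises if no control trials are present (some sessions
    lack the control stimulus); callers should skip those with a warning.
    """
    labels = np.asarray(labels)
    if not np.any(labels == control_id):
        raise ValueError("no control trials in input")
    mat = rates if neuron_ids is None else rates.subset_neurons(neuron_ids)
    odour_mean = mat.values[:, labels != control_id].mean(axis=1)
    control_mean = mat.values[:, labels == control_id].mean(axis=1)
    diffs = odour_mean - control_mean
    if diffs.size >= 2 and np.any(diffs != 0):
        stat, p = stats.wilcoxon(diffs, alternative="two-sided")
    else:
        stat, p = float("nan"), float("nan")
    return ContrastResult(
        neuron_ids=list(mat.neuron_ids),
        differences=diffs,
        statistic=float(stat),
        p=float(p),
    )


def event_response_test(
    spike_times: np.ndarray,
    event_onsets: np.ndarray,
    response_window: TimeWindow,
    baseline_rates: np.ndarray,
) -> tuple[float, float]:
    """One-sided (greater) rank-sum test of event-window rates vs baseline rates.

    Mirrors the single-event response test used for concept-cell style
    responses: the firing rates after a handful of onsets are compared
    against the pooled pre-odour baseline rate sample.  Ties are handled
    by mid-ranks (exact p for small tie-free samples, otherwise normal
    approximation with continuity correction).  Returns (statistic, p).
    """
    event_onsets = np.asarray(event_onsets, dtype=float)
    if event_onsets.size == 0:
        raise ValueError("need at least one event onset")
    spike_times = np.asarray(spike_times, dtype=float)
    event_rates = (
        window_spike_counts(spike_times, event_onsets, response_window)
        / response_window.length_s
    )
    res = stats.mannwhitneyu(
        event_rates, np.asarray(baseline_rates, dtype=float), alternative="greater"
    )
    return float(res.statistic), float(res.pvalue)
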