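"""Population sparseness, repetition suppression, valence, and count statistics.

The sparseness of the population response to a stimulus ``k`` is
summarised by the activity ratio

    A_k = (mean_i x_i)^2 / mean_i x_i^2,

where ``x_i >= 0`` is the mean response rate of neuron ``i`` to stimulus
``k``, and by the normalised sparseness index
``SI_k = (1 - A_k) / (1 - 1/N)`` which runs from 0 (uniformly
distributed activity) to 1 (a single active neuron).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .session import CONTROL_STIMULUS, RateMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sparseness
# ---------------------------------------------------------------------------


def activity_ratio(x: np.ndarray) -> float:
    """A_k of a non-negative per-neuron activity vector."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("activity must be non-negative")
    denom = np.mean(x**2)
    if denom == 0:
        raise ValueError("all-zero activity vector: A_k undefined")
    return float(np.mean(x) ** 2 / denom)


def sparseness_index(x: np.ndarray) -> float:
    """SI_k = (1 - A_k) / (1 - 1/N); 0 = uniform, 1 = one-hot."""
    n = np.asarray(x).size
    if n < 2:
        raise ValueError("need >= 2 neurons")
    return float((1.0 - activity_ratio(x)) / (1.0 - 1.0 / n))


@dataclass
class SparsenessResult:
    region: str
    stimulus_ids: list[int]
    activity_ratios: np.ndarray  # A_k per stimulus
    sparseness_indices: np.ndarray  # SI_k per stimulus
    n_neurons: int
    skipped_stimuli: list[int] = field(default_factory=list)

    @property
    def mean_sparseness(self) -> float:
        return float(np.mean(self.sparseness_indices))


def population_sparseness(
    rates: RateMatrix,
    labels: np.ndarray,
    region: str = "",
    exclude_control: bool = True,
) -> SparsenessResult:
    """Per-odour activity ratio and sparseness index of a region's population.

    ``rates`` must be raw (non-negative) response rates; ``x_i`` is the
    trial-averaged rate of neuron ``i`` over the trials of each stimulus.
    The odourless control is excluded by default so that sparseness is
    estimated over the 15 true odours.
    """
    if rates.normalization != "raw":
        raise ValueError("sparseness requires raw (non-negative) rates")
    if rates.n_neurons < 2:
        raise ValueError("need >= 2 neurons")
    labels = np.asarray(labels)
    stimulus_ids = sorted(set(labels.tolist()))
    if exclude_control:
        stimulus_ids = [s for s in stimulus_ids if s != CONTROL_STIMULUS]

    kept, A, SI, skipped = [], [], [], []
    for s in stimulus_ids:
        x = rates.values[:, labels == s].mean(axis=1)
        if np.all(x == 0):
            logger.warning("stimulus %d: all-zero activity, skipped", s)
            skipped.append(s)
            continue
        kept.append(s)
        A.append(activity_ratio(x))
        SI.append(sparseness_index(x))
    return SparsenessResult(
        region=region,
        stimulus_ids=kept,
        activity_ratios=np.array(A),
        sparseness_indices=np.array(SI),
        n_neurons=rates.n_neurons,
        skipped_stimuli=skipped,
    )


def pooled_sparseness(
    rate_label_pairs: list[tuple[RateMatrix, np.ndarray]],
    region: str = "",
    exclude_control: bool = True,
) -> SparsenessResult:
    """Sparseness over neurons pooled across sessions.

    ``x_i`` for each neuron is the trial-averaged raw rate within its own
    session; neurons from all sessions are concatenated per stimulus.
    Only stimuli present in every session enter the result.
    """
    if not rate_label_pairs:
        raise ValueError("no sessions with neurons in this region")
    stim_sets = [set(np.unique(lab).tolist()) for _, lab in rate_label_pairs]
    stimulus_ids = sorted(set.intersection(*stim_sets))
    if exclude_control:
        stimulus_ids = [s for s in stimulus_ids if s != CONTROL_STIMULUS]
    kept, A, SI, skipped = [], [], [], []
    n_neurons = sum(rm.n_neurons for rm, _ in rate_label_pairs)
    if n_neurons < 2:
        raise ValueError("need >= 2 neurons")
    for s in stimulus_ids:
        x = np.concatenate(
            [
                rm.values[:, np.asarray(lab) == s].mean(axis=1)
                for rm, lab in rate_label_pairs
            ]
        )
        if np.all(x == 0):
            logger.warning("stimulus %d: all-zero activity, skipped", s)
            skipped.append(s)
            continue
        kept.append(s)
        A.append(activity_ratio(x))
        SI.append(sparseness_index(x))
    return SparsenessResult(
        region=region,
        stimulus_ids=kept,
        activity_ratios=np.array(A),
        sparseness_indices=np.array(SI),
        n_neurons=n_neurons,
        skipped_stimuli=skipped,
    )


@dataclass
class SparsenessComparison:
    F: float
    p: float
    tukey_summary: str


def compare_sparseness_across_regions(
    results: list[SparsenessResult],
) -> SparsenessComparison:
    """One-way ANOVA on the per-odour SI values of each region, with Tukey HSD
    pairwise comparisons."""
    groups = [r.sparseness_indices for r in results]
    F, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate(
        [[r.region] * r.sparseness_indices.size for r in results]
    )
    tukey = pairwise_tukeyhsd(values, labels)
    return SparsenessComparison(F=float(F), p=float(p), tukey_summary=str(tukey.summary()))


# ---------------------------------------------------------------------------
# Repetition suppression
# ---------------------------------------------------------------------------


@dataclass
class SuppressionResult:
    neuron_ids: list[str]
    slopes: np.ndarray  # delta mean z per presentation cycle
    cycle_means: np.ndarray  # neurons x 8 mean z per cycle
    statistic: float  # signed-rank statistic of slopes vs 0
    p: float
    first_vs_second_statistic: float
    first_vs_second_p: float

    @property
    def median_slope(self) -> float:
        return float(np.median(self.slopes))


def repetition_suppression(
    rates: RateMatrix,
    cycles: np.ndarray,
    labels: np.ndarray | None = None,
    neuron_ids: list[str] | None = None,
    n_cycles: int = 8,
) -> SuppressionResult:
    """Per-neuron response decline across the 8 presentation cycles.

    For each neuron (typically the odour-modulated set), the mean z-scored
    rate per presentation cycle is computed over odour trials (control
    excluded when ``labels`` are given), a least-squares slope is fit over
    the 8 cycle means, and the slopes are tested against 0 with a
    two-sided Wilcoxon signed-rank test.  A paired first-versus-second
    cycle signed-rank test captures the first-trial effect.
    """
    cycles = np.asarray(cycles)
    mat = rates if neuron_ids is None else rates.subset_neurons(neuron_ids)
    mask = np.ones(cycles.size, dtype=bool)
    if labels is not None:
        mask &= np.asarray(labels) != CONTROL_STIMULUS
    present = sorted(set(cycles[mask].tolist()))
    if present != list(range(1, n_cycles + 1)):
        raise ValueError(f"need all presentation cycles 1..{n_cycles}, have {present}")

    cycle_means = np.stack(
        [mat.values[:, mask & (cycles == c)].mean(axis=1) for c in range(1, n_cycles + 1)],
        axis=1,
    )
    x = np.arange(1, n_cycles + 1, dtype=float)
    xc = x - x.mean()
    slopes = (cycle_means - cycle_means.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)

    if slopes.size >= 2 and np.any(slopes != 0):
        stat, p = stats.wilcoxon(slopes, alternative="two-sided")
    else:
        stat, p = float("nan"), 1.0 if slopes.size else float("nan")
    d12 = cycle_means[:, 0] - cycle_means[:, 1]
    if d12.size >= 2 and np.any(d12 != 0):
        stat12, p12 = stats.wilcoxon(d12, alternative="two-sided")
    else:
        stat12, p12 = float("nan"), 1.0 if d12.size else float("nan")
    return SuppressionResult(
        neuron_ids=list(mat.neuron_ids),
        slopes=slopes,
        cycle_means=cycle_means,
        statistic=float(stat),
        p=float(p),
        first_vs_second_statistic=float(stat12),
        first_vs_second_p=float(p12),
    )


# ---------------------------------------------------------------------------
# Valence
# ---------------------------------------------------------------------------


@dataclass
class ValenceResult:
    neuron_ids: list[str]
    contrasts: np.ndarray  # mean z liked - mean z disliked, per neuron
    statistic: float
    p: float
    spearman_r: float
    spearman_p: float
    excluded_neuron_ids: list[str] = field(default_factory=list)


def valence_analysis(
    rates: RateMatrix,
    labels: np.ndarray,
    ratings: np.ndarray,
    reference_valence: np.ndarray | None = None,
    neuron_ids: list[str] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> ValenceResult:
    """Liked-versus-disliked firing contrast plus valence correlation.

    ``rates`` holds z-scored rating-phase trials; ``ratings`` is the
    per-trial 'liked'/'disliked' array.  Per neuron the contrast is the
    mean z over liked trials minus the mean over disliked trials (neurons
    lacking either category are excluded, logged); the population test is
    a two-sided signed-rank.  If 15 per-odour ``reference_valence``
    scores are given, the per-odour population-mean z (odour trials only)
    is Spearman-correlated with them using a seeded permutation p-value.
    """
    labels = np.asarray(labels)
    ratings = np.asarray(ratings, dtype=object)
    mat = rates if neuron_ids is None else rates.subset_neurons(neuron_ids)
    liked = ratings == "liked"
    disliked = ratings == "disliked"
    excluded = []
    kept_ids, contrasts = [], []
    for i, nid in enumerate(mat.neuron_ids):
        if not liked.any() or not disliked.any():
            excluded.append(nid)
            continue
        contrasts.append(
            mat.values[i, liked].mean() - mat.values[i, disliked].mean()
        )
        kept_ids.append(nid)
    if excluded:
        logger.warning("valence contrast: excluded %d neuron(s)", len(excluded))
    contrasts = np.array(contrasts)
    if contrasts.size >= 2 and np.any(contrasts != 0):
        stat, p = stats.wilcoxon(contrasts, alternative="two-sided")
    else:
        stat, p = float("nan"), float("nan")

    r = p_r = float("nan")
    if reference_valence is not None:
        reference_valence = np.asarray(reference_valence, dtype=float)
        odour_ids = sorted(s for s in set(labels.tolist()) if s != CONTROL_STIMULUS)
        if len(odour_ids) != reference_valence.size:
            raise ValueError(
                f"{reference_valence.size} reference scores for {len(odour_ids)} odours"
            )
        pop_mean = np.array(
            [mat.values[:, labels == s].mean() for s in odour_ids]
        )
        r, p_r = spearman_permutation(pop_mean, reference_valence, n_perm=n_perm, seed=seed)
    return ValenceResult(
        neuron_ids=kept_ids,
        contrasts=contrasts,
        statistic=float(stat),
        p=float(p),
        spearman_r=r,
        spearman_p=p_r,
        excluded_neuron_ids=excluded,
    )


# ---------------------------------------------------------------------------
# Generic statistics
# ---------------------------------------------------------------------------


def spearman_permutation(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided seeded permutation p-value.

    p uses the add-one rule ``(1 + #{|r_perm| >= |r|}) / (1 + n_perm)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with >= 3 values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input: rank correlation undefined")
    rng = np.random.default_rng(seed)
    r = float(stats.spearmanr(x, y).statistic)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    for _ in range(n_perm):
        rp = float(np.corrcoef(rx, rng.permutation(ry))[0, 1])
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    return r, (1 + count) / (1 + n_perm)


def exact_binomial_test(k: int, n: int, p0: float, sided: str = "two") -> float:
    """Exact binomial p-value.

    ``right``: P(X >= k); ``left``: P(X <= k); ``two``: the small-p
    convention — the sum of the probabilities of all outcomes whose
    probability does not exceed P(X = k).
    """
    if not (0 <= k <= n) or not (0.0 <= p0 <= 1.0):
        raise ValueError("need 0 <= k <= n and p0 in [0, 1]")
    if sided == "right":
        return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    if sided == "left":
        return float(stats.binomtest(k, n, p0, alternative="less").pvalue)
    if sided == "two":
        return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    raise ValueError(f"unknown sidedness {sided!r}")


@dataclass
class StatTestResult:
    statistic: float
    p: float
    method: str
    inputs: dict


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> StatTestResult:
    """Pooled two-proportion Z-test, two-sided normal p."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion 0 or 1: Z undefined")
    z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    p = 2 * stats.norm.sf(abs(z))
    return StatTestResult(
        statistic=float(z),
        p=float(p),
        method="two_proportion_ztest",
        inputs={"k1": k1, "n1": n1, "k2": k2, "n2": n2},
    )


def session_significance_count(
    p_values: np.ndarray, alpha: float = 0.05, p_chance: float = 0.05
) -> tuple[int, float]:
    """Count sessions significant at ``alpha`` and test the count against the
    per-session chance rate with a right-sided exact binomial test."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("need at least one session p-value")
    k = int(np.sum(p_values < alpha))
    return k, exact_binomial_test(k, p_values.size, p_chance, sided="right")


def behaviour_decoding_correlation(
    decoding_accuracies: np.ndarray,
    identification_accuracies: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between per-session decoding accuracy and
    behavioural odour-identification accuracy (permutation p)."""
    return spearman_permutation(
        decoding_accuracies, identification_accuracies, n_perm=n_perm, seed=seed
    )
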