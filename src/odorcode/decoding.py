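"""Pseudopopulation identity decoding with a maximum-correlation classifier.

Identity decoding follows the template-matching scheme common in human
single-unit work: per class, the template is the mean training population
vector, and each test vector is assigned to the class whose template has
the maximal Pearson correlation with it.  Populations are assembled as
pseudopopulations — neurons recorded in different sessions are combined
by aligning trials with the same stimulus label, with each neuron's
trials independently shuffled within class so that trial-by-trial noise
correlations across sessions are destroyed by construction.

Significance is assessed against a surrogate distribution of accuracies
obtained on label-permuted data, with the add-one percentile rule
``p = (1 + #{null >= observed}) / (1 + n_permutations)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats

from .session import RateMatrix, SessionData, TimeWindow, compute_rate_matrix

logger = logging.getLogger(__name__)

CHANCE_16 = 1.0 / 16.0  # 6.25% for the 16-class design


@dataclass
class DecodingConfig:
    """Settings for pseudopopulation decoding (defaults: odour identity)."""

    window: TimeWindow = field(default_factory=lambda: TimeWindow(0.0, 2.0))
    n_splits: int = 8
    n_resample_runs: int = 10
    n_subsample_runs: int = 1000
    n_neurons: int = 200
    n_permutations: int = 1000
    n_per_class: int = 8
    alpha: float = 0.05
    seed: int = 0
    drop_first_cycle: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = [self.window.start_s, self.window.end_s]
        return d


@dataclass
class DecodingResult:
    accuracy: float
    subsample_accuracies: np.ndarray
    null_accuracies: np.ndarray
    p: float
    chance: float
    config: dict
    skip_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


@dataclass
class Pseudopopulation:
    """Trials x neurons matrix of pseudotrials aligned by stimulus label."""

    X: np.ndarray
    labels: np.ndarray
    neuron_ids: list[str]


@dataclass
class SweepResult:
    axis: str
    grid: np.ndarray
    accuracies: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    onset: float | int | None  # first grid point with sustained significance
    chance: float


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B.

    Rows with zero variance produce NaN correlations.
    """
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (A @ B.T) / np.outer(na, nb)
    C[na == 0, :] = np.nan
    C[:, nb == 0] = np.nan
    return C


def max_correlation_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Assign each test population vector to its maximally correlated template.

    Templates are per-class means of the training vectors.  A test vector
    with zero variance (correlation undefined with every template) is
    assigned a seeded uniform-random class; exact ties among maxima are
    broken the same way.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[1] < 2:
        raise ValueError("need >= 2 neurons: correlations are undefined in 1-d")
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    templates = np.stack([train_X[train_y == c].mean(axis=0) for c in classes])
    C = _pearson_rows(test_X, templates)

    preds = np.empty(test_X.shape[0], dtype=classes.dtype)
    for i, row in enumerate(C):
        valid = np.isfinite(row)
        if not valid.any():
            preds[i] = classes[rng.integers(classes.size)]
            logger.debug("test vector %d: all correlations undefined; random class", i)
            continue
        m = row[valid].max()
        tied = np.flatnonzero(valid & (row >= m - 1e-12))
        if tied.size == 1:
            preds[i] = classes[tied[0]]
        else:
            preds[i] = classes[tied[rng.integers(tied.size)]]
    return preds


# ---------------------------------------------------------------------------
# Pseudopopulation assembly
# ---------------------------------------------------------------------------


def session_feature_matrix(
    session: SessionData,
    region: str,
    window: TimeWindow,
    modality: str = "odour",
    label: str = "stimulus_id",
    phase: str | None = None,
    drop_first_cycle: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Raw-rate trials x neurons matrix for one session and region.

    ``label`` selects the per-trial class label: ``stimulus_id`` (chemical
    identity) or ``chosen_stimulus_id`` (perceived identity during the
    identification phase).
    """
    trials = [t for t in session.trials if t.modality == modality]
    if phase is not None:
        trials = [t for t in trials if t.phase == phase]
    if drop_first_cycle:
        trials = [t for t in trials if t.presentation_cycle > 1]
    neurons = session.neurons_in_region(region)
    if not trials or not neurons:
        return np.empty((0, 0)), np.empty(0, dtype=int), []
    rm = compute_rate_matrix(session, trials, window, "raw", neurons=neurons)
    if label == "stimulus_id":
        y = np.array([t.stimulus_id for t in trials])
    elif label == "chosen_stimulus_id":
        y = np.array(
            [-1 if t.chosen_stimulus_id is None else t.chosen_stimulus_id for t in trials]
        )
    else:
        raise ValueError(f"unknown label source {label!r}")
    return rm.values.T, y, list(rm.neuron_ids)


def assemble_pseudopopulation(
    feature_sets: list[tuple[np.ndarray, np.ndarray, list[str]]],
    n_neurons: int,
    n_per_class: int,
    rng: np.random.Generator,
    classes: np.ndarray | None = None,
) -> Pseudopopulation:
    """Sample ``n_neurons`` across sessions and align their trials by label.

    For each class, each sampled neuron's trials with that label are
    independently shuffled (and, if more than ``n_per_class`` are
    available, subsampled) and concatenated position-wise into
    ``n_per_class`` pseudotrials.
    """
    if classes is None:
        class_sets = [set(np.unique(y)) - {-1} for _, y, _ in feature_sets if y.size]
        common = set.intersection(*class_sets)
        classes = np.array(sorted(common))
    pool = [
        (s, j)
        for s, (X, y, ids) in enumerate(feature_sets)
        for j in range(len(ids))
        if y.size
    ]
    if len(pool) < n_neurons:
        raise ValueError(f"requested {n_neurons} neurons but pool has {len(pool)}")
    sel = rng.choice(len(pool), size=n_neurons, replace=False)
    picks = [pool[i] for i in sel]

    n_classes = classes.size
    out = np.empty((n_classes * n_per_class, n_neurons))
    labels = np.repeat(classes, n_per_class)
    neuron_ids: list[str] = [""] * n_neurons

    for s, (X, y, ids) in enumerate(feature_sets):
        cols = [k for k, (si, _) in enumerate(picks) if si == s]
        if not cols:
            continue
        colidx = np.array([picks[k][1] for k in cols])
        for k, j in zip(cols, colidx):
            neuron_ids[k] = ids[j]
        # independent within-class shuffles, one permutation per neuron/class
        perms = np.argsort(rng.random((len(cols), n_classes, n_per_class)), axis=-1)
        for ci, c in enumerate(classes):
            tidx = np.flatnonzero(y == c)
            if tidx.size < n_per_class:
                raise ValueError(
                    f"class {c}: only {tidx.size} trials, need {n_per_class}"
                )
            if tidx.size > n_per_class:
                tidx = rng.choice(tidx, size=n_per_class, replace=False)
            vals = X[np.ix_(tidx, colidx)]  # (n_per_class, n_cols)
            shuffled = np.take_along_axis(vals, perms[:, ci, :].T, axis=0)
            out[ci * n_per_class : (ci + 1) * n_per_class, cols] = shuffled
    return Pseudopopulation(X=out, labels=labels, neuron_ids=neuron_ids)


def build_pseudopopulation(
    sessions: list[SessionData],
    region: str,
    n_neurons: int,
    rng: np.random.Generator | int,
    window: TimeWindow = TimeWindow(0.0, 2.0),
    modality: str = "odour",
    n_per_class: int = 8,
    drop_first_cycle: bool = False,
) -> Pseudopopulation:
    """Pseudopopulation of ``n_neurons`` sampled without replacement from the
    pooled neurons of ``region`` across ``sessions``."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    feats = [
        session_feature_matrix(
            s, region, window, modality=modality, drop_first_cycle=drop_first_cycle
        )
        for s in sessions
    ]
    eff_per_class = n_per_class - (1 if drop_first_cycle else 0)
    return assemble_pseudopopulation(feats, n_neurons, eff_per_class, rng)


# ---------------------------------------------------------------------------
# Cross-validated accuracy
# ---------------------------------------------------------------------------


def cross_validated_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int = 8,
    n_resample_runs: int = 10,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Stratified cross-validated accuracy of the max-correlation classifier.

    Every class must have the same trial count, divisible by ``n_splits``
    (8 trials and 8 splits give leave-one-trial-per-class-out folds).  On
    each resample run the trials of each class are re-partitioned into
    splits at random; the returned accuracy is averaged over all folds
    and runs.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = np.asarray(y)
    classes = np.unique(y)
    idx_by_class = [np.flatnonzero(y == c) for c in classes]
    counts = {ix.size for ix in idx_by_class}
    if len(counts) != 1:
        raise ValueError(f"unequal trials per class: {sorted(counts)}")
    n_per_class = counts.pop()
    if n_per_class % n_splits:
        raise ValueError(f"{n_per_class} trials per class not divisible by {n_splits} splits")
    k = n_per_class // n_splits

    correct = 0
    total = 0
    for _ in range(n_resample_runs):
        order = [rng.permutation(ix) for ix in idx_by_class]
        for f in range(n_splits):
            test_idx = np.concatenate([o[f * k : (f + 1) * k] for o in order])
            train_mask = np.ones(y.size, dtype=bool)
            train_mask[test_idx] = False
            preds = max_correlation_classify(X[train_mask], y[train_mask], X[test_idx], rng)
            correct += int((preds == y[test_idx]).sum())
            total += test_idx.size
    return correct / total


def _permutation_p(null: np.ndarray, observed: float) -> float:
    return (1.0 + int(np.sum(null >= observed))) / (1.0 + null.size)


# ---------------------------------------------------------------------------
# Decoding analyses
# ---------------------------------------------------------------------------


def population_decoding_with_null(
    sessions: list[SessionData],
    region: str,
    config: DecodingConfig | None = None,
    modality: str = "odour",
) -> DecodingResult:
    """Observed accuracy over random neuron subsamples plus a label-permutation
    null distribution and percentile p-value."""
    config = config or DecodingConfig()
    rng = np.random.default_rng(config.seed)
    feats = [
        session_feature_matrix(
            s,
            region,
            config.window,
            modality=modality,
            drop_first_cycle=config.drop_first_cycle,
        )
        for s in sessions
    ]
    n_per_class = config.n_per_class - (1 if config.drop_first_cycle else 0)

    def one_accuracy(permute: bool) -> float:
        pop = assemble_pseudopopulation(feats, config.n_neurons, n_per_class, rng)
        labels = rng.permutation(pop.labels) if permute else pop.labels
        return cross_validated_accuracy(
            pop.X, labels, config.n_splits, config.n_resample_runs, rng
        )

    obs = np.array([one_accuracy(False) for _ in range(config.n_subsample_runs)])
    null = np.array([one_accuracy(True) for _ in range(config.n_permutations)])
    observed = float(obs.mean())
    chance = 1.0 / np.unique(
        np.concatenate([y for _, y, _ in feats if y.size])
    ).size
    return DecodingResult(
        accuracy=observed,
        subsample_accuracies=obs,
        null_accuracies=null,
        p=_permutation_p(null, observed),
        chance=chance,
        config=config.to_dict(),
    )


def sweep_decoding(
    sessions: list[SessionData],
    region: str,
    axis: str,
    grid: np.ndarray,
    config: DecodingConfig | None = None,
    n_runs: int = 100,
) -> SweepResult:
    """Accuracy sweep over window length or neuron count.

    Per grid point, ``n_runs`` subsample accuracies are computed and
    tested against chance with a right-sided Wilcoxon signed-rank test,
    Bonferroni-corrected for the grid size.  The onset is the first grid
    point from which significance is sustained through the end of the
    grid.
    """
    if axis not in ("window_length", "n_neurons"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    grid = np.asarray(grid)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and ascending")
    config = config or DecodingConfig()
    rng = np.random.default_rng(config.seed)

    accs = np.empty(grid.size)
    pvals = np.empty(grid.size)
    chance = CHANCE_16
    for i, g in enumerate(grid):
        if axis == "window_length":
            window = TimeWindow(0.0, float(g))
            n_neurons = config.n_neurons
        else:
            window = config.window
            n_neurons = int(g)
        feats = [
            session_feature_matrix(s, region, window, modality="odour")
            for s in sessions
        ]
        classes = np.unique(np.concatenate([y for _, y, _ in feats if y.size]))
        chance = 1.0 / classes.size
        runs = np.empty(n_runs)
        for r in range(n_runs):
            pop = assemble_pseudopopulation(feats, n_neurons, config.n_per_class, rng)
            runs[r] = cross_validated_accuracy(
                pop.X, pop.labels, config.n_splits, config.n_resample_runs, rng
            )
        accs[i] = runs.mean()
        diffs = runs - chance
        if np.all(diffs == 0):
            pvals[i] = 1.0
        else:
            pvals[i] = stats.wilcoxon(diffs, alternative="greater").pvalue

    significant = pvals < config.alpha / grid.size
    onset = None
    for i in range(grid.size):
        if significant[i:].all():
            onset = grid[i]
            break
    return SweepResult(
        axis=axis,
        grid=grid,
        accuracies=accs,
        p_values=pvals,
        significant=significant,
        onset=onset,
        chance=chance,
    )


def session_decoding(
    session: SessionData,
    region: str,
    config: DecodingConfig | None = None,
) -> DecodingResult:
    """Single-session decoding on all recorded neurons of a region (>= 2).

    No subsampling across sessions: the observed accuracy uses
    ``n_resample_runs`` resample runs on the session's own trials, and
    the surrogate distribution re-decodes ``n_permutations`` label
    permutations (10 resample runs each).
    """
    config = config or DecodingConfig()
    rng = np.random.default_rng(config.seed)
    X, y, ids = session_feature_matrix(
        session, region, config.window, drop_first_cycle=config.drop_first_cycle
    )
    if len(ids) < 2:
        return DecodingResult(
            accuracy=float("nan"),
            subsample_accuracies=np.empty(0),
            null_accuracies=np.empty(0),
            p=float("nan"),
            chance=float("nan"),
            config=config.to_dict(),
            skip_reason=f"region {region} has {len(ids)} neuron(s); need >= 2",
        )
    observed = cross_validated_accuracy(X, y, config.n_splits, config.n_resample_runs, rng)
    null = np.empty(config.n_permutations)
    for j in range(config.n_permutations):
        null[j] = cross_validated_accuracy(
            X, rng.permutation(y), config.n_splits, 10, rng
        )
    return DecodingResult(
        accuracy=float(observed),
        subsample_accuracies=np.array([observed]),
        null_accuracies=null,
        p=_permutation_p(null, observed),
        chance=1.0 / np.unique(y).size,
        config=config.to_dict(),
    )


def cross_modal_decoding(
    sessions: list[SessionData],
    region: str,
    direction: str,
    config: DecodingConfig | None = None,
) -> DecodingResult:
    """Train identity templates on one modality and test on the other.

    ``direction`` is ``"image_to_odour"`` or ``"odour_to_image"``.  The
    same [0, 2) s window is applied to both modalities.  Sessions without
    an image block are excluded; if none remain the result is skipped.
    """
    if direction not in ("image_to_odour", "odour_to_image"):
        raise ValueError(f"unknown direction {direction!r}")
    config = config or DecodingConfig()
    rng = np.random.default_rng(config.seed)
    both = [s for s in sessions if s.has_image_block]
    if not both:
        return DecodingResult(
            accuracy=float("nan"),
            subsample_accuracies=np.empty(0),
            null_accuracies=np.empty(0),
            p=float("nan"),
            chance=float("nan"),
            config=config.to_dict(),
            skip_reason="no session with an image block",
        )
    train_mod, test_mod = (
        ("image", "odour") if direction == "image_to_odour" else ("odour", "image")
    )
    feats_train = [
        session_feature_matrix(s, region, config.window, modality=train_mod) for s in both
    ]
    feats_test = [
        session_feature_matrix(s, region, config.window, modality=test_mod) for s in both
    ]
    class_sets = [
        set(np.unique(y)) for _, y, _ in feats_train + feats_test if y.size
    ]
    classes = np.array(sorted(set.intersection(*class_sets)))
    chance = 1.0 / classes.size

    # The per-session neuron pools of the two modalities are identical;
    # sample once and reuse the same picks for train and test.
    def one_accuracy(permute: bool) -> float:
        # identical child seeds give identical neuron picks for both builds
        seed = int(rng.integers(2**31))
        pop_tr = assemble_pseudopopulation(
            feats_train, config.n_neurons, config.n_per_class,
            np.random.default_rng(seed), classes=classes,
        )
        pop_te = assemble_pseudopopulation(
            feats_test, config.n_neurons, config.n_per_class,
            np.random.default_rng(seed), classes=classes,
        )
        train_labels = rng.permutation(pop_tr.labels) if permute else pop_tr.labels
        preds = max_correlation_classify(pop_tr.X, train_labels, pop_te.X, rng)
        return float((preds == pop_te.labels).mean())

    obs = np.array([one_accuracy(False) for _ in range(config.n_subsample_runs)])
    null = np.array([one_accuracy(True) for _ in range(config.n_permutations)])
    observed = float(obs.mean())
    return DecodingResult(
        accuracy=observed,
        subsample_accuracies=obs,
        null_accuracies=null,
        p=_permutation_p(null, observed),
        chance=chance,
        config=config.to_dict(),
    )


@dataclass
class ChemicalPerceivedResult:
    chemical_accuracies: np.ndarray
    perceived_accuracies: np.ndarray
    statistic: float
    p: float
    frac_chemical_better: float
    n_sessions_used: int
    config: dict


def chemical_vs_perceived_decoding(
    sessions: list[SessionData],
    region: str,
    config: DecodingConfig | None = None,
) -> ChemicalPerceivedResult:
    """Compare decoders trained on chemical vs perceived odour identity.

    Uses identification-phase trials only (4 per odour).  Eligible
    sessions are those in which every odour label was chosen at least
    twice.  Per subsample run, the same neuron sample is decoded twice —
    once labelled by the presented odour, once by the chosen odour label
    (2 trials per class, 2 cross-validation splits) — and the paired
    accuracy differences are tested with a two-sided signed-rank test
    across runs.
    """
    config = config or DecodingConfig(n_neurons=100, n_splits=2, n_per_class=2)
    rng = np.random.default_rng(config.seed)

    eligible = []
    for s in sessions:
        id_trials = [
            t for t in s.trials if t.modality == "odour" and t.phase == "identification"
        ]
        if not id_trials:
            continue
        stim_set = sorted({t.stimulus_id for t in id_trials})
        chosen_counts = {c: 0 for c in stim_set}
        ok = True
        for t in id_trials:
            if t.chosen_stimulus_id in chosen_counts:
                chosen_counts[t.chosen_stimulus_id] += 1
        if all(v >= config.n_per_class for v in chosen_counts.values()):
            eligible.append(s)
    if not eligible:
        raise ValueError("no session in which every odour was chosen often enough")

    feats_chem = [
        session_feature_matrix(
            s, region, config.window, phase="identification", label="stimulus_id"
        )
        for s in eligible
    ]
    feats_perc = [
        session_feature_matrix(
            s, region, config.window, phase="identification", label="chosen_stimulus_id"
        )
        for s in eligible
    ]
    class_sets = [set(np.unique(y)) - {-1} for _, y, _ in feats_chem if y.size]
    classes = np.array(sorted(set.intersection(*class_sets)))

    acc_c = np.empty(config.n_subsample_runs)
    acc_p = np.empty(config.n_subsample_runs)
    for r in range(config.n_subsample_runs):
        seed = int(rng.integers(2**31))
        pop_c = assemble_pseudopopulation(
            feats_chem, config.n_neurons, config.n_per_class,
            np.random.default_rng(seed), classes=classes,
        )
        pop_p = assemble_pseudopopulation(
            feats_perc, config.n_neurons, config.n_per_class,
            np.random.default_rng(seed), classes=classes,
        )
        acc_c[r] = cross_validated_accuracy(
            pop_c.X, pop_c.labels, config.n_splits, config.n_resample_runs, rng
        )
        acc_p[r] = cross_validated_accuracy(
            pop_p.X, pop_p.labels, config.n_splits, config.n_resample_runs, rng
        )
    diffs = acc_c - acc_p
    if np.all(diffs == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(diffs, alternative="two-sided")
    return ChemicalPerceivedResult(
        chemical_accuracies=acc_c,
        perceived_accuracies=acc_p,
        statistic=float(stat),
        p=float(p),
        frac_chemical_better=float(np.mean(diffs > 0)),
        n_sessions_used=len(eligible),
        config=config.to_dict(),
    )
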