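"""End-to-end orchestration: detect -> decode -> sparseness -> suppression ->
valence -> session statistics, with per-stage outputs and provenance.

Every stage writes its outputs (TSV/JSON) into the configured output
directory together with an echo of the configuration, so a rerun with the
same configuration and seed reproduces every numeric artifact exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import popstats, responsiveness
from .decoding import DecodingConfig, population_decoding_with_null, session_decoding
from .session import (
    IMAGE_BASELINE_WINDOW,
    IMAGE_RESPONSE_WINDOW,
    ODOUR_BASELINE_WINDOW,
    ODOUR_RESPONSE_WINDOW,
    REGIONS,
    SessionData,
    compute_rate_matrix,
    read_session,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    session_paths: list[str] = field(default_factory=list)
    output_dir: str = "odorcode-out"
    seed: int = 0
    alpha: float = 0.05
    # stage toggles
    run_detect: bool = True
    run_decode: bool = True
    run_sparseness: bool = True
    run_suppression: bool = True
    run_valence: bool = True
    run_session_stats: bool = True
    # decoding scale (desk-sized defaults; raise for full analyses)
    n_neurons: int = 50
    n_subsample_runs: int = 50
    n_permutations: int = 200
    reference_valence: list[float] | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _odour_z_matrix(session: SessionData):
    trials = session.odour_trials()
    rm = compute_rate_matrix(
        session, trials, ODOUR_RESPONSE_WINDOW, "zscored", ODOUR_BASELINE_WINDOW
    )
    labels = np.array([t.stimulus_id for t in trials])
    cycles = np.array([t.presentation_cycle for t in trials])
    ratings = np.array([t.rating or "NA" for t in trials], dtype=object)
    return rm, labels, cycles, ratings


def run_pipeline(
    config: PipelineConfig, sessions: list[SessionData] | None = None
) -> dict:
    """Run all enabled stages in dependency order; returns the report bundle.

    A stage failure aborts with the stage name and cause.  Given identical
    configuration (including seed), outputs are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(out / "config.json", config.to_dict())
    if sessions is None:
        sessions = [read_session(p) for p in config.session_paths]
    if not sessions:
        raise ValueError("no sessions to analyse")

    bundle: dict = {"config": config.to_dict(), "regions": {}}
    regions = [r for r in REGIONS if any(s.neurons_in_region(r) for s in sessions)]

    # per-session derived matrices, shared by several stages
    per_session = {}
    for s in sessions:
        try:
            per_session[s.session_id] = _odour_z_matrix(s)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage detect: session {s.session_id}: {exc}") from exc

    modulated: dict[str, dict[str, list[str]]] = {s.session_id: {} for s in sessions}

    if config.run_detect:
        rows = []
        for s in sessions:
            rm, labels, _, _ = per_session[s.session_id]
            results = responsiveness.detect_modulated_neurons(rm, labels, config.alpha)
            by_region: dict[str, list] = {r: [] for r in regions}
            region_of = {n.neuron_id: n.region for n in s.neurons}
            for res in results:
                by_region.setdefault(region_of[res.neuron_id], []).append(res)
            for r, rs in by_region.items():
                if not rs:
                    continue
                mods = [x.neuron_id for x in rs if x.modulated]
                modulated[s.session_id][r] = mods
                rows.append(
                    {
                        "session_id": s.session_id,
                        "region": r,
                        "n_neurons": len(rs),
                        "n_modulated": len(mods),
                        "fraction": len(mods) / len(rs),
                    }
                )
        detect_df = pd.DataFrame(rows)
        detect_df.to_csv(out / "detect.tsv", sep="\t", index=False)
        bundle["detect"] = rows

    if config.run_decode:
        decode_out = {}
        for i, r in enumerate(regions):
            pool = sum(len(s.neurons_in_region(r)) for s in sessions)
            n_neurons = min(config.n_neurons, pool)
            if n_neurons < 2:
                decode_out[r] = {"skip_reason": "fewer than 2 neurons"}
                continue
            dc = DecodingConfig(
                n_neurons=n_neurons,
                n_subsample_runs=config.n_subsample_runs,
                n_permutations=config.n_permutations,
                seed=config.seed + i,
            )
            try:
                res = population_decoding_with_null(sessions, r, dc)
            except Exception as exc:
                raise RuntimeError(f"stage decode: region {r}: {exc}") from exc
            decode_out[r] = {
                "accuracy": res.accuracy,
                "p": res.p,
                "chance": res.chance,
                "null_mean": float(res.null_accuracies.mean()),
                "config": res.config,
            }
        _write_json(out / "decoding.json", decode_out)
        bundle["decoding"] = decode_out

    if config.run_sparseness:
        spars_out = {}
        for r in regions:
            pairs = []
            for s in sessions:
                neurons = s.neurons_in_region(r)
                if not neurons:
                    continue
                trials = s.odour_trials()
                rm = compute_rate_matrix(
                    s, trials, ODOUR_RESPONSE_WINDOW, "raw", neurons=neurons
                )
                pairs.append((rm, np.array([t.stimulus_id for t in trials])))
            try:
                res = popstats.pooled_sparseness(pairs, region=r)
            except Exception as exc:
                raise RuntimeError(f"stage sparseness: region {r}: {exc}") from exc
            spars_out[r] = {
                "stimulus_ids": res.stimulus_ids,
                "SI": res.sparseness_indices.tolist(),
                "A": res.activity_ratios.tolist(),
                "mean_SI": res.mean_sparseness,
                "n_neurons": res.n_neurons,
            }
        _write_json(out / "sparseness.json", spars_out)
        bundle["sparseness"] = spars_out

    if config.run_suppression:
        supp_out = {}
        for r in regions:
            slopes_all, cm_all = [], []
            for s in sessions:
                ids = modulated.get(s.session_id, {}).get(r, [])
                ids = [i for i in ids if i in per_session[s.session_id][0].neuron_ids]
                if not ids:
                    continue
                rm, labels, cycles, _ = per_session[s.session_id]
                res = popstats.repetition_suppression(rm, cycles, labels, neuron_ids=ids)
                slopes_all.append(res.slopes)
                cm_all.append(res.cycle_means)
            if not slopes_all:
                supp_out[r] = {"skip_reason": "no modulated neurons"}
                continue
            slopes = np.concatenate(slopes_all)
            cm = np.vstack(cm_all)
            if slopes.size >= 2 and np.any(slopes != 0):
                stat, p = sps.wilcoxon(slopes, alternative="two-sided")
            else:
                stat, p = float("nan"), float("nan")
            supp_out[r] = {
                "n_neurons": int(slopes.size),
                "median_slope": float(np.median(slopes)),
                "p": float(p),
                "cycle_mean_z": cm.mean(axis=0).tolist(),
            }
        _write_json(out / "suppression.json", supp_out)
        bundle["suppression"] = supp_out

    if config.run_valence:
        val_out = {}
        ref = (
            np.asarray(config.reference_valence, dtype=float)
            if config.reference_valence is not None
            else None
        )
        for r in regions:
            contrasts = []
            pop_means = []
            for s in sessions:
                ids = modulated.get(s.session_id, {}).get(r, [])
                rm, labels, _, ratings = per_session[s.session_id]
                ids = [i for i in ids if i in rm.neuron_ids]
                if not ids:
                    continue
                rated = ratings != "NA"
                sub = rm.subset_neurons(ids)
                res = popstats.valence_analysis(
                    dataclasses.replace(
                        sub,
                        values=sub.values[:, rated],
                        trial_idxs=[t for t, m in zip(sub.trial_idxs, rated) if m],
                    ),
                    labels[rated],
                    ratings[rated],
                )
                contrasts.append(res.contrasts)
                if ref is not None:
                    odour_ids = sorted(set(labels[rated].tolist()) - {0})
                    pop_means.append(
                        [
                            sub.values[:, rated][:, labels[rated] == k].mean()
                            for k in odour_ids
                        ]
                    )
            if not contrasts:
                val_out[r] = {"skip_reason": "no modulated neurons"}
                continue
            call = np.concatenate(contrasts)
            if call.size >= 2 and np.any(call != 0):
                stat, p = sps.wilcoxon(call, alternative="two-sided")
            else:
                stat, p = float("nan"), float("nan")
            entry = {
                "n_neurons": int(call.size),
                "mean_contrast": float(call.mean()),
                "p": float(p),
            }
            if ref is not None and pop_means:
                pm = np.mean(np.array(pop_means), axis=0)
                rho, p_rho = popstats.spearman_permutation(
                    pm, ref, n_perm=2000, seed=config.seed
                )
                entry["spearman_r"] = rho
                entry["spearman_p"] = p_rho
            val_out[r] = entry
        _write_json(out / "valence.json", val_out)
        bundle["valence"] = val_out

    if config.run_session_stats:
        stats_out = {}
        for i, r in enumerate(regions):
            pvals = []
            dec_accs, beh_accs = [], []
            for s in sessions:
                dc = DecodingConfig(
                    n_subsample_runs=1,
                    n_resample_runs=10,
                    n_permutations=config.n_permutations,
                    seed=config.seed + i,
                )
                res = session_decoding(s, r, dc)
                if res.skipped:
                    continue
                pvals.append(res.p)
                id_trials = [
                    t
                    for t in s.odour_trials()
                    if t.phase == "identification" and t.correct is not None
                ]
                if id_trials:
                    dec_accs.append(res.accuracy)
                    beh_accs.append(np.mean([t.correct for t in id_trials]))
            if not pvals:
                stats_out[r] = {"skip_reason": "no session with >= 2 neurons"}
                continue
            k, p_binom = popstats.session_significance_count(
                np.array(pvals), alpha=config.alpha
            )
            entry = {
                "n_sessions": len(pvals),
                "n_significant": k,
                "binomial_p": p_binom,
            }
            if len(dec_accs) >= 3 and np.unique(dec_accs).size > 1 and np.unique(beh_accs).size > 1:
                rho, p_rho = popstats.behaviour_decoding_correlation(
                    np.array(dec_accs), np.array(beh_accs), n_perm=2000, seed=config.seed
                )
                entry["behaviour_correlation_r"] = rho
                entry["behaviour_correlation_p"] = p_rho
            stats_out[r] = entry
        _write_json(out / "session_stats.json", stats_out)
        bundle["session_stats"] = stats_out

    _write_json(out / "bundle.json", bundle)
    return bundle


def render_report(bundle: dict, output_dir: str | Path) -> list[Path]:
    """Render one figure panel per completed stage from the bundle.

    Chance lines are drawn at 1/n_classes for decoding and at alpha for
    the selection fraction; no numbers are recomputed here.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if bundle.get("detect"):
        df = pd.DataFrame(bundle["detect"])
        frac = df.groupby("region")["fraction"].mean()
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(frac.index, 100 * frac.values, color="firebrick")
        ax.axhline(100 * bundle["config"]["alpha"], ls="--", c="k", lw=1)
        ax.set_ylabel("odour-modulated neurons (%)")
        fig.tight_layout()
        p = out / "modulated_fractions.png"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    if bundle.get("decoding"):
        items = [
            (r, d) for r, d in bundle["decoding"].items() if "accuracy" in d
        ]
        if items:
            fig, ax = plt.subplots(figsize=(4, 3))
            xs = np.arange(len(items))
            ax.bar(xs, [100 * d["accuracy"] for _, d in items], color="steelblue")
            for x, (_, d) in zip(xs, items):
                ax.plot(x, 100 * d["null_mean"], "o", c="grey")
            chance = items[0][1].get("chance")
            if chance:
                ax.axhline(100 * chance, ls="--", c="k", lw=1)
            ax.set_xticks(xs, [r for r, _ in items])
            ax.set_ylabel("decoding accuracy (%)")
            fig.tight_layout()
            p = out / "decoding_accuracy.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)

    if bundle.get("sparseness"):
        items = [(r, d) for r, d in bundle["sparseness"].items() if "mean_SI" in d]
        if items:
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.bar([r for r, _ in items], [d["mean_SI"] for _, d in items], color="seagreen")
            ax.set_ylabel("sparseness index")
            ax.set_ylim(0, 1)
            fig.tight_layout()
            p = out / "sparseness.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)

    if bundle.get("suppression"):
        fig, ax = plt.subplots(figsize=(4, 3))
        any_curve = False
        for r, d in bundle["suppression"].items():
            if "cycle_mean_z" in d:
                ax.plot(range(1, 9), d["cycle_mean_z"], marker="o", label=r)
                any_curve = True
        if any_curve:
            ax.set_xlabel("presentation cycle")
            ax.set_ylabel("mean z-scored rate")
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = out / "suppression.png"
            fig.savefig(p)
            written.append(p)
        plt.close(fig)

    if bundle.get("valence"):
        items = [(r, d) for r, d in bundle["valence"].items() if "mean_contrast" in d]
        if items:
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.bar([r for r, _ in items], [d["mean_contrast"] for _, d in items], color="orchid")
            ax.axhline(0, c="k", lw=1)
            ax.set_ylabel("liked - disliked (z)")
            fig.tight_layout()
            p = out / "valence_contrast.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)

    return written
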