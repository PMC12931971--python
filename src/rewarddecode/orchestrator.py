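"""End-to-end study runner: simulate -> features -> decode -> validate -> interpret.

`run_study` composes the full pipeline on simulated (or pre-built) sessions
and returns a single report holding the per-region accuracy/AUC table, the
label-shuffle permutation results with Bonferroni correction, the balanced
two-way ANOVA over region x architecture, and the Shapley-based feature
rankings with the cross-repeat consistent set per region.  Every random draw
descends from the run seed, so a config reproduces its report exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import decode as dec
from . import inference_stats as infer
from . import interpretation as interp
from .core_io import Session, write_session
from .preprocess import apply_cascade
from .spike_features import FeatureConfig, build_feature_matrix, FEATURE_NAMES
from .synthetic_data import (
    DEFAULT_GRADIENT,
    EffectGradient,
    REGION_PRESETS,
    RegionArchetype,
    TaskConfig,
    simulate_study,
)

__all__ = ["RunConfig", "StudyReport", "run_study", "make_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full study run (desk scale by default)."""

    seed: int = 0
    n_neurons: int = 100
    n_sessions: int = 2
    task: TaskConfig = field(default_factory=TaskConfig)
    archetypes: Mapping[str, RegionArchetype] = field(
        default_factory=lambda: dict(REGION_PRESETS)
    )
    gradient: EffectGradient = field(default_factory=lambda: DEFAULT_GRADIENT)
    architectures: tuple[str, ...] = dec.GBT_ROSTER
    repeat_seeds: tuple[int, ...] = (0, 1, 2)
    n_iter: int = 0          # tuning candidates per architecture (0 = defaults)
    n_perm: int = 1000
    alpha: float = 0.05
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    shap_top_k: int = 9
    aggregate: str = "pool"  # permutation across repeats: "pool" | "average"


@dataclass
class StudyReport:
    config: RunConfig
    summary: pd.DataFrame            # region x architecture accuracy/AUC table
    permutation: pd.DataFrame        # observed accuracy, p, corrected p
    anova: infer.AnovaTable | None
    rankings: dict[str, interp.FeatureRanking]
    consistent_features: dict[str, list[str]]
    strategies: dict[str, pd.DataFrame]
    probabilities: pd.DataFrame
    evals: list[dec.ModelEval] = field(default_factory=list)

    def region_order(self) -> list[str]:
        """Regions ordered by mean accuracy (best first)."""
        means = self.summary.groupby("region")["mean_accuracy"].mean()
        return list(means.sort_values(ascending=False).index)

    def to_text(self) -> str:
        lines = ["# Study report", "", "## Decoding performance", ""]
        lines.append(self.summary.to_string(index=False, float_format="%.4f"))
        lines += ["", "## Permutation tests (Bonferroni corrected)", ""]
        lines.append(self.permutation.to_string(index=False, float_format="%.4f"))
        if self.anova is not None:
            lines += ["", "## Two-way ANOVA (region x architecture)", ""]
            lines.append(self.anova.table.to_string(float_format="%.4f"))
        lines += ["", "## Consistent top features per region", ""]
        for region, feats in sorted(self.consistent_features.items()):
            lines.append(f"{region}: {', '.join(feats) if feats else '(none)'}")
        lines += ["", "## Predicted-probability summary", ""]
        lines.append(self.probabilities.to_string(index=False, float_format="%.3f"))
        return "\n".join(lines) + "\n"

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.permutation.to_csv(out / "permutation.csv", index=False)
        if self.anova is not None:
            self.anova.table.to_csv(out / "anova.csv")
        self.probabilities.to_csv(out / "probabilities.csv", index=False)
        with open(out / "consistent_features.json", "w", encoding="utf-8") as fh:
            json.dump(self.consistent_features, fh, indent=1)
        with open(out / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(self.to_text())


def _region_interpretation(
    matrix: pd.DataFrame,
    evals: list[dec.ModelEval],
    k: int,
) -> tuple[interp.FeatureRanking | None, list[str], pd.DataFrame, dec.ModelEval]:
    """Rank features across the best architecture's repeats for one region."""
    best = interp.select_best_instance(evals)
    same_arch = [e for e in evals if e.architecture == best.architecture]
    attributions = []
    for e in sorted(same_arch, key=lambda e: e.repeat):
        X_raw = matrix.loc[e.test_index, [c for c in FEATURE_NAMES]]
        X = apply_cascade(e.state, X_raw)
        attributions.append(interp.attribute(e.model, X, X.columns.tolist()))
    ranking = interp.rank_features(attributions, k=k)
    consistent = ranking.consistent
    strategy = interp.strategy_report(consistent)
    return ranking, consistent, strategy, best


def run_study(
    config: RunConfig = RunConfig(),
    sessions_by_region: Mapping[str, Sequence[Session]] | None = None,
) -> StudyReport:
    """Run the full pipeline; see module docstring.

    ``sessions_by_region`` bypasses simulation when real or pre-built sessions
    are supplied.
    """
    if sessions_by_region is None:
        sessions_by_region = simulate_study(
            archetypes=config.archetypes,
            gradient=config.gradient,
            n_neurons=config.n_neurons,
            task_config=config.task,
            seed=config.seed,
            n_sessions=config.n_sessions,
        )

    all_evals: list[dec.ModelEval] = []
    matrices: dict[str, pd.DataFrame] = {}
    for region in sorted(sessions_by_region):
        matrix = build_feature_matrix(
            sessions_by_region[region], config.feature_config
        )
        matrices[region] = matrix
        all_evals.extend(
            dec.run_repeats(
                matrix,
                architectures=config.architectures,
                seeds=config.repeat_seeds,
                n_iter=config.n_iter,
                region=region,
            )
        )

    summary = dec.summarize_evals(all_evals)

    # permutation tests per region x architecture, repeats pooled (or averaged)
    m = len(sessions_by_region) * len(config.architectures)
    perm_rows = []
    perm_seed_root = np.random.SeedSequence(entropy=config.seed, spawn_key=(997,))
    seeds_iter = iter(perm_seed_root.generate_state(4 * m))
    by_cond: dict[tuple[str, str], list[dec.ModelEval]] = {}
    for e in all_evals:
        by_cond.setdefault((e.region, e.architecture), []).append(e)
    for (region, arch), evs in sorted(by_cond.items()):
        pred = np.concatenate([e.predictions for e in evs])
        y = np.concatenate([e.y_true for e in evs])
        res = infer.permutation_test(
            pred,
            y,
            n_perm=config.n_perm,
            seed=int(next(seeds_iter)) % (2**31),
            correction_factor=m,
        )
        if config.aggregate == "average":
            obs = float(np.mean([e.accuracy for e in evs]))
        else:
            obs = res.observed_accuracy
        perm_rows.append(
            {
                "region": region,
                "architecture": arch,
                "observed_accuracy": obs,
                "p_uncorrected": res.p_uncorrected,
                "p_corrected": res.p_corrected,
                "significant": res.p_corrected < config.alpha,
            }
        )
    permutation = pd.DataFrame(perm_rows)

    anova = None
    if len(config.repeat_seeds) >= 2 and len(config.architectures) >= 2:
        scores = {
            (region, arch): [e.accuracy for e in sorted(evs, key=lambda e: e.repeat)]
            for (region, arch), evs in by_cond.items()
        }
        anova = infer.two_way_anova(scores)

    rankings: dict[str, interp.FeatureRanking] = {}
    consistent: dict[str, list[str]] = {}
    strategies: dict[str, pd.DataFrame] = {}
    best_instances: list[dec.ModelEval] = []
    for region in sorted(sessions_by_region):
        evs = [e for e in all_evals if e.region == region]
        ranking, cons, strategy, best = _region_interpretation(
            matrices[region], evs, config.shap_top_k
        )
        rankings[region] = ranking
        consistent[region] = cons
        strategies[region] = strategy
        best_instances.append(best)

    probabilities = interp.probability_summary(best_instances)

    return StudyReport(
        config=config,
        summary=summary,
        permutation=permutation,
        anova=anova,
        rankings=rankings,
        consistent_features=consistent,
        strategies=strategies,
        probabilities=probabilities,
        evals=all_evals,
    )


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, list[Session]]:
    """Write a tiny deterministic two-region session set for tests and docs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = simulate_study(
        archetypes={"dCA1": REGION_PRESETS["dCA1"], "M1": REGION_PRESETS["M1"]},
        gradient=DEFAULT_GRADIENT,
        n_neurons=10,
        task_config=TaskConfig(n_trials=60),
        seed=seed,
        n_sessions=1,
    )
    for region, sess_list in sessions.items():
        for s in sess_list:
            write_session(s, out)
    return sessions
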