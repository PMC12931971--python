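"""Shared fixtures.

The hierarchy and null studies are expensive (thousands of simulated neurons),
so they are computed once per test session and shared between the module-level
property tests and the end-to-end acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import rewarddecode as rd
from rewarddecode import decode as dec
from rewarddecode import inference_stats as infer

REGIONS = ("M1", "M2", "PPC", "LEC", "dCA1", "vCA1")

# desk-scale study conditions: 100 neurons/region over 2 sessions of 120
# trials, reduced roster (LightGBM), 2 evaluation repeats
DESK_TASK = rd.TaskConfig(n_trials=120)
DESK_NEURONS = 100
HIERARCHY_SEEDS = (0, 1, 2, 3, 4)
NULL_SEEDS = tuple(range(100, 110))
NULL_NEURONS = 60


@pytest.fixture(scope="session")
def hierarchy_runs():
    """Per study seed: region -> mean held-out accuracy, plus the dCA1/LEC
    matrices and 3-repeat evaluations needed for mechanism recovery."""
    runs = []
    for seed in HIERARCHY_SEEDS:
        sessions = rd.simulate_study(
            n_neurons=DESK_NEURONS, task_config=DESK_TASK, seed=seed, n_sessions=2
        )
        accs = {}
        mech = {}
        for region in REGIONS:
            matrix = rd.build_feature_matrix(sessions[region])
            evals = dec.run_repeats(
                matrix, architectures=("lightgbm",), seeds=(0, 1), n_iter=0,
                region=region,
            )
            accs[region] = float(np.mean([e.accuracy for e in evals]))
            if region in ("dCA1", "LEC") and seed in (0, 1, 2):
                mech[region] = {
                    "matrix": matrix,
                    "evals": dec.run_repeats(
                        matrix, architectures=("lightgbm",), seeds=(0, 1, 2),
                        n_iter=0, region=region,
                    ),
                }
        runs.append({"seed": seed, "accuracy": accs, "mechanism": mech})
    return runs


@pytest.fixture(scope="session")
def null_runs():
    """Zero-effect studies: per seed and region, the Bonferroni-corrected
    permutation p-value of the pooled test-set predictions."""
    rows = []
    m = len(REGIONS)  # regions x 1 architecture
    for seed in NULL_SEEDS:
        sessions = rd.simulate_study(
            gradient=rd.EffectGradient.zeros(),
            n_neurons=NULL_NEURONS,
            task_config=DESK_TASK,
            seed=seed,
            n_sessions=2,
        )
        for region in REGIONS:
            matrix = rd.build_feature_matrix(sessions[region])
            evals = dec.run_repeats(
                matrix, architectures=("lightgbm",), seeds=(0, 1), n_iter=0,
                region=region,
            )
            pred = np.concatenate([e.predictions for e in evals])
            y = np.concatenate([e.y_true for e in evals])
            res = infer.permutation_test(
                pred, y, n_perm=1000, seed=seed * 7 + hash(region) % 1000,
                correction_factor=m,
            )
            rows.append(
                {"seed": seed, "region": region, "p_corrected": res.p_corrected}
            )
    return rows
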