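"""Shared configuration for the numbered analysis drivers.

The showcase cohort carries 50 planted gene-drug effects at population
|r| ~ 0.95 (the same conditions as the calibration study in
06_fdr_calibration.py), so the association screen and the networks downstream
have true signal to recover.
"""

from pathlib import Path

import numpy as np

from nbscreen.pipeline_io import RunConfig
from nbscreen.synthetic_cohort import (
    CohortConfig,
    planted_pairs_for_target_r,
    with_planted_pairs,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def run_config() -> RunConfig:
    base = CohortConfig()
    pairs = planted_pairs_for_target_r(
        base, n_pairs=50, target_r=0.95, rng=np.random.default_rng(SEED)
    )
    return RunConfig(cohort=with_planted_pairs(base, pairs))
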