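"""Shared study setup for the analysis scripts.

One synthetic cohort of 41 overnight recordings (the default simulator
configuration), split into a 20-night training group and a 21-night test
group, regenerated deterministically by every script so the steps are
independently re-runnable.
"""

from pathlib import Path

from somnoscore.epoch_data import clean_default_runs
from somnoscore.simulate import SimulationConfig, generate_cohort

SEED = 1
N_TRAINING, N_TEST = 20, 21
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_cohort():
    """(cleaned activity, hypnogram) pairs: 20 training then 21 test nights."""
    cfg = SimulationConfig(n_participants=N_TRAINING + N_TEST, seed=SEED)
    cohort = [(clean_default_runs(a)[0], h) for a, h in generate_cohort(cfg)]
    return cohort[:N_TRAINING], cohort[N_TRAINING:]
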