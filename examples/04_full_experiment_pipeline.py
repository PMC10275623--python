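"""End-to-end experiment: stimulus export, response log, group statistics.

Part 1 mirrors a human study in miniature: export a subject's WAV stimuli
plus manifest, simulate a response log, and ingest it back into (Psi, y).
Part 2 runs a ten-subject simulated ideal cohort through the full
pipeline and prints the per-target group summary (mean ± sd r, Fisher-z
t-test), the same reporting shape used for real cohorts.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from revcorr import (
    ExperimentConfig,
    build_session_stimuli,
    ingest_responses,
    reconstruct,
    run_full_pipeline,
    simulate_cohort,
)

# --- Part 1: the human-experiment plumbing, scaled down ----------------
config = ExperimentConfig(trials_per_block=10, blocks_per_target=2,
                          targets=["buzzing-like"], master_seed=7)
with tempfile.TemporaryDirectory() as tmp:
    manifest = build_session_stimuli(config, "S01", tmp)
    print(f"exported {len(manifest)} stimuli + manifest for S01")

    rng = np.random.default_rng(0)
    log = pd.DataFrame({
        "stimulus_id": manifest["stimulus_id"],
        "response": rng.choice(["yes", "no"], len(manifest)),
    })
    session = ingest_responses(Path(tmp) / "S01_manifest.csv", log)
    psi = session.psi["buzzing-like"]
    rec = reconstruct(psi, session.y["buzzing-like"], subject_id="S01",
                      target_label="buzzing-like")
    print("ingested session: Psi", psi.shape, "-> x_hat", np.round(rec.x_hat, 1))

# --- Part 2: a simulated ten-subject cohort at full scale --------------
config = ExperimentConfig(master_seed=1)  # 2 targets, 2 x 100 trials each
sessions = simulate_cohort(config, "ideal", n_subjects=10, rng=3)
out = run_full_pipeline(config, sessions)
for label, test in out["group_tests"].items():
    print(f"{label:13s}: {test.format()}")
print("(a real study substitutes human response logs for the simulated cohort)")
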