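"""Shared helpers for the numbered analysis scripts.

The scripts operate on the default synthetic cohort written by
``01_simulate.py`` under ``results/synthetic_cohort/``; if it is not
there yet, it is generated on the fly (seed 1) so every script can run
standalone.
"""

from __future__ import annotations

from pathlib import Path

import cnvpheno.io as pio
from cnvpheno.simulate import GeneratorConfig, generate_study

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "synthetic_cohort"
SEED = 1


def ensure_cohort() -> dict[str, Path]:
    """Write (if needed) and return the synthetic-cohort input files."""
    marker = COHORT_DIR / pio.STUDY_FILES["generator_config"]
    if not marker.exists():
        study = generate_study(GeneratorConfig(), seed=SEED)
        pio.write_study(study, COHORT_DIR)
    return {k: COHORT_DIR / v for k, v in pio.STUDY_FILES.items()}
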