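"""Shared study conditions for the analysis scripts.

One synthetic VA-like cohort of 10,000 patients: ~90% male, ~18% black,
age ~N(55, 18) truncated to the grid, Scr log-normal (median 0.95 mg/dL),
with mutually exclusive single-parameter drift at total probability 0.3
split equally across age, race, gender, and creatinine.
"""

from pathlib import Path

from egfr_discordance import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_CSV = RESULTS / "cohort.csv"

STUDY_CONFIG = SimulationConfig(
    n_patients=10_000,
    seed=42,
    p_age=0.075,
    p_race=0.075,
    p_gender=0.075,
    p_scr=0.075,
)
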