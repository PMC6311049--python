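"""Generate the synthetic drifted cohort and its ground truth.

Writes results/cohort.csv (as-stored records + automated eGFR),
results/cohort_truth.csv (injected changes), and a provenance JSON.
"""

from common import COHORT_CSV, RESULTS, STUDY_CONFIG

from egfr_discordance import emit_cohort
from egfr_discordance.simulate import simulate_cohort


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    then, automated, now, truths = simulate_cohort(STUDY_CONFIG)
    emit_cohort(now, automated, COHORT_CSV, truths=truths, config=STUDY_CONFIG)
    n_drift = sum(1 for t in truths if t.changed_parameters)
    print(f"simulated {STUDY_CONFIG.n_patients} patients (seed {STUDY_CONFIG.seed})")
    print(f"  {n_drift} records drifted "
          f"({100 * n_drift / STUDY_CONFIG.n_patients:.1f}%)")
    print(f"  wrote {COHORT_CSV}")


if __name__ == "__main__":
    main()
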