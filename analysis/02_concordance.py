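"""Screen automated vs. retrospectively calculated eGFR and summarise
agreement: discordance rate, Bland–Altman, stage matrix, kappa.

Reads results/cohort.csv; writes results/concordance_summary.json and the
Bland–Altman point cloud CSV.
"""

import json

import pandas as pd

from common import COHORT_CSV, RESULTS

from egfr_discordance import bland_altman, cohen_kappa, stage_agreement
from egfr_discordance.cohort import read_cohort, rows_from_frame
from egfr_discordance.concordance import build_pairs


def main() -> None:
    rows = rows_from_frame(read_cohort(COHORT_CSV))
    pairs = build_pairs(rows)
    n_disc = sum(not p.concordant_value for p in pairs)
    matrix, pct = stage_agreement(pairs)
    kappa = cohen_kappa(matrix)
    ba = bland_altman(pairs)

    summary = {
        "n_pairs": len(pairs),
        "n_discordant": n_disc,
        "percent_discordant": round(100 * n_disc / len(pairs), 2),
        "percent_stage_agreement": round(pct, 2),
        "kappa_x100": round(kappa.kappa_x100, 2),
        "kappa_ci_x100": [round(v, 2) for v in kappa.ci_x100],
        "bland_altman": {
            "mean_difference": round(ba.mean_difference, 3),
            "loa": [round(ba.loa_lower, 2), round(ba.loa_upper, 2)],
        },
        "stage_matrix": {"labels": list(matrix.labels),
                         "counts": matrix.counts.tolist()},
    }
    (RESULTS / "concordance_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    pd.DataFrame(ba.points, columns=["mean_egfr", "difference"]).to_csv(
        RESULTS / "bland_altman_points.csv", index=False)

    print(f"{len(pairs)} pairs; {n_disc} discordant "
          f"({summary['percent_discordant']}%) at whole-number screening")
    print(f"stage agreement {summary['percent_stage_agreement']}%, "
          f"kappa {summary['kappa_x100']} "
          f"({summary['kappa_ci_x100'][0]}-{summary['kappa_ci_x100'][1]})")
    print(f"Bland–Altman mean difference {summary['bland_altman']['mean_difference']}, "
          f"LoA {summary['bland_altman']['loa']}")


if __name__ == "__main__":
    main()
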