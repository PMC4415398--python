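"""Group stage: merge lambda, NDS and age; apply the exclusion rules;
run the three-way inference (NDS~LA at alpha 0.05; NDS~age and LA~age
at the Bonferroni-corrected alpha 0.025).

Reads results/la.csv, results/nds.csv, results/sim/cohort_truth.csv;
writes results/cohort.csv and results/associations.csv.  This driver
reuses the same library calls as the one-shot `lapref run` pipeline,
but over the staged CSV artifacts.
"""

from pathlib import Path

import pandas as pd

from lapref.group_inference import build_cohort_table, correlate_nds_la, regress_on_age
from lapref.valuation import LossAversionResult
from lapref.fmri_nds import NDSResult

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    truth = pd.read_csv(ROOT / "sim" / "cohort_truth.csv")
    la = pd.read_csv(ROOT / "la.csv")
    nds = pd.read_csv(ROOT / "nds.csv")
    la_results = [
        LossAversionResult(r.subject_id, r.s_minus, r.s_plus, r.lam) for r in la.itertuples()
    ]
    nds_results = [
        NDSResult(r.subject_id, r.nds, int(r.n_voxels_used), 1.96, "left")
        for r in nds.itertuples()
    ]
    table = build_cohort_table(truth, la_results, nds_results)
    table.to_csv(ROOT / "cohort.csv", index=False, float_format="%.6f")

    assoc = {
        "nds_la": correlate_nds_la(table),
        "nds_age": regress_on_age(table, "nds"),
        "la_age": regress_on_age(table, "lam"),
    }
    rows = []
    for a in assoc.values():
        rows.append(
            {
                "name": a.name, "estimate": a.estimate, "test_statistic": a.test_statistic,
                "p": a.p, "n_used": a.n_used, "alpha": a.alpha, "significant": a.significant,
            }
        )
        verdict = "significant" if a.significant else "not significant"
        print(
            f"{a.name}: estimate={a.estimate:.4f}, stat={a.test_statistic:.2f}, "
            f"p={a.p:.4g} at alpha={a.alpha} -> {verdict} (n={a.n_used}, "
            f"excluded: {a.excluded or 'none'})"
        )
    pd.DataFrame(rows).to_csv(ROOT / "associations.csv", index=False, float_format="%.6g")
    print(f"wrote {ROOT/'cohort.csv'} and {ROOT/'associations.csv'}")


if __name__ == "__main__":
    main()
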