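"""Behavioral stage: keypress logs -> (K, H) valuation points -> limb
curve fits -> per-subject lambda = |s-/s+| with cohort outlier flags.

Reads results/sim/keypress.csv; writes results/valuation.csv and
results/la.csv.
"""

from pathlib import Path

import pandas as pd

from lapref import keypress_analysis as ka
from lapref.valuation import flag_outliers, subject_loss_aversion

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    events = ka.read_keypress_csv(ROOT / "sim" / "keypress.csv")
    by_subject: dict[str, list] = {}
    for e in events:
        by_subject.setdefault(e.subject_id, []).append(e)

    val_frames, rows = [], []
    for sid, evs in sorted(by_subject.items()):
        sess = ka.build_session(sid, evs)
        vals = ka.category_valuation(sess)
        val_frames.append(ka.valuations_to_frame(sid, vals))
        res = subject_loss_aversion(vals, subject_id=sid)
        rows.append(
            {"subject_id": sid, "s_minus": res.s_minus, "s_plus": res.s_plus, "lam": res.lam}
        )
    pd.concat(val_frames, ignore_index=True).to_csv(
        ROOT / "valuation.csv", index=False, float_format="%.6f"
    )
    la = pd.DataFrame(rows)
    la["outlier"] = flag_outliers(la["lam"].to_numpy())
    la.to_csv(ROOT / "la.csv", index=False, float_format="%.6f")

    inc = la[~la.outlier]
    se = inc.lam.std(ddof=1) / len(inc) ** 0.5
    print(
        f"{len(la)} subjects; {int(la.outlier.sum())} lambda outliers flagged by the "
        f"2-SD rule; included-cohort lambda = {inc.lam.mean():.2f} +/- {se:.2f} (mean +/- SE)"
    )
    print(f"wrote {ROOT/'valuation.csv'} and {ROOT/'la.csv'}")


if __name__ == "__main__":
    main()
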