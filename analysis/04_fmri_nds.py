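"""Imaging stage: per-subject GLM on the simulated voxel tables, the
negative-minus-positive contrast, and NDS sampling over supra-threshold
left VS/NAc voxels (z > 1.96).

Reads results/sim/voxels_*.tsv + events.tsv; writes results/nds.csv.
"""

from pathlib import Path

import pandas as pd

from lapref import fmri_nds as fn
from lapref import task_design as td

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    timeline = td.read_events_tsv(ROOT / "sim" / "events.tsv")
    rows = []
    for path in sorted((ROOT / "sim").glob("voxels_*.tsv")):
        vox = fn.read_voxel_tsv(path)
        sid = path.stem.replace("voxels_", "")
        res = fn.subject_nds(vox, timeline, roi="left", z_threshold=1.96, subject_id=sid)
        rows.append(
            {
                "subject_id": sid,
                "nds": res.nds,
                "n_voxels_used": res.n_voxels_used,
                "valid": res.valid,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "nds.csv", index=False, float_format="%.6f")
    ok = df[df.valid]
    print(
        f"{len(df)} subjects; {len(ok)} with valid imaging "
        f"(mean {ok.n_voxels_used.mean():.1f} supra-threshold left VS/NAc voxels); "
        f"NDS range {ok.nds.min():.3f}-{ok.nds.max():.3f}"
    )
    print(f"wrote {ROOT/'nds.csv'}")


if __name__ == "__main__":
    main()
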