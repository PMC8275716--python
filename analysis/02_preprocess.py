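#!/usr/bin/env python
"""Preprocess every session: dF/F, normalized beta / high-gamma wavelet
power, per-unit firing-rate matrices, and the ISI quality screen.

Derived matrices are stored back into each container under /derived; the QC
table goes to results/unit_qc.csv.
"""

from pathlib import Path

import pandas as pd

from mtsig import read_session
from mtsig.pipeline import preprocess_session, write_features

ROOT = Path(__file__).resolve().parents[1] / "results"
SESSIONS = Path(__file__).resolve().parents[1] / "scratch" / "sessions"


def main() -> None:
    qc = []
    for path in sorted(SESSIONS.glob("*.h5")):
        rec = read_session(path)
        feat = preprocess_session(rec)
        write_features(feat, path)
        qc.append(feat.qc)
        n_single = feat.qc.is_single_unit.sum()
        print(f"{rec.mouse_id}: {len(feat.dff)} odors, "
              f"{n_single}/{len(feat.qc)} units pass the ISI criterion, "
              f"max violation {feat.qc.isi_violation_pct.max():.3f}%")
    pd.concat(qc).to_csv(ROOT / "unit_qc.csv", index=False)
    print(f"wrote {ROOT / 'unit_qc.csv'}")


if __name__ == "__main__":
    main()
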