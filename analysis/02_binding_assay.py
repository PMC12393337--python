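#!/usr/bin/env python
"""Run the end-to-end synthetic apo/holo binding assay.

Simulates in-cell nitrile spectra for the four probe variants plus the
attachment-site knockout control, processes and fits each, and tabulates the
apo -> holo frequency shifts with binding calls.  Expected outcome: the two
probes near the chromophore pocket (F92, F96) shift by ~+14.9 and ~+6.3 cm^-1
and are called bound; the distant probes (F28, F62) and the C69A control are
called unshifted.
"""

import json
from pathlib import Path

from cnprobe.workflow import AssayConfig, run_binding_assay

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = run_binding_assay(AssayConfig(seed=SEED))
    report.table.to_csv(OUT / "assay_report.csv", index=False)
    (OUT / "assay_report.json").write_text(
        json.dumps({"meta": report.meta,
                    "rows": report.table.to_dict(orient="records")},
                   indent=2, default=str) + "\n")
    print(report.table[["variant", "condition_b", "shift_cm1", "shift_se_cm1",
                        "binding_call"]].to_string(index=False))
    called = report.table.loc[report.table["binding_call"], "variant"].tolist()
    print(f"\nbinding detected for: {called}")


if __name__ == "__main__":
    main()
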