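"""Staged Monte Carlo calibration of the full model.

Runs the three-stage search (GSK3 switch, SMAD module, GLI1/SNAIL1 relay)
plus the polish walk against the packaged constraint files, reports the
per-stage fit quality, and writes the calibrated parameter set.  The
packaged ``params_full_calibrated.json`` is the output of this script.

Usage: python analysis/02_calibrate.py [seed] [n_starts] [n_iters]
"""

import json
import sys
from pathlib import Path

from snailrelay.calibrate import calibrate_full
from snailrelay.io import RunRecord

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
n_starts = int(sys.argv[2]) if len(sys.argv) > 2 else 12
n_iters = int(sys.argv[3]) if len(sys.argv) > 3 else 1200

rec = RunRecord(command=" ".join(sys.argv), seed=seed,
                config={"n_starts": n_starts, "n_iters": n_iters})
params, report = calibrate_full(seed=seed, n_starts=n_starts,
                                n_iters=n_iters, verbose=True)
out = OUT / f"params_full_calibrated_seed{seed}.json"
params.to_json(out)
rec.finish(out)
rec.to_json(OUT / f"calibration_seed{seed}.run.json")
print(json.dumps(report, indent=1, default=float))
print(f"wrote {out}")
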