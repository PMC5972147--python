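"""Model discrimination: the SMAD-only pathway cannot make two SNAIL1 waves.

Runs the multi-start Metropolis search for the SMAD-only variant twice —
once against the transient nuclear-pSMAD2/3 shape alone, once against
pSMAD plus the two-wave SNAIL1 shape — and reports whether each
constraint set is satisfiable.  The expected outcome is pSMAD yes,
two-wave no; the full relay model passes both (checked in the test
suite with the calibrated parameter set).

Usage: python analysis/03_falsify_smad_only.py [seed] [starts] [iters]
"""

import json
import sys
from pathlib import Path

from snailrelay.calibrate import data_path, design_center
from snailrelay.io import RunRecord, dump_json
from snailrelay.search import SearchConfig, falsify_two_wave
from snailrelay.targets import load_targets

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 7
starts = int(sys.argv[2]) if len(sys.argv) > 2 else 20
iters = int(sys.argv[3]) if len(sys.argv) > 3 else 2000

rec = RunRecord(command=" ".join(sys.argv), seed=seed)
report = falsify_two_wave(
    design_center(),
    load_targets(data_path("targets_psmad_continuous.json")),
    load_targets(data_path("targets_twowave_snail1.json")),
    SearchConfig(n_starts=starts, n_iters=iters, seed=seed),
)
out = OUT / "falsification_smad_only.json"
dump_json({"kind": "falsification_report", **report}, out)
rec.finish(out)
rec.to_json(OUT / "falsification.run.json")
print(json.dumps(report, indent=1, default=float))
if report["conclusive"]:
    verdict = ("SMAD-only fits pSMAD" if report["pSMAD_fit_pass"] else
               "SMAD-only FAILS pSMAD (unexpected)")
    verdict += (", and fits two-wave (unexpected)" if report["two_wave_fit_pass"]
                else ", but cannot fit the two-wave SNAIL1 shape")
    print(verdict)
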