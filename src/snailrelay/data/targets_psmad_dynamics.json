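{
 "schema_version": 1,
 "kind": "fit_targets",
 "note": "nuclear pSMAD2/3 fold-change shape, continuous and pulsed TGF-beta",
 "targets": [
  {
   "species": "pSMAD_nuc",
   "time_h": 12,
   "context": "continuous",
   "value": 3.0,
   "kind": "ge",
   "tolerance": 0.2,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "high at 12 h"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 12,
   "context": "continuous",
   "value": 1.15,
   "kind": "ge",
   "tolerance": 0.1,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": 7,
   "note": "still rising from 7 h"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 12,
   "context": "continuous",
   "value": 1.05,
   "kind": "ge",
   "tolerance": 0.1,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": 17,
   "note": "declining by 17 h"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 24,
   "context": "continuous",
   "value": 0.72,
   "kind": "le",
   "tolerance": 0.15,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": 12,
   "note": "decline by 24 h"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 48,
   "context": "continuous",
   "value": 0.45,
   "kind": "le",
   "tolerance": 0.2,
   "weight": 1,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": 12,
   "note": "near minimum at 48 h"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 72,
   "context": "continuous",
   "value": 4.0,
   "kind": "le",
   "tolerance": 0.25,
   "weight": 1,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "residual support only"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 12,
   "context": "pulse2",
   "value": 3.0,
   "kind": "ge",
   "tolerance": 0.2,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "2-h pulse still activates pSMAD (H at 12 h)"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 48,
   "context": "pulse2",
   "value": 1.35,
   "kind": "le",
   "tolerance": 0.15,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "2-h pulse decayed to L by 48 h"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 12,
   "context": "pulse8",
   "value": 3.0,
   "kind": "ge",
   "tolerance": 0.2,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "8-h pulse H at 12 h"
  },
  {
   "species": "pSMAD_nuc",
   "time_h": 48,
   "context": "pulse8",
   "value": 2.0,
   "kind": "eq",
   "tolerance": 0.25,
   "weight": 2,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "8-h pulse leaves an intermediate (M) residue"
  }
 ]
}
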