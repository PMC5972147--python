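{
 "schema_version": 1,
 "kind": "fit_targets",
 "note": "GSK3 A/AA/D fraction dynamics under continuous TGF-beta",
 "targets": [
  {
   "species": "GSK3_AA",
   "time_h": 8,
   "context": "continuous",
   "value": 0.13,
   "kind": "eq",
   "tolerance": 0.08,
   "weight": 2,
   "units": "fraction",
   "ref_context": null,
   "ref_time_h": null,
   "note": "AA transient peak"
  },
  {
   "species": "GSK3_AA",
   "time_h": 12,
   "context": "continuous",
   "value": 0.1,
   "kind": "eq",
   "tolerance": 0.06,
   "weight": 2,
   "units": "fraction",
   "ref_context": null,
   "ref_time_h": null,
   "note": "AA back to basal"
  },
  {
   "species": "GSK3_D",
   "time_h": 12,
   "context": "continuous",
   "value": 0.65,
   "kind": "eq",
   "tolerance": 0.08,
   "weight": 2,
   "units": "fraction",
   "ref_context": null,
   "ref_time_h": null,
   "note": "D at 12 h"
  },
  {
   "species": "GSK3_D",
   "time_h": 24,
   "context": "continuous",
   "value": 0.65,
   "kind": "eq",
   "tolerance": 0.15,
   "weight": 1,
   "units": "fraction",
   "ref_context": null,
   "ref_time_h": null,
   "note": "D sustained"
  },
  {
   "species": "GSK3_D",
   "time_h": 4,
   "context": "continuous",
   "value": 0.5,
   "kind": "le",
   "tolerance": 0.1,
   "weight": 1,
   "units": "fraction",
   "ref_context": null,
   "ref_time_h": null,
   "note": "D rise is delayed"
  }
 ]
}
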