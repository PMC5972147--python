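{
 "schema_version": 1,
 "kind": "fit_targets",
 "note": "two-wave SNAIL1 shape: early peak, dip, sustained second rise",
 "targets": [
  {
   "species": "SNAIL1_prot",
   "time_h": 18,
   "context": "continuous",
   "value": 3.0,
   "kind": "ge",
   "tolerance": 0.2,
   "weight": 1,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "first wave"
  },
  {
   "species": "SNAIL1_prot",
   "time_h": 32,
   "context": "continuous",
   "value": 0.92,
   "kind": "le",
   "tolerance": 0.08,
   "weight": 1,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": 18,
   "note": "dip after the first wave"
  },
  {
   "species": "SNAIL1_prot",
   "time_h": 52,
   "context": "continuous",
   "value": 1.15,
   "kind": "ge",
   "tolerance": 0.1,
   "weight": 1,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": 32,
   "note": "second rise"
  },
  {
   "species": "SNAIL1_prot",
   "time_h": 72,
   "context": "continuous",
   "value": 1.05,
   "kind": "ge",
   "tolerance": 0.1,
   "weight": 1,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": 18,
   "note": "sustained above first wave"
  },
  {
   "species": "SNAIL1_prot",
   "time_h": 72,
   "context": "continuous",
   "value": 4.0,
   "kind": "ge",
   "tolerance": 0.2,
   "weight": 1,
   "units": "fold",
   "ref_context": null,
   "ref_time_h": null,
   "note": "persistent elevation"
  }
 ]
}
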