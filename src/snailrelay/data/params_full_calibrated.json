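{
 "schema_version": 1,
 "kind": "parameter_set",
 "name": "full_calibrated",
 "values": {
  "b_R": 0.04944373705620167,
  "k_R": 0.2500536870033312,
  "K_IR": 1.1067971810589328,
  "d_R": 0.11999999999999998,
  "b_I": 0.005928165754209362,
  "k_I": 0.316227766016838,
  "K_RI": 0.6988262629862877,
  "d_I": 0.015811388300841903,
  "b_S": 0.0012184344876158067,
  "a_SR": 0.648213800496765,
  "K_SR": 11.240561344456188,
  "a_SG": 0.7746024177216473,
  "K_SG": 0.21027551398232347,
  "d_Sm": 1.9488326211359512,
  "k_tp": 0.3,
  "d_Sp": 3.661799128294305,
  "eps_Sp": 0.2846847179341313,
  "b_G": 0.003747121697453119,
  "a_GR": 0.11463683929870722,
  "K_GR": 5.357462173419492,
  "a_GG": 0.014426375434755981,
  "K_GG": 0.031169944956677426,
  "n_GG": 4.0,
  "d_Gm": 0.07535677580356905,
  "k_tg": 0.0790569415042095,
  "rho0": 0.045087611128513096,
  "rho1": 0.05654372145203026,
  "lam_loc": 0.19213329297295212,
  "k_in": 0.2764613992352284,
  "d_Gc": 0.12,
  "eps_G": 0.7,
  "d_Gn": 0.10126422596850683,
  "eps_Gn": 0.97,
  "f_aa_b": 0.1,
  "f_d_b": 0.37,
  "r_aa": 2.985018120434762,
  "k_aa": 0.7043959697016708,
  "tau_b": 0.9450270648823216,
  "r_d": 0.16803160493771616,
  "k_d": 0.3758868730526758,
  "tau_d": 4.489236799676936,
  "m_nuc": 1.0,
  "m_cyt": 1.0,
  "k_per": 1.7105278352542665,
  "K_per": 8.704945107941095,
  "r_per": 0.02055480479109447,
  "n_SG": 3.3631979877440443
 },
 "bounds": {}
}
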