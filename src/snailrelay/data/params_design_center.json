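{
 "schema_version": 1,
 "kind": "parameter_set",
 "name": "design_center",
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
 "bounds": {
  "b_R": [
   0.02208570607763185,
   0.1106907393175334
  ],
  "k_R": [
   0.11169487914124059,
   0.5598004748713088
  ],
  "K_IR": [
   0.49438814061796404,
   2.4778102453444824
  ],
  "d_R": [
   0.1,
   0.5
  ],
  "b_I": [
   0.002648014373956561,
   0.013271509986885421
  ],
  "k_I": [
   0.14125375446227548,
   0.707945784384138
  ],
  "K_RI": [
   0.31215422544014865,
   1.5644771271341198
  ],
  "d_I": [
   0.007062687723113774,
   0.03539728921920691
  ],
  "b_S": [
   0.0005442546937288467,
   0.00272773504338619
  ],
  "a_SR": [
   0.2895464688877228,
   1.4511699374838283
  ],
  "K_SR": [
   5.020974319134949,
   25.16448229120822
  ],
  "a_SG": [
   0.3460021904367263,
   1.7341188065395947
  ],
  "K_SG": [
   0.09392662192701433,
   0.47074823807555
  ],
  "d_Sm": [
   0.8705115557099837,
   4.362892784468598
  ],
  "k_tp": [
   0.13400507764528893,
   0.6716163415705018
  ],
  "d_Sp": [
   1.635665588361766,
   8.19774711370358
  ],
  "eps_Sp": [
   0.1271639924373015,
   0.637329695866505
  ],
  "b_G": [
   0.0016737777800451738,
   0.008388760552876375
  ],
  "a_GR": [
   0.05120639517077924,
   0.2566399153966776
  ],
  "K_GR": [
   2.3930904484359248,
   11.993863816714496
  ],
  "a_GG": [
   0.006444025200915214,
   0.032296631638711236
  ],
  "K_GG": [
   0.01392310298039647,
   0.06978081466252535
  ],
  "n_GG": [
   1.0,
   4.0
  ],
  "d_Gm": [
   0.03366063530885301,
   0.1687028069258052
  ],
  "k_tg": [
   0.03531343861556887,
   0.1769864460960345
  ],
  "rho0": [
   0.02013989610038997,
   0.10093858812095137
  ],
  "rho1": [
   0.02525715261177635,
   0.12658562446798022
  ],
  "lam_loc": [
   0.08582278947695166,
   0.43013286440129167
  ],
  "k_in": [
   0.12349077090147335,
   0.6189199784660867
  ],
  "d_Gc": [
   0.053602031058115576,
   0.2686465366282007
  ],
  "eps_G": [
   0.3126785145056742,
   0.97
  ],
  "d_Gn": [
   0.045233068211999475,
   0.2267023632564572
  ],
  "eps_Gn": [
   0.43328308438643426,
   0.97
  ],
  "f_aa_b": [
   0.08000000000000002,
   0.12
  ],
  "f_d_b": [
   0.296,
   0.444
  ],
  "r_aa": [
   1.3333586166715157,
   6.682623165226834
  ],
  "k_aa": [
   0.31464212204300335,
   1.576946147293474
  ],
  "tau_b": [
   0.42212808402151675,
   2.115652066671247
  ],
  "r_d": [
   0.07505696088847057,
   0.3761759059216293
  ],
  "k_d": [
   0.1679024986975623,
   0.8415058884133793
  ],
  "tau_d": [
   2.005268419695988,
   10.050149319475638
  ],
  "m_nuc": [
   0.44668359215096315,
   2.2387211385683394
  ],
  "m_cyt": [
   0.44668359215096315,
   2.2387211385683394
  ],
  "k_per": [
   0.7640647179255867,
   3.8293948228932684
  ],
  "K_per": [
   3.888356150292082,
   19.487944623224784
  ],
  "r_per": [
   0.009181494040047906,
   0.04601647598496897
  ],
  "n_SG": [
   1.0,
   4.0
  ]
 }
}
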