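{
 "mu_BS": {
  "value": 0.05,
  "lower": 0.001,
  "upper": 10.0,
  "unit": "1/h",
  "fixed": false
 },
 "mu_BLu": {
  "value": 1.6,
  "lower": 0.001,
  "upper": 10.0,
  "unit": "1/h",
  "fixed": false
 },
 "mu_BLi": {
  "value": 0.7,
  "lower": 0.001,
  "upper": 10.0,
  "unit": "1/h",
  "fixed": false
 },
 "mu": {
  "value": 0.5,
  "lower": 0.001,
  "upper": 10.0,
  "unit": "1/h",
  "fixed": false
 },
 "mu_S0": {
  "value": 0.0498,
  "lower": 0.001,
  "upper": 10.0,
  "unit": "1/h",
  "fixed": false
 },
 "mu_Lu0": {
  "value": 0.3,
  "lower": 0.001,
  "upper": 10.0,
  "unit": "1/h",
  "fixed": false
 },
 "Q_Blood": {
  "value": 5000000.0,
  "lower": 5000000.0,
  "upper": 5000000.0,
  "unit": "mm^3",
  "fixed": true
 },
 "Q_Spleen": {
  "value": 100000.0,
  "lower": 100000.0,
  "upper": 100000.0,
  "unit": "mm^3",
  "fixed": true
 },
 "Q_Lung": {
  "value": 1600000.0,
  "lower": 1600000.0,
  "upper": 1600000.0,
  "unit": "mm^3",
  "fixed": true
 },
 "Q_Liver": {
  "value": 1500000.0,
  "lower": 1500000.0,
  "upper": 1500000.0,
  "unit": "mm^3",
  "fixed": true
 },
 "k_ph1_TRAF2": {
  "value": 1.0,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_ph1_IRAK1": {
  "value": 0.8,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_ph2": {
  "value": 0.5,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "dimensionless",
  "fixed": false
 },
 "k_deg_TRAF2p": {
  "value": 0.3,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_IRAK1p": {
  "value": 0.3,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_syn_IKK": {
  "value": 0.002,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_act_IKK": {
  "value": 0.0213,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_IKK": {
  "value": 0.002,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_IKKb": {
  "value": 0.84,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "N_tot": {
  "value": 1.0,
  "lower": 0.1,
  "upper": 10.0,
  "unit": "dimensionless",
  "fixed": false
 },
 "k_ass": {
  "value": 0.89,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transc_mIkBa": {
  "value": 6.06,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_mIkBa": {
  "value": 0.0323,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_tranl_IkBa": {
  "value": 2.62,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_loss_IkBa": {
  "value": 32.3,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transc1_mIL8": {
  "value": 0.005,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transc2_mIL8": {
  "value": 0.5,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_mIL8": {
  "value": 0.2,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transl_IL8": {
  "value": 0.4,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_IL8": {
  "value": 0.05,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_sec_IL8": {
  "value": 0.05,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transc2_mIL6": {
  "value": 0.4,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_mIL6": {
  "value": 0.2,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transl_IL6": {
  "value": 0.4,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_IL6": {
  "value": 0.08,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transc2_mIL12": {
  "value": 0.3,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_mIL12": {
  "value": 0.25,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transl_IL12": {
  "value": 0.3,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_IL12": {
  "value": 0.08,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_transc2_CD70": {
  "value": 0.2,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_CD70": {
  "value": 0.0482,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_act_N": {
  "value": 0.00559,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "K_4": {
  "value": 6911.0,
  "lower": 691.1,
  "upper": 69110.0,
  "unit": "signal units",
  "fixed": false
 },
 "k_diff1_EE": {
  "value": 0.05,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_diff2_EE": {
  "value": 0.01,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 },
 "k_deg_SLE": {
  "value": 0.05,
  "lower": 0.0001,
  "upper": 100.0,
  "unit": "1/h",
  "fixed": false
 }
}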