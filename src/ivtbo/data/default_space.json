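[
 {
  "name": "cofactor",
  "kind": "categorical",
  "domain": [
   "MgAcetate",
   "MgCl2"
  ],
  "units": ""
 },
 {
  "name": "cofactor_mM",
  "kind": "real",
  "domain": [
   0.0,
   100.0
  ],
  "units": "mM"
 },
 {
  "name": "DTT_mM",
  "kind": "real",
  "domain": [
   0.0,
   10.0
  ],
  "units": "mM"
 },
 {
  "name": "RNaseInh_UmL",
  "kind": "integer",
  "domain": [
   0,
   2000
  ],
  "units": "U/mL"
 },
 {
  "name": "NTPs_mM",
  "kind": "real",
  "domain": [
   1.0,
   10.0
  ],
  "units": "mM"
 },
 {
  "name": "DNA_nM",
  "kind": "integer",
  "domain": [
   10,
   100
  ],
  "units": "nM"
 },
 {
  "name": "PPase_UmL",
  "kind": "integer",
  "domain": [
   0,
   10
  ],
  "units": "U/mL"
 },
 {
  "name": "spermidine_mM",
  "kind": "real",
  "domain": [
   0.0,
   10.0
  ],
  "units": "mM"
 },
 {
  "name": "T7_UmL",
  "kind": "integer",
  "domain": [
   1000,
   50000
  ],
  "units": "U/mL"
 },
 {
  "name": "temperature_C",
  "kind": "integer",
  "domain": [
   20,
   50
  ],
  "units": "degC"
 },
 {
  "name": "time_min",
  "kind": "integer",
  "domain": [
   10,
   300
  ],
  "units": "min"
 },
 {
  "name": "pH",
  "kind": "real",
  "domain": [
   6.5,
   8.0
  ],
  "units": ""
 }
]
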