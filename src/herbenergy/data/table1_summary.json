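{
 "adf": {
  "max": 0.401,
  "mean": 0.329,
  "min": 0.281,
  "sd": 0.0467
 },
 "adfd": {
  "max": 0.773,
  "mean": 0.648,
  "min": 0.519,
  "sd": 0.056
 },
 "ash": {
  "max": 0.075,
  "mean": 0.062,
  "min": 0.051,
  "sd": 0.0082
 },
 "de": {
  "max": 15.21,
  "mean": 11.53,
  "min": 8.03,
  "sd": 2.15
 },
 "de_ge": {
  "max": 0.839,
  "mean": 0.648,
  "min": 0.461,
  "sd": 0.092
 },
 "dm_fresh": {
  "max": 809,
  "mean": 566,
  "min": 323,
  "sd": 272.3
 },
 "dmd": {
  "max": 0.831,
  "mean": 0.655,
  "min": 0.476,
  "sd": 0.088
 },
 "domd": {
  "max": 0.731,
  "mean": 0.622,
  "min": 0.499,
  "sd": 0.076
 },
 "ee": {
  "max": 0.05,
  "mean": 0.033,
  "min": 0.017,
  "sd": 0.0089
 },
 "ge": {
  "max": 18.25,
  "mean": 17.55,
  "min": 17.03,
  "sd": 0.45
 },
 "ged": {
  "max": 0.829,
  "mean": 0.652,
  "min": 0.461,
  "sd": 0.104
 },
 "me": {
  "max": 13.36,
  "mean": 9.89,
  "min": 6.33,
  "sd": 1.84
 },
 "me_ge": {
  "max": 0.737,
  "mean": 0.556,
  "min": 0.363,
  "sd": 0.093
 },
 "n": {
  "max": 0.124,
  "mean": 0.064,
  "min": 0.035,
  "sd": 0.0364
 },
 "nd": {
  "max": 0.793,
  "mean": 0.557,
  "min": 0.327,
  "sd": 0.202
 },
 "ndf": {
  "max": 0.867,
  "mean": 0.643,
  "min": 0.499,
  "sd": 0.1054
 },
 "ndfd": {
  "max": 0.811,
  "mean": 0.702,
  "min": 0.542,
  "sd": 0.064
 },
 "omd": {
  "max": 0.773,
  "mean": 0.681,
  "min": 0.55,
  "sd": 0.071
 }
}
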