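{
  "TPC": "mg GAE/g DW",
  "TFC": "mg GAE/g DW",
  "TC": "mg TAE/g DW",
  "TAC": "mg ME/g DW"
}
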