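{
  "interview_invited": 25,
  "interview_interested": 21,
  "interview_completed": 19,
  "delphi_panelists": 76,
  "ahp_participants": 10
}
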