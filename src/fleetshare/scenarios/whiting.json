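{
  "name": "whiting",
  "world": {
    "L": 7.0,
    "n_schools": 3,
    "F_s": 0.5,
    "F_n": 60.0,
    "tau_l": 8.0,
    "dt": 0.2
  },
  "agents": {
    "v": 1.0,
    "r_sense": 0.22,
    "C_q": 1.0,
    "turn_rate": 0.05
  },
  "n_agents": 20,
  "management_defaults": {
    "T": 640.0,
    "t_max": 3000.0
  },
  "notes": "Pelagic whiting-like target (Pacific hake analogue): large schools, many fish per school, high mobility (short school lifespan). All fleet parameters identical to the groundfish scenario.",
  "provenance": "Artifact calibration constants: larger F_s, larger F_n and smaller tau_l than the groundfish scenario with everything else equal, so a school usually outlives a single visit but often escapes a lone searcher entirely. turn_rate sits on the flat low-turn-rate optimum plateau identified by agents.optimize_turn_rate for this geometry."
}
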