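{
  "name": "groundfish",
  "world": {
    "L": 7.0,
    "n_schools": 3,
    "F_s": 0.18,
    "F_n": 8.0,
    "tau_l": 100.0,
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
  "notes": "Demersal groundfish-like target: small schools, few fish per school, low mobility (long school lifespan). Contrasting corner of the ecological parameter space to the whiting scenario; all fleet parameters identical between the two.",
  "provenance": "Artifact calibration constants: chosen so a lone searcher needs tau_s ~ 19 time units (~95 timesteps) per discovery, a quota is several schools' worth of fish, a season completes in ~1e3 steps, and the groundfish/whiting sign structure (smaller F_s, smaller F_n, larger tau_l) holds. turn_rate sits on the flat low-turn-rate optimum plateau identified by agents.optimize_turn_rate for this geometry."
}
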