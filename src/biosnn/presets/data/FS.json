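{
  "preset_id": "FS",
  "description": "Fast-spiking inhibitory cortical interneuron: leak + fast Na + delayed-rectifier K, non-adapting and sustaining high firing rates.",
  "units": {
    "voltage": "mV",
    "time": "ms",
    "current": "uA/cm^2",
    "conductance": "mS/cm^2",
    "capacitance": "uF/cm^2"
  },
  "C_m": 1.0,
  "g_leak": 0.038,
  "E_leak": -70.4,
  "spike_threshold": 0.0,
  "noise": {
    "mu": 0.0,
    "theta": 0.066667,
    "sigma": 0.2
  },
  "currents": [
    {
      "name": "Na",
      "g_max": 58.0,
      "E_rev": 50.0,
      "gates": [
        {
          "name": "m",
          "family": "na_m",
          "exponent": 3,
          "params": {
            "V_T": -57.9
          }
        },
        {
          "name": "h",
          "family": "na_h",
          "exponent": 1,
          "params": {
            "V_T": -57.9
          }
        }
      ]
    },
    {
      "name": "Kd",
      "g_max": 3.9,
      "E_rev": -90.0,
      "gates": [
        {
          "name": "n",
          "family": "kd_n",
          "exponent": 4,
          "params": {
            "V_T": -57.9
          }
        }
      ]
    }
  ]
}
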