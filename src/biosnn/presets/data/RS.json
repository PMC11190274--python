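{
  "preset_id": "RS",
  "description": "Regular-spiking excitatory cortical neuron: leak + fast Na + delayed-rectifier K + slow muscarinic K (spike-frequency adaptation).",
  "units": {
    "voltage": "mV",
    "time": "ms",
    "current": "uA/cm^2",
    "conductance": "mS/cm^2",
    "capacitance": "uF/cm^2"
  },
  "C_m": 1.0,
  "g_leak": 0.0205,
  "E_leak": -70.3,
  "spike_threshold": 0.0,
  "noise": {
    "mu": 0.0,
    "theta": 0.066667,
    "sigma": 0.2
  },
  "currents": [
    {
      "name": "Na",
      "g_max": 56.0,
      "E_rev": 50.0,
      "gates": [
        {
          "name": "m",
          "family": "na_m",
          "exponent": 3,
          "params": {
            "V_T": -56.2
          }
        },
        {
          "name": "h",
          "family": "na_h",
          "exponent": 1,
          "params": {
            "V_T": -56.2
          }
        }
      ]
    },
    {
      "name": "Kd",
      "g_max": 6.0,
      "E_rev": -90.0,
      "gates": [
        {
          "name": "n",
          "family": "kd_n",
          "exponent": 4,
          "params": {
            "V_T": -56.2
          }
        }
      ]
    },
    {
      "name": "M",
      "g_max": 0.075,
      "E_rev": -90.0,
      "gates": [
        {
          "name": "p",
          "family": "km_p",
          "exponent": 1,
          "params": {
            "tau_max": 608.0
          }
        }
      ]
    }
  ]
}
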