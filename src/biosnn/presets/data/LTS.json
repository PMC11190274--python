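{
  "preset_id": "LTS",
  "description": "Low-threshold spiking cortical neuron: RS-like backbone plus a low-threshold (T-type-style) Ca current with instantaneous activation, enabling rebound bursts.",
  "units": {
    "voltage": "mV",
    "time": "ms",
    "current": "uA/cm^2",
    "conductance": "mS/cm^2",
    "capacitance": "uF/cm^2"
  },
  "C_m": 1.0,
  "g_leak": 0.01,
  "E_leak": -70.0,
  "spike_threshold": 0.0,
  "noise": {
    "mu": 0.0,
    "theta": 0.066667,
    "sigma": 0.2
  },
  "currents": [
    {
      "name": "Na",
      "g_max": 50.0,
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
      "g_max": 5.0,
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
      "g_max": 0.03,
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
    },
    {
      "name": "CaT",
      "g_max": 0.4,
      "E_rev": 120.0,
      "gates": [
        {
          "name": "s",
          "family": "cat_s",
          "exponent": 2,
          "params": {
            "Vx": -7.0
          }
        },
        {
          "name": "u",
          "family": "cat_u",
          "exponent": 1,
          "params": {
            "Vx": -7.0
          }
        }
      ]
    }
  ]
}
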