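{
  "preset_id": "IB",
  "description": "Intrinsically bursting cortical neuron: RS-like backbone plus a high-threshold (L-type-style) Ca current driving burst onsets.",
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
      "g_max": 0.07,
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
      "name": "CaL",
      "g_max": 0.17,
      "E_rev": 120.0,
      "gates": [
        {
          "name": "q",
          "family": "cal_q",
          "exponent": 2,
          "params": {}
        },
        {
          "name": "r",
          "family": "cal_r",
          "exponent": 1,
          "params": {}
        }
      ]
    }
  ]
}
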