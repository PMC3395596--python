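{
  "version": 1,
  "comment": "Biophysical constants for the antennal-lobe model. Units: capacitance uF, conductance uS, voltage mV, time ms, current nA, calcium in arbitrary concentration units.",
  "cells": {
    "PN": {
      "capacitance_uF": 9.533333e-06,
      "leak": {
        "g_uS": 0.0014,
        "E_mV": -65.0
      },
      "channels": {
        "Na": {
          "g_uS": 0.953333333,
          "E_mV": 50.0,
          "VT_mV": -55.0
        },
        "K": {
          "g_uS": 0.095333333,
          "E_mV": -95.0,
          "VT_mV": -55.0
        },
        "KA": {
          "g_uS": 0.026666667,
          "E_mV": -95.0
        }
      },
      "ca_pool": null,
      "spike": {
        "mode": "threshold_crossing",
        "threshold_mV": 0.0,
        "refractory_ms": 2.0
      }
    },
    "eLN": {
      "capacitance_uF": 9.533333e-06,
      "leak": {
        "g_uS": 0.0014,
        "E_mV": -65.0
      },
      "channels": {
        "Na": {
          "g_uS": 0.953333333,
          "E_mV": 50.0,
          "VT_mV": -55.0
        },
        "K": {
          "g_uS": 0.095333333,
          "E_mV": -95.0,
          "VT_mV": -55.0
        },
        "KA": {
          "g_uS": 0.026666667,
          "E_mV": -95.0
        }
      },
      "ca_pool": null,
      "spike": {
        "mode": "threshold_crossing",
        "threshold_mV": 0.0,
        "refractory_ms": 2.0
      }
    },
    "LN": {
      "capacitance_uF": 9.533333e-06,
      "leak": {
        "g_uS": 0.0014,
        "E_mV": -64.0
      },
      "channels": {
        "CaT": {
          "g_uS": 0.01,
          "E_mV": 140.0
        },
        "KCa": {
          "g_uS": 0.003333333,
          "E_mV": -90.0
        },
        "K": {
          "g_uS": 0.233333333,
          "E_mV": -90.0,
          "VT_mV": -55.0
        }
      },
      "ca_pool": {
        "tau_ms": 1000.0,
        "rest": 0.00024,
        "influx_per_nA_ms": 0.06
      },
      "spike": {
        "mode": "local_max",
        "threshold_mV": -20.0,
        "refractory_ms": 5.0
      }
    }
  },
  "synapses": {
    "nACh": {
      "alpha_per_ms": 2.0,
      "beta_per_ms": 0.05,
      "E_mV": 0.0,
      "release_threshold_mV": -20.0
    },
    "GABA_A": {
      "alpha_per_ms": 1.0,
      "beta_per_ms": 0.16,
      "E_mV": -75.0,
      "release_threshold_mV": -20.0
    },
    "GABA_B": {
      "K1_per_ms": 0.09,
      "K2_per_ms": 0.0012,
      "K3_per_ms": 0.18,
      "K4_per_ms": 0.034,
      "Kd": 100.0,
      "hill": 4,
      "E_mV": -95.0,
      "release_threshold_mV": -20.0
    }
  },
  "input": {
    "peak_current_nA": 0.035,
    "sigma_x": 0.15,
    "truncation": 0.1,
    "class_scale": {
      "PN": 1.0,
      "eLN": 1.0,
      "LN": 0.7
    },
    "noise_fraction": 0.1,
    "noise_tau_ms": 20.0,
    "class_sigma_scale": {
      "PN": 1.0,
      "eLN": 0.16667,
      "LN": 1.0
    }
  }
}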