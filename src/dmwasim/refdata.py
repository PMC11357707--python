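"""Published ex vivo porcine vertebra ablation study values.

Reference numbers from the directional-MWA ex vivo validation study that the
simulator is benchmarked against: the finite-element simulated probe
temperatures per protocol, the experimental replicate summaries, the
experiment-vs-simulation comparison inputs, and the histology-derived probe
placement statistics.  These are *inputs* to the validation statistics
pipeline (and the calibration anchor), not outputs of this package.

Conditions are keyed ``(generator setpoint W, duration min, T_i degC)``.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

Condition = Tuple[float, float, float]

#: Reference simulated probe temperatures per protocol:
#: condition -> {"T_i", "T1_final", "dT1", "T2_final", "dT2"} in degC.
SIMULATED_PROBE_TEMPERATURES: Dict[Condition, Dict[str, float]] = {
    (80.0, 3.5, 20.0): {"T_i": 20.0, "T1_final": 51.3, "dT1": 31.3,
                        "T2_final": 33.4, "dT2": 13.4},
    (80.0, 3.5, 30.0): {"T_i": 30.0, "T1_final": 62.5, "dT1": 32.5,
                        "T2_final": 39.6, "dT2": 9.6},
    (80.0, 3.5, 37.0): {"T_i": 37.0, "T1_final": 68.9, "dT1": 31.9,
                        "T2_final": 43.8, "dT2": 6.8},
    (120.0, 5.0, 20.0): {"T_i": 20.0, "T1_final": 81.4, "dT1": 61.4,
                         "T2_final": 41.8, "dT2": 21.8},
}

#: Calibration anchor: the 80 W / 3.5 min / 20 degC protocol, forward probe.
CALIBRATION_ANCHOR_CONDITION: Condition = (80.0, 3.5, 20.0)
CALIBRATION_ANCHOR_T1_FINAL_C = 51.3

#: Experimental replicate summaries (mean, sd):
#: visible-ablation depth D / length L (mm), per-channel initial/final/delta
#: temperatures (degC), and recorded sensor placement distances (mm).
EXPERIMENT_SUMMARY: Dict[Condition, Dict[str, Tuple[float, float]]] = {
    (80.0, 3.5, 20.0): {
        "n": (7, 0), "D_mm": (3.0, 0.5), "L_mm": (9.0, 1.5),
        "T1_initial": (19.9, 0.8), "T1_final": (53.4, 2.9), "dT1": (33.5, 2.9),
        "T2_initial": (20.9, 0.5), "T2_final": (35.9, 1.5), "dT2": (15.0, 1.5),
        "D_T1_mm": (9.3, 0.9), "D_T2_mm": (4.3, 0.0),
    },
    (80.0, 3.5, 37.0): {
        "n": (6, 0), "D_mm": (5.5, 0.5), "L_mm": (10.5, 0.8),
        "T1_initial": (30.2, 3.7), "T1_final": (63.7, 9.8), "dT1": (33.5, 9.1),
        "T2_initial": (35.1, 4.0), "T2_final": (45.9, 4.3), "dT2": (10.8, 5.8),
        "D_T1_mm": (9.3, 1.0), "D_T2_mm": (5.3, 0.5),
    },
    (120.0, 5.0, 20.0): {
        "n": (6, 0), "D_mm": (7.8, 1.0), "L_mm": (14.0, 2.0),
        "T1_initial": (17.2, 1.7), "T1_final": (80.3, 9.8), "dT1": (63.1, 9.5),
        "T2_initial": (17.5, 1.2), "T2_final": (49.8, 4.8), "dT2": (32.3, 4.1),
        "D_T1_mm": (9.8, 1.0), "D_T2_mm": (5.0, 0.0),
    },
}

#: Inputs of the experiment-vs-simulation comparison table:
#: condition -> channel -> dT (degC).  (The table's experimental dT1 for the
#: 80 W / 20 degC condition, 33.6, differs by 0.1 degC from the replicate
#: summary above; the comparison uses the table's own values.)
COMPARISON_EXPERIMENT_DT: Dict[Condition, Dict[str, float]] = {
    (80.0, 3.5, 20.0): {"T1": 33.6, "T2": 15.0},
    (80.0, 3.5, 37.0): {"T1": 33.5, "T2": 10.8},
    (120.0, 5.0, 20.0): {"T1": 63.2, "T2": 32.3},
}
COMPARISON_SIMULATION_DT: Dict[Condition, Dict[str, float]] = {
    (80.0, 3.5, 20.0): {"T1": 31.3, "T2": 13.4},
    (80.0, 3.5, 37.0): {"T1": 31.9, "T2": 6.8},
    (120.0, 5.0, 20.0): {"T1": 61.4, "T2": 21.8},
}
#: The published signed percent differences for those inputs.
COMPARISON_PERCENT_DIFF: Dict[Condition, Dict[str, int]] = {
    (80.0, 3.5, 20.0): {"T1": -7, "T2": -11},
    (80.0, 3.5, 37.0): {"T1": -5, "T2": -37},
    (120.0, 5.0, 20.0): {"T1": -3, "T2": -33},
}

#: Histology-derived probe placement statistics (meters).
T1_PLACEMENT_MEAN_M = 10.1e-3
T1_PLACEMENT_RANGE_M = (8.3e-3, 12.7e-3)
T2_PLACEMENT_MEAN_M = 2.4e-3
T2_PLACEMENT_RANGE_M = (1.4e-3, 3.6e-3)
#: Experimentally recorded (externally referenced) mean T2 distance.
T2_RECORDED_MEAN_M = 4.8e-3

#: Warmed-specimen pre-ablation cooling: 37 degC bath specimens had drifted to
#: 30.2 +/- 3.7 degC by ablation start; room-temperature specimens 19.9 degC.
WARMED_INITIAL_MEAN_C = 30.2
WARMED_INITIAL_SD_C = 3.7
ROOM_INITIAL_MEAN_C = 19.9
ROOM_INITIAL_SD_C = 0.8
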