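"""Unit conversion constants.

SI units (m, s, Pa, kg) are used internally everywhere; clinical units
(cmH2O, ml/min, mm, cm^2) appear only at I/O boundaries. All conversion
constants live here and nowhere else.
"""

#: 1 cmH2O in Pa (conventional water column at 4 degC, g = 9.80665 m/s^2)
CMH2O_TO_PA = 98.0665
PA_TO_CMH2O = 1.0 / CMH2O_TO_PA

#: 1 ml/min in m^3/s
ML_MIN_TO_M3_S = 1e-6 / 60.0
M3_S_TO_ML_MIN = 60.0 / 1e-6

#: lengths
MM_TO_M = 1e-3
M_TO_MM = 1e3

#: volumes / areas
M3_TO_ML = 1e6
ML_TO_M3 = 1e-6
M2_TO_CM2 = 1e4
CM2_TO_M2 = 1e-4
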