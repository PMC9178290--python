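# Influence rating scale, version 1.
# For each metric: the upper-inclusive bounds of the 0.5, 1, 1.5, 2 and 2.5
# score bins.  x == 0 scores 0; values above the last bound score 3.
#   convergence_pct : average % difference between last converged time steps
#   valgus_rmse     : average valgus kinematics RMSE (degrees)
#   pressure_pct    : average % difference between peak contact pressures
#   location_mm     : average distance between peak-pressure locations (mm)
version: 1
scales:
  convergence_pct: [1, 5, 10, 20, 40]
  valgus_rmse: [0.2, 0.5, 0.9, 1.4, 2]
  pressure_pct: [1, 5, 10, 20, 40]
  location_mm: [0.2, 0.5, 1.25, 2.5, 4]
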