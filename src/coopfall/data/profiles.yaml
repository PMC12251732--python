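# Synthetic risk-conditioned cohort profiles.
#
# These distributions are synthetic stand-ins chosen from conventional
# adult reference ranges: the source clinical datasets publish no
# per-risk-class distributions, so these parameters define the package's
# own simulation conditions.  Vital signs are drawn from per-sign
# truncated normals (mean, sd, low, high); systolic pressure is derived
# as diastolic + pulse pressure so the systolic > diastolic invariant
# holds by construction.  adl_mix gives expected time fractions (sum 1);
# mfs_range is the inclusive Morse-Fall-Scale band of the latent class.
low:
  vitals:
    diastolic_bp: {mean: 75, sd: 8, low: 55, high: 95}
    pulse_pressure: {mean: 45, sd: 8, low: 25, high: 65}
    heart_rate: {mean: 72, sd: 8, low: 55, high: 95}
    spo2: {mean: 97, sd: 1, low: 94, high: 100}
  adl_mix: {sitting: 0.35, standing: 0.20, walking: 0.30, running: 0.10, jumping: 0.05}
  mfs_range: [0, 24]
  fall_rate: 0.3

moderate:
  vitals:
    diastolic_bp: {mean: 68, sd: 9, low: 50, high: 95}
    pulse_pressure: {mean: 38, sd: 9, low: 20, high: 60}
    heart_rate: {mean: 88, sd: 10, low: 60, high: 110}
    spo2: {mean: 94.5, sd: 1.5, low: 90, high: 100}
  adl_mix: {sitting: 0.50, standing: 0.25, walking: 0.20, running: 0.04, jumping: 0.01}
  mfs_range: [25, 45]
  fall_rate: 2.0

high:
  vitals:
    diastolic_bp: {mean: 58, sd: 8, low: 40, high: 80}
    pulse_pressure: {mean: 30, sd: 8, low: 15, high: 50}
    heart_rate: {mean: 105, sd: 10, low: 80, high: 140}
    spo2: {mean: 91, sd: 2, low: 85, high: 98}
  adl_mix: {sitting: 0.70, standing: 0.18, walking: 0.10, running: 0.015, jumping: 0.005}
  mfs_range: [46, 80]
  fall_rate: 4.0
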