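"""Worked-example DSL texts shipped with the package.

Two requirement texts (a gray/white-matter contrast task and a CSF-SNR task)
and six sequence texts: the four family defaults (RARE, SE-EPI, EPI, bSSFP)
plus the two optimized sequences returned for the requirement examples.
These drive the documentation examples and the acceptance checks.
"""

REQUIREMENT_GWC = """\
define optimization requirement :
  maximize "GWC".
  obey the following constraints:
    "SNR_GM" is higher than 30.
    "SNR_WM" is higher than 30.
    "SNR_GM" is higher than "SNR_WM".
  aim for the following :
    avoid "ghosting".
"""

REQUIREMENT_SNR_CSF = """\
define optimization requirement :
  maximize "SNR_CSF".
  obey the following constraints:
   "Sharpness" is higher than 0.85.
  aim for the following :
    avoid "ghosting".
    avoid "motion".
    avoid "distortion".
    have high "CGC".
    have high "CWC".
"""

SEQUENCE_RARE_DEFAULT = """\
define MRI sequence "RARE-default"
  using a "SpinEcho" with "LineReadout".
Add gradient spoiling around refocussing
  of type balanced.
Add gradient spoiling after echotrain.
Specify echo
  as excitation
    with type sincpulse and angle 90,
  and refocussing
    with type sincpulse and angle 180.
Specify readout
  with duration 2000
  and number-of-columns 64.
Specify timing parameters
  with TE 44
  and TR 500.
Specify trajectory
  with Epi-Factor 1
  and ETL 8
  and number-of-rows 64.
Specify measurements
  with count 1.
"""

SEQUENCE_SE_EPI_DEFAULT = """\
define MRI sequence "SE-EPI-default"
  using a "SpinEcho" with "EPIReadout".
Specify echo
  as excitation
    with type sincpulse and angle 90,
  and refocussing
    with type sincpulse and angle 180.
Specify readout
  with duration 500
  and number-of-columns 64.
Add gradient spoiling around refocussing
  of type balanced.
Add gradient spoiling after segment.
Specify timing parameters
  with TE 50
  and TR 1000.
Specify trajectory
  with Epi-Factor 64
  and ETL 1
  and number-of-rows 64.
Specify measurements
  with count 10.
"""

SEQUENCE_EPI_DEFAULT = """\
Define MRI sequence "EPI-default"
   using a "GradientEcho" with "EPIReadout".
Specify echo
  as excitation
    with type sincpulse and angle 90.
Specify readout
  with duration 500
  and number-of-columns 64.
Add gradient spoiling after segment.
Specify timing parameters
  with TE 35
  and TR 1000.
Specify trajectory
  with Epi-Factor 64
  and ETL 1
  and number-of-rows 64.
Specify measurements
  with count 10.
"""

SEQUENCE_BSSFP_DEFAULT = """\
Define MRI sequence "bSSFP"
  using a "GradientEcho" with "LineReadout".
Add prescans
  with count 8 and type linear.
Specify echo
  as excitation
    with type sincpulse and angle 90.
Specify readout
  with duration 2000
  and number-of-columns 64.
Add gradient spoiling around readout
  of type balanced.
Specify timing parameters
  with TE 4
  and TR 8.
Specify trajectory
  with Epi-Factor 1
  and ETL 1
  and number-of-rows 64.
Specify measurements
  with count 1.
"""

SEQUENCE_OPTIMIZED_1 = """\
define MRI sequence "Example 1"
  using a "SpinEcho" with "EPIReadout".
Specify echo
  as excitation
    with type sincpulse and angle 90,
  and refocussing
    with type sincpulse and angle 180.
Specify readout
  with duration 500
  and number-of-columns 32.
Specify timing parameters
  with TE 46
  and TR 5014.
Specify trajectory
  with Epi-Factor 32
  and ETL 1
  and number-of-rows 32.
Specify measurements
  with count 10.
"""

SEQUENCE_OPTIMIZED_2 = """\
define MRI sequence "Example 2"
  using a "GradientEcho" with "LineReadout".
Specify echo
  as excitation
    with type sincpulse and angle 90,
Specify readout
  with duration 2000
  and number-of-columns 64.
Specify timing parameters
  with TE 17
  and TR 36.
Specify trajectory
  with Epi-Factor 1
  and ETL 1
  and number-of-rows 64.
Specify measurements
  with count 2.
Add prescans
  with count 8.
"""

DEFAULT_SEQUENCES = {
    "RARE": SEQUENCE_RARE_DEFAULT,
    "SE-EPI": SEQUENCE_SE_EPI_DEFAULT,
    "EPI": SEQUENCE_EPI_DEFAULT,
    "bSSFP": SEQUENCE_BSSFP_DEFAULT,
}

ALL_SEQUENCE_TEXTS = {
    **DEFAULT_SEQUENCES,
    "optimized-1": SEQUENCE_OPTIMIZED_1,
    "optimized-2": SEQUENCE_OPTIMIZED_2,
}
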