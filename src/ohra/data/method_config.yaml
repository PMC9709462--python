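# Method configuration for the six OHRA engines.
#
# Band lists are left-closed/right-open breakpoints: a value x maps to
# rating 1 below the first breakpoint, rating k for breakpoint[k-2] <= x <
# breakpoint[k-1], and the top rating at or above the last breakpoint.
#
# The ICMM, Australian and Romanian rating tables encode one evaluator's
# frozen judgment in the style of the source methods (product-banded
# consequence x likelihood grid; log-scaled Fine-Kinney nomogram; severity x
# probability grid).  Edit them to match a local evaluator; every result file
# carries the checksum of this configuration.

# EPA hazard-quotient -> risk level (five levels)
hq_bands: [0.1, 0.5, 1.0, 2.0]

# Singaporean exposure rating from the concentration ratio CR
er_bands: [0.1, 0.5, 1.0, 2.0]

# Singaporean hazard rating: carcinogenicity class first, else the worse of
# the acute-toxicity bands; a per-chemical hr_override in the registry wins.
hr_table:
  carcinogenicity: {IARC-1: 5, IARC-2A: 4, IARC-2B: 3, IARC-3: 2}
  ld50_oral: {thresholds: [25, 200, 2000, 5000], ratings: [5, 4, 3, 2, 1]}
  lc50_inhal: {thresholds: [100, 500, 2500, 20000], ratings: [5, 4, 3, 2, 1]}

coshh:
  # risk phrase (base token, compound codes like R48/20 keyed by first token)
  # -> hazard band A-E
  phrase_bands:
    R10: A
    R11: A
    R12: A
    R36: A
    R38: A
    R65: A
    R66: A
    R67: A
    R20: B
    R21: B
    R22: B
    R33: B
    R64: B
    R23: C
    R24: C
    R25: C
    R34: C
    R35: C
    R37: C
    R41: C
    R43: C
    R62: C
    R63: C
    R26: D
    R27: D
    R28: D
    R39: D
    R40: D
    R48: D
    R60: D
    R61: D
    R42: E
    R45: E
    R46: E
    R49: E
    R68: E
  # exposure potential 1-4 from quantity band x dustiness/volatility band
  ep_table:
    small: {low: 1, medium: 1, high: 2}
    medium: {low: 1, medium: 2, high: 3}
    large: {low: 2, medium: 3, high: 4}
  # hazard band -> control strategy CS1-CS4 by exposure potential EP1-EP4
  matrix:
    A: [1, 1, 1, 2]
    B: [1, 1, 2, 3]
    C: [1, 2, 3, 4]
    D: [2, 3, 4, 4]
    E: [4, 4, 4, 4]

icmm:
  # exposure probability rating from CR when not supplied by an evaluator
  probability_bands: [0.1, 0.5, 1.0, 2.0]
  # rows: consequence 1-5; columns: likelihood 1-5
  matrix:
    - [1, 1, 2, 2, 2]
    - [1, 2, 3, 3, 3]
    - [2, 3, 3, 4, 4]
    - [2, 3, 4, 5, 5]
    - [2, 3, 4, 5, 5]

australian:
  # exposure-frequency rating from EF (days/year)
  frequency_bands: [10, 50, 100, 200]
  # table[likelihood-1][frequency-1][severity-1] -> level 1.0-5.0 (fractional)
  table:
    - [[1.0, 1.57, 1.91, 2.15, 2.33], [1.57, 2.15, 2.48, 2.72, 2.91], [1.91, 2.48, 2.82, 3.06, 3.24], [2.15, 2.72, 3.06, 3.3, 3.48], [2.33, 2.91, 3.24, 3.48, 3.67]]
    - [[1.57, 2.15, 2.48, 2.72, 2.91], [2.15, 2.72, 3.06, 3.3, 3.48], [2.48, 3.06, 3.39, 3.63, 3.82], [2.72, 3.3, 3.63, 3.87, 4.06], [2.91, 3.48, 3.82, 4.06, 4.24]]
    - [[1.91, 2.48, 2.82, 3.06, 3.24], [2.48, 3.06, 3.39, 3.63, 3.82], [2.82, 3.39, 3.73, 3.97, 4.15], [3.06, 3.63, 3.97, 4.21, 4.39], [3.24, 3.82, 4.15, 4.39, 4.58]]
    - [[2.15, 2.72, 3.06, 3.3, 3.48], [2.72, 3.3, 3.63, 3.87, 4.06], [3.06, 3.63, 3.97, 4.21, 4.39], [3.3, 3.87, 4.21, 4.45, 4.63], [3.48, 4.06, 4.39, 4.63, 4.82]]
    - [[2.33, 2.91, 3.24, 3.48, 3.67], [2.91, 3.48, 3.82, 4.06, 4.24], [3.24, 3.82, 4.15, 4.39, 4.58], [3.48, 4.06, 4.39, 4.63, 4.82], [3.67, 4.24, 4.58, 4.82, 5.0]]

romanian:
  # probability rating 1-6 from CR
  probability_bands: [0.1, 0.5, 1.0, 2.0, 5.0]
  # severity 1-7 from the 1-5 hazard rating
  severity_from_hr: [1, 3, 4, 6, 7]
  # rows: severity 1-7; columns: probability 1-6
  matrix:
    - [1, 1, 1, 1, 1, 1]
    - [1, 1, 1, 2, 2, 2]
    - [1, 1, 2, 2, 3, 3]
    - [1, 2, 2, 3, 4, 4]
    - [1, 2, 3, 4, 5, 5]
    - [1, 2, 3, 4, 5, 6]
    - [2, 3, 4, 5, 6, 7]

# catalog inherent-risk tier of each study industry
industry_ir:
  Mining of soil and sand: severe
  Ferrous casting: severe
  Ship repair: medium
  Equipment repair: medium
  Petrol station: low
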