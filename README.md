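# ohra — occupational health risk assessment toolkit

`ohra` is a Python library and command-line pipeline for assessing the health
risk of airborne chemical toxicants in workplaces, and — its real purpose —
for **comparing risk-assessment methods against each other** on the same
exposure data.  It implements the six most widely used occupational health
risk assessment (OHRA) models, harmonizes their incommensurable ordinal
outputs onto a common risk-ratio scale, compares the resulting distributions
nonparametrically, and checks each method's ordering against the inherent
risk of industries and chemicals.  It is written for industrial hygienists,
public-health researchers and methodologists studying OHRA strategy.

## The models

Every record is one measurement of one hazard at one job/location: an
airborne concentration CA (mg/m³) plus an exposure pattern (ET h/day,
EF days/year, ED years).  Two shared quantities drive most engines:

* **Exposure concentration** (μg/m³), averaged over the full period
  (AT = ED × 365 × 24 h, so ED cancels):

  EC = (CA × ET × EF × ED) / AT

* **Concentration ratio** CR = CA / OEL against the China PC-TWA (default)
  or ACGIH TLV-TWA; CR > 1 means the limit is exceeded.

The six engines:

| Method | Type | Core rule | Levels |
|---|---|---|---|
| EPA | quantitative | HQ = EC/RfC, banded (<0.1, 0.1–0.5, 0.5–1, 1–2, ≥2) | 1–5 |
| COSHH | control banding | risk-phrase hazard band × exposure potential → CS1–CS4 | 2–5 |
| Singaporean | semi-quantitative | Risk = √(HR × ER), rounded up | 1–5 |
| ICMM | matrix | consequence × likelihood grid | 1–5 |
| Australian | calculator | likelihood × frequency × severity nomogram | 1–5 (fractional) |
| Romanian | matrix | severity (1–7) × probability (1–6) grid | 1–7 |

To compare methods, each level is converted to a **risk ratio**
RR = level / denominator (5 for the five-level methods; 10 by default for the
Romanian grid, the conversion its published level→RR tables actually follow —
switchable to the literal 7).  RR distributions are then compared with
Kruskal–Wallis, pairwise Mann–Whitney (exact enumeration at small n) and
Spearman correlation, all midrank/tie-corrected, and each method's RR
ordering is verified against inherent risk: the catalog tier of each industry
(severe/medium/low) and the RfC-based rank of each chemical.

Because real campaign data are rarely shareable, the package ships a
synthetic generator that emulates a published five-industry exposure
structure (soil-sand mining, ferrous casting, ship repair, equipment repair,
petrol stations; 1,519 records over 13 hazards including manganese, benzene,
xylene and ethyl acetate): each summary row (n, mean, min–max) is expanded
into seeded, range-respecting, mean-faithful clipped-lognormal draws.

## Worked example

```
$ ohra simulate --seed 1 --out exposure.csv
wrote 1519 exposure records to exposure.csv (seed 1)
                         size      mean       min        max
industry
Mining of soil and sand   148  1.354582  0.143000  21.600000
Ferrous casting            97  1.355587  0.032517  13.004168
Ship repair               989  0.746636  0.000300  28.980000
Equipment repair           85  0.053402  0.000400   0.331797
Petrol station            200  0.024987  0.000300   0.486952

$ ohra assess --exposure exposure.csv --out results.csv
wrote 7985 results to results.csv (1129 (record, method) pairs skipped, see results.skips.csv)

$ ohra report --results results.csv --by industry
industry    Equipment repair Ferrous casting Mining of soil and sand Petrol station    Ship repair
method
Australian     0.6 (0.5–0.8)   0.9 (0.6–1.0)           0.9 (0.8–1.0)  0.6 (0.6–0.6)  0.7 (0.5–1.0)
COSHH          0.4 (0.4–1.0)   1.0 (0.4–1.0)           1.0 (1.0–1.0)  1.0 (1.0–1.0)  0.4 (0.4–1.0)
EPA            0.4 (0.2–1.0)             NaN                     NaN            NaN  1.0 (0.2–1.0)
ICMM           0.2 (0.2–0.6)   0.8 (0.2–1.0)           0.8 (0.6–1.0)  0.4 (0.4–0.4)  0.4 (0.2–1.0)
Romanian       0.1 (0.1–0.2)   0.4 (0.1–0.7)           0.4 (0.3–0.7)  0.1 (0.1–0.1)  0.1 (0.1–0.6)
Singaporean    0.4 (0.2–0.6)   0.8 (0.4–1.0)           0.8 (0.8–1.0)  0.4 (0.4–0.4)  0.4 (0.2–1.0)
```

Each cell is the median (min–max) risk ratio of one method in one industry.
Reading it: the EPA model only scores ship and equipment repair — the other
industries' hazards (silica and other dusts, gasoline) have no RfC, so those
(record, method) pairs land in the skip log, and its cells print NaN.  The
severe-tier industries (mining, ferrous casting) sit above the medium tier
(ship, equipment repair) for the Singaporean, ICMM, Australian and Romanian
rows, and the COSHH row is dragged to 1.0 at petrol stations because control
banding scores gasoline's carcinogen risk phrases regardless of its very low
measured concentrations.

Downstream:

```
$ ohra compare --results results.csv --exposure exposure.csv --out-dir cmp
$ ohra verify  --results results.csv --exposure exposure.csv --out-dir ver
```

`compare` writes the Kruskal–Wallis omnibus, the pairwise Mann–Whitney
matrix with significance letters, and the Spearman RR/CR correlation matrix
(unit diagonal; a CR column relates each method to raw exposure intensity).
`verify` writes, per method, whether its median RR ordering follows the
inherent-risk sequence of the five industries and of the four focal
toxicants (manganese > benzene ≈ xylene > ethyl acetate, by ascending RfC
with concentration-ratio tie-breaking), and whether it statistically
separates all groups at α = 0.05.

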