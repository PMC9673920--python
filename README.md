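# glycopk

Glycoform-resolved pharmacokinetics of therapeutic monoclonal antibodies.

The Fc N-glycan attached to an IgG influences how fast the antibody is
cleared from serum: oligomannose glycoforms (e.g. Man5) clear faster than
the agalactosylated, core-fucosylated reference G0F; monoantennary species
clear moderately faster; galactosylated and sialylated species clear more
slowly. Standard total-concentration assays cannot see any of this.
`glycopk` implements the glycoform-resolved approach: the compositional
glycosylation profile measured by LC-MS (relative abundances *f*<sub>g</sub>(*t*))
is combined with the absolute total concentration from ELISA
(*C*<sub>total</sub>(*t*)) into per-glycoform concentration-time series

&nbsp;&nbsp;&nbsp;&nbsp;*C*<sub>g</sub>(*t*) = *f*<sub>g</sub>(*t*) · *C*<sub>total</sub>(*t*),

per animal and time point, and each series is summarized by
non-compartmental analysis (NCA): C<sub>max</sub>, terminal rate constant
λ<sub>z</sub> by log-linear best fit, AUC by the trapezoidal rule,
AUC<sub>∞</sub> = AUC<sub>last</sub> + C<sub>last</sub>/λ<sub>z</sub>, and

&nbsp;&nbsp;&nbsp;&nbsp;CL<sub>g</sub> = dose<sub>g</sub> / AUC<sub>∞,g</sub>  (mL/day/kg; CL/F after subcutaneous dosing),

where dose<sub>g</sub> distributes the nominal protein dose over glycoforms
according to the profile of a spiked serum standard. Because inter-animal
variability dominates absolute clearances, CL<sub>g</sub> is normalized to
the reference glycoform *within each animal*, and glycoforms are compared
by paired t tests with Benjamini–Hochberg FDR control (5%) per experimental
group. Serum profiles of different routes (IV bolus vs subcutaneous) are
compared per glycoform with Welch tests, using spiked standards as a
batch-effect screen: a difference seen in serum but not between standard
batches is flagged *PK-specific*.

The package is aimed at PK scientists and analytical chemists running such
studies: it reads and writes tidy CSV tables, ships the full statistical
machinery, and includes a synthetic-study generator (one-compartment
kinetics with glycoform-specific clearance multipliers, first-order
subcutaneous absorption with a galactose-dependent bioavailability bias,
ELISA and LC-MS observation noise, background interference and quantitation
floors) so that every stage of the pipeline can be validated against known
truth.

## Worked example

Simulate a five-minipig IV study (0.5 mg/kg, sampling 0.08–168 h) and
analyze it end to end:

```sh
glycopk simulate --out sim --seed 1
glycopk run --profiles sim/profiles.csv --concentrations sim/concentrations.csv \
            --doses sim/doses.csv --standards sim/standards.csv --out results
glycopk report results
```

`results/report.md` then contains (output of the commands above):

```
| glycoform | CHO-mAb1-IV CL (mL/day/kg) |
| --------- | -------------------------- |
| G0F       | 17.89 ± 0.89               |
| G1F       | 14.86 ± 1.15**             |
| G2F       | 14.74 ± 0.59**             |
| Man5      | 20.49 ± 0.95*              |
| G0F-N     | 19.08 ± 1.15               |
| Total     | 17.04 ± 0.83               |

| glycoform | group       | n | mean  | sd    | ci95_low | ci95_high |
| --------- | ----------- | - | ----- | ----- | -------- | --------- |
| G0F       | CHO-mAb1-IV | 5 | 1.000 | 0.000 | 1.000    | 1.000     |
| G0F-N     | CHO-mAb1-IV | 5 | 1.069 | 0.081 | 0.968    | 1.170     |
| G1F       | CHO-mAb1-IV | 5 | 0.832 | 0.073 | 0.742    | 0.922     |
| G2F       | CHO-mAb1-IV | 5 | 0.826 | 0.050 | 0.764    | 0.888     |
| Man5      | CHO-mAb1-IV | 5 | 1.149 | 0.087 | 1.040    | 1.257     |
```

The first table is clearance per glycoform, mean ± SD over the five
animals; stars mark glycoforms whose clearance differs from the G0F
reference after FDR adjustment (** p < 0.01). The second table gives the
within-animal clearance ratios CL<sub>g</sub>/CL<sub>G0F</sub> with 95%
confidence intervals — for this seed the pipeline recovers the planted
multipliers (Man5 1.20, G0F-N 1.08, G1F 0.92, G2F 0.85) to within the
per-study sampling noise; averaged over replicate studies the recovery is
within 1% (see `scripts/acceptance.py`). The oligomannose glycoform clears
fastest and the galactosylated glycoforms slowest, the pattern the method
is designed to resolve.

The same `run` command accepts real study exports: a profile table
(`animal_id, group, route, time_h, glycoform, fraction` — percent or unit
scale), a concentration table (`animal_id, group, time_h, conc_ug_ml`), a
dose table (`group, nominal_dose_mg_per_kg, route`) and spiked-standard
profiles. `--compare-groups A B --compare-time-h 24` adds the per-glycoform
serum-profile comparison with the PK-specific/batch-effect flags.

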