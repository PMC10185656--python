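# aisquant

Quantification toolkit for axon-initial-segment (AIS) integrity studies in
cultured neurons — multichannel immunofluorescence morphometry of the
soma / GAP / AIS compartments, neurofilament accumulation scoring,
patch-clamp feature extraction, and the nonparametric group-comparison
layer used to call phenotypes. A deterministic synthetic-data generator
renders microscopy fields and sweep families with complete ground truth,
so every measurement in the pipeline is validated against known answers.

## Who this is for

Labs quantifying AIS disruption in iPSC-derived motor neuron models (ALS
and related axonopathies) from semi-automatic image analysis: a seed point
and neurite entry zones per cell, then automatic soma delimitation,
ankyrin-G AIS detection, GAP delineation, and per-channel integrated
densities — plus current-clamp firing-pattern classification and
voltage-clamp current-density ratios from the same cultures.

## The measurements

For each cell with a single soma-derived AIS:

* geometry — soma area; GAP and AIS lengths `L` (medial-axis geodesics),
  areas `A` (pixel counts × pixel_size²), and mean axonal calibers
  `c = A / L`;
* chemistry — integrated densities `ID = A · ⟨gray⟩` of pNF-M/H and panNav
  in GAP and AIS, their proximal totals `ID_total = ID_GAP + ID_AIS`
  (exact), and the sodium-channel polarity index
  `ID^Nav_AIS / ID^Nav_GAP` (undefined for GAP-less cells, which are
  removed from ratio comparisons);
* pathology — presence and extent (`gap_only` / `gap_and_ais`) of
  phospho-neurofilament accumulations detected above a control-calibrated
  threshold; NF-L soma positive-area fraction; β3-tubulin neurite network
  density with somas deleted.

Patch-clamp records yield QC flags (Rs ≤ 10 MΩ, ΔRs ≤ 20%, RMP < −35 mV
after 15 mV junction correction), RMP, rheobase, first-AP threshold /
amplitude / half-width / delay (dV/dt ≥ 10 mV/ms criterion), maximum
firing frequency, the four-class firing pattern (none / one spike /
adaptive / repetitive), and Na/K current densities.

Group comparisons use Kruskal–Wallis with Dunn's post-hoc (Holm-adjusted)
and Fisher's exact tests for pattern frequencies; integrated-density
calls must additionally pass a 3-fold median-difference gate.

See `docs/methods.md` for the full measurement model, parameter defaults
and limitations.

## Worked example

A 20-cell-per-group synthetic study, measured end to end and compared:

```python
import pandas as pd
from aisquant import synthgen as sg, aismorph as am, imgcore as ic, groupstats as gs

cfg = sg.RenderConfig(channels=("map2", "tuj1", "ankg", "pnf", "pannav"), z_slices=3)

controls = list(sg.generate_cohort(20, sg.control_params(), cfg, seed=1, group="control"))
mutants = list(sg.generate_cohort(20, sg.mutant_params(), cfg, seed=2, group="mutant"))
calibration = list(sg.generate_cohort(6, sg.calibration_params(), cfg, seed=3))

thresholds = am.calibrate_thresholds({
    ch: [ic.max_intensity_projection(stack, ch) for _, stack, _, _ in calibration]
    for ch in ("ankg", "pnf")
})

rows = []
for group, cohort in (("control", controls), ("mutant", mutants)):
    for gt, stack, masks, ann in cohort:
        m = am.measure_cell(stack, ann, thresholds)
        if m.included:
            row = m.to_row(); row["group"] = group; rows.append(row)
df = pd.DataFrame(rows)

print(df.groupby("group")[["gap_length", "gap_caliber", "nav_ais_to_gap_ratio"]]
        .median().round(2))
report = gs.build_report(df, control_group="control",
                         measures=["gap_length", "gap_caliber", "nav_ais_to_gap_ratio"])
print(report[["measure", "dunn_p_adj", "declared_significant"]].round(6).to_string(index=False))
```

Output:

```
         gap_length  gap_caliber  nav_ais_to_gap_ratio
group
control        4.91         1.42                 65.22
mutant         7.72         1.91                  6.48
             measure  dunn_p_adj  declared_significant
          gap_length    0.000002                  True
         gap_caliber    0.000000                  True
nav_ais_to_gap_ratio    0.000000                  True
```

The mutant condition (generated with a longer GAP, thicker proximal axon
and sodium-channel leakage into the GAP) shows the expected phenotype:
GAP length and caliber up, AIS/GAP panNav ratio collapsed from ~65 to ~6,
all Dunn-significant against the control group.

The same flow is available from the shell:

```bash
aisquant generate --n-cells 20 --seed 1 --out cohort/ --with-ephys
aisquant measure --images cohort/images --annotations cohort/annotations/annotations.json \
                 --thresholds thr.json --out measurements.csv
aisquant ephys --sweeps cohort/ephys --out features.csv
aisquant compare --measurements measurements.csv --out report/
```

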