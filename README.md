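# pyrtrace

Stable-isotope tracing and imaging-lipidomics data reduction for renal
gluconeogenesis studies: given GC-MS selected-ion-monitoring (SIM) signal
areas from an oral [U-¹³C₃]pyruvate tolerance test, `pyrtrace` corrects
mass isotopomer distributions (MIDs) for natural isotope abundance,
computes atom percent excess (APE) and fractional contributions (FC), and
partitions blood glucose carbon into gavaged-pyruvate, endogenous-pyruvate
and non-pyruvate sources. A second branch screens MALDI-MSI lipid
intensities over kidney regions of interest for genotype-dependent species.
It is written for metabolism researchers reducing tracer GC-MS data and
for reviewers wanting a reproducible, testable version of that reduction.

## The model

For a fragment carrying n labelable carbons with corrected MID M₀..Mₙ:

```
APE            = Σ_{i=1..n} Mᵢ·i / n
FC(met ← src)  = APE_met / APE_src
```

Blood glucose (C4–C6 fragment, n = 3) is partitioned as

```
FC(glc ← gavaged tracer) = APE_glc / APE_tracer          (APE_tracer = 0.40)
FC(glc ← blood pyruvate) = APE_glc / APE_blood_pyruvate
FC(glc ← non-pyruvate)   = 1 − FC(glc ← blood pyruvate)
```

with absolute attributions FC × [glucose, mg/dL]. Upstream, measured SIM
channel vectors are inverted through per-fragment natural-abundance
correction matrices (column j = theoretical isotope pattern with j carbons
fixed as ¹³C) by non-negative least squares. Downstream statistics use the
two-stage (BKY) linear step-up FDR procedure. See `docs/methods.md` for
assumptions, parameter defaults and limitations.

## Worked example

Generate a synthetic tracing cohort (8 mice per genotype, 5 % channel
noise, seed 1), correct it, and partition glucose carbon:

```python
import pyrtrace as pt
from pyrtrace.midcorr import correct_area_table
from pyrtrace.tracer import partition_table

cfg = pt.SimConfig(seed=1)            # control: f_np=0.55; KSPAPN: f_np=0.70
sim = pt.simulate_optt(cfg)
mids = correct_area_table(sim.areas)
parts = partition_table(mids, sim.metadata)
print(parts.groupby("genotype")[[
    "ape_pyruvate", "ape_glucose_C456", "glc_fc_from_non_pyruvate",
    "glc_mgdl_from_gavaged", "glc_mgdl_from_endogenous_pyruvate",
    "glc_mgdl_from_non_pyruvate"]].mean().round(3).to_string())
```

prints

```
          ape_pyruvate  ape_glucose_C456  glc_fc_from_non_pyruvate  glc_mgdl_from_gavaged  glc_mgdl_from_endogenous_pyruvate  glc_mgdl_from_non_pyruvate
genotype
KSPAPN           0.247             0.078                     0.686                 44.785                             27.687                     158.238
control          0.191             0.093                     0.509                 42.125                             46.503                      91.795
```

Read: in the overexpressor cohort, blood pyruvate is more enriched
(APE 0.247 vs 0.191), the recovered non-pyruvate share of glucose carbon
is higher (0.686 vs 0.509, planted truths 0.70 / 0.55), and most of the
extra circulating glucose is attributed to non-pyruvate sources
(158 vs 92 mg/dL). The same objects expose per-sample MIDs, FCs and NNLS
residuals.

The command line mirrors the library:

```
pyrtrace simulate --seed 1 --out-dir data/
pyrtrace correct --areas data/sim_areas.tsv --out mids.tsv
pyrtrace partition --mids mids.tsv --metadata data/sample_metadata.tsv --out parts.tsv
pyrtrace msi-screen --roi data/msi_roi.tsv --db data/lipid_db.tsv --out-prefix msi
pyrtrace frag-mz C11H25O3Si2 --deprotonated --channels 5
```

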