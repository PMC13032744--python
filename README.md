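# spinefate

Synaptic calcium event extraction and longitudinal dendritic-spine fate
analysis, with a ground-truth synthetic-data generator.

`spinefate` is for labs doing two-photon imaging of dendritic spines in
slice culture who need to go from per-ROI fluorescence time series to
per-synapse event rates, spine survival across imaging days, astrocyte
proximity, and treatment-level statistics — for example when testing how
soluble Aβ from Alzheimer's-disease brain extract changes synaptic
activity and spine loss, and whether astrocyte contact protects spines.
Every stage ships with a simulator that generates the same data
structure with known ground truth, so the whole chain is testable by
parameter recovery without any imaging data.

## What it computes

**Trace conditioning.** Each ROI trace F(t) is detrended with an
order-10 least-squares polynomial baseline B(t), denoised with the Okada
filter (samples that are single-point local extrema are replaced by
their neighbours' mean; 4 iterations), converted to
ΔF/F = (F − B)/B, and z-scored.

**Event detection.** Events are inferred by sparse non-negative AR(1)
deconvolution (OASIS-style pool-adjacent updates):

    c_t = g·c_{t−1} + s_t,  s_t ≥ 0,
    minimise ½‖z − c‖² + λ·Σ s_t,  accepted events have s ≥ s_min·σ̂

with g estimated from the trace autocovariance and refined on isolated
event decays, λ set by a noise-budget constraint, and σ̂ the recording's
noise floor, so `s_min = 2.5` is an operative 2.5σ event threshold.
Per-spine rates (Hz) average over repeat recordings.

**Bleaching.** Normalised dendrite-intensity profiles are fitted with
`A·e^(−t/τ1) + B·e^(−t/τ2)`; the bleach rate is F0 − F60 (mean of
frames 5–10 minus mean of the last five frames).

**Longitudinal analysis.** Day-1/Day-2 spine maps are aligned by rigid
translation and matched one-to-one; a spine survives iff its match lies
within the spine radius. A spine is astrocyte-proximal iff astrocyte
signal lies within twice its head radius. Relative changes are
ΔHz/Hz = (POST − PRE)/PRE, likewise for the phosphatidylserine probe
(ΔPsVue/PsVue).

**Statistics.** Group means average within animal first; inference uses
a hierarchical permutation test that permutes treatment at the level it
was assigned (slices within animal), avoiding pseudoreplication. A Tukey
ladder transform and pg/mL → pM conversion utilities are included.

## Worked example

```python
import numpy as np
from spinefate import synthetic, longitudinal
from spinefate.stats import hierarchical_permutation_test, pg_per_ml_to_pM

cfg = synthetic.SimulationConfig(seed=42)          # 10 animals, 4 arms
spines, truth = synthetic.simulate_spine_population(cfg)
sp = longitudinal.annotate_changes(spines)
for arm, grp in sp.groupby("treatment"):
    print(f"  {arm:12s} survival {grp.survived.mean():.2f}  "
          f"rate PRE {grp.rate_pre.mean():.3f} Hz  POST {grp.rate_post.mean():.3f} Hz")
res = hierarchical_permutation_test(sp, "rate_post", "abeta", n_perm=1000, seed=0)
print(f"Abeta effect on POST rate: +{res.observed:.3f} Hz, p = {res.p_value:.4f}")
print(f"Abeta40 227.2 pg/mL = {pg_per_ml_to_pM(227.2, 4329.8):.1f} pM")
```

prints

```
  Abeta+/TBOA  survival 0.68  rate PRE 0.093 Hz  POST 0.212 Hz
  Abeta+/veh   survival 0.75  rate PRE 0.095 Hz  POST 0.215 Hz
  Abeta-/TBOA  survival 0.89  rate PRE 0.098 Hz  POST 0.100 Hz
  Abeta-/veh   survival 0.89  rate PRE 0.102 Hz  POST 0.098 Hz
Abeta effect on POST rate: +0.114 Hz, p = 0.0010
Abeta40 227.2 pg/mL = 52.5 pM
```

Read: Aβ+ treatment roughly doubles POST event rates (permutation
p ≈ 0.001 with slices-within-animal exchange), lowers survival, and the
survival deficit is largest for astrocyte-free spines under vehicle —
all effects the generator planted and the pipeline recovers.

The same chain is scriptable from a shell:

```bash
spinefate simulate --seed 1 --out sim/ --traces
spinefate process  --traces sim/traces.csv --out processed.csv
spinefate events   --traces processed.csv --out events/
spinefate report   --spines sim/spines.csv --out report/
```

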