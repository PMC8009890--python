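# erpstates

Microstate analysis of infant event-related potentials (ERPs) with
outcome prediction, built for studies of early social attention in
infants at elevated likelihood of autism.

## The problem

In face-processing ERP studies of 8-month-old infants, the **Nc**
("negative central") — a frontal negativity between roughly 300 and
800 ms after stimulus onset — indexes attention engagement. Classic
analyses reduce each averaged ERP to the Nc mean amplitude and peak
latency over frontal electrode regions. A complementary, data-driven
view treats the whole scalp field as a sequence of **microstates**:
brief periods during which the field keeps a quasi-stable topography
while only its strength varies, where strength is the global field
power

GFP(t) = sqrt( (1/N) Σ_i (v_i(t) − v̄(t))² ),

the standard deviation of the potential across the N channels.
This package implements both views and links them to later outcomes:

1. **Nc features** — mean amplitude and peak latency of region-averaged
   waveforms in an inclusive window, and condition difference scores
   (face-direct-gaze FD minus non-social Noise, face-averted FA minus Noise).
2. **Microstate discovery** — atomize-and-agglomerate hierarchical
   clustering (AAHC) of GFP-normalised topographies of a reference
   group's grand average; the number of maps is selected by
   cross-validated explained variance
   GEV = Σ_t (GFP_t · corr(v_t, map))² / Σ_t GFP_t²
   with a randomization test on each added map.
3. **Template fitting** — each sample of each subject's ERP is labelled
   with the best-correlating map (signed spatial correlation; evoked
   analyses are polarity-sensitive), yielding per-map **duration** and
   **mean GFP** inside the 300–794 ms window.
4. **Outcome prediction** — a genetic algorithm selects feature subsets
   whose fitness is the AUC of a 10-fold cross-validated class-weighted
   SVM (categorical outcome, within the family-history group, 70/30
   stratified holdout); an elastic net with leave-one-out outer and
   repeated 10-fold inner cross-validation predicts the dimensional
   VABS Socialization score. Uncertainty comes from repeated refits,
   subject bootstrap, and label-shuffle permutation tests.
5. **Synthetic cohorts** — a generator plants known topographies,
   group/condition-dependent segment durations and strengths, and
   outcomes linked to the planted features, so every stage can be
   validated by parameter recovery.

## Worked example

```python
from erpstates import (SimConfig, simulate_cohort, select_n_maps, CvParams,
                       fit_templates, extract_features)
from erpstates.microstates import match_maps

cfg = SimConfig(seed=7)                      # 40/72/19 cohort, 64 ch, 500 Hz
records, erps, truth, planted = simulate_cohort(cfg)
ref = [erps[r.subject_id]["FD"] for r in records if r.group == "noFH-noASD"]
sel = select_n_maps(ref, range(2, 8), CvParams(seed=11))
print(sel.k_opt)                             # 4
print({k: round(v, 3) for k, v in sel.test_ev.items()})
# {2: 0.586, 3: 0.86, 4: 0.971, 5: 0.973, 6: 0.974, 7: 0.975}
perm, cors = match_maps(sel.maps, planted.maps)
print(cors.round(3))                         # [0.994 0.999 0.995 0.998]
```

The selection walks k upward: explained variance in held-out subjects
jumps until the planted k=4 (0.59 → 0.86 → 0.97) and then flattens; the
randomization test stops the chain there, and each recovered map matches
a distinct planted topography at |spatial correlation| ≥ 0.99.

Per-subject features then feed the prediction stages:

```python
seg = fit_templates(erps["S001"]["FD"], sel.maps, (0, 794))
feats = extract_features(seg, sel.maps.k, (300, 794), cfg.fs)
print(feats.duration_ms)                     # [284.  28. 184.   0.] — sums to 496 ms
```

## Command line

```bash
erpstates simulate --out-dir data --seed 7
erpstates microstate learn --erp-dir data/erps --subjects data/subjects.csv \
    --k-range 2 7 --window 0 794 --out maps/
erpstates microstate fit --maps maps/ --erp-dir data/erps --out features.csv
erpstates classify --features features.csv --subjects data/subjects.csv --out reports/
erpstates regress  --features features.csv --subjects data/subjects.csv --out reports/
erpstates run --simulate --out-dir run/   # the whole pipeline + manifest
```

ERPs travel as plain CSV matrices (rows = channels, columns = samples,
microvolts) with a JSON sidecar for sampling metadata; EDF epoch files
are read via mne.

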