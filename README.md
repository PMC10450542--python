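# appmarker

Behavioral markers from 7-day smartphone app-usage event logs for
depression screening.

The pipeline turns raw foreground/background app events into the 864-cell
behavioral feature grid — per app category and overall smartphone use, split
by weekday/weekend and the four diurnal periods (night/morning/afternoon/
evening), covering usage duration, launch counts, unique-app counts, usage
entropy and a label-aware hamming-distance uniqueness ratio, plus gap-based
session counts (micro ≤ 15 s, review ≤ 60 s, engage > 60 s at a 45 s gap
threshold).  Features pass a 50 % user-sparsity filter, four selection
regimes (information-gain filter, embedded random-forest ranking,
Boruta-style all-relevant wrapper, bootstrap stability selection with a
0.50→0.98 threshold sweep) and nested leave-one-participant-out
cross-validation with inner tuning, a classifier zoo and a top-5 stacking
ensemble with a logistic meta-learner.  Participants are labeled by PHQ-9
total ≥ 10.

Because no real cohort ships with the package, a synthetic cohort generator
(`appmarker.synthetic`) emits 7-day event streams with configurable planted
group effects (weekday education-app duration, weekend photo/video app-count
dispersion, weekday usage entropy, weekday communication-app diversity) so
every stage is testable end to end by parameter recovery.

## CLI

```bash
# generate a synthetic cohort (events.csv, catalog.csv, phq9.csv, truth.csv)
appmarker synth --n 60 --seed 7 --scale-factor 0.1 --out data/

# pair events into categorized usage intervals
appmarker ingest --events data/events.csv --catalog data/catalog.csv \
    --window-start 2020-08-03T00:00:00 --out intervals.csv

# extract the sparsity-filtered feature matrix
appmarker features --events data/events.csv --catalog data/catalog.csv \
    --phq9 data/phq9.csv --window-start 2020-08-03T00:00:00 --out matrix.csv

# nested LOPOCV evaluation with a chosen feature-selection regime
appmarker evaluate --matrix matrix.csv --phq9 data/phq9.csv --fs boruta \
    --budget 5 --seed 0 --out report/
```

The weekend defaults to Friday–Saturday and is configurable (`--weekend
sat-sun`).  For fully leakage-free hamming-ratio features (recomputed per
outer fold from training labels only) use the Python API:

```python
from datetime import datetime
from appmarker import ObservationWindow, nested_lopocv, sparsity_filter
from appmarker.feature_selection import make_boruta
from appmarker.pipeline import matrix_from_cohort
from appmarker.synthetic import EffectConfig, generate, scale

window = ObservationWindow(start=datetime(2020, 8, 3))
cohort = generate(60, window, scale(EffectConfig(), 0.1), seed=7)
fm, hamming_index = matrix_from_cohort(cohort, window)
fm = sparsity_filter(fm)
result = nested_lopocv(fm.df, cohort.labels, make_boruta(max_depth=6),
                       seed=7, hamming_index=hamming_index)
```

## Layout

- `src/appmarker/event_model.py` — event parsing, fg/bg pairing, app catalog
- `src/appmarker/phq9.py` — PHQ-9 scoring and the ≥10 dichotomization
- `src/appmarker/diurnal.py` — day-type/period assignment, boundary splitting
- `src/appmarker/sessions.py` — 45 s gap segmentation, session typing
- `src/appmarker/markers.py` — the 864-feature grid, entropy, hamming ratio,
  sparsity filter, standardization
- `src/appmarker/feature_selection.py` — IG / RF / Boruta / stability regimes
- `src/appmarker/modeling.py` — nested LOPOCV, tuning, stacking, metrics,
  appearance frequency, permutation-importance attributions
- `src/appmarker/synthetic.py` — synthetic cohort generator
- `src/appmarker/pipeline.py`, `src/appmarker/cli.py` — glue and CLI
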