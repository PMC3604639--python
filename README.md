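# pianoprint

Pianists do not play scales perfectly evenly. Even when instructed to play a
two-octave C-major scale as regularly as possible at eight notes per second,
each player produces a consistent pattern of per-note timing deviations — a
few milliseconds early here, a few late there — that is stable across
recording sessions, largely tied to the movement rather than the sound, and
too small to hear. `pianoprint` implements the full analysis of these
*pianistic fingerprints* for researchers in sensorimotor timing and music
psychophysics:

- **Extraction** — read Standard MIDI Files, isolate correctly performed
  15-note scale runs (wrong, missing, or surplus notes reject a run), fit an
  ordinary least-squares line to onset time vs. position in the run, and keep
  the residuals *d*₁…*d*₁₅ (ms, positive = late). Averaging over runs per
  hand × movement direction gives the 2 × 2 × 15 *fingerprint*; the sample SD
  of a run's 14 inter-keystroke intervals gives its *unevenness* (SD-IKI).
- **Identification** — temporal distance between traces,
  √(Σᵢ(aᵢ−bᵢ)²/15), or Pearson correlation (Fisher-z); independent
  nearest-match assignment of each query fingerprint to a database; exact
  one-sided binomial test against chance and Clopper–Pearson 95% intervals;
  bootstrap over 8-pianist subsamples; grouped contrasts (same movement vs.
  same sound, cross-hand self vs. other, time vs. keyboard alignment).
- **Stimuli** — render any trace to MIDI on the nominal 125 ms grid with its
  deviations multiplied by a magnification factor (0 = isochronous,
  1 = veridical, 5 = exaggerated), with metronome lead-in, fixed note
  duration and velocity; build the 144-trial same/different recognition set.
- **Psychophysics** — maximum-likelihood adaptive procedure (2,500 candidate
  psychometric curves p(yes) = a + (1−a)·logistic(k(x−m)), k = 4, stimulus at
  the 64%-response point of the running maximum-likelihood curve), catch
  trials with the 30% block-validity rule, d′ for the recognition task, and
  conversion of factor thresholds to unevenness in ms.
- **Synthesis** — a calibrated generator of pianist populations, session
  recordings, and simulated listeners, so every stage runs end-to-end without
  any recordings (none are publicly deposited).

## Worked example

```python
import numpy as np
from pianoprint import (gen_population, gen_session_runs, session_fingerprint,
                        nn_identify)

pop = gen_population(8, seed=11)                      # eight latent fingerprints
rng = np.random.default_rng(12)
db, queries = [], []
for p in pop:                                         # two sessions each
    db.append(session_fingerprint(gen_session_runs(p, "first", seed=rng), p.label, "first"))
    queries.append(session_fingerprint(gen_session_runs(p, "followup", seed=rng), p.label, "followup"))

res = nn_identify(queries, db)                        # match follow-up to first
print(res.n_correct, res.n_total, res.p_binomial, res.ci95)
```

prints

```
8 8 5.960464477539063e-08 (0.6305834294988116, 1.0)
```

all eight follow-up fingerprints are matched to the right pianist (chance
1/8); the exact binomial tail probability is 6·10⁻⁸ and the Clopper–Pearson
95% interval for the recognition rate is (0.63, 1.0).

The numbered scripts under `analysis/` run the full study on synthetic
cohorts and write their tables to `results/`:

```sh
python analysis/01_simulate_cohort.py      # traces + unevenness tables
python analysis/02_identify_pianists.py    # distances, identification, contrasts
python analysis/03_perception.py           # 144-trial set, d', MLP thresholds
python analysis/04_larger_cohorts.py       # 18/20-pianist cohorts + bootstrap
```

A typical run of `02_identify_pianists.py` reports self distance 3.28 ms vs.
other distance 7.06 ms and flawless 8/8 combined identification; 
`03_perception.py` reports d′ = −0.53 for veridical pairs (the deviations sit
below the simulated listener's threshold) vs. d′ = +2.47 when magnified
five-fold, and a mean irregularity threshold slightly above factor 1.

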