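# Methods

## Scope and data model

`myoforge` models one class of experiment: an excised striated-muscle strip
mounted isometrically in an organ bath, stimulated with programmed pulse
trains through field electrodes, its force sampled uniformly in time. The
package covers four stages — protocol representation, trace synthesis, trace
analysis, and per-sample reporting — connected by two plain-text formats
(the trace file and the summary CSV, see `trace_io`).

Time is measured from the first stimulus onset. Forces are in millinewtons,
durations in seconds unless a field name says otherwise.

## Stimulation protocol

`StimulationProtocol` stores the programmed parameters (pulse voltage,
width, interval, intra-train frequency, train pause, trains per group,
number of groups, group pause, total run time); defaults are 20 V / 25 ms /
60 ms / 11.8 Hz / 500 ms / 500 / 10 / 60 s / 45 min. The intra-train
frequency is defined as `1000/(width + interval)` Hz rounded to one decimal,
and the constructor rejects an inconsistent value.

The stated train/group counts do not determine a train-onset period: 500
trains × 10 groups plus nine 60-s group pauses cannot be arranged to fill a
45-min run for any plausible train length, and the pulse-accounting rule of
"2 stimuli per second" is likewise incompatible with the observed ~0.83
trains/s. The schedule therefore takes the onset period as an explicit
parameter. Its default, **1.2097 s**, is fixed by the one quantity the
protocol's outputs do pin down: a 5-min analysis quadrant must contain
exactly 248 trains. `build_schedule` produces a continuous onset sequence by
default; a grouped mode inserting the group pause after every
`trains_per_group` onsets exists but is off, because per-quadrant counts are
uniform only for a continuous sequence. `pulse_count` implements the
2-stimuli-per-second accounting rule as stated, independent of the schedule.

## Synthetic traces

The generator exists because no raw recordings of this experiment type are
publicly deposited; it emulates the features the analysis relies on and
nothing more.

* **Twitch kernel** — normalized difference of exponentials with
  `rise_tau = 0.02 s`, `decay_tau = 0.12 s`. This is a minimal
  phenomenological twitch (fast rise, slow relaxation, peak equal to the
  drawn amplitude); there is no cross-bridge, calcium or length–tension
  modeling.
* **Twitch pair per train** — a major twitch at the onset and a companion at
  `intra_pair_delay = 0.5 s` (the train pause, the only within-train time
  constant the protocol states) scaled by `minor_ratio`: default 0.5 for the
  *alternating* high/low pattern and 0.9 for the *high-only* pattern, so
  both patterns still produce a classifiable major/minor pair — matching
  recordings in which even "high peaks only" samples yield equal major and
  minor counts.
* **Amplitudes** — i.i.d. normal draws (per-sample mean and SD in mN)
  truncated below at `amp_floor` (default 0, keeping forces physical). A
  positive floor models fully responsive tissue whose amplitude spread is
  large relative to its mean: with SDs like 17.6 mN on a 15.9 mN mean, a
  floor of zero would make a few trains fall below any detection threshold,
  which is not what fully responsive preparations show. The demo fixture set
  uses a 1 mN floor for that reason. Truncation inflates the realized mean
  above the nominal mean for high-SD samples (by ≈ +4 mN at 15.9 ± 17.6);
  this is why the demo's measured force ordering can swap two samples whose
  nominal means are close — a known limitation, not corrected for.
* **Fatigue envelope** — multiplies the amplitude at each onset time:
  exponential `exp(−λt)` or linear `max(0, 1−λt)`. The demo solves λ per
  sample so the envelope passes through the sample's half-time force at
  22.5 min; λ is treated as a property of the preparation and does not
  rescale when a shorter recording is generated.
* **Noise and drift** — additive Gaussian noise (`noise_sd = 0.05 mN`
  default, a realistic transducer noise floor at these force scales) and a
  linear baseline drift term; a positive drift emulates viability loss.
* **Sampling** — 100 Hz default, resolving the 20 ms rise; the generator
  refuses a rate that cannot resolve the twitch pair (< 10/`intra_pair_delay`).
* **Determinism** — one `numpy` Generator seeded from `TraceModel.seed`
  drives amplitude and noise draws; identical parameters and seed give
  bit-identical traces, and the seed is written into trace metadata.

The sham generator produces noise around a zero baseline (inert elastic
ribbon). What passing tests on these traces shows: the analysis correctly
inverts this generative family (counts, classification, response rate,
envelope and drift recovery). What it does not show: robustness to real
recording artifacts absent from the generator — movement/electrode
artifacts, non-Gaussian or correlated noise, slow non-linear baseline
wander, missed or ectopic contractions.

## Trace analysis

* **Noise estimate** — `1.4826·MAD(Δforce)/√2` from first differences.
  Twitches occupy roughly half the samples at the default period, so a
  spread statistic of the raw trace would be signal-contaminated;
  differencing suppresses the smooth twitch component.
* **Peak detection** — `scipy.signal.find_peaks` with a minimum separation
  of `0.4·intra_pair_delay`; candidate heights are measured above the
  baseline and must exceed `min_height`, default **5× the noise SD**. The
  multiple is set by a false-positive budget: at 100 Hz a 45-min pure-noise
  trace has ~270 000 samples, so a 3σ threshold would admit dozens of
  spurious peaks on a sham trace while 5σ admits ≪ 1 expected.
* **Baseline** — median force over the 0.1 s preceding each train onset
  (the relaxed state, after the previous pair has decayed). Troughs *within*
  a train window sit well above rest (the major twitch has not fully decayed
  when the companion rises), so a trough-median baseline would overestimate
  rest force by ~0.2 mN at default settings and bias all heights low.
* **Height refinement** — 3-point parabolic interpolation around each grid
  maximum. At 100 Hz the grid undershoots a 20 ms-rise twitch peak by up to
  ~0.5% of amplitude; refinement removes this bias, which would otherwise be
  comparable to the 2-SEM tolerance of mean-force recovery at n = 248.
* **Classification** — within each train window `[onset_k, onset_{k+1})`
  the tallest peak is *major*, the second tallest *minor*; further peaks in
  the window are discarded as spurious, windows with a single peak yield a
  major only, and peaks before the first onset are dropped. The
  classification is pairwise within-train rather than by global threshold,
  so it is invariant to rescaling the trace and handles both amplitude
  patterns with one rule.
* **Quadrants** — half-open `[start, start + 300 s)` windows; the default
  analysis quadrant is the first.
* **Response rate** — `100 × responding/programmed` trains, one decimal; a
  train responds if at least one peak is assigned to it.
* **Fatigue** — `initial_force` is the mean major height over the first
  60 s (a window average is noise-robust; a single "initial peak" is not);
  `half_time_force` the mean within ±30 s of half the run time;
  `fatigue_percent = 100·(initial − half)/initial`. The absolute half-time
  force and the decrement are both reported, since either convention is
  found in practice. `fit_fatigue_rate` estimates an exponential λ by
  log-linear regression of major heights on time.
* **Viability** — the pre-run check passes when each of the (default 3)
  biphasic test stimuli in the ~2-min check window elicits a peak. The
  in-run trend flag regresses the inter-peak trough envelope on time and
  flags slopes above 0.001 mN/s (rising troughs = incomplete relaxation =
  loss of sustained contractility); on peak-free traces it falls back to
  regressing the raw signal.

`MyographyModel.fit()` composes these into a `MyographyResults` object
(counts, response rate, force mean/SD/SEM/median, `FatigueResult`, viability
slope and flag, the peak table, a `summary()` text block). Degenerate inputs
are signalled, not silently defaulted: empty windows raise
`InsufficientDataError` in the estimators, and the report layer converts
them to NaN fields (sham rows).

## Reporting

`run_pipeline` analyses each readable trace file into one row (schema
`SUMMARY_COLUMNS` in `report.py`; forces mN, weights g, lengths cm),
logs and skips unreadable files, and is byte-deterministic on identical
inputs. Physical sample metrics enter as the arithmetic mean of three raw
measurements. `rank_by_force` orders samples by descending mean force with
ties broken by id. Clinical covariates are carried as opaque metadata; no
between-sample statistics are computed, matching the descriptive design of
the feasibility studies this supports.

## Problem sizes and numerical choices

The test suite and the acceptance script run on 300-s quadrants (248
trains) at 100 Hz for stochastic checks, a single 45-min run for the
response-rate measurement, 20 seeds for fatigue-rate recovery, 50 random
parameter draws on 60-s noiseless traces for the detection-vs-oracle
equivalence, and a 5-min demo for the byte-determinism check (determinism
does not depend on duration; one seeded generator stream per trace).
Floating-point tie-breaks: schedule construction guards the `k·T < duration`
boundary with a 1e-12 relative epsilon; `pulse_count` floors after adding
1e-9 so exact integer products are not truncated by representation error;
the parabolic refinement clamps its offset to ±half a sample and falls back
to the grid value when the 3-point stencil is not concave.
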