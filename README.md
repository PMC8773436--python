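# fireflash

Video-imagery analysis of firefly flash patterns: flash-spot detection,
flying/perching discrimination, flash-interval (FI) and flash-duration (FD)
measurement, and species identification by FI/FD reference-range matching —
with a ground-truthed synthetic scene simulator for validation.

## The problem

Nocturnal fireflies advertise with species-specific flash signals, and a
sympatric population mixes several species' signals in one dark scene.
Field surveys therefore need a way to (i) count flash activity in fixed-point
night video, (ii) separate flying individuals (oblong, motion-blurred flashes
forming discrete trajectories, consecutive flashes ~59 px apart at the
reference recording scale) from perching ones (round flashes clustering
within ~11 px), and (iii) identify species from flash timing alone.

The key timing characters are:

* **FI (flash interval)** — time between peaks of successive flash signals of
  one individual; for triple-pulse species, between the *first* peaks of
  adjacent grouped bursts;
* **FD (flash duration)** — width of a flash signal where intensity is ~10%
  of the pulse height above baseline (crossings linearly interpolated).

Species identification uses interval matching against per-species Min–Max
reference ranges (spanning ~90% of reference data points): an individual is
assigned to a species iff **>50%** of its FI (or FD) points fall inside that
species' range while **≤50%** fall in every other species' range; individuals
flashing fewer than 7 times in 10 s are excluded. The packaged references
cover three sympatric Taiwanese species (FI ranges, flying males):
*Abscondita cerata* 0.6–1.2 s (single pulse), *Luciola kagiana* 0.42–0.53 s
(triple pulse), *Luciola curtithorax* 0.07–0.43 s (single pulse).

Detection works per frame via **topographic prominence**: a local intensity
maximum is accepted when its peak value exceeds the highest saddle connecting
it to higher terrain by at least a threshold (default 80 on the 8-bit scale),
with frame decimation (default 1-in-30) so a flash spanning several frames is
counted once.

Because the original field recordings are an external deposit, the package
ships a simulator that renders dark, noisy scenes with flying and perching
individuals whose flash schedules, footprints and trajectories follow the
published per-species statistics — every analysis stage is validated closed
loop against the simulator's exact ground truth.

## Worked example

Simulate a flying *A. cerata* trace from the packaged profile, extract its
timing, and match it against the references:

```python
import fireflash as ff

profile = ff.flying_profile("A. cerata")
trace, truth = ff.simulate_trace(profile, duration=30.0, sample_rate=30.0, seed=42)
series = ff.timing_for_profile(trace, profile)
print(f"flash events detected: {len(series.events)} (ground truth: {len(truth.event_times)})")
print(f"mean FI: {series.fi.mean():.3f} s   (generator target 0.89 s)")
print(f"mean FD: {series.fd.mean():.3f} s   (generator target 0.20 s)")

refs = ff.default_references()
res = ff.assign_species(series.fi, refs, basis="FI",
                        event_times=[ev.t_first_peak for ev in series.events])
for sp, frac in res.fractions.items():
    print(f"  {sp:16s} {100*frac:5.1f}% of FI points in range")
print(f"assignment: {res.assignment}")
```

prints

```
flash events detected: 32 (ground truth: 32)
mean FI: 0.918 s   (generator target 0.89 s)
mean FD: 0.202 s   (generator target 0.20 s)
  A. cerata        100.0% of FI points in range
  L. kagiana         0.0% of FI points in range
  L. curtithorax     0.0% of FI points in range
assignment: A. cerata
```

All 32 simulated flashes are detected; the extracted mean FI/FD sit within
sampling error of the generator's targets, every interval falls inside the
*A. cerata* reference range and none in the competitors', so the >50%/≤50%
rule assigns *A. cerata*.

A command-line interface mirrors the library stages
(`fireflash simulate | stack | detect | track | profile | classify | report`);
`fireflash report clip.tif --out results/` runs the whole chain —
detection → track linking → behavior classification → per-track timing →
species matching → composition and activity time-course — and writes CSV/JSON
outputs plus a run manifest.

## Layout

```
src/fireflash/
  video_io.py       frame I/O, grayscale conversion, time-stack projections
  spot_detect.py    prominence-based flash-spot detection, flash rates
  behavior.py       track linking, flying/perching classification
  pulse_timing.py   ROI traces, pulse detection, FI/FD measurement
  species_match.py  reference ranges, matching rule, composition, time-course
  spectra.py        emission-spectrum averaging, peak wavelength, FWHM
  synth.py          ground-truthed trace/scene/population/spectrum simulator
  pipeline.py       end-to-end orchestration with run manifests
  cli.py            click-based command-line interface
docs/methods.md     model, parameters, numerical choices, limitations
```
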