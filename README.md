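# tremorkit

Offline signal-processing and protocol engine for entrainment-based
treatment of functional tremor.

Functional tremor has a diagnostic weakness that doubles as a therapeutic
lever: it *entrains* — the tremor adopts (or abates at) the frequency of an
externally cued voluntary rhythmic movement. `tremorkit` implements the
computational core of a wearable-accelerometer therapy built on that
phenomenon:

* estimate the dominant baseline tremor frequency **f₀** from 3-axis
  accelerometer data by FFT (Hann taper, zero-padded to ≤ 0.1 Hz grid,
  peak must exceed 5× the median in-band power to count as significant);
* run a 7-day cued session protocol: a 10-second baseline measurement,
  then auditory cue timestamps at **⅔·f₀** for the first half of the
  treatment time and **⅓·f₀** for the second half, each clamped to a
  configurable [f_min, f_max] band (defaults 1–5 Hz) with a fallback
  frequency when no tremor is detectable; day 1 is a 60-minute session,
  days 2–7 are 30-minute sessions;
* track the user's voluntary wrist flexion-extension frequency continuously
  in 3-second sliding windows;
* map the tracked frequency onto a bounded biofeedback gauge, linear in the
  relative error and exactly zero at the goal, with the goal range centered;
* persist time-stamped JSON-lines session logs and compute duration-weighted
  adherence fractions per day, at home (days 2–7) and overall.

A simulator of free-running tremor, of noise-only (no-tremor) input, and of
cue-following subjects with configurable responsiveness, lag and jitter
provides ground truth for every stage, so the whole pipeline is testable
without hardware. Intended users: researchers prototyping or validating
entrainment-therapy software, and anyone who needs a reproducible offline
replay of such sessions.

## Worked example

`examples/02_run_session.py` replays a day-2 session on a simulated subject
with a 6 Hz tremor who follows the cues (responsiveness 1, ~1 s lag):

```
baseline frequency    : 6.00 Hz (significant: True)
phase-1 cue frequency : 4.00 Hz  (2/3 of baseline)
phase-2 cue frequency : 2.00 Hz  (1/3 of baseline)
cues scheduled        : 5370
median tracked, ph. 1 : 4.00 Hz
median tracked, ph. 2 : 2.00 Hz
windows in goal range : 99.8 %
completed             : 1800 of 1800 s
```

The engine recovers the 6 Hz baseline from the first 10 seconds, cues at
4 Hz then 2 Hz, and the tracked movement frequency sits on each goal, so
nearly every gauge window falls inside the centered goal range. The other
scripts in `examples/` demonstrate frequency analysis, the gauge mapping
and adherence reporting.

The same operations are available from a shell:

```sh
tremorkit simulate scenario.cfg rec.csv --day 2 --seed 1
tremorkit session rec.csv --day 2 --log sessions.jsonl
tremorkit report --log sessions.jsonl
```

Each command prints one JSON object on stdout. Recordings are delimited
text with header `t,x,y,z` (seconds, m/s²); protocol and scenario files are
flat `key = value` text.

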