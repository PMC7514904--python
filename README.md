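# visitropy

Entropy-based detection of visitors (multi-occupancy episodes) in a
single-resident home, from nothing but binary occupancy-sensor logs.

## The problem

Ambient assisted-living systems monitor an older adult's activities of
daily living (ADL) with passive infra-red (PIR) motion sensors — one binary
stream per room, with no idea of *who* triggered each sensor.  Activity
recognition and abnormality detection built on such data assume a single
occupant, so a visiting carer or relative silently corrupts the learned
routine.  `visitropy` detects the multi-occupancy episodes themselves: when
two people move through the house, the merged sensor stream switches rooms
far more irregularly than one person's routine, and that irregularity is
measurable.

## The method

1. **Encoding.**  Each room gets an odd integer code (Living room = 1,
   Bedroom = 3, Bathroom = 5, Kitchen = 7, Corridor = 9).  The event log
   becomes a per-minute sequence A = a(1), …, a(N): minute *t* carries the
   code of the room whose sensor most recently activated.  Odd codes keep
   distinct rooms ≥ 2 apart, so a tolerance r < 2 separates same-room from
   different-room exactly.

2. **Entropy.**  Over each time window (default 60 min, N = 60 samples)
   one of three regularity statistics is computed from length-m templates
   under the Chebyshev distance with tolerance r:

   * ApEn(m, r, N) = φᵐ(r) − φᵐ⁺¹(r), with self-matches included in the
     per-template match frequencies Cᵢᵐ(r) and φᵐ = mean ln Cᵢᵐ;
   * SampEn(m, r, N) = −ln(Aᵐ(r)/Bᵐ(r)), self-matches excluded, undefined
     (and reported as such) when no templates match;
   * FuzzyEn(m, r, N) = ln φᵐ(r) − ln φᵐ⁺¹(r), with baseline-removed
     templates and the exponential membership Dᵢⱼ = exp(−(dᵢⱼᵐ)ⁿ/r).

   Defaults are the headline regime: FuzzyEn, m = 2, r = 1, n = 2.

3. **Detection.**  Windows tile each day from midnight (+ optional shift).
   For every time-of-day slot, the mean and SD of the entropy across days
   form a time-varying threshold mean + k·SD (k = 1 by default), estimated
   with one-sided sigma-clipping so that the anomalies being hunted do not
   inflate their own threshold.  A window is flagged as "visitor" when its
   entropy strictly exceeds its slot's threshold.

4. **Evaluation.**  Against ground-truth visit intervals, a window counts
   as a true visitor window when visits cover ≥ 30 % of it; flags are
   scored window-by-window into accuracy / precision / recall.

A seeded synthetic generator (`visitropy.simulate`) produces the two study
designs used throughout the tests: a 3-day recording with three sub-hour
visits on day 3, and a 7-day recording with ~2 h visits around 12:00 and
20:00 on three days of the week, injected by superimposing a second
occupancy stream that multiplies the room-switch rate (interleaving
intensity, default 3).

## Worked example

The one-hour event log

| start    | location    | code |
|----------|-------------|------|
| 09:00:01 | Bedroom     | 3    |
| 09:05:22 | Corridor    | 9    |
| 09:06:00 | Living room | 1    |
| 09:06:00 | Bathroom    | (simultaneous — first logged sensor wins) |
| 09:09:59 | Corridor    | 9    |
| 09:11:00 | Living room | 1    |

encodes to the 60-sample sequence `[3,3,3,3,3,9,1,1,1,1,9,1,1,…,1]`
(4 room-to-room transitions), and

```python
>>> from visitropy import EntropyConfig, entropy
>>> seq = [3]*5 + [9] + [1]*4 + [9] + [1]*49
>>> entropy(seq, EntropyConfig("apen", m=2, r=1.0)).value
0.13044132411737264
>>> entropy(seq, EntropyConfig("sampen", m=2, r=1.0)).value
0.043124426633754764
>>> entropy(seq, EntropyConfig("fuzzyen", m=2, r=1.0, n=2.0)).value
0.07615814256521036
```

Small values: one person moving through a morning routine is a fairly
regular signal.  An hour shared with a visitor in this pipeline typically
scores an order of magnitude higher.

End to end, from a shell:

```sh
$ visitropy run-all --preset datasetB --seed 7 --outdir demo
windows=168 tp=12 fp=0 tn=156 fn=0
accuracy=100.0 precision=100.0 recall=100.0
```

All 12 injected visit windows of the 7-day recording are flagged and
nothing else is (168 one-hour windows evaluated).  `demo/windows.csv`
holds the per-window entropy, threshold, and flag; `demo/events.csv` and
`demo/truth.csv` the simulated log and ground truth.  Every output starts
with commented `key=value` lines recording the exact parameters used.

Subcommands `simulate`, `detect`, and `evaluate` run the stages
separately; all accept a YAML config (`--config`) mirroring the flags.

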