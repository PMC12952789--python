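# Methods

This note documents the model's assumptions, parameter choices, numerical
decisions, and known limitations. Empirical numbers quoted here are the
ones the test suite and `scripts/acceptance.py` themselves compute.

## Arena and agents

The roost is a 2D corridor, 2.5 m wide, with a right-angle turn 5.5 m
before the exit and a total path length of 14.5 m (first leg 9 m to the
inner corner). A thin 1.25 m barrier sits 2.25 m before the exit opening;
its lateral placement is configurable and defaults to flush against the
inner wall, leaving a single 1.25 m passage, matching the offset layout of
the source roost diagram (a centered barrier leaves two 0.625 m slots that
a 0.3 m-wide agent with localization noise cannot thread reliably). Walls
are discretized into point reflectors every 0.2 m (target strength
−22.5 dB); segment endpoints are included once, so corners carry a single
reflector. Bats are 0.15 m-radius isotropic spherical reflectors (−23 dB,
configurable −49…−23).

Bats spawn uniformly in a 2 × 1.5 m rectangle at the far end, headings
uniform within ±30° of the corridor axis, take-off times uniform in
[0, 0.1] s, and per-individual terminal-frequency offsets Normal(0, 1 kHz).
Everything derives from one master seed through per-bat substreams
(spawning, receiver noise, bearing errors, tie-breaks), so trials are
bit-reproducible and robust to event reordering.

## Propagation

The three level equations (own echoes; direct conspecific calls;
conspecific calls reflected off walls or bats) are evaluated analytically
in dB per component, with the emitted level `P_t` interpreted as the
dB-SPL reference 0.1 m from the mouth and the printed constant grouping
`λ²/(4π)³` retained as-is. Consequences worth knowing:

- wall-echo detection range is ≈ 4.3 m for a 120 dB search call and
  ≈ 1–2 m for quieter approach/buzz calls — the agent is deliberately
  short-sighted, and navigation has to work from local cues;
- direct conspecific calls are far louder than echoes at equal range, so
  masking is dominated by the calls themselves, with second-order echoes
  relevant only at close quarters.

The absorption exponent is applied uniformly as `α(f)` in dB/m over the
path beyond the 0.1 m reference (the equations' printed forms differ in
whether the /10 power conversion appears; the dimensionally consistent
reading is used in all three). `α(f)` follows ISO 9613-1 at 20 °C, 50 % RH,
evaluated at the call's terminal frequency; the speed of sound is 343 m/s.
Piston directivity is held at its 90° value behind the head rather than
mirroring the forward lobe backwards. Components below −10 dB-SPL are
dropped; occlusion (no line of sight, no sound) is on by default — without
it agents would hear through the right-angle turn.

Poses are frozen at each call's emission; all path lengths of a reception
window use those snapshots. Echoes of a call arriving after the bat's next
emission are discarded (no pulse–echo ambiguity, matching the source
model's explicit exclusion).

## Receiver

Waveforms are rendered at 250 kHz only inside the receiver. The gammatone
bank is built directly as order-8 FIR impulse responses
`t⁷ e^(−2π b t) cos(2π f_c t)` with `b = 1.019·ERB(f_c)`, normalized to
unit gain at `f_c`, and applied by batched FFT convolution (the installed
signal library only provides the order-4 design). Channels are *active*
when their center frequency lies inside the emitted sweep; de-chirp
references are the per-channel peak times of the clean call.

Two deliberate readings of the detection thresholds:

- the 7 dB detection margin is referenced to **each channel's own noise
  floor** (measured once per bank on a fixed unit-RMS noise realization),
  not to the broadband 0 dB-SPL level — a narrowband channel passes only a
  sliver of the broadband noise power, and the broadband reading would
  cost ~15 dB of sensitivity;
- the channel-count threshold is 10 % of the active channels with a floor
  of 1.5 coincident channels, because narrowband calls can have fewer than
  ten active channels, where a literal 10 % rule would accept single-channel
  noise peaks.

Both passes of the dual-pass procedure share one noise realization per
call, so disabling masking reproduces the interference-free pass exactly
and trial jamming is exactly zero. The focal bat's own emitted call is
tracked as a scene component but gated out of both rendered inputs: the
emission is known to the animal, and rendering it would let the 70 dB
dynamic-range anchor self-jam distant echoes even for a lone bat.

An echo is *jammed* when the full pass has no peak within 100 µs of its
interference-free time, or when a stronger peak **not explained by any
interference-free detection** falls inside the 4 ms forward/backward
masking window (3 ms before, 1 ms after). Restricting suppression to
unexplained peaks is essential: dense own-echo trains otherwise suppress
each other and a lone bat would report ~90 % jamming. Surviving peaks
shifted by more than one 5 µs bin are detections with timing errors, and
the detected (full-pass) delay is the one used for ranging.

Bearing errors use `std = sqrt((k₂/SNR)² + (k₃ + k₄ sin φ)²)` with SNR in
dB, `k₃ = 1°`, `k₂ = 11.18°·dB` (so the std is exactly 1.5° at φ=0,
SNR=10 dB), `k₄ = 2°`, capped at 3°. SNR is the component level over the
stronger of the noise floor and the loudest temporally overlapping
interference component.

## Perception and behavior

Detections are stored allocentrically: a guidance buffer of the current
plus last `W` calls (default `W = 5`; `W = 0` keeps only the newest call)
and a 1 s buffer for the clustering variant. Conspecific detections are
kept on a separate list from wall detections; avoidance reads conspecific
positions only from the newest call because neighbors move several body
lengths per integration window.

Movement priorities follow the fixed order conspecific avoidance →
obstacle avoidance → opening approach → wall-following → correlated random
walk. Where the source description is silent, this package's choices are:

- **Collision course.** Avoidance requires range < 1.5 m, bearing within
  ±60°, and a projected lateral miss distance < 0.3 m (body radius plus
  clearance). Without the miss-distance qualifier, every point of a 2.5 m
  corridor is permanently "too close" and wall-following never engages.
- **Avoidance maneuver.** Rotate just far enough to put the threat abeam,
  turning toward the flank with the longer free path (nearest detection in
  a ±30° cone about the candidate direction); speed scales linearly with
  threat distance (floor 0.25×). When both flanks are cramped the bat
  turns toward the most open of twelve scanned directions.
- **Openings.** Bearing-adjacent detections ≥ 0.5 m apart form candidate
  openings; candidates must subtend ≥ 20° (grazing a wall produces
  collinear false breaks), keep the approach line and the region beyond the
  gap (along the opening's normal) clear of detections, and keep their
  center ≥ 0.4×width from any detection. A chosen opening is *committed*
  for up to 1 s so its own flanking detections cannot capture the
  controller mid-passage.
- **Speed law.** The "delayed linear adaptive law" is a first-order lag
  (time constant = one current IPI) toward the phase target (nominal speed
  in search, half in approach and buzz), additionally scaled by the cosine
  of the heading offset to the steering target (floor 0.25×). Without the
  turn-dependent slow-down the 4 m/s² centripetal cap makes the right-angle
  corner geometrically impossible from 3 m/s.
- **Wall-following.** Steer toward the farthest detection within ±110° of
  heading, weighted by alignment with the recent direction of travel
  (exponential average of displacement), holding the 0.8 m standoff with a
  bilateral proportional correction (±45° at 0.45 m error).
- **Collisions.** Wall contact resets the heading perpendicular to the
  contacted wall and counts one debounced event (re-armed only after
  0.15 m of clearance beyond the body radius). Conspecific overlap
  (< 0.4 m) decelerates and rotates both bats apart without counting.

Call parameters (IPI, duration, bandwidth, terminal frequency, level) are
linearly interpolated against the distance to the closest detected object
between the phase anchors (search > 1.2 m; approach 1.2–0.4 m; buzz
0.4–0.2 m; final buzz < 0.2 m); the distance is snapped to a 0.05 m grid
purely so per-design filter banks and templates can be cached.

## Engine and metrics

Each bat's emit → wait one IPI → process → decide → emit loop runs on its
own clock; kinematics integrate in lockstep 1 ms ticks. Exited bats stop
calling and are removed as reflectors and maskers. Metrics pool
individuals across repeats: exit probability within the 15 s limit,
time-to-exit of successful bats, debounced wall collisions per bat-second
in the arena, jamming probability (jammed / interference-free detections,
pooled), the per-call probability that the nearest wall reflector within
1 m ahead was detected, and the mean nearest-neighbor distance sampled at
50 Hz.

## What the simulations show — and what they do not

A lone bat navigates out in roughly 5–9 s using echolocation alone, with a
collision rate near 0.05 /bat/s; with five bats and masking on, about 80 %
exit within 15 s with ~20–25 % of echoes jammed; the confusion variant
collapses exits (≈ 0.2 at five bats) and multi-call clustering recovers
part of the loss (≈ 0.4) while restoring the collision rate — the same
qualitative ordering as the source study. Across repeated 48-seed batches
the lone-bat success rate is 80–90 %, not 100 %: the residual failures are
single reversals at the concave outer corner of the turn, each costing a
~7.5 s lap of the first leg. The pathfinding rules are underdetermined at
exactly such corner singularities, and this implementation's resolution is
evidently somewhat less forgiving than the original's.

Runtime grows steeply with density because crowded bats buzz at 5–10 ms
IPIs (hundreds of decisions per simulated second, each with a full
dual-pass receiver run): 10 bats cost ~5 s of CPU per simulated second and
40 bats ~100 s. The test suite therefore scales its multi-bat checks to
densities 1–10 and windows of a few seconds; they probe directions and
invariants (masking only removes detections; exit probability
non-increasing in density; bit-reproducibility), not headline magnitudes,
which require the full repeat schedule and many CPU-hours.

Not modeled, by design: Doppler shifts, pulse–echo ambiguity across calls,
binaural processing, frequency-dependent target strength, 3D flight,
vision, spatial memory, or any exchange of information between bats.
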