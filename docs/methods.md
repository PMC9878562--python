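# Methods

This note documents the quantitative choices behind `chemorelay`: the
motility measures, the gating and neighborhood protocols, the agent-based
generator, and the numerical conventions. Everything here is implemented
and exercised by the test suite; no empirical claim is made beyond what the
code computes.

## Track model and units

A track table is long-format: one row per (cell, frame) with canonical
units µm / seconds / 0-based frames. Invariants enforced at construction:
strictly increasing frames and times per cell, finite positions, one group
per cell, and no per-cell mixing of 2D and 3D coordinates. Optional
per-frame polarity vectors must be unit norm (tolerance 1e-3).

Real exports are mapped through a dialect registry (delimiter, column
names, unit scales, frame base). Gaps inside a track are closed by linear
interpolation up to a configurable maximum (default 2 missing frames);
larger gaps split the track into suffixed segments, because tracklet
metrics assume uniform sampling. `regularize` resamples to a uniform grid
by per-axis linear interpolation (polarity interpolated and renormalized),
never upsamples, never extrapolates past the last observation, and keeps
each cell's start time. Uniformity is judged at relative tolerance 1e-6.

## Tracklet metrics

Tracks are cut into windows of `W` frames starting at 0, s, 2s, …
(defaults `W = 10`, stride `s = W`, i.e. disjoint). Disjoint windows make
"N tracklets per group" sampling unambiguous and avoid autocorrelated
duplicates; 10 frames is 3.3 min at 20 s sampling, a timescale on which
cell turning is visible. For each tracklet:

- displacement `D` (µm), path length `L` (µm), velocity `v = L / elapsed`
  (µm/min);
- arrest coefficient `A`: fraction of the `W − 1` steps whose instantaneous
  speed is below `v_arrest` (default 2 µm/min — below typical
  jitter-corrected lymphocyte speeds; exposed in config and echoed into
  every output). This is a continuous per-tracklet proportion, not a
  binary arrested/motile call.
- directionality `Γ = D / L` when `L ≥ eps_path` (default 1 µm). Below the
  floor, D/L is numerically meaningless; if polarity vectors are present
  and the fallback is enabled, `Γ` is the norm of the mean polarity vector
  (coherence of a visibly polarized but arrested cell), else 0. Without
  polarity data the high-arrest/high-directionality gate is reachable only
  through small-L, high-straightness motion — a stated limitation, since
  shape-derived polarity cannot be recovered from positions alone.

`D ≤ L` always (triangle inequality); all five metrics are invariant under
rigid rotation and translation. Both are property-tested.

## Gating protocol

Gates are fixed thresholds, not fitted: `a* = 0.6`, `d* = 0.5`, with
"≥ threshold counts as high" on both axes (any fixed convention works; it
must be documented for reproducibility). The defaults place the
archetypes — pure-stationary jitter and pure-ballistic motion — deep inside
the immobile and directional gates. No automatic threshold selection is
attempted.

Count tables use a seeded sample of `sample_n = 1000` tracklets per group,
drawn without replacement. For platform-stable determinism the sampler
sorts rows by (cell_id, window start) and shuffles with a generator seeded
by (seed, group index in sorted group order), so results are independent of
input row order and of which other groups are present.

## Neighborhood and lead–lag analyses

"Motile" is defined through the gates: a leader counts as motile at frame
t when the tracklet covering t (the latest-starting one, if windows
overlap) is in the chemokinesis or directional gate. This keeps a single
definition of motility across the pipeline. The neighborhood radius is
50 µm, boundary inclusive; neighbor counts of 2 and more are pooled into a
"≥2" bin.

Conditional velocity produces one record per (cell, frame); the spatial
query is a per-frame KD-tree, verified in the tests against an all-pairs
brute-force scan. Because frame-level records of one cell are strongly
autocorrelated, the reported Mann–Whitney comparisons (bin 0 vs ≥1, bin 1
vs ≥2) are computed on per-cell mean velocities — each cell contributes at
most one value per bin — to avoid pseudoreplication. Raw p-values are
reported with Benjamini–Hochberg adjustment whenever a run emits two or
more comparisons.

A direction-change event occurs when the heading (unit step vector, defined
only at speeds ≥ `eps_speed`, default = `v_arrest`) turns by more than θ
(default 60°) relative to the previous defined heading. The lead–lag score
is the fraction of follower events with at least one in-radius leader event
in the preceding window `[t − Δt, t)` (default Δt = 60 s, three frames at
20 s). Eligibility ("in radius") is evaluated at the follower's event
time. The null circularly shifts each leader's event train by an
independent uniform offset (default 999 shifts, seeded); the p-value uses
the +1 correction. Zero follower events yield a distinct undefined result,
never a score of 0. The event definition and test are declared surrogates:
thresholds, smoothing and the statistical procedure for "preceded by" are
not uniquely determined by the source experiments.

## The synthetic-track generator

The generator emulates the chamber experiment: a 1000×500×100 µm arena, a
linear CXCL12 profile `c(x) = c0·x/x_max` along x (c0 = 400, matching a
400 nM source reservoir; an error-function profile is available), 6 h at
20 s frames, 100 leaders + 100 followers in mixed arms (uniform initial
positions). Movement is a persistent biased random walk: new heading =
normalize(p·previous + (1−p)·(χ·gradient + (1−χ)·random unit vector)),
step length half-normal with scale σ·dt, reflecting boundaries.

Defaults were calibrated once so that the *tracklet-level* population
structure matches the qualitative structure of the experiment, and then
frozen:

| parameter | value | role |
|---|---|---|
| leader run speed σ_v | 4 µm/min | motile-phase speed scale |
| persistence p | 0.2 | short heading memory; unbiased walkers then straddle Γ = 0.5, so unbiased motion is *not* spuriously directional |
| leader bias χ_wt | 0.25 | run-phase tracklets split between chemokinesis and directional gates rather than all-directional |
| run↔pause switching | 0.02 / frame | ≈ 17 min dwells; leaders spend ~half their time paused, so ~half of leader tracklets gate immobile and phase-mixed ("polarized"-gated) tracklets stay rare |
| jitter σ (paused / inactive) | 0.3 µm/min | isotropic positional noise, far below v_arrest; headings are *not* persistent while jittering |
| LTB4 kernel | q·e^{−d/λ}, λ = 15 µm, q = 1 | quasi-steady field re-evaluated each frame |
| activation threshold ℓ* | 0.0369 | effective reach −λ·ln ℓ* ≈ 49.5 µm, i.e. confined below 50 µm |
| secretion gate c_min | 20 (= 0.05·c0) | leaders secrete only where CXCL12 is present |
| rescued follower σ_v1, χ_syn | 2.0 µm/min, 0.2 | partial rescue: slower and less directional than leaders |

Follower activation is a hard synergy gate: LTB4 ≥ ℓ* AND local CXCL12 > 0
AND an intact Gi response — the cue alone never moves cells. Because
activation is a saturating threshold, one in-reach secreting leader is as
good as two; this is what makes the 1-vs-≥2 motile-neighbor comparison
flat by construction. Perturbation arms: PTX on leaders or a C-terminally
truncated receptor removes leader chemotaxis (χ = 0, chemokinesis
remains) *and* cue secretion; PTX on followers or LTB4-receptor knockout
removes the follower response while secretion persists.

Declared surrogates and non-goals: half-normal step lengths, the
exponential kernel, threshold activation, reflecting boundaries and the
linear gradient are modeling conveniences, not mechanistic claims. There
is no PDE-accurate diffusion, no receptor kinetics, no volume exclusion.
An optional CXCL12 sink term around leaders exists for exploring
scavenger-shaped micro-gradients but is off by default and not endorsed as
a parameterization; an optional "deposit" mode leaves decaying point cues
where a leader paused. The simulator also omits leader–leader coupling, so
leader velocity does not depend on leader neighbors — a known divergence
from the real data, where it does.

What passing tests show: that the *analysis* correctly recovers structure
known to be present by construction (immobile follower-alone arm,
intermediate rescued velocity, sub-50 µm neighbor effect with saturation,
perturbation arms collapsing onto the follower-alone profile). They do not
show that real cells follow this generative model, and real-data gate
counts are not reproduction targets here because the original videos and
tracks are not publicly deposited.

## Determinism, seeds and problem sizes

A single run seed drives everything: the pipeline derives stage seeds by
fixed offsets (simulation +0, gate sampling +1, permutation null +2,
modulo 2³¹). Identical configuration gives byte-identical report bodies
and bit-identical simulated tracks. The headline-number script
(`scripts/acceptance.py`) runs five replicate seeds of the follower-alone
and mixed arms at full scale (100–200 agents, 1081 frames) and reports the
worst replicate (minimum immobile count, maximum directional count); the
test suite exercises the same presets at full scale for seeds 1–5 and
reduced scales elsewhere. These sizes give >10 000 disjoint tracklets per
group — an order of magnitude more than the 1000-tracklet samples — while
keeping a full run in seconds.

## Known limitations

- The polarity fallback for arrested-cell directionality is a surrogate
  for image-derived cell-shape polarity, which position data cannot carry.
- Gate thresholds are conventions; printed real-data gate counts from the
  motivating experiments are not exact targets at any threshold choice.
- The lead–lag event definition (θ, Δt, eps_speed) is configurable
  precisely because no operational definition is canonical.
- `fill_gaps` assumes the tracker's frame indices are trustworthy; no
  drift correction or gap-closing inference is attempted.
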