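# Methods

## The overlap model

Strands are arrays of canonical bases (A/C/G/T) with a 5′→3′ orientation;
only Watson–Crick pairings (A/T, C/G) are scored, with no thermodynamic
weighting, no gaps and no bulges — the binding strength of a configuration
is summarized by counting complementary opposing bases.  Strand 1 is
written 5′→3′ left to right; strand 2 is written 3′→5′ left to right
(antiparallel), and the relative position `r` is the rightward shift of
strand 2's left end from strand 1's left end, `r ∈ [−l+1, L−1]`, giving
`L + l − 1` registers.  At each register, `TMO|r` counts complementary
columns and `MCO|r` the longest run of adjacent ones; `ω = max_r MCO|r`.

Only the antiparallel register is scored.  This is the orientation in
which DNA duplexes actually form, it is equivalent to the longest common
substring of strand 1 and the reverse complement of strand 2, and it is
the only convention under which the reference ecosystem's five pairwise ω
values (4, 10, 7, 8, 6) come out self-consistently.  Parallel-register
contacts in trajectory data contribute to TMO but never to MCO.

ω can be degenerate.  `profile()` enumerates *all* maximal runs of length
ω, ordered by `(r, start1)`, reporting both strands' 5′→3′ 0-based start
indices.  For the reference pair p4–res there are two windows (resource
spans 8–11 and 14–17); the second predator's unique window spans resource
bases 9–18, so the two predators' optimal attachments contend for resource
bases 9–11 (sequence ACC read 5′→3′).  Window reports always carry
explicit coordinates on both strands because reading direction is
otherwise ambiguous.

Self-interaction ω(s, s) is computed between two independent copies of the
sequence (inter-strand); intra-strand folding is a separate per-frame
statistic (`self_fold`).

An independent oracle, `omega_oracle`, computes ω by brute force over all
substring pairs of strand 1 and the reverse complement of strand 2.  It is
O(L·l·ω) and exists purely to cross-check the profile computation; the two
routes are kept separate and compared on random inputs in the tests and in
the acceptance script.

### Sequence design

`design_sequence` draws an L-mer with an exact target ω against a resource
by embedding the reverse complement of a random ω-long resource window at
a random position in a uniform random background, then rejecting the draw
unless the realized ω equals the target (accidental windows in the random
background can overshoot, and background bases adjacent to the embedded
window can extend it).  The search is seeded and deterministic; very low
targets (ω ≤ 2 for a 50-mer against a 20-mer) are combinatorially near
impossible for a random background and fail cleanly after `max_tries`
attempts.  The natural regime is L > l, which is what makes predators
compete for a short resource.

## File formats and units

The analysis consumes the plain-text dialects of the oxDNA simulation
engine: a topology file (`N n_strands` header, then per nucleotide
`strand_id base neighbor_3 neighbor_5`), per-frame hydrogen-bond pair
lists (`t = <step>` stamps, then `i j` index pairs), and configuration
records (`t/b/E` headers plus 15 floats per nucleotide).  Strand sequences
are recovered by walking each strand's neighbor chain from its 5′ terminus,
so both common listing orders parse identically; cycles and broken chains
are rejected with line numbers.  Pair lists tolerate `#` comments, both
step-stamp variants (`t = n` and `# t = n`), and extra per-line columns.
One bond per base is enforced on read: later duplicates are dropped with a
logged warning.  Orientations and velocities are parsed for validation but
discarded; geometry is outside the analysis path.

Unit constants: one MD timestep is 0.005 simulation time units ≈ 15 fs;
frames are recorded every 10³ steps (15 ps); one simulation length unit is
34.072/40 nm.  `steps_to_time` is exact arithmetic on the 15 fs/step
constant, so 10⁸ steps report as 1.50 µs.

## Trajectory statistics

Per frame and strand pair, TMO is the number of bonds joining the two
strands and MCO the longest antiparallel chain `(i+k, j−k)` in local
5′→3′ coordinates; bonds to third strands are excluded.  When sequences
are known, frame MCO ≤ ω of the pair — a consecutive bonded run implies a
complementary substring match — and this invariant is property-tested.

Histograms pool frames across runs with equal weight per frame; the value
0 ("not bonded") is always present as a bin.  Ensemble time series are
pointwise means over runs sharing a step grid; smoothing is available but
off by default, since averaged curves are reported unsmoothed.

A binding event is a maximal stretch of consecutive frames with
MCO ≥ threshold (default 4 consecutive paired bases, the minimum for an
effective attachment — fewer bases detach too easily).  Lifetimes span
from the event's first frame to one recording interval past its last, so
a single-frame event lasts one interval.  Events still running at the end
of the trace are flagged `censored` (the lifetime is a lower bound, which
is how "at least N steps" statements are represented); events already
running at the first frame are flagged `left_censored` separately.

Complex detection builds an undirected strand graph per frame with an edge
when the pair's chosen statistic meets the rule (default TMO ≥ 1, because
a parasitic strand may attach through only a few non-consecutive bonds;
MCO ≥ k is available for stricter analyses), and labels connected
components by species multiset (`trimer[p10+p4+res]`,
`tetramer[p10+p4+2xres]`).  Species names default to the strand name minus
a copy-number suffix (`res_2` → `res`).  Per-composition occupancy is a
simple tally over all component instances in all frames, so the fractions
sum to 1.  Self-folding counts intra-strand pairs more than `min_loop`
(default 3) bases apart — a hairpin needs at least that many unpaired
bases to turn — and reports the longest intra-strand antiparallel run and
its closing loop length.

## The synthetic generator

Real trajectories come from an MD engine; the generator reproduces only
the *statistical* structure the analysis relies on, with exact ground
truth.  Each strand pair follows an alternating-renewal chain:

- geometric dwell times (in frames) for bound and unbound sojourns; the
  unbound mean defaults to `d_b · p_unbound / (1 − p_unbound)` so the
  configured stationary unbound probability is realized exactly;
- at each bound-sojourn start, a run length `m` is drawn from the
  configured stationary distribution (restricted to `m ≤ ω`), one of the
  pair's ω-windows is chosen (uniformly, or by configured weights), and
  the `m`-run is placed uniformly inside the window;
- each bound frame may add isolated extra complementary pairs at the same
  register (per-candidate rate), kept non-adjacent to the run and to each
  other, so TMO exceeds MCO without altering it.

Because the dwell law is memoryless and shared by all bound states, the
per-frame MCO distribution equals the configured stationary probabilities
and the mean binding-event length equals the configured bound dwell — the
quantities the recovery tests check.  Pairs evolve independently except
for the one-bond-per-base rule: when two pairs claim the same nucleotide
in a frame, the earlier pair in the configuration order keeps its bonds
and the loser contributes none that frame (logged; determinism over
realism).  In the three-strand preset the strong predator is first in
priority, so exclusion falls on the weak one, whose two ω-windows both
overlap the strong predator's window on the resource — competitive
exclusion emerges from the shared-base geometry rather than from an
explicit rule.

What the generator does **not** emulate: excluded volume and crowding,
3-D geometry (configuration files carry placeholder coordinates),
non-geometric dwell laws (any law can be plugged in, geometric is the
tractable default), spurious non-canonical or parallel-register bonds, and
any relaxation/equilibration phase.  Recovery tests passing therefore
validates the *analysis pipeline*, not the physics of any MD engine.

### Preset parameters

All presets use the reference p4/p10/res sequences and a recording
interval of 10³ steps per frame.

| preset | pair | P(unbound) | run-length probabilities | extra-pair rate |
|---|---|---|---|---|
| `p4res` | p4–res | 0.25 | {4: 0.60, 3: 0.05, 2: 0.05, 1: 0.05} | 0.25 |
| `p10res` | p10–res | 0.15 | {10: 0.55, 9: 0.30} | 0.10 |
| `p4p10` | p4–p10 | 0.20 | {7: 0.50, 5: 0.10, 4: 0.10, 3: 0.05, 2: 0.05} | 0.30 |
| `competition3` | p10–res | 0.25 | {10: 0.55, 9: 0.20} | 0.10 |
| | p4–res | as `p4res` | | |
| | p4–p10 | 0.70 | {7: 0.20, 5: 0.10} | 0.10 |

The weak binder spends 25% of frames unbound and 60% at its full ω run;
the strong binder sits at ω for 55% of frames and at ω−1 for 30% with TMO
rarely more than 1–2 above MCO; the predator–predator pair has a broad TMO
surplus.  The bound-dwell mean is 10 frames (10⁴ MD steps) in all presets
— a decorrelation scale chosen so that a 10⁴-frame run contains several
hundred independent binding cycles, giving stationary estimates a standard
error well inside the ±0.02 recovery tolerance; it is a statistical
choice, not a fitted physical lifetime.

## Numerical and interface choices

Probabilities are exact frequency ratios (no smoothing or binning).
Component and window orderings are deterministic (`(r, start1)` for
windows, sorted member tuples for components).  Uppercase coercion is the
only input normalization; U and IUPAC ambiguity codes are rejected with
the offending symbol named.  All randomness flows through a single
`numpy` `default_rng` seeded from the scenario config, and fixture files
are byte-stable for a fixed seed.  The CLI is a thin wrapper over the
library; exit codes are 0 (success), 2 (usage), 3 (parse error),
4 (constraint failure), and warnings go to the log stream, never into
output tables.

Test problem sizes (10⁴ frames for recovery, 10³ random pairs for oracle
equivalence) were chosen as the smallest scales at which the checked
estimators are comfortably inside their tolerances.

## Known limitations

- The ω metric is combinatorial: no nearest-neighbor ΔG, melting
  temperature, or bulge/mismatch energetics.  Two windows with equal ω but
  different GC content score identically.
- Frame statistics trust the bond lists; no geometric validation of
  recorded bonds is attempted.
- The generator's independent-pair assumption understates correlations a
  crowded simulation box would induce.
- `design_sequence` is rejection sampling; runtime grows steeply as the
  target ω moves far below the typical random-background ω.
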