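# Methods

## Model

`epigame` simulates a population on a two-layer multiplex network: a
behaviour layer (adjacency A) on which individuals imitate each other's
stance towards protective policy, and a contact layer (adjacency B) on
which an SIS disease spreads. Both layers share one node set and, in the
regime implemented here, one edge set (A = B); all constructors enforce
this. Each node combines a strategy — support (T) or disregard (D) — with a
health status — susceptible (S) or infected (I) — giving four states
DS, DI, TS, TI with payoffs

    π_DS = 0,   π_DI = −C_I,   π_TS = −C_T,   π_TI = −C_I − C_T,

where C_I is the cost of infection and C_T the cost of compliance, with
C_I > C_T so that the choice is a genuine dilemma.

One synchronous time step has two phases. In the behaviour phase node i
keeps its strategy with the retention probability

    R_i^D = Π_j (1 − a_ji · p_j^T · Γ(π_i, π_j)),
    R_i^T = Π_j (1 − a_ji · p_j^D · Γ(π_i, π_j)),

each opposite-strategy neighbour acting as an independent imitation trigger
through the Fermi rule Γ(π_i, π_j) = 1/(1 + exp(−(π_j − π_i)/ω)). In the
health phase a susceptible node escapes infection with probability

    q_i^D = Π_j (1 − b_ji · p_j^I · β),
    q_i^T = Π_j (1 − b_ji · p_j^I · d·β),

the factor d rewarding supporters with an attenuated infection rate, while
infected nodes recover with probability μ. The master equations combine
the phases, routing the infection channel through the *post*-behaviour
strategy; all R and q quantities are evaluated on the time-t state before
any node advances (fully synchronous update). The mean-field closure is at
the individual level: node states are treated as independent across nodes.

In the deterministic engine the payoff entering Γ is the *expected* payoff
π_i = Σ_C π^C p_i^C, recomputed every step. In the agent-based engine each
agent occupies exactly one state and the current-state payoff is used; this
is the standard relationship between the probability-level and realized
dynamics and the source of the small systematic gap between them at small N.

## Parameters

| symbol | code name        | meaning                                  | default | range   |
|--------|------------------|------------------------------------------|---------|---------|
| β      | `beta`           | infection probability per contact/step   | 0.3     | [0, 1]  |
| μ      | `mu`             | recovery probability per step            | 0.5     | (0, 1]  |
| d      | `d`              | response strength (T infects at d·β)     | 0.6     | (0, 1]  |
| C_I    | `cost_infection` | cost of being infected                   | 2.0     | ≥ 0     |
| C_T    | `cost_support`   | cost of compliance                       | 0.2     | ≥ 0, < C_I |
| ω      | `omega`          | Fermi selection intensity                | 0.5     | > 0     |

d = 1 is admitted as the decoupled limit (protection void), used in
threshold closed-form tests. All defaults are the reference scenario used
throughout the test suite; variants (d = 0.8, C_I = 4, ω = 0.9) probe the
sensitivity of the oscillatory regime.

## Initial conditions

Defaults are a homogeneous product mixing: every node starts with the same
row built from a support fraction σ0 and an infected fraction ρ0,
independently mixed. The package default is **σ0 = 0.2, ρ0 = 0.1** — a
minority initially supports the response, a tenth is infected, which is the
natural configuration at outbreak onset.

σ0 = 0.5 must be avoided with homogeneous rows, for a structural reason:
whenever p_j^T = p_j^D for every j, the two retention products coincide
(R_i^D = R_i^T), so p_i^T = 1/2 is an exactly invariant manifold of the
deterministic dynamics. A run started there keeps ρ_T pinned at 0.5 forever
and can never develop the oscillations that are the model's signature; the
stochastic engine leaves the manifold by fluctuation, the deterministic one
cannot. Per-node realized-state initials (each node in one definite state)
are supported and mirror the Monte Carlo initializer, but they are not the
default for trajectory experiments because node-level phase cancellation
damps the population-level oscillation amplitude.

Heterogeneous per-node initial rows can be supplied as a CSV
(`node,p_DS,p_DI,p_TS,p_TI`) through the config `init.state_file` key.

## Steady state and oscillations

The endemic regime of the coupled system is periodic, not a fixed point:
rises in the support density ρ_T are mirrored by falls in the infection
density ρ_I (their first differences are negatively correlated — anti-phase)
in a sustained feedback cycle. Consequently all steady summaries are
trailing-window averages rather than convergence detections: means and
peak-to-trough amplitudes of ρ_T, ρ_I over the final `window` steps
(default 100; 200 for amplitude diagnostics). The default horizon is 2000
steps for trajectory experiments; sweep experiments use 600–800 steps,
which the trajectory diagnostics show is well past the transient at the
reference parameters.

## Epidemic threshold

Linearising around the disease-free state gives β_c = μ / Λ_max(H) with
h_ji = (1 − (1 − d) p_i^T) b_ji: node i's support probability discounts
column i of the contact matrix. Λ_max is the largest-magnitude eigenvalue
(the Perron root of this nonnegative matrix), computed with a dense
eigensolver; H is non-symmetric once p^T varies by node. Perron-root
monotonicity pins β_c between μ/Λ_max(B) (no support) and μ/(d·Λ_max(B))
(full support).

β_c depends on the steady p^T, which depends on the operating β. The
default convention evaluates p^T from a full dynamics run at the scenario's
own β, averaged per node over the trailing window (this absorbs the
periodic regime into one representative vector). An optional fixed-point
mode (`threshold_fixed_point`) re-evaluates p^T at β = β_c and iterates to
a 10⁻⁴ relative tolerance; it is off by default.

A consequence worth stating: because clamping seeds to T can only *lower*
entries of H in their columns, and in practice the imitation spillover
raises non-seed p^T as well, the computed β_c rises monotonically with the
seed count K under persistent clamping at the reference parameters. A dip
of β_c below the no-intervention baseline at small K would require the
risk-feedback channel (less infection → less support among non-seeds) to
overpower the spillover; in this implementation it does not. One-shot
(non-persistent) modulation does leave β_c marginally below baseline after
the transient, but then the infection density is not durably reduced
either. The K-sweep test asserts the dip and is expected to fail; it is
kept as an executable record of this analysis.

## Interventions

Ego-based selection repeats (uniform random ego → uniform random
neighbour) until K distinct seeds accumulate; alter-based selection
includes each neighbour of a random ego independently with probability P
(default 0.4), dropping uniformly at random from the final batch if it
overshoots K. Both are bounded at 200 draw attempts per requested seed
before raising. Seeds are clamped to T by transferring their D-state
probability mass to the corresponding T states — health marginals are
untouched, so the clamp itself never changes ρ_I.

Clamping is **persistent** by default (re-applied after every step from
`apply_time`, default 0): one-shot modulation decays by imitation within a
few steps and cannot sustain steady-state effects. A one-shot mode
(`persistent: false`) exists for comparison. In sweeps, seed selection is
the only stochastic element of the deterministic engine; each (K,
replicate) cell draws a fresh seed set from a spawned sub-seed, and error
bars are across-replicate standard deviations (default 10 replicates;
acceptance-scale runs use 2).

## Synthetic data

`make_fixture_contacts` emits temporal contact files in the SocioPatterns
dialect — rows `t i j` with timestamps on a 20-second sensor lattice spread
over one day, uniformly random distinct node pairs — purely as a format
fixture: it reproduces the file dialect, not the burstiness, circadian
rhythm, or community structure of real proximity data. Aggregation is an
unweighted union over a window (default one day, starting at the earliest
record): an edge exists iff at least one contact occurred, contact counts
are discarded (the dynamics use binary adjacency), and nodes inactive in
the window are dropped. Passing the pipeline tests therefore demonstrates
parsing, aggregation and determinism, not realism of the contact process.

The Barabási–Albert generator grows from a complete seed clique on
m_attach + 1 nodes, each arrival attaching m_attach edges preferentially;
it requires at least one arrival beyond the clique (n_nodes > m_attach + 1).
The reference substrate is N = 500, m = 3 (m is not dictated by the
scenario definitions; 3 gives mean degree ≈ 6, typical of close-contact
networks).

## Numerical choices

* Retention/avoidance products are computed directly (not in log space);
  factors are bounded in [0, 1] and underflow is not reachable at the
  network sizes involved.
* State rows must sum to 1 within 10⁻¹⁰; post-step entries are clipped to
  [0, 1] only to absorb rounding, with a hard failure if any entry strays
  beyond ±10⁻⁹ before clipping. The vectorized step agrees with a literal
  nested-loop transcription to 10⁻¹².
* Fermi-rule overflow for huge payoff gaps saturates cleanly to Γ ∈ {0, 1}.
* The exact-chain oracle enumerates all 4^N configurations (capped at
  N ≤ 4) and builds the one-step transition matrix from per-agent next-state
  distributions, which are independent given the current configuration.
* Monte Carlo infection draws use the closed form 1 − (1 − rate)^k with k
  the number of infected neighbours — identical in law to per-neighbour
  Bernoulli triggers, since all triggers share one rate.
* Ensemble sub-seeds come from `numpy.random.SeedSequence.spawn`, so runs
  are independent but fully reproducible from one master seed.

## Problem sizes

Unit tests run on 2–10-node graphs; scenario-scale tests use N = 200 for
the β-grid mean-field/Monte Carlo comparison (50 runs per point, 500
steps), N = 500 with 800–2000 steps for oscillation, ordering and K-sweep
checks, and 20,000 sampled chains against the exact 64-state chain on the
3-path. These sizes keep every property at full strength while running on
a single core in minutes.

## Known limitations

* The individual-level closure ignores dynamic correlations; MMCA-vs-MC
  gaps up to a few hundredths in ρ_I are expected and tested for, not
  eliminated.
* Identical layers (A = B) are assumed by every constructor; the data model
  stores both matrices but no supported workflow builds A ≠ B.
* Heterogeneous per-node β, μ, d are not supported; strategies are binary.
* The threshold's β_c(K) dip discussed above does not occur under
  persistent clamping in this implementation.
* Aggregated contact graphs discard edge weights and all temporal structure
  within the window.
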