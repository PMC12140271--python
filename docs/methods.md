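# Methods

## Model overview

`pasom` simulates a population of agents debating a single controversial
science topic on an undirected social network.  It is a continuous-opinion,
discrete-action (CODA) model: each agent's belief that the pro-science
position is true is a beta distribution with pseudo-counts (α_S, β_S),
summarised by the closed-form approximate median
π_S\* ≈ (α_S − 1/3)/(α_S + β_S − 2/3), but the only actions available are to
stay silent or to post in support of the pro (I = 1) or anti (I = 0) side.
A post is either constructive (an argument for the supported side, and the
only thing that moves observers' opinions) or toxic (an attack on the
opposing side, which moves no opinions but raises observers' expected cost
of supporting the attacked side).  Toxicity thereby implements an expected-
sanction mechanism in the sense of the Spiral of Silence: local minorities
fall silent not because their opinions change but because posting stops
paying.

Each round executes seven sub-models in a fixed order: (1) originator
opportunities with probability q per agent; (2) would-share decisions from
start-of-round beliefs, then sharing-chain resolution — only connected
components of would-sharers containing an originator actually post, so
activity needs an exogenous spark and a connected audience; (3) each actual
sharer turns toxic with probability p_X = min(1, 2 c_X |π_S\* − 0.5| ·
(share of active connections opposing it)), and only when arguing for the
side its own opinion favours; (4) every agent passively observes all of its
neighbours' posts and updates its opinion (α_S += λ·A_1·θ, β_S += λ·A_0),
its four interaction expectations, and its interest; (5) constructive
sharers holding at least one connection more than their optimum drop one
neighbour that attacked their side this round; (6) constructive sharers
holding at least one connection fewer than their optimum link to a same-side
originator from their own chain; (7) isolated agents reconnect to a
like-minded agent (same side of 0.5, or within γ on the other side).
Rewiring decisions in steps 5–6 are evaluated against the pre-rewiring graph
snapshot and applied in agent-ID order, skipping operations invalidated by
earlier ones; this tie-break keeps runs bit-reproducible.

## Parameters

The baseline configuration (all defaults of `ModelConfig`) describes a
popular, contested topic: 500 agents, 200 rounds, q = 0.1 originator
opportunities per agent-round, round shocks σ_e = 0.15 (shared by all
agents, one draw per polarity — common information news shocks) and agent
shocks σ_f = 0.4 (idiosyncratic motivation), benefit/cost coefficients
b_A = b_AG = 1, c_T = 1.25, c_TG = 1, c_C = 1, c_BG = 0.2, c_KG = 0.05,
toxic propensity c_X = 1, indecision threshold u = 0.2, interest threshold
μ = 500 with attention multiplier ν = 0.2 after interest loss, expectation
memory decay d_T = d_A = 0.9, reconnection tolerance γ = 0.1, and
pro-science weight θ = 1.1 (θ is not printed with the other baseline values
and is kept configurable; 1.1 reproduces the reported pro/anti division).
The desired-connection count per polarity is
K\*_I = b_AG·λ·w_I/(c_TG·π_T I\* + c_KG) − 1/π_A I\* + c_BG with w_1 = π_S\*
and w_0 = 1 − π_S\*; the printed form of these equations is typographically
ambiguous and this grouping is adopted because it matches the stated
dependencies and gives finite, interpretable optima.

## Priors and their calibration

Initial opinion medians are uniform on (0.025, 0.975), so the population
starts spread "relatively evenly" over the unit interval.  The total
pseudo-count behind a median m is strength_mid + (strength_edge −
strength_mid)·|2m − 1| (defaults 4 and 10, times the regime multiplier:
1 = weak priors, 5 = strong priors), making mid-range agents the most
malleable.  The median relation is inverted exactly so the drawn m *is* the
initial opinion.

Interaction expectations are beta pseudo-count pairs (r·w, (1−r)·w) with
weight w = 10 per polarity.  The constructive response rate prior is
r_A = 0.40 per connection per active round.  The toxic prior warrants a
note: the model's documented opening-round behaviour (roughly a tenth to a
fifth of agents willing to post before shocks, about twice that after) pins
the total expected toxic cost of a post at c_T·K·π_T\* ≈ 0.1.  We therefore
read the "approximately 8%" toxic rate as the expected toxic response to a
post as a whole and apportion it across a typical six-connection
neighbourhood: r_T = 0.08/6 per connection.  Under a per-connection reading
of 8% no agent would ever post before shocks (the maximum pre-shock payoff
is −0.36), activity instead ramps up over tens of rounds, and the simulated
dynamics diverge qualitatively (late synchronized cascades, inflated
network growth).  With the apportioned prior the baseline network produces
19% pre-shock willingness in round one and ~30% with shocks, and the
downstream headline results follow.

Expectation updating is a decayed beta-binomial: each round the stored
pairs decay (d_A, d_T), then, in rounds where the agent observed at least
one active neighbour, the round's evidence is added with the agent's degree
as the trial count (silent neighbours count as observed non-responses).
Rounds with nothing to observe only rescale the pair, leaving the
expectation unchanged.  Interest is lost permanently once α_S + β_S ≥ μ,
dropping λ from 1 to ν; the exact interest and expectation equations of the
original model live in external documentation, so these two rules are this
package's own reconstructions, kept as simple as the described behaviour
allows.

## Starting networks

The default starting network has 100 clusters of mean size 5, complete
within clusters and with 2/500 edge probability between them, generated
once per batch and shared by all simulations.  Cluster sizes are
(mean − 1) plus a multinomial allocation of the remainder: sizes vary with
the right mean while the size variance stays small.  A plain multinomial
allocation would give Var(size) ≈ 5 and mean degree ≈ 7.0; the low-variance
law reproduces the documented mean degree of ≈ 5.9 (ours: ≈ 6.2).  A 3-D
lattice and edge-list/GraphML file input are available alternatives, and a
1000-agent configuration is a matter of scaling n_agents and n_clusters.

## What the simulations show — and don't

Echo-chamber membership follows the operational rule: opinion < 0.4 with
≥ 90% of connections below 0.5 (anti) or opinion > 0.6 with ≥ 90% above
0.5 (pro); agents without connections carry no label, and all agents stay
in the denominator.  At baseline, batches of 20 seeded simulations place
98–99% of agents in a chamber by round 200, split roughly 60/38
pro/anti — matching the reported study within a few points.  Two published
properties are *not* reproduced and the corresponding acceptance checks are
left failing deliberately: (a) the strict claim that every single baseline
run ends with ≥ 98% membership (our minimum across 20 runs is ≈ 96–97.5%),
and (b) the ceiling that with toxicity switched off (c_X = 0) no run
exceeds 85% membership.  In our reconstruction, once toxic expectations
decay toward zero the desired-connection optimum rises steeply (the
equations permit optima near 20 when π_T\* → 0), the graph densifies from
degree ≈ 6 to ≈ 20, and a minority of c_X = 0 runs tip into near-consensus
through the shared round shocks — outcomes the original model evidently
avoids through mechanisms documented only externally.  The package
reproduces the direction of the effect cleanly: mean membership at c_X = 0
sits well below baseline in every batch.

The synthetic dynamics emulate a single-topic, homogeneous-agent online
network with exogenous sparks and passive observation.  They do not model
content, feed algorithms, heterogeneous susceptibility, or multi-topic
attention — so passing tests here speak to the mechanism's internal logic,
not to any particular platform's data.

## Numerics and reproducibility

Populations are stored as struct-of-arrays and the network as a dense
boolean adjacency matrix; per-round observation counts are adjacency
matrix–vector products and chain resolution is connected components on the
would-sharer submatrix, so a 500-agent, 200-round simulation runs in about
two seconds on one CPU.  Batch sizes of 10–20 replicates (vs the study's
200) keep the bundled checks desk-scale; the CLI exposes full-scale runs.
One master seed spawns named child streams (network, then one per
simulation), so results are bit-identical under a fixed seed and unchanged
by the number of simulations requested.  Opinion medians are clamped to
(ε, 1 − ε) with ε = 1e−9; a non-positive denominator in the
desired-connection equation is reported as +inf with a warning; ties in
quantile-run selection break by simulation order.
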