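# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## The DEC process

The state space over `N` areas contains the empty range, all `N`
singletons, and every subset of size ≤ `max_range_size` whose areas form a
connected patch under the adjacency matrix (complete adjacency by default).
States are ordered by size, then lexicographically by area index; state 0
is `∅`. This ordering is the tie-break everywhere a deterministic choice is
needed (scenario ranking, consensus top areas), so results are reproducible
bit for bit.

Anagenesis is a CTMC with generator `Q`: expansion `S → S∪{j}` at rate
`d · Σ_{i∈S, i~j} m_ij` (only into states that exist in the space),
contraction `S → S\{i}` at rate `e`, and `∅` absorbing. `d` and `e` are in
events per Ma (per area pair and per occupied area respectively); branch
lengths are in Ma. Epoch multipliers `m^(k)` rescale pairwise dispersal
within epoch `k`; epochs are delimited by strictly decreasing boundary ages
ending at 0, and a branch spanning a boundary is split there, with the
segment transition matrices multiplied in time order. With all multipliers
equal to 1 the stratified likelihood equals the unstratified one (tested to
1e-9).

Cladogenesis: a singleton range is copied to both daughters; a larger range
`S` splits either by vicariance (`{i}` vs `S\{i}`, if `S\{i}` is a valid
state) or as a peripheral isolate (`{i}` vs `S`). Left/right assignments
count as distinct scenarios and all scenarios of a given `S` carry equal
probability `1/n(S)`. The root state is averaged uniformly over non-empty
ranges, with no conditioning on survival, so the likelihood is a proper
probability and `log L ≤ 0`. Tips and root may not be `∅`; `∅` exists only
inside `Q` as the absorbing global-extinction state.

These are the classical conventions of likelihood-based range-evolution
inference; nothing in the cladogenetic weighting is estimated.

## Likelihood, fitting, ancestral scenarios

The likelihood is computed by postorder pruning with per-node rescaling
(log-scaler accumulation) to avoid underflow. `exp(Qt)` is applied through
an eigendecomposition of `Q` when the eigenbasis reconstructs `Q` to
1e-10 (the generic case for these small dense generators); otherwise the
code falls back to scipy's Padé scaling-and-squaring expm. The
eigendecomposition makes a likelihood evaluation on a 200-tip tree a few
milliseconds, which is what makes multistart ML fitting and the recovery
study cheap.

`fit_dec` maximises over `(d, e) ∈ [1e-9, 10]²` with Nelder–Mead in log10
space (`fatol` 1e-8), from 5 starting points drawn log-uniformly in
[1e-3, 1] by a seeded generator; the best optimum over starts is returned,
with a warning flag if no start reports convergence. Extinction is often
estimated at the lower bound: extinction that leaves no signature in extant
ranges is nearly unidentifiable in DEC, and the recovery study therefore
scores only the dispersal rate (`d` median within ±50% of truth over 20
replicates of 200 tips).

Relative scenario probabilities are computed exactly in one inside–outside
sweep: with inside (post-branch) partials `D` and outside vectors `F`, the
weight of scenario `(S → S_L, S_R)` at node `v` is
`F_v(S) · D_left(S_L) · D_right(S_R) / n(S)`, and the weights at a node sum
to the total likelihood, so normalising them yields the probability of the
likelihood mass attributable to each scenario. This equals (and is tested
against) the constrained-likelihood-over-total ratio computed by brute
force. Scenarios are reported sorted by decreasing probability.

Consensus across model runs (`combine_runs`): the support of an area at a
node within a run is the summed relative probability of scenarios whose
ancestral range contains it; across runs, an area is *accepted* when its
mean support exceeds 0.7 **and** it is top-ranked in every run, falls in a
*moderate* tier above 0.5 under the same agreement, and the node is
*equivocal* otherwise. The same rule is applied to whole scenarios. The
published analyses this mirrors did not define "combined" support
operationally; across-run mean with top-rank agreement is this package's
documented convention, and both thresholds are parameters.

## Hosts as areas

`encode_hosts_as_areas` turns a validated association table into a DEC
problem: each (parasite lineage, area) terminal carries its observed host
set (≤ 2 hosts, matching the repertoire cap of the source analyses) as its
"range" over the 15 host "areas". Host adjacency is complete by default; an
optional gate restricts switches to hosts sharing at least one area in the
table, mirroring geography-constrained dispersal without asserting an
unpublished matrix.

Event translation: vicariance → cospeciation; singleton sympatric copy →
duplication; peripheral isolate → duplication plus an explicit `sharing`
record (one daughter retains the full repertoire) — this keeps a 1:1
mapping to the cospeciation/host-switch/duplication/loss vocabulary without
losing the retention information. Along a branch, a host present at the
child end but absent from the parent-side daughter range is a host switch
(donor = first retained host in sorted order — the reconstruction
identifies the repertoire, not which member seeded the colonisation), and
a host absent at the child end is a lineage loss. Gains and losses are set
differences, so each gained host appears in exactly one switch and each
lost host in exactly one loss.

Codivergence levels per parasite lineage: one host and parasite ranked as a
species → Species–Species; one host and an intraspecific parasite lineage →
Species–Lineage; several hosts → Tribe–Lineage. The focal tribes of a
Tribe–Lineage association are the goodeine tribes carrying at least two of
the lineage's hosts (plurality tribe as fallback); non-goodeid hosts and
single-host minority tribes are listed as exceptions. The threshold of two
encodes "a monophyletic host group, allowing stray colonisations": it keeps
one stray cyprinid or a single out-of-tribe goodeine from redefining the
association, while letting two well-represented tribes share focal status.
On the packaged table this yields Species–Species for *M. resolanae* on
*Xenotaenia resolanae*, Species–Lineage for Lineage II on *Characodon
audax*, and Tribe–Lineage for Lineage I (Ilyodontini; exceptions *Codoma
ornata* and *Chapalichthys pardalis*) and Lineage III
(Chapalichthyini + Girardinichthyini).

The packaged table expands printed rows listing two hosts into one record
per host (12 printed rows → 17 records); area codes A–L and host codes a–o
are case-sensitive exactly as printed. Tribe labels were assembled from the
source system's figure legend and text; the one non-goodeid host is
labelled `non-goodeid:Cyprinidae` so classifiers can treat it as an
out-group explicitly.

## Congruence test

The statistic is the cospeciation count of the LCA reconciliation: each
parasite node maps to the least common ancestor of its descendants' hosts,
and a node is a cospeciation when neither child's image coincides with the
node's image (equivalently, the children map into disjoint subtrees rooted
at distinct children of the image). The null permutes the parasite-tip →
host-tip assignment as a multiset, preserving host multiplicities.
`p_value` uses the add-one convention `(1 + #{null ≥ obs}) / (B + 1)`;
because the count is a small integer with heavy ties this p-value is
conservative (super-uniform), so the result also carries
`p_value_smoothed`, the standard randomized tie-broken permutation p-value,
which is exactly uniform under the null and is the quantity to use in
calibration studies. Power claims use the conservative `p_value`.
Polytomous trees are rejected; the caller must resolve or prune, mirroring
the strictly-dichotomous requirement of classical reconciliation tools.
This statistic deliberately replaces heavyweight event-cost reconciliation:
it tests the same null (parasite phylogeny independent of host phylogeny)
at desk scale with an exact permutation reference.

## Synthetic data

`simulate_host_tree` draws a Yule tree conditioned on `n` tips, including
the final inter-speciation interval, so the expected root age is
`Σ_{k=2..n} 1/(kλ)` (tested at 3 standard errors over 1000 replicates).

`simulate_cophylo` starts one parasite on the host root lineage. At each
host speciation a resident parasite cospeciates with probability `p_c`,
else follows one daughter chosen uniformly ("missing the boat"). Along
branches, host switches, duplications and losses are independent Poisson
processes per lineage; a switch recipient is chosen uniformly among
co-extant host branches. A host switch is a speciation (one daughter stays,
one colonises) — because of this branching, raw event counts grow faster
than linearly in the switch rate; the Poisson property that is tested is
the per-lineage-time event rate, which the simulator exposes via
`total_lineage_time`. Extinct lineages are pruned and unifurcations
suppressed; if fewer than two parasites survive, the result is flagged
empty rather than raising. Defaults in the CLI (12 host tips, `p_c` 0.8,
switch 0.2, duplication 0.05, loss 0.05 per lineage per Ma) produce mostly
codivergent histories with a realistic sprinkling of switches, matching the
qualitative regime of the motivating fish–trematode system.

`simulate_dec_history` runs the anagenetic CTMC exactly (exponential
waiting times, regenerated at epoch boundaries by memorylessness) and draws
cladogenetic scenarios uniformly, logging every dispersal, local
extinction, vicariance and retention event. Its single-branch law is tested
against `exp(Qt)` at total-variation distance < 0.02 over 10,000 draws.

What the generators do **not** emulate: host extinction (pure-birth hosts
only), within-host population structure, sampling error in tip repertoires,
unsampled sister lineages, and phylogenetic uncertainty (trees are known
without error). Passing recovery tests therefore demonstrates correctness
of the inference machinery under the model, not robustness to the ways real
data violate it.

## Problem sizes and tolerances

The test suite and acceptance script use: 100 random instances (≤ 4 tips,
≤ 3 areas) for the pruning-vs-enumeration sweep at 1e-10 relative
tolerance; 20 replicates of 200-tip trees for parameter recovery; 500
independent-tree replicates (199 permutations each) for type-I calibration
and 100 perfect-cospeciation replicates (999 permutations) for power; and
10,000 draws for the single-branch CTMC law. These sizes give stable
verdicts at interactive runtimes. Ultrametricity tolerance defaults to
1e-6 Ma; transition-matrix rows are checked to 1e-9; per-node scenario
probabilities sum to 1 within 1e-9.

## Known limitations

* Extinction rate `e` is weakly identified from extant ranges; expect
  boundary estimates on small trees.
* `max_range_size = 1` leaves no mechanism for tips to occupy different
  areas (no jump dispersal is modelled); use ≥ 2.
* The consensus rule and the focal-tribe threshold are documented
  conventions, exposed as parameters, not re-derivations of any published
  tool's internals.
* Founder-event (jump) cladogenesis and Bayesian estimation are out of
  scope.
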