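# Methods

## Model

`invasim` simulates a plant invasion into a multilayered ecological network
coupling three native guilds: plants (richness S_P), mutualists/pollinators
(S_M) and herbivores (S_H). Two bipartite subnetworks — plant–mutualist and
plant–herbivore — share the plant guild; within each guild every ordered pair
of species competes. Dynamics are generalized Lotka–Volterra. For native
plant i,

    dP_i/dt = P_i ( r_i − d_i P_i − Σ_j a^pp_ij P_j − φ_i a^pp_ik P_k
                    + Σ_l a^pm_il M_l − Σ_h a^ph_ih H_h )

with analogous equations for mutualists (competition within guild, benefit
from linked plants, benefit from the invader when linked) and herbivores
(competition within guild, gains from linked plants and from the invader).
The invader P_k obeys

    dP_k/dt = P_k ( r_k − d_k P_k − Σ_i a^pp_ki P_i + Σ_l α_l M_l
                    − Σ_h a^ph_kh H_h )

where α is its vector of mutualistic benefit strengths. Interaction
coefficients are nonnegative; signs live in the equations.

### Adaptive reallocation

With adaptation on, the invader's benefit strengths follow replicator
dynamics at rate G_k:

    dα_l/dt = G_k α_l ( M_l − Σ_l' (α_l'/T) M_l' ),

i.e. the payoff of link l is the partner's density (the sensitivity of the
invader's per-capita growth to α_l), compared against the strength-share
weighted mean payoff. T = Σα at assembly. This form conserves Σα = T — the
total amount of mutualistic interaction strength equals that of a
non-adaptive invader — and Σα = T is an *attracting* invariant, so numerical
drift self-corrects (verified to <1e-6 over the full horizon in the tests).
Two readings of the payoff were possible (the invader's own per-capita
growth, or the partner's); we take the invader's, the standard
adaptive-foraging construction, which yields ∂W/∂α_l = M_l. Only the
invader-side strengths adapt; the mutualists' benefit *from* the invader
stays at its assembled value. Links are never hard-zeroed during
integration (the replicator boundary is absorbing); "realized" links are
reported as α > 1e-6 at the end of a run.

## Parameter distributions

Per community, one standard deviation σ is drawn per coefficient family and
all entries of that family are |N(0, σ²)| draws (a per-entry-σ switch
exists in the config):

| family | σ range |
|---|---|
| plant–plant competition A_pp | U[0.05, 0.2] |
| mutualist & herbivore competition A_mm, A_hh | U[0.03, 0.05] |
| mutualism B_pm, B_mp; herbivory C_ph, C_hp | U[0.05, 0.2] |
| native-on-invader competition a_ki | U[0.3, 0.5] |
| invader-on-native competition a_ik | U[5, 5.5] |
| invader mutualism b_kl, b_lk; herbivory c_kh, c_hk | U[0.05, 0.2] |

The wildly asymmetric invader competition ranges make the invader far more
competitive than natives; a `same_sigma_variant` flag draws both invader
competition families from the native U[0.05, 0.2] instead. Intrinsic rates:
r_P ~ U[0.5, 1.5], r_M ~ U[−0.5, 0.5] (facultative or obligate mutualists),
r_H ~ U[−1, 0] (herbivores need plants); self-limitation d ~ U[0.5, 1.5];
initial abundances U[0.1, 10] (natives) and U[0.1, 2] (invader); r_k, d_k ~
U[0.5, 1.5]; adaptation rate G_k = 0.5; herbivore–invader link probability
0.6. Each herbivore links to the invader by an independent Bernoulli draw;
the linkage rules do not apply to herbivores.

## Invader linkage

The invader links to round(F1·S_M) mutualists and round(F2·S_P) native
plants (round-half-up, so F=0 gives none and F=1 all). Three rules select
the partners: uniformly at random, most-to-least native degree, or
least-to-most, with ties broken uniformly at random. Degrees are counted in
the *native* plant–mutualist subnetwork, before invasion.

## Stable-community generation

A sampled community is accepted only if, integrated on its own to t = 2×10³,
every native species ends above the 10⁻⁶ extinction threshold. Because that
event is rare under the stated distributions, generation is two-stage:
candidates first pass a cheap necessary condition — the interior equilibrium
x* solving (diag(d) − W) x* = r must be componentwise positive (a linear
solve costing microseconds) — and only feasible candidates are integrated.
Empirically, essentially all feasible candidates also pass the integration
screen, so the pre-filter changes the accepted ensemble only by excluding
communities that drift through t = 2×10³ without any coexistence
equilibrium, which no reading of "stable coexistence" would admit. Caps:
50 000 candidate draws and 200 integration screens per community (both
configurable); exhaustion raises an error, which the experiment layer
records as a failed run.

### Default sizes and connectance

Guild sizes and native connectance are free choices of the experimental
design (the coefficient distributions do not determine them). The
feasibility of full coexistence falls steeply with herbivore richness and
with sparser networks: at connectance 0.25 the feasible fraction of sampled
communities is below ~10⁻⁴, at 0.5 roughly 0.2–0.6%, at 0.6 roughly 0.5–2%
for S_P = S_M ∈ [6, 14] and S_H ∈ [2, 4]. The defaults are therefore
connectance 0.6 (which still leaves substantial degree heterogeneity,
Binomial(n, 0.6) degrees, so the most/least linkage rules remain
meaningful) with 8/8/3 guilds for factorial grids, and S_P, S_M ∈ [6, 14],
S_H ∈ [2, 6] for diversity scans (native diversity 14–34). Larger herbivore
guilds make stable native communities astronomically rare under the stated
coefficient laws and are not reachable by rejection sampling.

## Integration and outcomes

The coupled system is integrated with an adaptive-step Dormand–Prince
Runge–Kutta 4(5) scheme (scipy `solve_ivp`, `RK45`) at rtol = 10⁻⁶,
atol = 10⁻⁹ — tight enough that an isolated logistic species matches r/d to
10⁻⁶ at t = 2×10³. No species is removed mid-run; the 10⁻⁶ threshold is
applied to the final state only. Final densities in (−atol, 0) are clamped
to zero; anything more negative is treated as solver failure. Community
persistence is the fraction of the initially present *native* species above
threshold at the end (the invader is excluded from numerator and
denominator); invasion succeeds iff the invader itself ends above threshold.

## Experiments and seeding

`run_single(F1, F2, rule, adaptive, seed, cfg)` is fully determined by its
arguments: a `SeedSequence` child stream drives each stage (guild sizes,
community generation, invader assembly) separately, so two runs with the
same seed but different invader settings face the identical native
community — used for paired F1 contrasts. Grid and scan cells derive
disjoint seeds keyed by their coordinates, so enlarging a design never
perturbs existing cells. Failed runs are recorded and excluded from cell
means (never retried, keeping the seed→record map stable).

## Diversity–invasibility analysis

Invasion success is regressed on native diversity with a binomial GAM:
cubic B-splines (10 basis functions), penalty weight selected by
generalized cross-validation, GCV(λ) = n·deviance / (n − edf)², over a
log-spaced grid λ ∈ [10⁻², 10⁴]; fits with non-finite deviance or
degenerate effective degrees of freedom (diverged IRLS) are discarded. The
smooth term's significance is a Wald test at its effective degrees of
freedom (statsmodels `GLMGam`). Under a simulated null the test rejects at
5–10% at nominal 5% — the usual slight anti-conservatism of the edf
approximation, shared by comparable GAM implementations; a test
cross-checks the fitted curves against R's mgcv on identical data.
Degenerate designs (fewer than 30 records, fewer than 3 distinct diversity
values, or a constant outcome) are refused with an explanatory error.
Curve shapes are classified mechanically from the sign pattern of first
differences of the fitted curve (differences below 10⁻³ of the curve's
range are ignored): all negative → *negative*, all positive → *positive*,
a single negative-to-positive change → *U-shape*, anything else (or a
nonsignificant smooth) → *flat*.

## Problem sizes in the shipped tests

The test suite and acceptance script run desk-scale versions of the
experiments: 8/8/3 guilds with 25 paired seeds for the persistence–F1
contrast (paired differences averaged over F2 ∈ {0.4, 0.6, 0.8}, where the
decline is expressed; at F2 ≲ 0.1 persistence is insensitive to F1);
500 communities (250 per F2 ∈ {0.2, 0.4} at F1 = 0.4) for the
diversity–invasibility scan; 200 replicates for the GAM null-calibration
check. These sizes give 2–3σ resolution on the qualitative effects.

## What the generator does and does not emulate

The synthetic communities reproduce the distributional assumptions of the
model — guild structure, Bernoulli bipartite topology with min-degree-1
repair, half-normal interaction strengths, uniform rates — conditioned on
stable coexistence. They do not emulate nestedness or modularity structure
of empirical pollination webs, body-size constraints, or spatial processes.
Passing tests therefore validate the simulator and its qualitative
model-level conclusions (persistence declining with invader–mutualist
connectance; negative diversity–invasibility relationship without
adaptation), not predictions about any empirical community.

## Known limitations

- Stable-community generation is rejection sampling conditioned on a rare
  event; runtime grows steeply with S_H and with lower connectance, and the
  accepted ensemble is necessarily the feasible subset of the stated
  distributions.
- Native species do not adapt; only the invader's mutualistic strengths
  evolve.
- The replicator payoff reading (partner density) is one of two defensible
  interpretations; the alternative (partner fitness) is not implemented.
- Persistence surfaces at full grid resolution (21×21×3 rules×2 adaptation
  ×4 replicates) take hours on one core; the shipped experiments default to
  the reduced designs described above.
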