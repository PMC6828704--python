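# Methods

`dominet` infers temporal dominance hierarchies from dyadic agonistic
interactions, builds per-session directed weighted interaction networks, and
tests their consistency through time. This note records the models, the
parameter choices, the numerical conventions, and what the synthetic-data
experiments do and do not demonstrate.

## Dominance inference

### Randomized Elo-rating

Each individual starts a session with score 1000. After each decided contest
the winner gains and the loser loses

    transfer = k * (1 - p),    p = 1 / (1 + exp(-(s_winner - s_loser) / s0)),

with k = 100 by default. The update is zero-sum, so the score total is
conserved exactly (to floating-point) after every event — this is asserted in
the tests. `p` is the expected-win probability under the classic Elo
convention: the scale s0 = 400/ln 10 makes a 200-point advantage worth
p ≈ 0.76, i.e. the familiar base-10 logistic `1/(1 + 10^(-d/400))`. A
fixed-transfer variant (every win moves exactly k points) is available via
`EloConfig(update_rule="fixed")` for sensitivity analysis; the
expectation-weighted rule is the default because it is what the Elo
literature and the animal-dominance packages implement.

Final Elo scores depend on event order. Within an observation day the scored
order is partly arbitrary (simultaneous dyads, camera handovers), so the
per-day hierarchy is the mean of the final scores over 1000 uniformly random
permutations of the day's events (`EloConfig.n_randomizations`), seeded and
reproducible. Internally the permutations are run as one vectorised batch —
scores are a (randomizations × individuals) array updated event-step by
event-step — which keeps 1000 randomizations of a ~130-event day in the
low milliseconds. The vectorised path and the plain sequential
`run_elo_sequence` are the same update; the tests pin the sequential path to
hand-computed values and the batch path to the sequential one in the
single-event case.

Draws are excluded from Elo by default (a hierarchy is defined by wins and
losses); `draw_rule="half"` instead applies the update with a half outcome,
`transfer = k * (0.5 - p)`.

Rankings sort by descending mean score; exact ties (rare with continuous
scores) break by total wins, then identifier, and are flagged in
`EloResult.ties`.

### David's scores

The order-independent cross-check. With `wins[i, j]` the decided wins of i
over j and `n_ij = wins[i, j] + wins[j, i]`:

    P_ij = wins[i, j] / n_ij                       (interacting dyads)
    D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1)        (chance-corrected)
    w_i  = Σ_j D_ij        w2_i = Σ_j D_ij · w_j
    l_i  = Σ_j D_ji        l2_i = Σ_j D_ji · l_j
    DS_i = w_i + w2_i - l_i - l2_i
    normDS_i = (DS_i + N(N-1)/2) / N

Dyads that never interacted contribute zero to every sum (the standard
convention). ΣDS = 0 identically; normDS lies in [0, N-1]. The
chance-corrected D_ij is used rather than raw P_ij because a 1-0 dyad should
not carry the same weight as a 10-0 dyad; both matrices are exposed on the
result. Elo and David's-score hierarchies are compared per day (Pearson on
the score vectors plus Spearman on the ranks) and pooled across days by
stacking individual-day score pairs; both views are reported since either
could be the headline comparison.

## Networks and QAP

Per session and per category (agonistic, affiliative) the records are
aggregated into a directed adjacency matrix: cell (i, j) counts interactions
initiated by i toward j, draws included — a draw is still an interaction.
Counts are divided by the session's recording duration (interactions per
hour) so sessions of different length are comparable, and nodes are ordered
by that day's dominance ranking.

Association between two networks on the same individuals is the Pearson
correlation over corresponding off-diagonal cells (the diagonal is
structurally zero and excluded). The QAP test jointly permutes rows and
columns of the second matrix — relabeling its nodes while preserving its
weight structure — and recomputes the correlation per permutation:

- sampled mode (default, 1000 permutations): p_greater =
  (#{null ≥ observed} + 1) / (n + 1), the identity arrangement included, so
  p is never exactly zero;
- exact mode (N ≤ 8): full enumeration of all N! relabelings with exact
  proportions.

Ties between the observed and permuted correlations are counted with a 1e-9
tolerance so that automorphism-equivalent relabelings, which reproduce the
observed value up to float summation order, land on the "greater or equal"
side. One-tailed p_greater (consistency = positive association) is the
headline; p_lesser is always reported as well. Correlation is scale-free, so
testing on rates rather than raw counts changes nothing (asserted in the
tests). A zero-variance matrix has no defined correlation and is reported as
NaN rather than an arbitrary value.

`consistency_report` tests consecutive session pairs whose rosters are
identical and lists skipped pairs (for example the two sessions flanking an
individual's reintroduction); an all-pairs mode exists behind a flag.

## Synthetic data

`simulate_group` emulates the observational design the pipeline targets: a
five-female captive crow group recorded over five ~3.2 h sessions at ~27-day
intervals. Its defaults are the study conditions:

- Latent abilities (red 2.2, yellow 1.1, blue 0.0, green −1.1, grey −2.2)
  with steepness 0.5: the probability that the higher of two abilities wins
  a decided contest is `logistic(Δa / 0.5)`, i.e. ≈ 0.90 per adjacent pair —
  a steep, despotic hierarchy with an uncontested top individual.
- Per-session event counts are zero-truncated normal with mean 131.8 / SD
  111.7 (agonistic) and 44.6 / 13.1 (affiliative), rounded half-up. The
  observed dispersion (SD ≈ mean) rules out Poisson. Because truncating a
  normal at zero shifts its mean upward, the underlying parameters are
  solved numerically so the *truncated* distribution has the stated mean and
  SD; a 200-replicate calibration check confirms the per-session mean.
- Initiators are drawn with probability ∝ (rank weight)^2 (`initiation_bias`),
  concentrating aggression in the two dominants; recipients are uniform
  among the others. Affiliative events occur only among the top three ranks,
  with the same bias.
- 10% of agonistic events are draws (`draw_prob`); the observational record
  defines draws but reports no rate, and a modest one exercises the
  draws-in-networks / draws-out-of-hierarchies bookkeeping.
- grey is absent from sessions 1–2 and reintroduced from session 3; green
  gains 1.65 ability at session 4 and loses it again at session 5,
  producing a temporary blue/green rank switch.

Ground truth (per-session abilities, implied ranking, dyadic win
probabilities) is returned alongside the records, and the whole generator is
deterministic given `rng_seed` (byte-identical output tables).

### What the experiments show — and what they do not

`recovery_experiment` simulates replicate datasets, runs both inference
methods per session, and scores them against the latent order. The
validation configuration uses adjacent-dyad win probability 0.9 with 130
decided contests per session and *uniform* dyad sampling
(`initiation_bias = 0`): exact recovery of the full order requires
observations on every dyad, and the skewed initiation of the default
conditions routinely leaves bottom dyads with a handful of events — a
property of the data, not of the estimator. Under the validation conditions
randomized Elo recovers the exact latent order in ≥ 95% of 100 replicates
and agrees with the David's-score ranking at Spearman ≈ 1. Under the default
(study) conditions the top of the hierarchy is recovered every day and
overall rank agreement stays high, but sparse days can swap poorly observed
bottom neighbours — visible in `analysis/03_dominance.py` output.

QAP calibration uses pairs of independently simulated equal-ability,
unbiased-initiation groups, which makes the two matrices exchangeable under
node relabeling — the configuration in which a rejection is a genuine false
positive. (Two independent groups that *shared* a rank structure would be
truly associated; that would test power, not size.) The rejection rate at
α = 0.05 over 1000 pairs falls inside 0.05 ± 0.02. Sampled p-values are
checked against full enumeration for N = 4 and 5 across 100 random pairs
within 3 binomial SEs (plus the +1/(n+1) offset); because any single
comparison lands outside 3 SEs ~0.4% of the time by chance, the check
tolerates up to 4 of 100 violations rather than demanding all instances
simultaneously.

The generator reproduces marginal counts, hierarchy steepness, initiation
skew, absences and rank dynamics. It does not model behavioural sequences
(recruitment, chases, coalition formation), reciprocity or partner-specific
affinities beyond rank, within-session nonstationarity, or observer error in
winner assignment. Passing tests therefore validate the inference machinery
under the stated generative assumptions, not the ethological conclusions one
might draw from real observations.

## Numerical conventions and degenerate inputs

- Seeds: a single global seed fans out to named substreams
  (`pipeline.derive_seed`) so stages rerun in isolation reproduce the full
  run; all derived seeds stay below 2^31.
- A day without decided agonistic contests cannot yield a hierarchy: the
  pipeline skips it, lists it in the report, and still builds its networks.
- Fewer than 3 paired individuals: correlations are reported without
  p-values (NaN) rather than with meaningless ones.
- David's scores require N ≥ 2; an all-zero matrix yields DS = 0 for
  everyone and normDS = (N−1)/2.
- Problem sizes in the shipped experiments (100 recovery replicates, 1000
  type-I pairs, 1000 permutations/randomizations) keep the full suite and
  the acceptance script in the tens of seconds while leaving Monte-Carlo
  error well inside every asserted band.

## Known limitations

- The Elo expectation curve and k are global constants; no per-individual
  uncertainty or time-decay is modelled.
- QAP here tests pairwise network association only; it is not a model of
  network evolution, and no multiple-testing correction is applied across
  the session pairs (mirroring standard practice for these designs).
- Hierarchy steepness/linearity indices (h', triangle transitivity) are out
  of scope.
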