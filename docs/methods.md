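# Methods

This note documents the models and procedures implemented in `bovmt`, the
assumptions behind them, the parameter defaults and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, notation and the packaged reference

All positions are 1-based nucleotide positions ("np") on the 16,338-bp
bovine mitochondrial reference coordinate system. Variant labels follow the
field's shorthand: bare position = transition (the purine↔purine or
pyrimidine↔pyrimidine partner of the reference base), trailing base =
transversion to that base, `+X` = insertion of X after the position, `d` =
deletion, `h` = heteroplasmy, `@` = reversion to the reference allele.
Heteroplasmies are encoded in sequence as IUPAC two-base codes that include
the reference base; three- and four-base codes are rejected, since the label
grammar carries only a binary `h` flag.

The packaged reference is a **synthetic stand-in**, generated
deterministically (`scripts/make_reference_fixture.py`) with approximate
bovine base composition and the structural features the notation relies on:
a C homopolymer tract ending at np 221, an A tract ending at np 1600, a
non-G base at np 364 and C at np 15953 (so the Q-diagnostic `15953G` is a
C→G transversion). Every coordinate-dependent rule is exercised against
those features. Analyses of real data should load the true reference
sequence via `load_reference(path)`; nothing in the code assumes the
synthetic sequence beyond its length.

**Circularity.** The molecule is circular; coordinates are linearized at
np 1. This affects only the optional pairwise-alignment step used when an
input sequence is not length-matched to the reference — alignments are
computed on the linearized sequence, so variants spanning the origin may be
represented as separate events at both ends.

**Indel normalization.** Indels are left-aligned within homopolymer runs to
decide tract membership; an insertion/deletion whose run covers np 221 (C
tract) or np 1600 (A tract) is *scored at the tract's canonical np*,
matching the convention of scoring tract-length variation at a fixed
position. This is our convention for tract variants longer than one base as
well (the source material does not specify one): any single-base-composition
indel touching the tract is treated as tract-length variation.
`filter_hypervariable` then removes indels at np 221/1600 and the `364+G`
insertion — length variation only; substitutions at those positions are
kept.

## Haplogroup classification

The taurine phylogeny is configured as a rooted tree of named haplogroups,
each with defining variants; a node's full motif is the union along its
ancestry. A profile is assigned to the node maximizing
`matched − λ·mismatched` over full motifs, with λ = 1 by default
(configurable), ties broken toward the deeper node and then
lexicographically. A motif site at which the profile shows the reference
allele — including true back mutations — counts as mismatched. This mirrors
common mtDNA-classifier practice (score motif hits, penalize expected-but-
absent sites, prefer the most derived consistent node).

The default config transcribes the one diagnostic position recoverable from
the source text (`15953G`, separating Q from T); all other motifs are
synthetic placeholders flagged `status=synthetic` in
`bovmt/data/haplogroups.tsv`, and the placeholder nodes I (zebu) and R carry
no curated content. Classification correctness is therefore defined —
and tested — relative to the loaded config, which is the editable contract
of the module. Hypervariable sites are never motif members.

## Parsimony trees

Within each haplogroup, lineages are represented by their *residual items*:
non-founding variants they carry, plus reversion items for founder-motif
sites they lack. Greedy agglomeration merges the pair of lineages sharing
the most items (ties: smallest shared positions, then sample ids), placing
the shared items on a new internal branch; merging continues while any pair
shares an item, which is exactly the condition under which a merge strictly
reduces total mutation count. Lineages sharing nothing radiate from the
haplogroup root. Backbone branches carry the haplogroup defining variants.

The greedy construction attains the exhaustive parsimony minimum on small
instances (tested against a Sankoff-DP oracle over all rooted topologies of
≤ 5 tips); published trees of this kind are hand-curated, so exact topology
is not a contract — mutation counts, root-to-tip distances and annotations
are. Recurrence annotation flags any (position, kind, allele) occurring on
≥ 2 branches; back-mutation detection tracks per-site state from the root
and covers substitutions (indel reversions are not auto-detected — they are
rare and do not feed any downstream statistic). Ambiguous placements are
resolved deterministically by the tie-breaks above, which also biases
toward fewer recurrences by merging maximal shared sets first.

## Dating

**ρ/σ.** ρ = Σ l_b·n_b / n equals the mean root-to-tip mutation count;
σ = √(Σ l_b·n_b²) / n is the standard genealogy-based heuristic standard
error (the source material cites but does not print the formula; the
estimator here is the one in general use, and is verified in tests against
brute-force evaluation on random genealogies). Mutations are counted on the
coding region (np 364–15791) with heteroplasmies excluded; the caller
applies `restrict_region` to profiles **and** restricts the founder motif to
the same region (`build_clade_tree` takes the restricted founder set), so
control-region motif sites do not appear as spurious reversions.

**Clock.** T = divergence × 3,172 years per coding-region mutation
(`ClockModel`, configurable). Report rounding is half-even to 2 decimals
(ky) and 1 decimal (percent); raw values are kept internally. The related
literature constants of a ~75.5 ± 10 ky age for macro-haplogroup PQT and a
6-year generation time are documented here only; no Bayesian/skyline
machinery is implemented.

**ML divergence.** The clade is modeled as a clock tree: tips at height 0,
root at per-site height *h*, each other internal node at a free fraction of
its parent's height. The likelihood is computed by Felsenstein pruning over
site patterns under HKY85 (empirical base frequencies with a pseudocount
unless supplied) with discrete-gamma rates — 32 equal-probability
categories by default, each category's rate being the analytic conditional
mean, renormalized to average exactly 1. Optimization is bounded L-BFGS-B
over log h, logit height fractions, log κ and log α (initial values κ = 2,
α = 1; log-likelihood tolerance 1e-8); non-convergence raises
`OptimizerError` rather than returning silently. The reported divergence is
h × region length (15,428 sites for the full coding region), i.e. expected
mutations per genome from root to tip, so ρ and ML columns convert with the
same per-genome clock. The SE is the observed-information (curvature) SE of
h at the optimum with the other parameters held at their MLEs; the age
table's ML ΔT column is that curvature SE converted to ky.

Degenerate inputs: identical sequences drive h to its lower bound
(~1e-9 per site, i.e. a numerically-zero divergence); sites with N or gaps
are treated as missing in the pruning partials.

## Diversity

H = n/(n−1)·(1 − Σp_i²) computed from integer class counts (so all-distinct
samples give exactly 1.0), with Nei's variance estimator
V = 2/(n(n−1))·{2(n−2)(Σp_i³ − (Σp_i²)²) + Σp_i² − (Σp_i²)²}; SE is
reported to 3 decimals. Haplotype identity is equality of filtered variant
profiles over the whole molecule (control + coding), since published
haplotypes include control-region sites. For the 18/6/5/2 composition the
largest class rounds to 58.1% under half-even rounding (18/31 = 58.06%; a
printed value of 58.0% elsewhere reflects truncation, which we do not
match). M is the mean pairwise symmetric-difference size within a
haplogroup.

## The simulator

`simulate` emulates the empirical structure of a multi-haplogroup mitogenome
sample; its defaults *are* the study conditions the package is validated
against, and were fixed once:

* composition T1:18, T2:6, T3:5, Q1:2 (n = 31);
* clade ages 15.57 / 13.64 / 12.53 / 19.29 ky — the ρ-based ages of the
  corresponding haplogroup rows of the published age table;
* star genealogies (the observed within-haplogroup topology); constant-size
  and exponential-growth coalescent modes are provided for robustness
  testing, with waiting times rescaled so the expected root height equals
  the clade age (growth mode calibrates the expectation by an internal
  deterministic Monte-Carlo pass);
* clock: one coding-region mutation per 3,172 years; per-branch coding
  mutation counts are Poisson with mean branch_years/3,172, so dating is
  calibrated by construction, not fitted;
* HKY85 with κ = 20 and α = 0.5 (32 categories) — a high
  transition/transversion ratio and strong site-rate heterogeneity typical
  of mammalian mtDNA; base frequencies follow the bovine composition;
* control region: a single per-site rate multiplier (default 5×) over the
  coding per-site rate. The source material gives no control-region clock;
  only coding sites feed dating, so this affects realism, not estimates.

Mutation sites are drawn proportionally to their gamma rate within the
region; the substituted base follows the HKY conditional probabilities given
the current base. Recurrent and back hits at a site are allowed (no
infinite-sites assumption) and exercise the recurrence annotation. Founder
motifs (substitutions only) are applied at each clade root. A single seed
determines genealogies, site rates and mutations; the truth manifest records
haplogroups, ages, per-branch event counts, genealogies and the expected
per-tip variant labels, and re-calling variants from the emitted FASTA
reproduces those labels exactly (tested).

What the simulator does **not** emulate: sequencing error and read-level
artifacts, heteroplasmy, indel mutation, ancient-DNA damage, selection
(including the mild inflation of shallow clade ages by purifying selection),
and hand-curated topology details. Passing round-trip and recovery tests
therefore demonstrates internal consistency of the pipeline under the
model's assumptions, not robustness to real-data artifacts.

## Problem sizes used in validation

The oracle and recovery surfaces are sized for a single-CPU run: exhaustive
parsimony comparison at ≤ 5 tips, ρ/σ brute-force equivalence on 100 random
genealogies of ≤ 12 tips, pruning-vs-enumeration equality on 3–4 taxa ×
30–50 sites (tolerance 1e-10), Poisson clock calibration over 2,000
single-branch replicates, and ρ-age recovery over 200 simulated 6-tip star
clades of true age 17.64 ky (mean within 2 standard errors of truth). These
sizes are the package's validation choices and scale up transparently.

## Known limitations

* The ML clock model fixes the topology supplied by the caller; it does not
  search topologies, and only the clock-constrained variant is implemented.
* The curvature SE for the ML divergence conditions on κ and α at their
  MLEs, slightly understating uncertainty when those are poorly determined.
* Back-mutation detection in arbitrary (externally built) trees covers
  substitutions only.
* The default motif config is a structural scaffold, not a curated
  phylogeny; real-data classification requires supplying curated motifs.
* Multi-base deletions are emitted one label per np; tract conventions for
  multi-base tract indels are a documented house rule (see above).
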