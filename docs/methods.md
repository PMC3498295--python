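# Methods

This note records the models behind `forumnet`, the choices made where
the underlying analysis is under-determined, and what the synthetic data
can and cannot establish.

## Corpus model and study window

A corpus is three tables — members (id, forum, self-assigned user type),
threads (id, forum, creator, creation time), posts (id, thread, author,
time) — with the opening message of a thread stored as an ordinary post
by the creator at the thread's creation time. Eight user types are
representable; `unknown` is a real category, never a missing value.
Members registered as patient or survivor form the *patient/survivor*
group; all others (caregiver, doctor, nurse, student, researcher,
unknown) are *non-patient*.

The study-window filter removes threads created after a thread cutoff
(with all their posts) while keeping later replies to earlier threads up
to a separate post cutoff, mirroring harvest designs that allow a
response tail after the collection window closes. Date-valued cutoffs
are inclusive of the whole calendar day. Members left without a
surviving post are dropped by default, because a member only enters a
communication network with their first post; a flag retains them for
registration-count reporting. All timestamps are timezone-naive UTC and
durations are whole-day differences — the source granularity of such
corpora is rarely better, and calendar days are the unit in which
relationship length is conventionally reported.

The packaged reference count table (six cancer forums, 2001–2010)
reproduces its published marginals exactly: survivor percentages 13.3 /
6.0 / 11.7 / 18.9 / 28.8 for melanoma, renal cell, prostate, ovarian and
breast, 27,450 posts overall, 145 posts in the low-traffic testicular
forum. The published member grand total (8,388) exceeds the sum of the
per-forum rows (7,971); the source does not explain the discrepancy, so
the package reports both and reconciles nothing.

## Network construction

Thread structure does not record who a reply addresses, so attribution
is an explicit modelling choice with two first-class rules:
`to_creator` (default — each reply is one message to the thread creator,
the conservative creator/responder reading) and `to_all_prior` (one
message to each distinct earlier participant, the
reply-addresses-the-conversation reading). Neither is claimed to be
"the" true rule; every output records which was used. Self-pairs are
dropped (a communication channel presumes two distinct members) and
opening posts create no arcs. Breadth counts distinct neighbours over
the union of in- and out-arcs, not edge stubs. Contribution counts all
messages composed, opening posts included by default (configurable),
so member contributions sum to the post count of the forum.

## Dyads and intimacy

Tie strength is the symmetric message count of the unordered pair (both
arc directions summed). Intimacy cut points are μ+σ and μ+2σ of dyad
counts, computed per forum by default (forums are analysed separately
throughout; a global scope is available for sensitivity analysis), with
the population SD (÷n; the sample convention is a flag, and the choice
is recorded in the output metadata). Counts exactly at a cut are
assigned upward so the three classes are exhaustive — the verbal rule
("fewer than" / "more than") leaves boundary counts unassigned.

Dyad groups: *patient dyad* iff both members are patient/survivor. For
the other side of the comparison two readings exist, and the package
implements both: a pooled mode in which every remaining dyad (mixed
pairs included) is an "other" dyad, and a strict mode in which the
comparison group is both-members-non-patient and mixed dyads are
excluded. Table-style dyad comparisons in the pipeline default to the
strict reading, which matches the study framing these analyses
reproduce (patient/survivor dyads versus dyads where *both* members are
not patient/survivors). The choice matters mechanically: homophily
routes reply volume toward patient-created threads, and the repeat-
partner pools at those threads contain non-patients, so mixed dyads are
about as message-heavy as patient dyads; pooling them into the
comparison group dilutes any patient-dyad enrichment signal.

Duration is defined for all dyads; duration comparisons can be run on
all dyads (default) or restricted to intimate dyads, since which
population the original table-style analyses used is ambiguous.

## Rank-based comparison machinery

Kruskal–Wallis with midranks and the tie-correction factor
C = 1 − Σ(t³−t)/(N³−N); the all-values-identical case (C = 0) raises a
degenerate-data error rather than returning 0/0. Follow-up pairwise
comparisons use Dunn's z on the joint ranking with Bonferroni control
over the family; the reported "difference" is the signed mean-rank
difference R̄ᵢ−R̄ⱼ, of which only the sign (direction) is interpreted.
A separate-pairwise-Kruskal-Wallis variant (each pair re-ranked) is
available because the original pairwise procedure behind such tables is
typically unstated. Binary outcomes (intimate / highly-intimate
indicators) are analysed with the same rank machinery — a two-group
rank test on a 0/1 variable is a valid proportions comparison — to keep
one method throughout. P-values are two-sided; human-readable output
floors them at 10⁻⁴ ("<0.0001") while machine output keeps full
precision.

The chi-square reference is an approximation: at pooled N ≤ 10 the exact
permutation distribution of H is discrete with large atoms, so the
test-suite oracle compares the chi-square p against the exact bracket
[P(H>h), P(H≥h)] rather than a single permutation p.

## Synthetic generator

The generator emulates the *structure* of a threaded forum corpus —
exact per-type member counts, an 8.7-year posting window, skewed
participation, thread/reply dynamics — with three dials planting the
contrasts the analysis is meant to detect:

- `sociality` ∈ [0,1]: per reply slot, with probability `sociality` the
  author is a fresh draw from the member activity distribution;
  otherwise the author is re-drawn uniformly from members who already
  replied in any thread of the target thread's creator (repeat-partner
  reinforcement). High values produce broad/shallow contact, low values
  narrow/deep repeated contact.
- `homophily` ∈ [0,1]: probability that a patient/survivor's reply is
  routed to a patient/survivor-created thread when one exists; other
  draws choose threads uniformly.
- `activity_concentration` > 0: concentration of the symmetric Dirichlet
  from which per-member activity weights are drawn. The default 0.3
  gives a few hyper-active members and a long quiet tail, the
  participation skew characteristic of real forums.

Thread creators are drawn from the activity weights, creation times are
uniform over the window, per-thread reply counts are Poisson (mean 4 by
default), and reply times are uniform between thread creation and the
post cutoff, strictly increasing within a thread. One seeded stream per
forum corpus; multi-forum studies derive one substream per forum in
config order, so adding a forum never reshuffles another forum's draws.
Equal (config, seed) pairs are bit-for-bit reproducible through write
and re-read.

Presets: `female_style` (sociality 0.15, homophily 0.8) and `male_style`
(sociality 0.85, homophily 0.8), both with 200 members whose type mix is
scaled from the registration mix of a real female-specific cancer forum
(82 patients, 19 survivors, 15 caregivers, 2 doctors, 5 researchers,
77 unknown) and 300 threads. The sociality/homophily values are
calibration conventions of this package, not estimates from data.

What the generator does *not* emulate: message content, bursty or
seasonal activity, member churn, thread-length/eigen-degree
distributions matched to any real forum, or group-dependent reply
volume. Consequently, planted-effect tests show that the pipeline
*recovers* contrasts of the kind the analysis targets; they say nothing
about effect sizes in real communities.

A structural consequence worth knowing: because repeat-partner
reinforcement is group-blind, the expected number of messages per dyad
is roughly 1/sociality at every creator, regardless of who the creator
is. Homophily therefore changes *where* reply volume goes (patient
creators receive more), which multiplies the number of patient-side
dyads but thickens their weight tail only logarithmically (early pool
members at high-volume creators accumulate draws like the harmonic
series). The breadth contrast between sociality presets is consequently
large and recovered essentially always, while the highly-intimate
(μ+2σ tail) enrichment of patient dyads is a second-order effect:
with the default presets its per-study recovery rate is about 0.85,
so occasional simulated studies show a reversed sign. This is a
property of the generative model, not of the comparison machinery.

## Numerical and layout choices

- Thresholds, ranks and test statistics are plain double-precision
  arithmetic; the KW/Dunn implementations agree with independent
  definitional evaluations to 10⁻¹⁰ on the test fixtures.
- The Kamada–Kawai-style layout minimises
  Σ_{i<j} (1/d²ᵢⱼ)(‖xᵢ−xⱼ‖−dᵢⱼ)² over unweighted shortest-path
  distances by SMACOF majorization (stress provably nonincreasing per
  iteration), from a seeded circular initialisation with small jitter;
  termination at relative stress change ≤ 10⁻⁶ or 500 iterations.
  Connected components are laid out independently and packed on a grid
  by decreasing size with 1.2× spacing. Edge weights are not used in the
  distances; the weighted variant was considered and rejected to keep
  the drawn geometry a function of topology alone.
- Degenerate inputs: empty dyad scopes, all-identical pooled samples and
  empty networks raise errors rather than returning conventional values;
  a dyad comparison with an empty group or a constant outcome yields an
  explicit NA row.

## Known limitations

Message counts proxy intimacy; content is neither stored nor analysed.
Attribution of replies is a modelling choice, not an observation. The
generator's realism claims are limited to the planted contrasts above.
Rank-mean differences are reported on the rank scale and are not
comparable across tables with different group sizes.
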