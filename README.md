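# forumnet

Communication-network analysis of threaded online health-forum corpora:
who talks to whom, how heavily, for how long — and whether member groups
differ in the way they socialise.

The package is built for researchers in consumer health informatics and
patient social-network analysis who study peer support in online disease
communities (the motivating setting is a set of six cancer-specific
forums active 2001–2010, where members self-register as patient,
survivor, caregiver, doctor, nurse, student, researcher or unknown).
Because raw forum corpora of this kind are rarely redistributable, the
package ships a seeded synthetic-corpus generator whose social structure
is planted by interpretable dials, so the full pipeline is testable and
results are reproducible end to end.

## What it computes

Starting from a corpus of members, threads and posts (three CSV tables):

1. **Directed communication networks.** Each forum becomes a weighted
   digraph: a member enters the network with their first post; each
   reply is one message from its author to the thread creator (default)
   or to every earlier participant (`to_all_prior`). Per-member
   **breadth** is the number of distinct correspondents; **contribution**
   the number of messages composed. Networks export to Pajek `.net`.
2. **Dyadic intimacy.** Every pair with at least one attributed message
   is a *dyad* with symmetric count *w*. With μ and σ the mean and SD of
   dyad counts in the forum, a dyad is an *acquaintance* if
   w < μ+σ, *slightly intimate* if μ+σ ≤ w < μ+2σ, *highly intimate* if
   w ≥ μ+2σ. Relationship duration is the whole-day span between the
   dyad's first and last message.
3. **Rank-based group comparison**, implemented from first principles
   with midranks throughout:
   - Kruskal–Wallis omnibus statistic with tie correction,
     H = [12/(N(N+1)) Σᵢ nᵢ R̄ᵢ² − 3(N+1)] / C,
     C = 1 − Σₜ(t³−t)/(N³−N), χ²-referenced at k−1 df;
   - Dunn pairwise follow-up on the joint ranking,
     z = (R̄ᵢ−R̄ⱼ) / √(S(1/nᵢ+1/nⱼ)), S = N(N+1)/12 − Σₜ(t³−t)/(12(N−1));
   - Bonferroni control, p_adj = min(1, m·p). Because these are rank
     tests, the *sign* of the mean-rank difference carries the direction
     of an effect; its magnitude is on the rank scale.
4. **Visualisation.** The intimate sub-network (dyads at level
   slightly-intimate or above) laid out by a seeded Kamada–Kawai-style
   stress majorization, nodes glyphed by user type, arc width monotone
   in message count.

The synthetic generator's dials: `sociality` (1 = broad/shallow fresh
partner choice, 0 = narrow/deep repeat-partner reinforcement),
`homophily` (probability a patient/survivor's reply lands on a
patient/survivor-created thread), and `activity_concentration` (skew of
per-member posting propensity). Presets `male_style` (sociality 0.85)
and `female_style` (sociality 0.15) plant the broad-vs-narrow contrast.

## Worked example

```python
from forumnet import (build_forum_comparison, female_style,
                      generate_forums, male_style)

corpus = generate_forums([male_style(), female_style()], seed=1)
table = build_forum_comparison(corpus, ["male_style", "female_style"], "breadth")
print(f"omnibus H = {table.omnibus.H:.2f}, p = {table.omnibus.p:.4g}")
print(table.frame().to_string(index=False))
```

prints

```
omnibus H = 15.53, p = 8.103e-05
                comparison  metric      diff        z    p_raw  p_bonferroni  n_i  n_j
male_style vs female_style breadth 24.492188 3.941336 0.000081      0.000081   64   50
```

The positive mean-rank difference (and z) says patients in the
broad-style forum correspond with more distinct members than patients in
the narrow-style forum — the planted contrast, recovered at p ≈ 8·10⁻⁵.
The scripts in `examples/` walk through each capability (simulation,
network construction, dyad classification, group comparison, plotting)
with commentary; a thin CLI (`forumnet simulate|analyze|report|plot`)
wraps the same functions for shell use.

## Layout

- `src/forumnet/forum_io.py` — corpus data model, CSV I/O, study-window
  filter, summary count tables
- `src/forumnet/reference_tables.py` — published six-forum count table
- `src/forumnet/synthetic_forum.py` — seeded corpus generator and presets
- `src/forumnet/network_builder.py` — networks, breadth/contribution, Pajek
- `src/forumnet/dyad_metrics.py` — dyads, intimacy thresholds, duration
- `src/forumnet/group_stats.py` — Kruskal–Wallis, Dunn, Bonferroni, tables
- `src/forumnet/viz_layout.py` — intimate subgraph, stress layout, rendering
- `src/forumnet/pipeline.py`, `cli.py` — one-command orchestration
- `docs/methods.md` — models, assumptions, parameter choices, limitations
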