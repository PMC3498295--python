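"""Build the directed communication network of one forum.

Each reply is attributed as one message from its author to the thread
creator (the default rule); arcs carry message counts.  Breadth is the
number of distinct correspondents of a member, contribution the number
of messages they composed.
"""

from forumnet import (
    build_network,
    export_pajek,
    female_style,
    generate_corpus,
    member_breadth,
    member_contribution,
)

config = female_style()
corpus = generate_corpus(config, seed=1)
network = build_network(corpus, config.forum_name)

print(f"{len(network.nodes())} posting members, {len(network.arcs())} arcs, "
      f"{network.total_weight()} attributed messages")

by_breadth = sorted(network.nodes(), key=lambda m: -member_breadth(network, m))[:5]
for m in by_breadth:
    print(f"  {m}: breadth {member_breadth(network, m):3d}, "
          f"contribution {member_contribution(corpus, config.forum_name, m):3d}")
# Members with high breadth correspond with many distinct partners; a high
# contribution at low breadth marks the narrow, repeated-partner style.

export_pajek(network, "scratch_forum.net")
print("Pajek export written to scratch_forum.net")
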