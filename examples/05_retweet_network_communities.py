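"""Retweet-network community structure: 3-core plus Louvain.

Builds the weighted directed retweet graph from a synthetic stream, peels it
to the 3-core (every account keeps at least three distinct neighbours),
extracts communities by modularity maximization, and prints the
inter-community retweet flows and each community's most active accounts.
"""

from datetime import date

import modeval as me

config = me.default_config(
    n_communities=4,
    days=90,
    start_date=date(2020, 2, 7),
    baseline_volume=50.0,
    seed=17,
)
eco = me.generate_ecosystem(config)

graph = me.build_graph(eco.tweets)
print(f"retweet graph: {graph.number_of_nodes()} accounts, "
      f"{graph.number_of_edges()} weighted arcs "
      f"(orphan retweets dropped: {graph.graph['orphan_retweets']})")

core = me.k_core(graph, k=3)
print(f"3-core: {core.number_of_nodes()} accounts remain")

partition = me.detect_communities(core, seed=0)
partition = me.community_flows(core, partition, tweets=eco.tweets, top_n=5)
print(f"communities: {partition.n_communities} "
      f"(weighted modularity {partition.modularity:.3f})")

print("\ninter-community retweet flows (row = retweeting community):")
print(partition.flow_matrix.astype(int).to_string())

print("\ntop accounts per community (by tweet count):")
for cid, accounts in sorted(partition.top_accounts.items()):
    print(f"  community {cid}: {', '.join(accounts[:3])} ...")

# High on-diagonal flow relative to off-diagonal reflects the planted
# within-community retweeting; the detected communities should align with the
# generator's community prefixes visible in the account ids.
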