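"""Rank the nodes of a directed network by PageRank and CheiRank.

PageRank (index K) highlights influential nodes with important incoming
links; CheiRank (index K*) highlights communicative nodes with important
outgoing links.  Run from the repository root:  python examples/01_rank_network.py
"""

import infinet as inf

net, panel = inf.generate_network(inf.SyntheticSpec(N=500, seed=11))
tm = inf.build_transition_matrices(net)

pr = inf.pagerank(inf.GoogleOperator(tm, alpha=0.85))
cr = inf.cheirank(net, alpha=0.85)

print(f"network: {net.N} nodes, {net.n_links} links, "
      f"{int(tm.dangling.sum())} dangling")
print(f"{'name':>8} {'P':>10} {'K':>5} {'P*':>10} {'K*':>5}")
for i in pr.top(5):
    print(f"{net.node_names[i]:>8} {pr.probabilities[i]:10.5f} "
          f"{pr.rank_index[i]:5d} {cr.probabilities[i]:10.5f} "
          f"{cr.rank_index[i]:5d}")
print("Top-K nodes concentrate the stationary random-surfer probability;"
      " in a preferential-attachment network these are the in-degree hubs.")
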