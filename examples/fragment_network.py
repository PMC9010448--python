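"""Build a fragment network and query the chemical space around a molecule.

Nodes are molecules and their sub-fragments (hydrogen-capped cores after
removing substituents, rings and linkers); edges run parent -> child. A
query walks the graph and returns library molecules within `hops` edges
whose heavy-atom and ring-atom counts stay within `hac`/`rac` of the query.
"""

from fragchal import (QueryParams, aggregate_queries, build_network,
                      make_toy_library, parse_smiles, query)

records = make_toy_library(30, seed=0)
library = [parse_smiles(s, i) for s, i in records]
net = build_network(library)
print(f"library {len(library)} molecules -> network {net.n_nodes} nodes, "
      f"{net.n_edges} edges")

q = library[0]
for hops in (0, 1, 2, 3):
    hits = query(net, q, QueryParams(hops=hops, hac=4, rac=2))
    print(f"query {q.id}, hops={hops}: {len(hits)} library molecules")
# growing hops can only add results (reachability is monotone)

merged = aggregate_queries(net, library[:5], QueryParams(2, 4, 2))
print(f"aggregated neighborhoods of 5 queries: {len(merged)} unique "
      f"molecules (deduplicated by canonical form)")
for h in merged[:5]:
    print(f"  {h.canonical_form}  suppliers={','.join(h.supplier_ids)} "
          f"hops={h.distance}")
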