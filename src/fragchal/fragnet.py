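"""Fragment-network graph for chemical-space enumeration.

Molecules are fragmented by deleting substituents, rings and linkers: every
acyclic single bond (never a ring or aromatic bond) is cleaved and each side,
hydrogen-capped and canonicalized, becomes a child node. Edges run parent ->
child and carry the attachment-annotated fragment string (the child side with
its cut position marked by ``*``), so positional information is preserved on
the edge while nodes stay real, deduplicatable structures. Heavy-atom count
strictly decreases along every edge, which makes the graph acyclic.

Neighborhood queries walk the graph undirected from a query molecule and
return library molecules within ``hops`` edge traversals whose heavy-atom and
ring-atom counts differ from the query's by at most ``hac`` and ``rac``
(absolute differences versus the query). A query molecule absent from the
network is anchored on whichever of its direct fragmentation children the
network already contains.

The network is held in a networkx DiGraph and serialized to line-oriented
JSON; libraries of 10^2-10^4 molecules need no graph database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
from rdkit import Chem

from .chem import Molecule, to_rdkit
from .errors import FormatError, ValidationError

_DUMMY = Chem.MolFromSmarts("[#0]")


@dataclass(frozen=True)
class FragNode:
    canonical_form: str
    heavy_atom_count: int
    ring_atom_count: int
    is_library_molecule: bool
    supplier_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class QueryParams:
    """hops: edge traversals; hac/rac: max |count difference| vs the query."""

    hops: int
    hac: int
    rac: int

    def __post_init__(self) -> None:
        if self.hops < 0 or self.hac < 0 or self.rac < 0:
            raise ValidationError("hops, hac and rac must all be non-negative")


@dataclass(frozen=True)
class QueryHit:
    canonical_form: str
    supplier_ids: tuple[str, ...]
    distance: int


def _canonical(rdmol: Chem.Mol) -> str:
    return Chem.MolToSmiles(rdmol)


def _ring_atom_count(rdmol: Chem.Mol) -> int:
    return sum(1 for a in rdmol.GetAtoms() if a.IsInRing() and a.GetAtomicNum() > 0)


def _cap_dummy(frag: Chem.Mol) -> Chem.Mol | None:
    """Replace the attachment wildcard by a hydrogen on its neighbor."""
    rw = Chem.RWMol(frag)
    dummies = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
    for d in dummies:
        for nb in rw.GetAtomWithIdx(d).GetNeighbors():
            # explicit count works whether or not the atom allows implicit H
            nb.SetNumExplicitHs(nb.GetTotalNumHs() + 1)
            nb.SetNoImplicit(True)
    for d in sorted(dummies, reverse=True):
        rw.RemoveAtom(d)
    capped = rw.GetMol()
    try:
        Chem.SanitizeMol(capped)
    except Exception:
        return None
    if capped.GetNumHeavyAtoms() < 1:
        return None
    return capped


def _fragment_once_rd(rdmol: Chem.Mol) -> list[tuple[str, str]]:
    """[(child canonical form, attachment-annotated label)] for one molecule."""
    children: dict[str, str] = {}
    for bond in rdmol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        cut = Chem.FragmentOnBonds(rdmol, [bond.GetIdx()], addDummies=True,
                                   dummyLabels=[(0, 0)])
        try:
            frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
        except Exception:
            continue
        if len(frags) != 2:
            continue  # cutting a (rare) acyclic bond inside a cage keeps one piece
        for frag in frags:
            capped = _cap_dummy(frag)
            if capped is None:
                continue
            if capped.GetNumHeavyAtoms() >= rdmol.GetNumHeavyAtoms():
                continue
            children.setdefault(_canonical(capped), _canonical(frag))
    return sorted(children.items())


def fragment_once(m: Molecule) -> list[str]:
    """Canonical forms of the direct children of one molecule (deduplicated)."""
    rd = to_rdkit(m)
    if rd.GetNumHeavyAtoms() < 2:
        return []
    return [child for child, _ in _fragment_once_rd(rd)]


@dataclass
class FragNetwork:
    """Molecules plus sub-fragments with parent->child edges."""

    graph: nx.DiGraph

    def node(self, canonical_form: str) -> FragNode:
        d = self.graph.nodes[canonical_form]
        return FragNode(canonical_form, d["hac"], d["rac"],
                        d["is_library"], tuple(d["supplier_ids"]))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def library_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["is_library"])

    def to_json(self, path: str | Path) -> None:
        """Line-oriented JSON: one header, then one record per node/edge."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"kind": "fragnet",
                                 "n_nodes": self.n_nodes,
                                 "n_edges": self.n_edges}) + "\n")
            for n in sorted(self.graph.nodes):
                d = self.graph.nodes[n]
                fh.write(json.dumps({"node": n, "hac": d["hac"], "rac": d["rac"],
                                     "is_library": d["is_library"],
                                     "supplier_ids": sorted(d["supplier_ids"])}) + "\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(json.dumps({"edge": [u, v], "label": d["label"]}) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FragNetwork":
        g = nx.DiGraph()
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("kind") != "fragnet":
                raise FormatError(f"{path}: not a fragment-network file")
            for line in fh:
                rec = json.loads(line)
                if "node" in rec:
                    g.add_node(rec["node"], hac=rec["hac"], rac=rec["rac"],
                               is_library=rec["is_library"],
                               supplier_ids=set(rec["supplier_ids"]))
                else:
                    u, v = rec["edge"]
                    g.add_edge(u, v, label=rec["label"])
        return cls(g)


def build_network(library: list[Molecule]) -> FragNetwork:
    """Recursive fragmentation closure over a library, deduplicated by
    canonical form; library molecules are flagged and keep their ids."""
    if not library:
        raise ValidationError("empty library")
    g = nx.DiGraph()

    def ensure_node(can: str, rd: Chem.Mol) -> None:
        if can not in g:
            g.add_node(can, hac=rd.GetNumHeavyAtoms(), rac=_ring_atom_count(rd),
                       is_library=False, supplier_ids=set())

    frontier: list[str] = []
    for mol in library:
        rd = to_rdkit(mol)
        can = _canonical(rd)
        ensure_node(can, rd)
        g.nodes[can]["is_library"] = True
        g.nodes[can]["supplier_ids"].add(mol.id)
        frontier.append(can)

    expanded: set[str] = set()
    while frontier:
        can = frontier.pop()
        if can in expanded:
            continue
        expanded.add(can)
        rd = Chem.MolFromSmiles(can)
        if rd is None or rd.GetNumHeavyAtoms() < 2:
            continue
        for child, label in _fragment_once_rd(rd):
            child_rd = Chem.MolFromSmiles(child)
            if child_rd is None:
                continue
            ensure_node(child, child_rd)
            g.add_edge(can, child, label=label)
            if child not in expanded:
                frontier.append(child)
    return FragNetwork(g)


def query(net: FragNetwork, q: Molecule, p: QueryParams,
          include_query: bool = True) -> list[QueryHit]:
    """Library molecules within ``p.hops`` of the query satisfying the
    hac/rac windows; sorted by (distance, canonical form)."""
    rd = to_rdkit(q)
    q_can = _canonical(rd)
    q_hac = rd.GetNumHeavyAtoms()
    q_rac = _ring_atom_count(rd)
    ug = net.graph.to_undirected(as_view=True)

    if q_can in net.graph:
        sources = {q_can: 0}
    else:
        # anchor an out-of-network query on its children already in the graph
        sources = {child: 1 for child, _ in _fragment_once_rd(rd)
                   if child in net.graph}
        if not sources:
            import warnings
            warnings.warn(f"query {q.id!r} shares no fragments with the network",
                          stacklevel=2)
            return []

    dist: dict[str, int] = dict(sources)
    frontier = [n for n, d0 in sources.items() if d0 < p.hops]
    while frontier:
        nxt = []
        for n in frontier:
            for nb in ug.neighbors(n):
                if nb not in dist:
                    dist[nb] = dist[n] + 1
                    if dist[nb] < p.hops:
                        nxt.append(nb)
        frontier = nxt

    hits = []
    for n, d in dist.items():
        if d > p.hops:
            continue
        attrs = net.graph.nodes[n]
        if not attrs["is_library"]:
            continue
        if not include_query and n == q_can:
            continue
        if abs(attrs["hac"] - q_hac) > p.hac or abs(attrs["rac"] - q_rac) > p.rac:
            continue
        hits.append(QueryHit(n, tuple(sorted(attrs["supplier_ids"])), d))
    return sorted(hits, key=lambda h: (h.distance, h.canonical_form))


def aggregate_queries(net: FragNetwork, queries: list[Molecule],
                      p: QueryParams) -> list[QueryHit]:
    """Union of per-query results, deduplicated by canonical form (keeping the
    smallest hop distance)."""
    if not queries:
        raise ValidationError("no query molecules")
    merged: dict[str, QueryHit] = {}
    for q in queries:
        for hit in query(net, q, p):
            prev = merged.get(hit.canonical_form)
            if prev is None or hit.distance < prev.distance:
                merged[hit.canonical_form] = hit
    return sorted(merged.values(), key=lambda h: (h.distance, h.canonical_form))
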