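"""Independent parsimony oracles for the test suite.

Everything here is deliberately brute force and shares no code with
chipsip.phylo: trees are enumerated as explicit node/edge structures and
parsimony scores are found by exhaustive minimization over all internal-node
state assignments.
"""

from __future__ import annotations

from itertools import product

import dendropy


def brute_force_score(tree: dendropy.Tree, states: dict[str, int]) -> int:
    """Minimum state changes by enumerating every internal assignment."""
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    k = max(states.values()) + 1
    edges = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((node, child))

    def node_state(node, assign):
        if node.is_leaf():
            return states[node.taxon.label]
        return assign[node]

    best = None
    for combo in product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        changes = sum(
            node_state(a, assign) != node_state(b, assign) for a, b in edges
        )
        if best is None or changes < best:
            best = changes
    return best


class _T:
    """Minimal mutable unrooted tree: root of degree 3, internal degree 3."""

    def __init__(self, labels3):
        self.children = {0: [1, 2, 3]}
        self.leaf_name = {1: labels3[0], 2: labels3[1], 3: labels3[2]}
        self.edges = [(0, 1), (0, 2), (0, 3)]
        self.next_id = 4

    def copy(self):
        t = _T.__new__(_T)
        t.children = {k: list(v) for k, v in self.children.items()}
        t.leaf_name = dict(self.leaf_name)
        t.edges = list(self.edges)
        t.next_id = self.next_id
        return t

    def attach(self, edge_idx, label):
        u, v = self.edges[edge_idx]
        w, leaf = self.next_id, self.next_id + 1
        self.next_id += 2
        self.children[u] = [w if c == v else c for c in self.children[u]]
        self.children[w] = [v, leaf]
        self.leaf_name[leaf] = label
        self.edges.pop(edge_idx)
        self.edges.extend([(u, w), (w, v), (w, leaf)])

    def newick(self):
        def rec(node):
            if node in self.leaf_name:
                return self.leaf_name[node]
            return "(" + ",".join(rec(c) for c in self.children[node]) + ")"
        return rec(0) + ";"


def enumerate_unrooted_newicks(labels: list[str]) -> list[str]:
    """Newick strings of every unrooted binary topology on the given labels.

    Built by the standard recursion: each topology on n leaves arises
    exactly once by attaching leaf n to one of the 2n-5 edges of a topology
    on the first n-1 leaves (counts 1, 3, 15, 105, ... topologies).
    """
    trees = [_T(labels[:3])]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            for i in range(len(t.edges)):
                t2 = t.copy()
                t2.attach(i, label)
                nxt.append(t2)
        trees = nxt
    return [t.newick() for t in trees]
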