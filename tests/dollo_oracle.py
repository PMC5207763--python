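"""Brute-force oracles for the gain/loss reconstruction tests.

Enumerates every internal-state assignment of a rooted tree compatible
with a leaf presence pattern under the single-gain irreversible model and
returns the minimum number of loss events.  Independent of the package's
inference code path (which works by MRCA placement and maximal absent
clades, never by state enumeration).
"""

from itertools import product

from genecycle.phylo import Tree


def oracle_min_losses(tree: Tree, presence: dict[str, bool]) -> int:
    """Minimum losses over all single-gain irreversible histories.

    A history assigns 0/1 to every node (leaves fixed by ``presence``).
    The gene is born exactly once: either above the root (root state 1)
    or on a single 0→1 edge.  Losses are 1→0 edges.
    """
    internals = [n for n in tree.nodes() if not n.is_leaf]
    branches = [(n.id, n.parent.id) for n in tree.branches()]
    state = {leaf.id: (1 if presence[leaf.id] else 0) for leaf in tree.leaves()}
    best = None
    for bits in product((0, 1), repeat=len(internals)):
        for node, bit in zip(internals, bits):
            state[node.id] = bit
        gains = state[tree.root.id]
        losses = 0
        for child, parent in branches:
            if state[parent] == 0 and state[child] == 1:
                gains += 1
            elif state[parent] == 1 and state[child] == 0:
                losses += 1
        if gains != 1:
            continue
        if best is None or losses < best:
            best = losses
    return best


def all_rooted_topologies(leaves: list[str]) -> list:
    """All rooted binary topologies on the labelled leaves ((2n-3)!! of them)."""
    if len(leaves) == 1:
        return [leaves[0]]
    out = []
    for t in all_rooted_topologies(leaves[:-1]):
        out.extend(_insert_everywhere(t, leaves[-1]))
    return out


def _insert_everywhere(t, x):
    res = [(t, x)]
    if isinstance(t, tuple):
        a, b = t
        res += [(sub, b) for sub in _insert_everywhere(a, x)]
        res += [(a, sub) for sub in _insert_everywhere(b, x)]
    return res


def topology_to_newick(t) -> str:
    def fmt(node) -> str:
        if isinstance(node, tuple):
            return "(" + ",".join(f"{fmt(c)}:1" for c in node) + ")"
        return str(node)

    return fmt(t) + ";"
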