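"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the deep-coalescence
oracle minimises over explicitly enumerated gene-to-species embeddings; the
DEC oracle sums over all internal-node states and cladogenetic scenarios
with nested products; the binary-character oracle enumerates all internal
state assignments.  They are only feasible on tiny instances, which is the
point.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# deep coalescence: minimisation over ancestor-consistent embeddings


def brute_force_dc(gene_tree, pop_tree, assignment) -> int:
    """Minimal extra-lineage count over all ancestor-consistent embeddings.

    Every gene internal node is assigned to some species node whose region
    set contains all populations below the gene node, with a parent mapped
    at or above its child's image; for each embedding the number of gene
    lineages crossing into each species branch is counted directly, and the
    minimum total of (lineages - 1) per branch is returned.
    """
    sp_nodes = list(pop_tree.tree.preorder_node_iter())
    sp_index = {id(n): i for i, n in enumerate(sp_nodes)}
    clade = [frozenset(l.taxon.label for l in n.leaf_iter()) for n in sp_nodes]
    # ancestor[i][j] True iff sp_nodes[i] is an ancestor-or-self of sp_nodes[j]
    ancestor = [[False] * len(sp_nodes) for _ in sp_nodes]
    for j, n in enumerate(sp_nodes):
        m = n
        while m is not None:
            ancestor[sp_index[id(m)]][j] = True
            m = m.parent_node
    by_label = {n.taxon.label: i for i, n in enumerate(sp_nodes) if n.is_leaf()}

    gene_nodes = list(gene_tree.postorder_node_iter())
    g_index = {id(n): i for i, n in enumerate(gene_nodes)}
    pops_below: list[frozenset] = [frozenset()] * len(gene_nodes)
    fixed: dict[int, int] = {}
    internal: list[int] = []
    for i, n in enumerate(gene_nodes):
        if n.is_leaf():
            pop = assignment.mapping[n.taxon.label]
            pops_below[i] = frozenset([pop])
            fixed[i] = by_label[pop]
        else:
            pops_below[i] = frozenset().union(
                *(pops_below[g_index[id(c)]] for c in n.child_nodes())
            )
            internal.append(i)

    candidates = {
        i: [s for s in range(len(sp_nodes)) if pops_below[i] <= clade[s]]
        for i in internal
    }

    non_root_sp = [i for i, n in enumerate(sp_nodes) if n.parent_node is not None]
    best = math.inf
    for combo in itertools.product(*(candidates[i] for i in internal)):
        s_of = dict(fixed)
        s_of.update(dict(zip(internal, combo)))
        ok = True
        for i, n in enumerate(gene_nodes):
            if n.parent_node is not None:
                pi = g_index[id(n.parent_node)]
                if not ancestor[s_of[pi]][s_of[i]]:
                    ok = False
                    break
        if not ok:
            continue
        cost = 0
        root_i = g_index[id(gene_tree.seed_node)]
        for x in non_root_sp:
            count = 0
            for i, n in enumerate(gene_nodes):
                if n.parent_node is None:
                    continue
                pi = g_index[id(n.parent_node)]
                if ancestor[x][s_of[i]] and not ancestor[x][s_of[pi]]:
                    count += 1
            if ancestor[x][s_of[root_i]]:
                count += 1
            cost += max(count - 1, 0)
        best = min(best, cost)
    return int(best)


def all_binary_topologies(labels):
    """Yield Newick strings for every rooted binary topology over labels."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for sub in all_binary_topologies(rest):
        # insert `first` on every edge of the subtree encoded in `sub`
        yield from _insert_everywhere(sub, first)


def _insert_everywhere(newick, label):
    # parse positions: attach at root
    yield f"({newick},{label})"
    # attach within: find each top-level component recursively
    if newick.startswith("("):
        inner = newick[1:-1]
        parts = _split_top(inner)
        for i, part in enumerate(parts):
            for sub in _insert_everywhere(part, label):
                yield "(" + ",".join(parts[:i] + [sub] + parts[i + 1:]) + ")"


def _split_top(s):
    parts, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


# ---------------------------------------------------------------------------
# DEC: full enumeration over internal states and scenarios


def _oracle_q(areas, states, D, d, e, max_size):
    n = len(states)
    idx = {s: i for i, s in enumerate(states)}
    Q = np.zeros((n, n))
    for i, R in enumerate(states):
        if R == 0:
            continue
        occ = [a for a in range(len(areas)) if R >> a & 1]
        for a in range(len(areas)):
            if R >> a & 1:
                Q[i, idx[R & ~(1 << a)]] += e
            elif bin(R | 1 << a).count("1") <= max_size:
                Q[i, idx[R | 1 << a]] += d * sum(D[b][a] for b in occ)
    for i in range(n):
        Q[i, i] = -Q[i].sum()
    return Q


def _oracle_branch_matrix(model, params, older, younger):
    states = model.states
    P = np.eye(len(states))
    t = older
    while t > younger + 1e-12:
        k = model.stratum_at(t)
        bottom = max(model.strata[k].younger, younger)
        Q = _oracle_q(
            model.areas, states, model.strata[k].dispersal.tolist(),
            params.d, params.e, model.max_range_size,
        )
        P = P @ expm(Q * (t - bottom))
        t = bottom
    return P


def _oracle_scenarios(R):
    occ = [a for a in range(R.bit_length()) if R >> a & 1]
    if len(occ) == 1:
        return [(R, R, 1.0)]
    outs = set()
    for a in occ:
        s = 1 << a
        outs |= {(s, R & ~s), (R & ~s, s), (s, R), (R, s)}
    return [(l, r, 1.0 / len(outs)) for l, r in sorted(outs)]


def enumeration_dec_likelihood(tree, ranges, model, params, root_state=None,
                               condition_on_survival=False):
    """Total data likelihood by explicit summation over every combination of
    root state, cladogenetic scenario and branch end state."""
    from refugia import trees as _t

    depths = _t.tip_depths(tree)
    total = max(depths.values())
    ages = {}
    for node in tree.preorder_node_iter():
        d_ = 0.0
        n = node
        while n.parent_node is not None:
            d_ += n.edge.length or 0.0
            n = n.parent_node
        ages[id(node)] = max(total - d_, 0.0)

    states = model.states
    idx = {s: i for i, s in enumerate(states)}

    def branch_prob(parent_node, child_node, s_top, s_bottom):
        P = _oracle_branch_matrix(model, params, ages[id(parent_node)],
                                  ages[id(child_node)])
        p = P[idx[s_top], idx[s_bottom]]
        if condition_on_survival:
            surv = 1.0 - P[idx[s_top], idx[0]]
            p = p / surv if surv > 0 else 0.0
        return p

    def subtree_lik(node, state_at_node):
        """P(tip data below | range at node, node about to cladogenese)."""
        if node.is_leaf():
            return 1.0 if ranges[node.taxon.label] == state_at_node else 0.0
        acc = 0.0
        kids = node.child_nodes()
        for left, right, w in _oracle_scenarios(state_at_node):
            for s1 in states:
                if s1 == 0:
                    continue  # a null end-state leaves no surviving tips
                p1 = branch_prob(node, kids[0], left, s1)
                if p1 == 0.0:
                    continue
                l1 = subtree_lik(kids[0], s1)
                if l1 == 0.0:
                    continue
                for s2 in states:
                    if s2 == 0:
                        continue
                    p2 = branch_prob(node, kids[1], right, s2)
                    if p2 == 0.0:
                        continue
                    l2 = subtree_lik(kids[1], s2)
                    acc += w * p1 * l1 * p2 * l2
        return acc

    roots = [root_state] if root_state is not None else [s for s in states if s]
    return sum(subtree_lik(tree.seed_node, r) for r in roots)


# ---------------------------------------------------------------------------
# binary-character marginal: enumeration over internal assignments


def enumeration_node_marginal(tree, char, node, rate, bias=0.5):
    """Marginal posterior at ``node`` by summing over every assignment of
    states to internal nodes (transfer-matrix style)."""
    pi = np.array([1.0 - bias, bias])

    def P(t):
        ex = math.exp(-rate * t)
        return np.array(
            [
                [pi[0] + pi[1] * ex, pi[1] * (1 - ex)],
                [pi[0] * (1 - ex), pi[1] + pi[0] * ex],
            ]
        )

    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    tips = [n for n in nodes if n.is_leaf()]
    target_mass = np.zeros(2)
    for combo in itertools.product((0, 1), repeat=len(internal)):
        st = {id(n): s for n, s in zip(internal, combo)}
        prob = pi[st[id(tree.seed_node)]]
        for n in nodes:
            if n.parent_node is None:
                continue
            if n.is_leaf():
                obs = char.data.get(n.taxon.label)
                if obs is None:
                    continue
                s_child = char.states.index(obs)
            else:
                s_child = st[id(n)]
            prob *= P(n.edge.length or 0.0)[st[id(n.parent_node)], s_child]
            if prob == 0.0:
                break
        if node.is_leaf():
            obs = char.data.get(node.taxon.label)
            s_target = char.states.index(obs) if obs is not None else None
            if s_target is None:
                raise ValueError("target tip unobserved")
            target_mass[s_target] += prob
        else:
            target_mass[st[id(node)]] += prob
    return target_mass / target_mass.sum()
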