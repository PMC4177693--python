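"""Distance trees with bootstrap, paralog-clade detection, and parsimony
inference of gain/loss/duplication scenarios on a species tree.

Tree building is neighbor joining over TN93 (or JC69/p) distances with
bipartition bootstrap supports - a deliberately transparent method whose
small cases admit exact oracles. Event inference is a Dollo-style weighted
parsimony: each miRNA family originates exactly once; copy-number increases
along a branch are duplications and decreases are losses, with losses
costed above duplications (functional miRNAs are rarely lost), solved
exactly by dynamic programming over bounded copy-number states.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import distance_matrix
from .trees import Node, parse_newick


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: pd.DataFrame) -> Node:
    """Neighbor-joining tree from a symmetric distance matrix.

    Ties in the Q-criterion are broken by lexicographic taxon pair, so the
    result is deterministic. Negative branch-length estimates are clamped to
    zero with a warning. The returned root is the final trifurcation
    (unrooted convention).
    """
    if list(d.index) != list(d.columns):
        raise ValueError("matrix index/columns differ")
    if not np.allclose(d.values, d.values.T, atol=1e-9):
        raise ValueError("matrix not symmetric")
    if len(d) < 3:
        raise ValueError("need >= 3 taxa")
    order = sorted(d.index)
    D = d.loc[order, order].to_numpy(dtype=float).copy()
    nodes: list[Node] = [Node(name=t) for t in order]
    clamped = False
    join_count = 0
    while len(nodes) > 3:
        r = len(nodes)
        tot = D.sum(axis=1)
        Q = (r - 2) * D - tot[:, None] - tot[None, :]
        np.fill_diagonal(Q, np.inf)
        # first row-major minimum = lexicographically earliest pair in the
        # current (initially sorted) ordering: deterministic tie-break
        i, j = divmod(int(np.argmin(Q)), r)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        la = 0.5 * dij + (tot[i] - tot[j]) / (2 * (r - 2))
        lb = dij - la
        if la < 0 or lb < 0:
            clamped = True
        join_count += 1
        un = Node(name=f"__nj{join_count}")
        na, nb = nodes[i], nodes[j]
        na.length, nb.length = max(la, 0.0), max(lb, 0.0)
        un.add(na)
        un.add(nb)
        du = np.maximum(0.5 * (D[i] + D[j] - dij), 0.0)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [un]
    (na, nb, nc) = nodes
    root = Node(name="__njroot")
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    for n, L in (
        (na, 0.5 * (dab + dac - dbc)),
        (nb, 0.5 * (dab + dbc - dac)),
        (nc, 0.5 * (dac + dbc - dab)),
    ):
        if L < 0:
            clamped = True
        n.length = max(L, 0.0)
        root.add(n)
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return root


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each as the leaf set of an internal edge
    (canonicalized to the smaller side, ties by sorted representation)."""
    all_leaves = tree.leafset()
    out: set[frozenset[str]] = set()
    for n in tree.preorder():
        if n is tree or n.is_leaf:
            continue
        side = n.leafset()
        other = frozenset(all_leaves - side)
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


_CODE_MAP = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _msa_codes(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = list(msa)
    mat = np.full((len(taxa), len(next(iter(msa.values())))), -1, dtype=np.int8)
    for i, t in enumerate(taxa):
        for j, ch in enumerate(msa[t].upper()):
            mat[i, j] = _CODE_MAP.get(ch, -1)
    return taxa, mat


def _tn93_codes(a: np.ndarray, b: np.ndarray, cap: float = 5.0) -> float:
    """TN93 distance from coded rows (gap/ambiguous = -1, dropped);
    saturation or degenerate composition capped at ``cap``."""
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        return cap
    diff = a != b
    sums = a + b  # A+G=2 (transition), C+T=4 (transition)
    prod = a * b
    p1 = int(np.sum(diff & (sums == 2) & (prod == 0)))  # A<->G
    p2 = int(np.sum(diff & (sums == 4) & (prod == 3)))  # C<->T
    q = int(np.sum(diff)) - p1 - p2
    counts = np.bincount(np.concatenate([a, b]), minlength=4).astype(float)
    tot = counts.sum()
    fA, fC, fG, fT = counts / tot
    gR, gY = fA + fG, fC + fT
    P1, P2, Q = p1 / n, p2 / n, q / n
    if min(fA, fC, fG, fT) <= 0:
        arg = 1.0 - 4.0 * (p1 + p2 + q) / n / 3.0
        return cap if arg <= 0 else min(-0.75 * math.log(arg), cap)
    k1 = 2 * fA * fG / gR
    k2 = 2 * fC * fT / gY
    k3 = 2 * (gR * gY - fA * fG * gY / gR - fC * fT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2 * gY)
    w3 = 1.0 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return cap
    return min(-k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3), cap)


def _codes_distance_df(taxa: list[str], mat: np.ndarray) -> pd.DataFrame:
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, j in itertools.combinations(range(len(taxa)), 2):
        v = _tn93_codes(mat[i], mat[j])
        d.iloc[i, j] = d.iloc[j, i] = v
    return d


def bootstrap_supports(
    msa: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "TN93",
    resample: bool = True,
) -> Node:
    """NJ tree with bootstrap supports from column resampling.

    ``msa`` maps taxon to aligned row. Supports are the percentage of
    replicate trees containing each internal bipartition of the point
    estimate. ``resample=False`` skips resampling (every replicate is the
    original alignment - a determinism hook). Saturated replicate distances
    are capped instead of raised so every replicate yields a tree. Replicate
    distances use a vectorized TN93 (``model`` other than TN93 falls back to
    the general per-pair path).
    """
    taxa = list(msa)
    L = len(next(iter(msa.values())))
    if L < 2:
        raise ValueError("alignment shorter than 2 columns")
    if len({len(v) for v in msa.values()}) != 1:
        raise ValueError("rows of unequal length")
    fast = model.upper() == "TN93"
    _, mat = _msa_codes(msa)
    if fast:
        point = nj_tree(_codes_distance_df(taxa, mat))
    else:
        point = nj_tree(distance_matrix(msa, model=model, aligned=True,
                                        saturation_cap=5.0))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(point)}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        if resample:
            pick = rng.integers(0, L, size=L)
        else:
            pick = np.arange(L)
        sub = mat[:, pick]
        try:
            if fast:
                rtree = nj_tree(_codes_distance_df(taxa, sub))
            else:
                rep = {t: "".join("ACGT-"[c] if c >= 0 else "-" for c in sub[i])
                       for i, t in enumerate(taxa)}
                rtree = nj_tree(distance_matrix(rep, model=model, aligned=True,
                                                saturation_cap=5.0))
        except Exception:
            continue
        rbps = bipartitions(rtree)
        for bp in counts:
            if bp in rbps:
                counts[bp] += 1
    all_leaves = point.leafset()
    for n in point.preorder():
        if n is point or n.is_leaf:
            continue
        side = n.leafset()
        canon = min(side, frozenset(all_leaves - side),
                    key=lambda s: (len(s), tuple(sorted(s))))
        if canon in counts:
            n.support = 100.0 * counts[canon] / n_reps
    return point


def root_with_outgroup(tree: Node, outgroup: str) -> Node:
    """Re-root on the edge above ``outgroup`` (does not modify the input).

    Bootstrap supports travel with their edges: after re-rooting, a node's
    support is the support of the edge between it and its new parent.
    """
    og = tree.find(outgroup)
    if og.parent is None:
        raise ValueError("outgroup is already the root")
    adj: dict[int, list[tuple[Node, float]]] = {}
    edge_support: dict[frozenset[int], float | None] = {}
    for n in tree.preorder():
        for c in n.children:
            adj.setdefault(id(n), []).append((c, c.length))
            adj.setdefault(id(c), []).append((n, c.length))
            edge_support[frozenset((id(n), id(c)))] = c.support

    def build(node: Node, come_from: Node, length: float) -> Node:
        nn = Node(name=node.name, length=length,
                  support=edge_support.get(frozenset((id(node), id(come_from)))))
        for nb, L in adj.get(id(node), ()):
            if nb is come_from:
                continue
            nn.add(build(nb, node, L))
        return nn

    half = og.length / 2.0
    new_root = Node(name="__root")
    new_root.add(build(og, og.parent, half))
    new_root.add(build(og.parent, og, half))
    # drop single-child chains left by the old root position
    def simplify(n: Node) -> None:
        for c in list(n.children):
            simplify(c)
        if len(n.children) == 1 and n.parent is not None:
            only = n.children[0]
            only.length += n.length
            if only.support is None:
                only.support = n.support
            idx = n.parent.children.index(n)
            n.parent.children[idx] = only
            only.parent = n.parent

    simplify(new_root)
    return new_root


def is_monophyletic(tree: Node, leaves: set[str]) -> tuple[bool, float | None]:
    """Does ``leaves`` form a clade in the rooted tree? Returns
    (verdict, support of the subtending node)."""
    target = frozenset(leaves)
    for n in tree.preorder():
        if n.leafset() == target:
            return True, n.support
    return False, None


def detect_paralog_clade(
    tree: Node,
    paralog_leaves: set[str],
    outgroup: str | None = None,
    support_threshold: float = 50.0,
) -> dict:
    """Verdict on whether the paralog copies form a supported clade.

    The tree is rooted on ``outgroup`` (if given) before the monophyly check;
    the verdict requires the subtending node's bootstrap support to exceed
    ``support_threshold`` (unsupported nodes count as failing).
    """
    leaves = set(tree.leaf_names())
    if not paralog_leaves:
        raise ValueError("empty paralog set")
    if not paralog_leaves < leaves:
        raise ValueError("paralog set must be a proper subset of the leaves")
    work = root_with_outgroup(tree, outgroup) if outgroup else tree
    mono, support = is_monophyletic(work, set(paralog_leaves))
    ok = bool(mono and support is not None and support > support_threshold)
    return {"monophyletic": mono, "support": support, "verdict": ok}


# ---------------------------------------------------------------------------
# Gain / loss / duplication inference (Dollo-style weighted parsimony)
# ---------------------------------------------------------------------------

@dataclass
class Event:
    branch: str  # child-node name of the branch (root name for root events)
    kind: str    # gain | duplication | loss
    family: str
    delta: int   # copy-count change (+1 gain/duplication, -1 loss)


class CopyNumberCapError(ValueError):
    pass


def _transition_cost(s: int, t: int, w_dup: float, w_loss: float) -> float:
    """Cost of parent state ``s`` -> child state ``t`` on one branch; state 0
    is absorbing (Dollo: no regain after loss)."""
    if s == 0:
        return 0.0 if t == 0 else math.inf
    if t >= s:
        return w_dup * (t - s)
    return w_loss * (s - t)


def infer_family_events(
    tree: Node,
    counts: dict[str, int],
    family: str,
    w_dup: float = 1.0,
    w_loss: float = 2.0,
    cap: int = 4,
) -> tuple[list[Event], float]:
    """Minimum-cost single-origin scenario for one family.

    The family is gained exactly once, on the branch of some node ``o`` whose
    subtree contains every extant copy; below the origin, copy-number
    transitions cost ``w_dup`` per extra copy and ``w_loss`` per lost copy
    (default loss twice duplication). Solved exactly: Sankoff dynamic
    programming over states 0..cap within each candidate origin subtree,
    minimized over origins. Ties prefer the more ancestral origin.
    """
    leaves = tree.leaf_names()
    observed = {sp: counts.get(sp, 0) for sp in leaves}
    if max(observed.values(), default=0) == 0:
        return [], 0.0
    over = [sp for sp, n in observed.items() if n > cap]
    if over:
        raise CopyNumberCapError(f"{family}: copy number above cap in {over}")
    states = range(cap + 1)
    # Sankoff up-pass: cost[node][s] = min cost of subtree given state s > 0
    cost: dict[int, list[float]] = {}
    choice: dict[int, dict[tuple[int, int], int]] = {}
    post = list(tree.postorder())
    for n in post:
        nid = id(n)
        if n.is_leaf:
            cost[nid] = [0.0 if s == observed[n.name] else math.inf
                         for s in states]
        else:
            cost[nid] = []
            choice[nid] = {}
            for s in states:
                total = 0.0
                for ci, c in enumerate(n.children):
                    best, arg = math.inf, 0
                    for t in states:
                        v = _transition_cost(s, t, w_dup, w_loss) + cost[id(c)][t]
                        if v < best - 1e-12:
                            best, arg = v, t
                    total += best
                    choice[nid][(s, ci)] = arg
                cost[nid].append(total)
    # candidate origins: nodes whose subtree covers all species with copies
    present = {sp for sp, n in observed.items() if n > 0}
    best_total, best_origin, best_state = math.inf, None, 0
    for n in tree.preorder():
        if not present <= n.leafset():
            continue
        size = len(n.leafset())
        for s in range(1, cap + 1):
            v = (s - 1) * w_dup + cost[id(n)][s]
            if (v < best_total - 1e-12 or (
                abs(v - best_total) <= 1e-12 and best_origin is not None
                and size > len(best_origin.leafset())
            )):
                best_total, best_origin, best_state = v, n, s
    if best_origin is None or math.isinf(best_total):
        raise CopyNumberCapError(f"{family}: no feasible scenario under cap {cap}")
    events: list[Event] = [Event(best_origin.name, "gain", family, +1)]
    events += [Event(best_origin.name, "duplication", family, +1)] * (best_state - 1)

    def down(n: Node, s: int) -> None:
        nid = id(n)
        for ci, c in enumerate(n.children):
            t = choice[nid][(s, ci)] if not n.is_leaf else s
            if t > s:
                events.extend([Event(c.name, "duplication", family, +1)] * (t - s))
            elif t < s:
                events.extend([Event(c.name, "loss", family, -1)] * (s - t))
            down(c, t)

    down(best_origin, best_state)
    return events, best_total


def infer_events(
    species_tree: Node | str,
    copy_matrix: pd.DataFrame,
    w_dup: float = 1.0,
    w_loss: float = 2.0,
    cap: int = 4,
) -> list[Event]:
    """Minimum-cost scenarios for every family (rows) over species (columns)."""
    tree = parse_newick(species_tree, require_lengths=False) \
        if isinstance(species_tree, str) else species_tree
    missing = set(copy_matrix.columns) - set(tree.leaf_names())
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    out: list[Event] = []
    for fam in copy_matrix.index:
        counts = {sp: int(copy_matrix.loc[fam, sp]) for sp in copy_matrix.columns}
        ev, _ = infer_family_events(tree, counts, fam, w_dup, w_loss, cap)
        out.extend(ev)
    return out


def replay_events(tree: Node, events: list[Event]) -> pd.DataFrame:
    """Replay scenarios from root state 0; returns families x species counts."""
    fams = sorted({e.family for e in events})
    by_branch: dict[tuple[str, str], int] = {}
    for e in events:
        by_branch[(e.branch, e.family)] = by_branch.get((e.branch, e.family), 0) + e.delta
    leaves = tree.leaf_names()
    out = pd.DataFrame(0, index=fams, columns=leaves)

    def walk(n: Node, state: dict[str, int]) -> None:
        state = dict(state)
        for f in fams:
            state[f] = state.get(f, 0) + by_branch.get((n.name, f), 0)
        if n.is_leaf:
            for f in fams:
                out.loc[f, n.name] = state[f]
        for c in n.children:
            walk(c, state)

    walk(tree, {})
    return out


def exhaustive_event_search(
    tree: Node,
    counts: dict[str, int],
    w_dup: float = 1.0,
    w_loss: float = 2.0,
    cap: int = 3,
) -> float:
    """Oracle: enumerate every internal-state assignment and origin placement;
    returns the minimum scenario cost. Exponential in internal nodes - use on
    small trees."""
    internal = [n for n in tree.preorder() if not n.is_leaf]
    leaves = tree.leaves()
    best = math.inf
    present = {sp for sp, n in counts.items() if n > 0}
    if not present:
        return 0.0
    for assign in itertools.product(range(cap + 1), repeat=len(internal)):
        states = {id(n): s for n, s in zip(internal, assign)}
        for lf in leaves:
            states[id(lf)] = counts.get(lf.name, 0)
        # exactly one origin: a node with state>0 whose parent has state 0
        # (or the root itself)
        origins = []
        total = 0.0
        for n in tree.preorder():
            s = states[id(n)]
            if n.parent is None:
                if s > 0:
                    origins.append(n)
                    total += (s - 1) * w_dup
                continue
            ps = states[id(n.parent)]
            if ps == 0 and s > 0:
                origins.append(n)
                total += (s - 1) * w_dup
            elif ps > 0:
                total += (w_dup * (s - ps) if s >= ps else w_loss * (ps - s))
        if len(origins) != 1:
            continue
        best = min(best, total)
    return best
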