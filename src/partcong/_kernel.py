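"""Numba kernels for Fitch scoring and TBR branch swapping.

Trees live in flat ``int32 (N, 3)`` adjacency arrays: ``N = 2L - 2`` nodes,
leaves ``0..L-1`` (slot 0 holds their single neighbour, slots 1-2 are -1),
internal nodes ``L..2L-3`` with three neighbours.  Character data are
``uint32 (L, C)`` state bitmasks; missing/inapplicable cells carry the full
alphabet mask so they never force steps.

The TBR scan relies on an exact identity: joining subtrees S1 and S2 by an
edge between points subdividing edges e1 and e2 yields a tree of length
``L(S1) + L(S2) + #{characters whose e1 and e2 root state sets are
disjoint}``, where the root state set of an edge is the Fitch down-pass set
obtained when the subtree is rooted on that edge.  All root sets of a
component are obtained in one down/up pass, so every reconnection is scored
in O(C) without re-traversing the tree.
"""

import numpy as np
from numba import njit

I32 = np.int32
U32 = np.uint32


@njit(cache=True)
def _postorder(nbr, root, parent0, order, parent):
    parent[:] = -2
    sp = 0
    order[sp] = root
    parent[root] = parent0
    cnt = 1
    head = 0
    while head < cnt:
        v = order[head]
        head += 1
        for k in range(3):
            w = nbr[v, k]
            if w >= 0 and w != parent[v]:
                parent[w] = v
                order[cnt] = w
                cnt += 1
    return cnt


@njit(cache=True)
def _find_leaf(nbr, start, avoid):
    """Walk from `start` (avoiding node `avoid`) to any leaf of its component."""
    prev = avoid
    v = start
    while nbr[v, 1] >= 0:  # internal
        nxt = -1
        for k in range(3):
            w = nbr[v, k]
            if w >= 0 and w != prev:
                nxt = w
                break
        if nxt == -1:       # degree-1 internal cannot occur; safety
            return v
        prev = v
        v = nxt
    return v


@njit(cache=True)
def component_rootsets(nbr, anchor, sets, down, up, edges, roots, order, parent):
    """Root sets of every edge of the component containing leaf `anchor`.

    Returns (n_edges, component_length).  ``edges[i] = (parent, child)`` and
    ``roots[i]`` is the Fitch down-pass state set of the component rooted on
    that edge.  The component length is the unrooted parsimony length.
    """
    C = sets.shape[1]
    cnt = _postorder(nbr, anchor, -1, order, parent)
    if cnt == 1:
        return 0, 0
    total = 0
    # down pass (children toward anchor-rooted leaves)
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        if nbr[v, 1] < 0:  # leaf
            for c in range(C):
                down[v, c] = sets[v, c]
        else:
            c1 = -1
            c2 = -1
            for k in range(3):
                w = nbr[v, k]
                if w >= 0 and w != parent[v]:
                    if c1 < 0:
                        c1 = w
                    else:
                        c2 = w
            if c2 < 0:
                for c in range(C):
                    down[v, c] = down[c1, c]
            else:
                for c in range(C):
                    a = down[c1, c] & down[c2, c]
                    if a == U32(0):
                        a = down[c1, c] | down[c2, c]
                        total += 1
                    down[v, c] = a
    # close the root edge at the leaf anchor
    child0 = nbr[anchor, 0]
    for c in range(C):
        if sets[anchor, c] & down[child0, c] == U32(0):
            total += 1
    # up pass: up[v] = down-pass set of (component minus subtree v), rooted
    # at v's parent side
    for c in range(C):
        up[child0, c] = sets[anchor, c]
    for i in range(cnt):
        v = order[i]
        if v == anchor or nbr[v, 1] < 0:
            continue
        c1 = -1
        c2 = -1
        for k in range(3):
            w = nbr[v, k]
            if w >= 0 and w != parent[v]:
                if c1 < 0:
                    c1 = w
                else:
                    c2 = w
        if c2 < 0:
            for c in range(C):
                up[c1, c] = up[v, c]
        else:
            for c in range(C):
                a = up[v, c] & down[c2, c]
                if a == U32(0):
                    a = up[v, c] | down[c2, c]
                up[c1, c] = a
                b = up[v, c] & down[c1, c]
                if b == U32(0):
                    b = up[v, c] | down[c1, c]
                up[c2, c] = b
    # collect edges and their root sets
    ne = 0
    for i in range(cnt):
        v = order[i]
        if v == anchor:
            continue
        p = parent[v]
        edges[ne, 0] = p
        edges[ne, 1] = v
        for c in range(C):
            a = down[v, c] & up[v, c]
            if a == U32(0):
                a = down[v, c] | up[v, c]
            roots[ne, c] = a
        ne += 1
    return ne, total


@njit(cache=True)
def tree_length(nbr, sets, down, order, parent):
    """Unrooted Fitch length via a single down pass rooted at leaf 0's edge."""
    C = sets.shape[1]
    anchor = 0
    while nbr[anchor, 0] < 0:
        anchor += 1
    cnt = _postorder(nbr, anchor, -1, order, parent)
    if cnt <= 1:
        return 0
    total = 0
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        if nbr[v, 1] < 0:
            for c in range(C):
                down[v, c] = sets[v, c]
        else:
            c1 = -1
            c2 = -1
            for k in range(3):
                w = nbr[v, k]
                if w >= 0 and w != parent[v]:
                    if c1 < 0:
                        c1 = w
                    else:
                        c2 = w
            if c2 < 0:
                for c in range(C):
                    down[v, c] = down[c1, c]
            else:
                for c in range(C):
                    a = down[c1, c] & down[c2, c]
                    if a == U32(0):
                        a = down[c1, c] | down[c2, c]
                        total += 1
                    down[v, c] = a
    child0 = nbr[anchor, 0]
    for c in range(C):
        if sets[anchor, c] & down[child0, c] == U32(0):
            total += 1
    return total


@njit(cache=True)
def steps_per_char(nbr, sets, down, order, parent, out):
    """Per-character Fitch step counts (same traversal as tree_length)."""
    C = sets.shape[1]
    out[:] = 0
    anchor = 0
    while nbr[anchor, 0] < 0:
        anchor += 1
    cnt = _postorder(nbr, anchor, -1, order, parent)
    if cnt <= 1:
        return
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        if nbr[v, 1] < 0:
            for c in range(C):
                down[v, c] = sets[v, c]
        else:
            c1 = -1
            c2 = -1
            for k in range(3):
                w = nbr[v, k]
                if w >= 0 and w != parent[v]:
                    if c1 < 0:
                        c1 = w
                    else:
                        c2 = w
            if c2 < 0:
                for c in range(C):
                    down[v, c] = down[c1, c]
            else:
                for c in range(C):
                    a = down[c1, c] & down[c2, c]
                    if a == U32(0):
                        a = down[c1, c] | down[c2, c]
                        out[c] += 1
                    down[v, c] = a
    child0 = nbr[anchor, 0]
    for c in range(C):
        if sets[anchor, c] & down[child0, c] == U32(0):
            out[c] += 1


@njit(cache=True)
def _replace(nbr, node, old, new):
    for k in range(3):
        if nbr[node, k] == old:
            nbr[node, k] = new
            return


@njit(cache=True)
def _detach(nbr, u, v):
    """Remove edge (u, v), suppressing u if it becomes degree 2.

    Returns the two former co-neighbours of u (-1, -1 if u is a leaf).
    """
    if nbr[u, 1] < 0:  # leaf
        nbr[u, 0] = -1
        return -1, -1
    p = -1
    q = -1
    for k in range(3):
        w = nbr[u, k]
        if w != v:
            if p < 0:
                p = w
            else:
                q = w
    _replace(nbr, p, u, q)
    _replace(nbr, q, u, p)
    nbr[u, 0] = -1
    nbr[u, 1] = -1
    nbr[u, 2] = -1
    return p, q


@njit(cache=True)
def _attach(nbr, mid, other, ea, eb):
    """Re-insert `mid` subdividing edge (ea, eb); `other` becomes its third
    neighbour.  If mid is a leaf (ea < 0), just link it to `other`."""
    if ea < 0:
        nbr[mid, 0] = other
        return
    _replace(nbr, ea, eb, mid)
    _replace(nbr, eb, ea, mid)
    nbr[mid, 0] = ea
    nbr[mid, 1] = eb
    nbr[mid, 2] = other


@njit(cache=True)
def apply_tbr(nbr_in, u, v, e1a, e1b, e2a, e2b):
    """Apply a TBR move: cut edge (u, v), reattach via edges e1 (u side) and
    e2 (v side).  e1a < 0 means u is a pruned leaf (likewise e2a for v)."""
    nbr = nbr_in.copy()
    _detach(nbr, u, v)
    _detach(nbr, v, u)
    _attach(nbr, u, v, e1a, e1b)
    _attach(nbr, v, u, e2a, e2b)
    return nbr


@njit(cache=True)
def tbr_scan(nbr, sets, cap):
    """Scan the full TBR neighbourhood.

    Returns (best_length, moves, n_moves) where moves lists up to `cap`
    moves (u, v, e1a, e1b, e2a, e2b) attaining best_length.
    """
    N = nbr.shape[0]
    C = sets.shape[1]
    down = np.empty((N, C), U32)
    up = np.empty((N, C), U32)
    edges1 = np.empty((N, 2), I32)
    roots1 = np.empty((N, C), U32)
    edges2 = np.empty((N, 2), I32)
    roots2 = np.empty((N, C), U32)
    order = np.empty(N, I32)
    parent = np.empty(N, I32)
    moves = np.empty((cap, 6), I32)
    best = np.iinfo(I32).max
    nmoves = 0
    work = nbr.copy()
    for u in range(N):
        for k in range(3):
            v = nbr[u, k]
            if v <= u:
                continue
            # --- bisect edge (u, v) on a working copy
            work[:, :] = nbr
            p, q = _detach(work, u, v)
            a, b = _detach(work, v, u)
            # component 1 (u side)
            if p < 0:
                ne1 = 0
                anchor1 = u
            else:
                anchor1 = _find_leaf(work, p, -1)
                ne1, L1 = component_rootsets(
                    work, anchor1, sets, down, up, edges1, roots1, order, parent
                )
            if p < 0:
                L1 = 0
                for c in range(C):
                    roots1[0, c] = sets[u, c]
            # component 2 (v side)
            if a < 0:
                ne2 = 0
                anchor2 = v
            else:
                anchor2 = _find_leaf(work, a, -1)
                ne2, L2 = component_rootsets(
                    work, anchor2, sets, down, up, edges2, roots2, order, parent
                )
            if a < 0:
                L2 = 0
                for c in range(C):
                    roots2[0, c] = sets[v, c]
            base = L1 + L2
            n1 = ne1 if ne1 > 0 else 1
            n2 = ne2 if ne2 > 0 else 1
            for i in range(n1):
                # skip reattachment pairs that rebuild the original tree:
                # both sides reattached at their merged edges
                i_merged = False
                if ne1 > 0:
                    x, y = edges1[i, 0], edges1[i, 1]
                    i_merged = (x == p and y == q) or (x == q and y == p)
                else:
                    i_merged = True
                for j in range(n2):
                    j_merged = False
                    if ne2 > 0:
                        x2, y2 = edges2[j, 0], edges2[j, 1]
                        j_merged = (x2 == a and y2 == b) or (x2 == b and y2 == a)
                    else:
                        j_merged = True
                    if i_merged and j_merged:
                        continue
                    extra = 0
                    for c in range(C):
                        if roots1[i, c] & roots2[j, c] == U32(0):
                            extra += 1
                    ln = base + extra
                    if ln > best:
                        continue
                    if ln < best:
                        best = ln
                        nmoves = 0
                    if nmoves < cap:
                        moves[nmoves, 0] = u
                        moves[nmoves, 1] = v
                        if ne1 > 0:
                            moves[nmoves, 2] = edges1[i, 0]
                            moves[nmoves, 3] = edges1[i, 1]
                        else:
                            moves[nmoves, 2] = -1
                            moves[nmoves, 3] = -1
                        if ne2 > 0:
                            moves[nmoves, 4] = edges2[j, 0]
                            moves[nmoves, 5] = edges2[j, 1]
                        else:
                            moves[nmoves, 4] = -1
                            moves[nmoves, 5] = -1
                        nmoves += 1
    return best, moves, nmoves


@njit(cache=True)
def insertion_costs(nbr, anchor, sets, leaf, out_edges, out_costs):
    """Cost of inserting `leaf` into each edge of the tree containing leaf
    `anchor`.  Returns (n_edges, base_length)."""
    N = nbr.shape[0]
    C = sets.shape[1]
    down = np.empty((N, C), U32)
    up = np.empty((N, C), U32)
    roots = np.empty((N, C), U32)
    order = np.empty(N, I32)
    parent = np.empty(N, I32)
    ne, L = component_rootsets(nbr, anchor, sets, down, up, out_edges, roots, order, parent)
    for i in range(ne):
        extra = 0
        for c in range(C):
            if roots[i, c] & sets[leaf, c] == U32(0):
                extra += 1
        out_costs[i] = L + extra
    return ne, L


@njit(cache=True)
def apply_insert(nbr_in, mid, leaf, ea, eb):
    """Insert `leaf` by subdividing edge (ea, eb) with new internal `mid`."""
    nbr = nbr_in.copy()
    _replace(nbr, ea, eb, mid)
    _replace(nbr, eb, ea, mid)
    nbr[mid, 0] = ea
    nbr[mid, 1] = eb
    nbr[mid, 2] = leaf
    nbr[leaf, 0] = mid
    return nbr


@njit(cache=True)
def edge_clades(nbr, n_leaves, order, parent):
    """Leaf bitmask below each internal node, rooted at the lowest present
    leaf.  Returns (masks, cnt): masks[v] = clade of v away from the root."""
    N = nbr.shape[0]
    anchor = 0
    while nbr[anchor, 0] < 0:
        anchor += 1
    cnt = _postorder(nbr, anchor, -1, order, parent)
    masks = np.zeros(N, np.uint64)
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        if nbr[v, 1] < 0:
            masks[v] = np.uint64(1) << np.uint64(v)
        else:
            m = np.uint64(0)
            for k in range(3):
                w = nbr[v, k]
                if w >= 0 and w != parent[v]:
                    m |= masks[w]
            masks[v] = m
    return masks, cnt
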