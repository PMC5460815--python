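"""Shared fixtures and independent reference implementations (oracles)."""

import numpy as np
import pandas as pd
import pytest

from dwdfam import DWD_PATTERN, compile_pattern


@pytest.fixture(scope="session")
def dwd():
    return compile_pattern(DWD_PATTERN)


def brute_force_matches(sequence: str, positions) -> list[int]:
    """Naive sliding-window matcher: checks every offset against the expanded
    pattern position by position. Independent of the regex scan path."""
    seq = sequence.upper()
    length = len(positions)
    out = []
    for start in range(len(seq) - length + 1):
        ok = True
        for k, allowed in enumerate(positions):
            if allowed is not None and seq[start + k] not in allowed:
                ok = False
                break
        if ok:
            out.append(start)
    return out


def domains_frame(rows):
    """rows: (protein_id, domain_name, start, end) tuples."""
    return pd.DataFrame(rows, columns=["protein_id", "domain_name", "start", "end"])


def random_additive_tree(n_leaves: int, rng) -> tuple[np.ndarray, set]:
    """A random binary tree with distinct positive branch lengths; returns its
    leaf path-length (additive) matrix and the set of non-trivial
    bipartitions, canonicalized as the side excluding leaf 'L0...'."""
    labels = [f"L{k:02d}" for k in range(n_leaves)]
    nodes = [frozenset([k]) for k in range(n_leaves)]
    children: dict = {}
    lengths: dict = {}
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = a | b
        children[parent] = (a, b)
        lengths[a] = float(rng.uniform(0.5, 2.0))
        lengths[b] = float(rng.uniform(0.5, 2.0))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = nodes[0] | nodes[1]
    children[root] = (nodes[0], nodes[1])
    lengths[nodes[0]] = float(rng.uniform(0.5, 2.0))
    lengths[nodes[1]] = float(rng.uniform(0.5, 2.0))

    dm = np.zeros((n_leaves, n_leaves))

    # pairwise distance = depth(a -> lca) + depth(b -> lca)
    def fill(node):
        if len(node) == 1:
            return
        a, b = children[node]
        depths_a = _depths(a)
        depths_b = _depths(b)
        for la, da in depths_a.items():
            for lb, db in depths_b.items():
                dist = da + lengths[a] + db + lengths[b]
                dm[la, lb] = dm[lb, la] = dist
        fill(a)
        fill(b)

    def _depths(node):
        if len(node) == 1:
            return {next(iter(node)): 0.0}
        a, b = children[node]
        out = {}
        for child in (a, b):
            for leaf, depth in _depths(child).items():
                out[leaf] = depth + lengths[child]
        return out

    fill(root)
    bipartitions = set()
    for node in children:
        if node != root and 1 < len(node) < n_leaves - 1:
            side = {labels[k] for k in node}
            if labels[0] in side:
                side = set(labels) - side
            bipartitions.add(frozenset(side))
    return dm, bipartitions
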