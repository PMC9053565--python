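"""Independent brute-force oracles used to cross-check the library.

These re-derive expected values from first principles (plain-dict BFS,
exhaustive candidate enumeration, direct entropy sums) without touching
the code paths they verify.
"""

from __future__ import annotations

from collections import deque
from math import inf, log2


def bfs_word_distance(lexicon_dict: dict, w1: str, w2: str, pos: str) -> float:
    """Shortest relation-edge path between two words, recomputed from a
    serialized lexicon with a hand-rolled BFS over a plain adjacency dict.
    """
    adjacency: dict[str, set[str]] = {}
    pos_of: dict[str, str] = {}
    for s in lexicon_dict["synsets"]:
        pos_of[s["id"]] = s["pos"]
        adjacency.setdefault(s["id"], set())
        for targets in s.get("relations", {}).values():
            for t in targets:
                adjacency.setdefault(s["id"], set()).add(t)
                adjacency.setdefault(t, set()).add(s["id"])
    sources, targets = set(), set()
    for e in lexicon_dict["entries"]:
        if e["pos"] != pos:
            continue
        if e["lemma"].casefold() == w1.casefold():
            sources.update(e["synsets"])
        if e["lemma"].casefold() == w2.casefold():
            targets.update(e["synsets"])
    if not sources or not targets:
        return inf
    if sources & targets:
        return 0
    best = inf
    for src in sources:
        dist = {src: 0}
        q = deque([src])
        while q:
            node = q.popleft()
            for nb in adjacency.get(node, ()):
                if pos_of.get(nb) != pos or nb in dist:
                    continue
                dist[nb] = dist[node] + 1
                q.append(nb)
        for t in targets:
            if t in dist:
                best = min(best, dist[t])
    return best


def brute_rounding_candidates(n: int) -> set[int]:
    """Every multiple of a power of ten within that power of ten of n
    (excluding n itself), found by exhaustive enumeration."""
    out = set()
    for k in range(1, len(str(n))):
        p = 10**k
        m = (n // p - 1) * p
        while m <= n + p:
            if m >= 0 and m % p == 0 and abs(n - m) < p and m != n:
                out.add(m)
            m += p
    return out


def entropy(labels) -> float:
    n = len(labels)
    counts: dict = {}
    for y in labels:
        counts[y] = counts.get(y, 0) + 1
    return -sum(c / n * log2(c / n) for c in counts.values())


def brute_gain_ratio(values, labels, nominal: bool) -> float:
    """Gain ratio by direct entropy sums; numeric features try every
    midpoint threshold and keep the split with the highest gain."""
    n = len(labels)

    def ratio_for(parts):
        cond = sum(len(p) / n * entropy(p) for p in parts if p)
        gain = entropy(labels) - cond
        sizes = [len(p) / n for p in parts if p]
        split = -sum(w * log2(w) for w in sizes)
        if split == 0 or gain <= 0:
            return 0.0, gain
        return gain / split, gain

    if nominal:
        parts = [
            [y for x, y in zip(values, labels) if x == v]
            for v in sorted(set(values))
        ]
        return ratio_for(parts)[0]
    uniq = sorted(set(values))
    if len(uniq) < 2:
        return 0.0
    best_gain, best_ratio = -1.0, 0.0
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = (lo + hi) / 2
        parts = [
            [y for x, y in zip(values, labels) if x <= t],
            [y for x, y in zip(values, labels) if x > t],
        ]
        r, g = ratio_for(parts)
        if g > best_gain:
            best_gain, best_ratio = g, r
    return best_ratio
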