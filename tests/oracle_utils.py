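"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def partitions(items, k):
    """All partitions of ``items`` into exactly k non-empty groups."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    for part in partitions(rest, k):  # first joins an existing group
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
    for part in partitions(rest, k - 1):  # first opens its own group
        yield [[first]] + part


def oracle_diversity(vectors, ids, k):
    """Exhaustive minimum-SSE partition, then nearest-to-centroid per group."""
    best, best_sse = None, np.inf
    for part in partitions(list(range(len(ids))), k):
        sse = sum(
            float(((vectors[g] - vectors[g].mean(axis=0)) ** 2).sum()) for g in map(list, part)
        )
        if sse < best_sse - 1e-12:
            best_sse, best = sse, part
    selected = []
    for group in best:
        centroid = vectors[group].mean(axis=0)
        dist = np.linalg.norm(vectors[group] - centroid, axis=1)
        order = sorted(range(len(group)), key=lambda i: (dist[i], ids[group[i]]))
        selected.append(ids[group[order[0]]])
    return set(selected)


def pairwise_auroc(labels, scores):
    """Oracle AUROC: concordant positive-negative pairs, ties worth 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
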