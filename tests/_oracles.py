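"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: segmentation by
exhaustive enumeration of all composition partitions, AUC by all-pairs
concordance counting, Youden by exhaustive threshold search.
"""

import itertools

import numpy as np


def greedy_partition_lengths_by_enumeration(masks):
    """Lexicographically largest valid run-length composition.

    A composition is valid when every run's bitwise-AND of membership
    masks is non-zero. Because validity is prefix-closed, the
    lexicographically largest composition equals the greedy left-maximal
    partition that the segmentation algorithm is specified to produce.
    """
    n = len(masks)
    best = None
    for cuts in range(1 << (n - 1)):
        lengths = []
        inter = masks[0]
        run_len = 1
        ok = True
        for i in range(1, n):
            if (cuts >> (i - 1)) & 1:
                lengths.append(run_len)
                inter = masks[i]
                run_len = 1
            else:
                inter &= masks[i]
                if not inter:
                    ok = False
                    break
                run_len += 1
        if ok:
            lengths.append(run_len)
            t = tuple(lengths)
            if best is None or t > best:
                best = t
    return best


def masks_for(tokens, taxonomy):
    """Subcategory sets of canonical tokens encoded as bitmasks."""
    subcats = sorted(taxonomy.subcategory_registry)
    bit = {sc: 1 << i for i, sc in enumerate(subcats)}
    return [
        sum(bit[sc] for sc in taxonomy.subcategories_of(tok)) for tok in tokens
    ]


def all_distinct_sequences(names, max_len):
    """Every ordered sequence of distinct animals up to max_len."""
    for length in range(1, max_len + 1):
        yield from itertools.permutations(names, length)


def concordance_auc(scores, is_case):
    """AUC as the all-pairs concordance count: (#case>control + ties/2)/mn."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[is_case]
    neg = scores[~is_case]
    gt = sum(1 for p in pos for q in neg if p > q)
    eq = sum(1 for p in pos for q in neg if p == q)
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def exhaustive_youden(scores, is_case):
    """Best (J, sensitivity, threshold) by scanning every candidate cutoff.

    Candidates are midpoints between adjacent distinct scores plus
    below-min and above-max sentinels; positive means score >= threshold.
    Ties resolve to higher sensitivity then lower threshold, mirroring the
    documented rule.
    """
    scores = np.asarray(scores, dtype=float)
    pos = scores[is_case]
    neg = scores[~is_case]
    distinct = np.unique(scores)
    candidates = (
        [-np.inf]
        + [(a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])]
        + [np.inf]
    )
    best = None
    for t in candidates:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        key = (sens + spec - 1.0, sens, -t)
        if best is None or key > best:
            best = key
    j, sens, neg_t = best
    return j, sens, -neg_t
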