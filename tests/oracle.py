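"""Independent brute-force oracle for the association-test statistics.

Pure-Python (math + itertools) reimplementation used only to cross-check the
package; deliberately shares no code with ``medbias``.
"""

import itertools
import math


def cos(u, v):
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return dot / (nu * nv)


def assoc(w, A, B):
    return sum(cos(w, a) for a in A) / len(A) - sum(cos(w, b) for b in B) / len(B)


def statistic(X, Y, A, B):
    return sum(assoc(x, A, B) for x in X) - sum(assoc(y, A, B) for y in Y)


def effect_size(X, Y, A, B, population=True):
    s = [assoc(w, A, B) for w in list(X) + list(Y)]
    mx = sum(assoc(x, A, B) for x in X) / len(X)
    my = sum(assoc(y, A, B) for y in Y) / len(Y)
    mean = sum(s) / len(s)
    var = sum((v - mean) ** 2 for v in s) / (len(s) if population else len(s) - 1)
    return (mx - my) / math.sqrt(var)


def exhaustive_permutation(X, Y, A, B):
    """Return (n_greater, n_ties, n_partitions) over all equal partitions."""
    union = list(X) + list(Y)
    n = len(X)
    assert len(Y) == n
    s_obs = statistic(X, Y, A, B)
    greater = ties = total = 0
    for combo in itertools.combinations(range(len(union)), n):
        xs = [union[i] for i in combo]
        ys = [union[i] for i in range(len(union)) if i not in combo]
        s = statistic(xs, ys, A, B)
        total += 1
        if s > s_obs + 1e-12:
            greater += 1
        elif abs(s - s_obs) <= 1e-12:
            ties += 1
    return greater, ties, total


def sd_population(values):
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
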