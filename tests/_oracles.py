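"""Independent brute-force oracles used by the tests.

Deliberately naive (pure-Python loops) and written without reference to
the package internals, so that agreement with the library is meaningful.
"""
import math


def oracle_fold_error_1nn(x, y, ids, fold_of, columns, fold):
    """Misclassification count on one fold under 1NN with (distance, id) ties."""
    test = [i for i in range(len(y)) if fold_of[i] == fold]
    train = [i for i in range(len(y)) if fold_of[i] != fold]
    wrong = 0
    for i in test:
        best = None
        for j in train:
            d = math.sqrt(sum((x[i][c] - x[j][c]) ** 2 for c in columns))
            key = (d, ids[j])
            if best is None or key < best[0]:
                best = (key, y[j])
        if best[1] != y[i]:
            wrong += 1
    return wrong


def oracle_cv_error_1nn(x, y, ids, fold_of, columns):
    """Mean per-fold misclassification count over all folds."""
    folds = sorted(set(fold_of))
    counts = [
        oracle_fold_error_1nn(x, y, ids, fold_of, columns, f) for f in folds
    ]
    return sum(counts) / len(counts)


def oracle_greedy_sfs_1nn(x, y, ids, fold_of, n_probes):
    """Naive nested-loop re-implementation of greedy forward selection.

    Returns (selected column indices in order, trace of per-round CCE lists).
    """
    remaining = list(range(n_probes))
    selected = []
    trace = []

    scores = [oracle_cv_error_1nn(x, y, ids, fold_of, [c]) for c in remaining]
    trace.append(list(scores))
    j = scores.index(min(scores))
    selected.append(remaining.pop(j))
    oce = scores[j]

    while remaining:
        scores = [
            oracle_cv_error_1nn(x, y, ids, fold_of, selected + [c])
            for c in remaining
        ]
        trace.append(list(scores))
        j = scores.index(min(scores))
        if scores[j] < oce:
            selected.append(remaining.pop(j))
            oce = scores[j]
        else:
            break
    return selected, trace, oce
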