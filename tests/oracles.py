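"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-sample / per-pair Python loops (or
closed forms), deliberately sharing no code path with the package internals
it checks.
"""

from math import comb

from mirpairs import ExpressionMatrix, LabelMap


def brute_ordering_count(matrix: ExpressionMatrix, a: str, b: str) -> int:
    va, vb = matrix.row(a), matrix.row(b)
    return sum(1 for x, y in zip(va, vb) if x > y)


def brute_stable_pairs(matrix: ExpressionMatrix, threshold: float) -> dict:
    """Unordered key -> (oriented a, oriented b, stability) by double loop."""
    ids = matrix.mirna_ids
    n = matrix.n_samples
    out = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            m_ij = brute_ordering_count(matrix, ids[i], ids[j])
            m_ji = brute_ordering_count(matrix, ids[j], ids[i])
            m = max(m_ij, m_ji)
            if m / n > threshold:
                if m_ij > m_ji:
                    a, b = ids[i], ids[j]
                elif m_ji > m_ij:
                    a, b = ids[j], ids[i]
                else:
                    a, b = sorted((ids[i], ids[j]))
                out[tuple(sorted((a, b)))] = (a, b, m / n)
    return out


def brute_contingency(pair, controls, cases):
    n1 = brute_ordering_count(controls, pair.a, pair.b)
    n2 = brute_ordering_count(controls, pair.b, pair.a)
    m1 = brute_ordering_count(cases, pair.a, pair.b)
    m2 = brute_ordering_count(cases, pair.b, pair.a)
    return n1, n2, m1, m2


def brute_coverage(pair, cases) -> frozenset:
    return frozenset(
        sid for sid in cases.sample_ids
        if cases.column(sid)[pair.a] < cases.column(sid)[pair.b]
    )


def hypergeom_point(n1, n2, m1, m2) -> float:
    """Point probability of the 2x2 table under fixed margins."""
    total = n1 + n2 + m1 + m2
    return (
        comb(n1 + n2, n1) * comb(m1 + m2, m1) / comb(total, n1 + m1)
        if comb(total, n1 + m1)
        else float("nan")
    )


def fisher_one_sided_oracle(n1, n2, m1, m2) -> float:
    """Tail sum of point probabilities at least as extreme toward case reversal.

    Extremity direction: moving mass from (n2, m1) into (n1, m2), i.e. tables
    with a larger controls/(E_a>E_b) cell given the margins.
    """
    row1, col1 = n1 + n2, n1 + m1
    total = n1 + n2 + m1 + m2
    k_max = min(row1, col1)
    return sum(
        hypergeom_point(k, row1 - k, col1 - k, (total - row1) - (col1 - k))
        for k in range(n1, k_max + 1)
        if row1 - k >= 0 and col1 - k >= 0 and (total - row1) - (col1 - k) >= 0
    )


def bh_step_up_oracle(p_values):
    """Hand Benjamini-Hochberg: q_(i) = min_{j>=i} min(1, m * p_(j) / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [min(1.0, m * p_values[order[i]] / (i + 1)) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def auc_pairwise_oracle(scores: dict, truth: LabelMap) -> float:
    cases = [scores[s] for s in truth.case_ids]
    controls = [scores[s] for s in truth.control_ids]
    wins = sum(
        1.0 if c > k else 0.5 if c == k else 0.0 for c in cases for k in controls
    )
    return wins / (len(cases) * len(controls))


def greedy_trace_oracle(pivot_key, coverage_sets, tie_order):
    """Greedy union-coverage trace over explicit Python sets.

    ``coverage_sets``: unordered-pair key -> set of covered case ids;
    ``tie_order``: keys in tie-break preference order (pivot included).
    """
    members = [pivot_key]
    covered = set(coverage_sets[pivot_key])
    remaining = [k for k in tie_order if k != pivot_key]
    while True:
        best, best_gain = None, 0
        for k in remaining:
            gain = len(coverage_sets[k] - covered)
            if gain > best_gain:
                best, best_gain = k, gain
        if best is None:
            return members, covered
        members.append(best)
        covered |= coverage_sets[best]
        remaining.remove(best)
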