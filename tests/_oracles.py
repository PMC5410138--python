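"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
scores come from exhaustive enumeration of every admissible local
alignment, and rank-sum p-values from full enumeration of group
assignments.
"""

from __future__ import annotations

import itertools
import math

from hmmscreen.profile_build import AA_INDEX


def enumerate_alignment_weights(model, peptide):
    """Probability-space weight of every local alignment (exhaustive).

    Semantics mirror the documented local model: entry mass 1/(M*L) at
    any (residue, match state), exit probability 1/(M-k+1) from match
    state k, core transitions otherwise, emissions as odds against the
    background, X score-neutral.
    """
    M = model.M
    L = len(peptide)
    res = [AA_INDEX.get(a) for a in peptide]
    bg = model.background
    t = model.transitions

    def emr(k, i):  # match state k emitting residue i (1-based)
        a = res[i - 1]
        return 1.0 if a is None else model.match_emit[k - 1][a] / bg[a]

    def insr(k, i):
        a = res[i - 1]
        return 1.0 if a is None else model.insert_emit[k][a] / bg[a]

    def texit(k):
        return 1.0 / (M - k + 1)

    weights = []

    def from_match(k, i, w):
        weights.append(w * texit(k))
        stay = 1.0 - texit(k)
        if k < M:
            if i < L:
                from_match(k + 1, i + 1, w * stay * t[k][0] * emr(k + 1, i + 1))
                from_insert(k, i + 1, w * stay * t[k][1] * insr(k, i + 1))
            from_delete(k + 1, i, w * stay * t[k][2])

    def from_insert(k, i, w):
        if i < L:
            from_match(k + 1, i + 1, w * t[k][3] * emr(k + 1, i + 1))
            from_insert(k, i + 1, w * t[k][4] * insr(k, i + 1))

    def from_delete(k, i, w):
        if k < M:
            if i < L:
                from_match(k + 1, i + 1, w * t[k][5] * emr(k + 1, i + 1))
            from_delete(k + 1, i, w * t[k][6])

    entry = 1.0 / (M * L)
    for i0 in range(1, L + 1):
        for j in range(1, M + 1):
            from_match(j, i0, entry * emr(j, i0))
    return weights


def oracle_forward(model, peptide):
    return math.log2(sum(enumerate_alignment_weights(model, peptide)))


def oracle_viterbi(model, peptide):
    return math.log2(max(enumerate_alignment_weights(model, peptide)))


def exact_ranksum_p(x, y):
    """Two-sided exact Wilcoxon rank-sum p by full enumeration (no ties)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    sums = [
        sum(combo)
        for combo in itertools.combinations(range(1, n + 1), len(x))
    ]
    total = len(sums)
    p_le = sum(1 for s in sums if s <= w_obs) / total
    p_ge = sum(1 for s in sums if s >= w_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
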