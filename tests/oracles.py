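"""Independent brute-force oracles used to validate the statistical kernels.

Every oracle here is deliberately written from first principles (exact
integer/Fraction arithmetic, literal rule transcription, exhaustive
enumeration) and never calls the implementation it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums P(table) over all tables with the same margins whose point
    probability does not exceed that of the observed table.  Exact rational
    arithmetic throughout.
    """
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    denom = comb(n, k)
    p_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, k - r2), min(k, r1) + 1):
        weight = comb(r1, x) * comb(r2, k - x)
        if weight <= p_obs:
            total += weight
    return Fraction(total, denom)


def odds_ratio_corrected_oracle(a, b, c, d):
    """Closed-form Haldane-Anscombe corrected OR (0.5 added when any cell 0)."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up by the literal formula.

    q_(i) = min over j >= i of p_(j) * m / j, clipped to 1, mapped back to
    input order.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [None] * m
    for rank, i in enumerate(order):
        out[i] = min(q_sorted[rank], 1.0)
    return out


# --- ACMG rule table, literal transcription -------------------------------

_PATHOGENIC_CLAUSES = [
    lambda n: n["PVS"] >= 1 and n["PS"] >= 1,
    lambda n: n["PVS"] >= 1 and n["PM"] >= 2,
    lambda n: n["PVS"] >= 1 and n["PM"] == 1 and n["PP"] == 1,
    lambda n: n["PVS"] >= 1 and n["PM"] >= 1 and n["PP"] >= 1,
    lambda n: n["PVS"] >= 1 and n["PP"] >= 2,
    lambda n: n["PS"] >= 2,
    lambda n: n["PS"] == 1 and n["PM"] >= 3,
    lambda n: n["PS"] == 1 and n["PM"] == 2 and n["PP"] >= 2,
    lambda n: n["PS"] == 1 and n["PM"] == 1 and n["PP"] >= 4,
]

_LIKELY_PATHOGENIC_CLAUSES = [
    lambda n: n["PVS"] >= 1 and n["PM"] == 1,
    lambda n: n["PS"] == 1 and 1 <= n["PM"] <= 2,
    lambda n: n["PS"] == 1 and n["PP"] >= 2,
    lambda n: n["PM"] >= 3,
    lambda n: n["PM"] == 2 and n["PP"] >= 2,
    lambda n: n["PM"] == 1 and n["PP"] >= 4,
]


def acmg_oracle(codes) -> str:
    """Literal rule-table evaluation of the five-tier combination.

    Mirrors the published combining criteria clause by clause, with the
    contradictory-evidence convention: a benign-direction classification in
    the presence of any pathogenic code (or vice versa) resolves to VUS.
    """
    n = {
        "PVS": sum(1 for c in codes if c == "PVS1"),
        "PS": sum(1 for c in codes if c.startswith("PS")),
        "PM": sum(1 for c in codes if c.startswith("PM")),
        "PP": sum(1 for c in codes if c.startswith("PP")),
        "BA": sum(1 for c in codes if c == "BA1"),
        "BS": sum(1 for c in codes if c.startswith("BS")),
        "BP": sum(1 for c in codes if c.startswith("BP")),
    }
    pathogenic = any(clause(n) for clause in _PATHOGENIC_CLAUSES)
    likely_pathogenic = any(clause(n) for clause in _LIKELY_PATHOGENIC_CLAUSES)
    benign = n["BA"] >= 1 or n["BS"] >= 2
    likely_benign = (n["BS"] == 1 and n["BP"] >= 1) or n["BP"] >= 2
    path_any = n["PVS"] + n["PS"] + n["PM"] + n["PP"] > 0
    benign_any = n["BA"] + n["BS"] + n["BP"] > 0
    if (pathogenic or likely_pathogenic) and (benign or likely_benign):
        return "VUS"
    if (pathogenic or likely_pathogenic) and benign_any:
        return "VUS"
    if (benign or likely_benign) and path_any:
        return "VUS"
    if pathogenic:
        return "Pathogenic"
    if likely_pathogenic:
        return "LikelyPathogenic"
    if benign:
        return "Benign"
    if likely_benign:
        return "LikelyBenign"
    return "VUS"


def ora_tail_oracle(query, gene_set, universe) -> Fraction:
    """P[|draw ∩ set| >= k] by exhaustive enumeration of all C(N, n) draws."""
    universe = sorted(universe)
    gene_set = set(gene_set) & set(universe)
    n = len(set(query))
    k = len(set(query) & gene_set)
    hits = 0
    total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(set(draw) & gene_set) >= k:
            hits += 1
    return Fraction(hits, total)


def auc_pair_oracle(scores, labels) -> float:
    """AUC by direct concordant/tied pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def rank_sum_exact_oracle(x, y) -> Fraction:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = sorted(list(x) + list(y))
    n_x = len(x)
    ranks = {}
    # average ranks for ties
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        avg = (i + 1 + j) / 2
        ranks[pooled[i]] = avg
        i = j
    def stat(values):
        return sum(ranks[v] for v in values)
    observed = stat(x)
    mean = stat(pooled) * n_x / len(pooled)
    obs_dev = abs(observed - mean)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_x):
        total += 1
        s = sum(ranks[pooled[i]] for i in idx)
        if abs(s - mean) >= obs_dev - 1e-12:
            hits += 1
    return Fraction(hits, total)
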