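"""Independent oracles, coded separately from the library implementations.

These deliberately use different algorithms or straight transcriptions of
the published constant tables so that agreement with the package is a real
cross-check, not a tautology.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, log, sqrt

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODE = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODE[_stop] = "*"


def brute_force_pathways(codon_a: str, codon_b: str):
    """NG86 pathway averaging by recursive path enumeration.

    Explores every sequence of single-nucleotide steps from ``codon_a`` to
    ``codon_b`` (changing one still-differing position at a time), prunes
    branches whose intermediate codon is a stop, and averages syn/nonsyn
    step counts over the surviving complete paths.
    """
    paths = []

    def walk(cur, syn, nonsyn):
        diff = [i for i in range(3) if cur[i] != codon_b[i]]
        if not diff:
            paths.append((syn, nonsyn))
            return
        for i in diff:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if CODE[nxt] == "*" and nxt != codon_b:
                continue
            step_syn = CODE[nxt] == CODE[cur]
            walk(nxt, syn + step_syn, nonsyn + (not step_syn))

    walk(codon_a, 0, 0)
    if not paths:
        return None
    n = len(paths)
    return sum(p[0] for p in paths) / n, sum(p[1] for p in paths) / n


def brute_force_sites(codon: str):
    """Count synonymous mutational targets codon-wide, without per-position loops."""
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant != codon and CODE[mutant] == CODE[codon]:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def brute_force_pi(sequences: list[str]) -> float:
    """π per site as a literal average over all sequence pairs.

    Pairwise deletion: a position enters a pair's comparison only when both
    bases are A/C/G/T; each pair contributes diffs/compared-positions.
    """
    vals = []
    for a, b in combinations(sequences, 2):
        num = den = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                den += 1
                num += x != y
        vals.append(num / den if den else 0.0)
    return sum(vals) / len(vals)


def tajima_constants(n: int) -> dict[str, float]:
    """Straight transcription of the Tajima (1989) constant definitions."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
        "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


def tajima_d(n: int, S: int, pi_total: float) -> float:
    c = tajima_constants(n)
    return (pi_total - S / c["a1"]) / sqrt(c["e1"] * S + c["e2"] * S * (S - 1))


def fu_li_star_constants(n: int) -> dict[str, float]:
    """Fu & Li (1993) starred-statistic constants (corrected variance form)."""
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    an1 = a + 1.0 / n
    cn = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )
    v_dstar = (
        (n / (n - 1)) ** 2 * b + a**2 * dn - 2 * (n * a * (a + 1)) / (n - 1) ** 2
    ) / (a**2 + b)
    u_dstar = (n / (n - 1)) * (a - n / (n - 1)) - v_dstar
    v_fstar = (
        dn + 2 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        - (2.0 / (n - 1)) * (4 * b - 6 + 8.0 / n)
    ) / (a**2 + b)
    u_fstar = (
        n / (n - 1) + (n + 1) / (3.0 * (n - 1)) - 4.0 / (n * (n - 1))
        + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))
    ) / a - v_fstar
    return {"a": a, "u_dstar": u_dstar, "v_dstar": v_dstar,
            "u_fstar": u_fstar, "v_fstar": v_fstar}


def fu_li_dstar(n: int, S: int, eta_s: int) -> float:
    c = fu_li_star_constants(n)
    return ((n / (n - 1)) * S - c["a"] * eta_s) / sqrt(
        c["u_dstar"] * S + c["v_dstar"] * S * S
    )


def fu_li_fstar(n: int, S: int, eta_s: int, pi_total: float) -> float:
    c = fu_li_star_constants(n)
    return (pi_total - ((n - 1) / n) * eta_s) / sqrt(
        c["u_fstar"] * S + c["v_fstar"] * S * S
    )


def fay_wu_h(n: int, xi: dict[int, int]) -> float:
    """H from an unfolded spectrum {derived count: number of sites}."""
    pi = sum(cnt * 2 * i * (n - i) for i, cnt in xi.items()) / (n * (n - 1))
    th = sum(cnt * 2 * i * i for i, cnt in xi.items()) / (n * (n - 1))
    return pi - th


def jc_distance(p: float) -> float:
    return -0.75 * log(1 - 4 * p / 3)


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by exact rational enumeration over the margin."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


def rank_sum_exact_p(a: list[float], b: list[float]) -> float:
    """Two-sided rank-sum p by enumerating all assignments of pooled ranks."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # assumes no ties
    w_obs = sum(ranks[v] for v in a)
    n1 = len(a)
    ws = [sum(s) for s in combinations(range(1, len(pooled) + 1), n1)]
    mean_w = n1 * (len(pooled) + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in ws if abs(w - mean_w) >= dev - 1e-12)
    return extreme / len(ws)
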