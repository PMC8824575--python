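"""Within-species diversity, SFS neutrality statistics, and the MK test.

Diversity is summarised by nucleotide diversity π (mean pairwise differences
per site, pairwise deletion of missing data) and Watterson's θ_w = S/(a1·L).
Site-frequency-spectrum statistics — Tajima's D, Fu & Li's D*/F* (and the
outgroup-based D/F), and Fay & Wu's H — contrast diversity estimators that
weight the frequency spectrum differently; their significance is judged
against *empirical* genome-wide null distributions rather than theoretical
ones, which absorbs demographic distortion of the spectrum.

The McDonald–Kreitman test contrasts fixed divergence with within-species
polymorphism at synonymous and nonsynonymous sites; the neutral index
NI = (Pn/Ps)/(Dn/Ds) and α = 1 − NI estimate the adaptive fraction of
amino-acid substitutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

from .kaks import NUCS, STANDARD_CODE
from .polarize import Assignment, PolarizedSubstitutions, SubClass
from .seq_io import CodonAlignment

_NUC_BYTES = np.frombuffer(b"ACGT", dtype="S1")


class SampleSizeError(ValueError):
    """Fewer than two sequences: no within-sample comparison possible."""


def _matrix(aln: CodonAlignment, exclude: tuple[str, ...] = ()) -> tuple[list[str], np.ndarray]:
    labels = [l for l in aln.labels if l not in exclude]
    arr = np.frombuffer(
        "".join(aln.records[l] for l in labels).encode(), dtype="S1"
    ).reshape(len(labels), aln.length)
    return labels, arr


def _allele_counts(arr: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column; gaps and N are uncalled."""
    return np.stack([(arr == b).sum(axis=0) for b in _NUC_BYTES])


def harmonic(n: int, power: int = 1) -> float:
    """a_n = Σ_{i=1}^{n-1} 1/i^power (the Watterson/Tajima constants)."""
    return float(sum(1.0 / i**power for i in range(1, n)))


@dataclass
class DiversityStats:
    n: int
    S: int
    L: int
    pi: float
    theta_w: float


@dataclass
class SiteCounts:
    """Per-locus column summaries shared by the SFS statistics.

    ``pi_total`` is the sum over surveyed sites of per-site mean pairwise
    differences (pairwise deletion); ``S`` counts biallelic segregating
    sites; ``singletons`` counts sites whose minor allele appears once.
    """

    n: int
    L: int
    S: int
    pi_total: float
    singletons: int
    multi_allelic: int


def site_counts(
    aln: CodonAlignment,
    exclude: tuple[str, ...] = (),
    min_called_fraction: float = 0.9,
) -> SiteCounts:
    labels, arr = _matrix(aln, exclude)
    n = len(labels)
    if n < 2:
        raise SampleSizeError("need at least two sequences")
    counts = _allele_counts(arr)
    called = counts.sum(axis=0)
    surveyed = called >= max(2, int(np.ceil(min_called_fraction * n)))
    counts = counts[:, surveyed]
    called = called[surveyed]
    L = int(surveyed.sum())

    n_alleles = (counts > 0).sum(axis=0)
    pairs = called * (called - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site_pi = np.where(pairs > 0, (pairs - same) / pairs, 0.0)
    pi_total = float(per_site_pi.sum())

    biallelic = n_alleles == 2
    multi = int((n_alleles > 2).sum())
    if multi:
        warnings.warn(
            f"{multi} sites with >2 alleles excluded from S-based statistics"
        )
    minor = np.where(biallelic, counts.max(axis=0), 0)
    minor = np.where(biallelic, called - minor, 0)
    S = int(biallelic.sum())
    singletons = int(((minor == 1) & biallelic).sum())
    return SiteCounts(n, L, S, pi_total, singletons, multi)


def diversity(aln: CodonAlignment, exclude: tuple[str, ...] = ()) -> DiversityStats:
    """π and Watterson's θ_w per site for a population alignment."""
    sc = site_counts(aln, exclude)
    if sc.L == 0:
        raise SampleSizeError("no surveyed sites")
    a1 = harmonic(sc.n)
    return DiversityStats(
        n=sc.n,
        S=sc.S,
        L=sc.L,
        pi=sc.pi_total / sc.L,
        theta_w=sc.S / (a1 * sc.L),
    )


def tajimas_d(aln: CodonAlignment, exclude: tuple[str, ...] = ()) -> float | None:
    """Tajima's (1989) D; ``None`` when there are no segregating sites."""
    sc = site_counts(aln, exclude)
    return tajimas_d_from_counts(sc.n, sc.S, sc.pi_total)


def tajimas_d_from_counts(n: int, S: int, pi_total: float) -> float | None:
    if S == 0:
        return None
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def _derived_spectrum(
    aln: CodonAlignment, outgroup_label: str
) -> tuple[int, np.ndarray]:
    """Unfolded SFS counts ξ_i (i = 1..n−1) polarized by an outgroup.

    Only fully-called columns where the outgroup carries an unambiguous base
    matching one of the sample alleles are polarizable; others are dropped.
    """
    if outgroup_label not in aln.records:
        raise ValueError(f"outgroup {outgroup_label!r} not in alignment")
    labels, arr = _matrix(aln, exclude=(outgroup_label,))
    n = len(labels)
    if n < 2:
        raise SampleSizeError("need at least two ingroup sequences")
    og = np.frombuffer(aln[outgroup_label].encode(), dtype="S1")
    counts = _allele_counts(arr)
    called = counts.sum(axis=0)
    full = called == n
    og_ok = np.isin(og, _NUC_BYTES)
    xi = np.zeros(n, dtype=int)
    usable = full & og_ok
    anc_counts = np.zeros(aln.length, dtype=int)
    for k, b in enumerate(_NUC_BYTES):
        anc_counts[og == b] = counts[k][og == b]
    n_alleles = (counts > 0).sum(axis=0)
    seg = usable & (n_alleles == 2) & (anc_counts > 0)
    derived = n - anc_counts[seg]
    for d in derived:
        if 1 <= d <= n - 1:
            xi[d] += 1
    return n, xi[1:]


def fay_wu_h(aln: CodonAlignment, outgroup_label: str) -> float | None:
    """Fay & Wu's H = π − θ_H from the outgroup-polarized spectrum.

    θ_H = Σ_i 2·ξ_i·i²/(n(n−1)) overweights high-frequency derived alleles;
    a strongly negative H is the classic hitchhiking signature.  ``None``
    when no polarizable segregating sites remain.
    """
    n, xi = _derived_spectrum(aln, outgroup_label)
    if xi.sum() == 0:
        return None
    i = np.arange(1, n)
    denom = n * (n - 1)
    pi = float((2.0 * xi * i * (n - i)).sum() / denom)
    theta_h = float((2.0 * xi * i * i).sum() / denom)
    return pi - theta_h


@dataclass
class FuLiResult:
    dstar: float | None
    fstar: float | None
    d: float | None = None
    f: float | None = None


def fu_li(
    aln: CodonAlignment,
    outgroup_label: str | None = None,
) -> FuLiResult:
    """Fu & Li (1993) singleton-based statistics.

    The starred statistics use within-sample singletons; when an outgroup is
    given, the unstarred D and F use derived (external-branch) singletons.
    All are ``None`` when S = 0.
    """
    exclude = (outgroup_label,) if outgroup_label else ()
    sc = site_counts(aln, exclude)
    n, S = sc.n, sc.S
    if S == 0:
        return FuLiResult(None, None)
    a = harmonic(n)
    b = harmonic(n, 2)
    an1 = a + 1.0 / n
    cn = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2)) if n > 2 else 1.0
    dn = cn + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    ) if n > 2 else 2.0

    eta_s = sc.singletons
    v_dstar = (
        (n / (n - 1)) ** 2 * b
        + a**2 * dn
        - 2 * (n * a * (a + 1)) / (n - 1) ** 2
    ) / (a**2 + b)
    u_dstar = (n / (n - 1)) * (a - n / (n - 1)) - v_dstar
    dstar = ((n / (n - 1)) * S - a * eta_s) / sqrt(u_dstar * S + v_dstar * S * S)

    v_fstar = (
        dn
        + 2 * (n * n + n + 3) / (9.0 * n * (n - 1))
        - (2.0 / (n - 1)) * (4 * b - 6 + 8.0 / n)
    ) / (a**2 + b)
    u_fstar = (
        n / (n - 1)
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))
    ) / a - v_fstar
    fstar = (sc.pi_total - ((n - 1) / n) * eta_s) / sqrt(
        u_fstar * S + v_fstar * S * S
    )

    result = FuLiResult(dstar, fstar)
    if outgroup_label is not None:
        n_og, xi = _derived_spectrum(aln, outgroup_label)
        eta = int(xi.sum())
        if eta > 0:
            eta_e = int(xi[0])
            v_d = 1.0 + (a**2 / (b + a**2)) * (cn - (n + 1) / (n - 1))
            u_d = a - 1.0 - v_d
            result.d = (eta - a * eta_e) / sqrt(u_d * eta + v_d * eta * eta)
            i = np.arange(1, n)
            pi_pol = float((2.0 * xi * i * (n - i)).sum() / (n * (n - 1)))
            v_f = (
                cn + 2 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)
            ) / (a**2 + b)
            u_f = (
                1.0
                + (n + 1) / (3.0 * (n - 1))
                - 4.0 * ((n + 1) / (n - 1) ** 2) * (an1 - 2.0 * n / (n + 1))
            ) / a - v_f
            result.f = (pi_pol - eta_e) / sqrt(u_f * eta + v_f * eta * eta)
    return result


class EmpiricalNull:
    """Genome-wide empirical distribution of a statistic.

    Quantiles use the (N+1) mid-rank convention
    ``(#{v < x} + 0.5·#{v = x} + 0.5)/(N + 1)`` so they never reach 0 or 1,
    which keeps two-tailed tests stable.
    """

    def __init__(self, values) -> None:
        vals = np.asarray([v for v in values if v is not None], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("empirical null is empty")
        self.values = np.sort(vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def quantile(self, x: float) -> float:
        less = float(np.searchsorted(self.values, x, side="left"))
        leq = float(np.searchsorted(self.values, x, side="right"))
        return (less + 0.5 * (leq - less) + 0.5) / (self.n + 1)

    def is_significant(self, x: float, gamma: float = 0.05) -> bool:
        q = self.quantile(x)
        return q < gamma / 2 or q > 1 - gamma / 2


def empirical_quantile(x: float, null: EmpiricalNull) -> float:
    return null.quantile(x)


@dataclass
class MKResult:
    """McDonald–Kreitman 2×2 table with NI, α, and Fisher's exact p."""

    Dn: float
    Ds: float
    Pn: float
    Ps: float
    NI: float | None
    alpha: float | None
    fisher_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def mk_test(Dn: float, Ds: float, Pn: float, Ps: float) -> MKResult:
    """MK test on counts: NI = (Pn/Ps)/(Dn/Ds), α = 1 − NI, Fisher two-tailed p.

    NI and α are undefined (``None``) when Ps or Dn is zero; the Fisher p is
    computed regardless.
    """
    if min(Dn, Ds, Pn, Ps) < 0:
        raise ValueError("counts must be nonnegative")
    ni = alpha = None
    if Ps > 0 and Dn > 0 and Ds > 0:
        ni = (Pn / Ps) / (Dn / Ds)
        alpha = 1.0 - ni
    _, fisher_p = stats.fisher_exact([[Dn, Ds], [Pn, Ps]], alternative="two-sided")
    return MKResult(Dn, Ds, Pn, Ps, ni, alpha, float(fisher_p))


def count_mk_cells(
    pop_aln: CodonAlignment,
    polarized: PolarizedSubstitutions,
    assignments: tuple[Assignment, ...] = (Assignment.NEW,),
    fixation_threshold: float = 0.99,
    code: dict[str, str] = STANDARD_CODE,
) -> tuple[int, int, int, int]:
    """Build the MK 2×2 cells from a population sample and polarized divergence.

    Divergence cells start from the lineage-assigned substitutions; sites in
    the population at derived frequency ≥ ``fixation_threshold`` with the
    ancestral allele absent among called alleles also count as divergence
    (and never as polymorphism).  Remaining segregating sites are classified
    synonymous/nonsynonymous against the major-allele codon context.
    """
    if (pop_aln.length - pop_aln.frame_offset) % 3 != 0:
        raise ValueError("population alignment violates the coding frame")
    labels, arr = _matrix(pop_aln)
    n = len(labels)
    counts = _allele_counts(arr)
    called = counts.sum(axis=0)
    anc_map = polarized.ancestral_map()

    Dn = sum(
        polarized.count(a, SubClass.NONSYNONYMOUS) for a in assignments
    )
    Ds = sum(polarized.count(a, SubClass.SYNONYMOUS) for a in assignments)
    polarized_positions = {r.position for r in polarized.records}
    Pn = Ps = 0

    consensus = _NUC_BYTES[counts.argmax(axis=0)].tobytes().decode()
    off = pop_aln.frame_offset

    def classify(pos: int, base_from: str, base_to: str) -> SubClass:
        ci = (pos - off) // 3
        pic = (pos - off) % 3
        ctx = consensus[off + 3 * ci : off + 3 * ci + 3]
        c_from = ctx[:pic] + base_from + ctx[pic + 1 :]
        c_to = ctx[:pic] + base_to + ctx[pic + 1 :]
        if any(b not in NUCS for b in c_from + c_to):
            return SubClass.UNCLASSIFIED
        return (
            SubClass.SYNONYMOUS
            if code[c_from] == code[c_to]
            else SubClass.NONSYNONYMOUS
        )

    def add_divergence(pos: int, anc: str, derived: str) -> None:
        cls = classify(pos, anc, derived)
        nonlocal Dn, Ds
        if cls == SubClass.SYNONYMOUS:
            Ds += 1
        elif cls == SubClass.NONSYNONYMOUS:
            Dn += 1

    n_alleles = (counts > 0).sum(axis=0)
    for pos in np.flatnonzero(n_alleles >= 1):
        pos = int(pos)
        if pos < off or pos >= off + pop_aln.n_codons * 3:
            continue
        col = counts[:, pos]
        anc = anc_map.get(pos)
        present = [k for k in range(4) if col[k] > 0]
        if n_alleles[pos] == 1:
            # monomorphic: a fixed difference only if it contradicts a known
            # ancestral state and polarize has not already counted it
            base = NUCS[present[0]]
            if anc is not None and base != anc and pos not in polarized_positions:
                add_divergence(pos, anc, base)
            continue
        if n_alleles[pos] > 2:
            warnings.warn(f"site {pos} has >2 alleles; excluded from MK cells")
            continue
        major_k = max(present, key=lambda k: col[k])
        minor_k = min(present, key=lambda k: col[k])
        if anc is not None:
            anc_present = col[NUCS.index(anc)] > 0
            major_freq = col[major_k] / called[pos]
            if not anc_present and major_freq >= fixation_threshold:
                # near-fixed derived state: divergence, not polymorphism
                if pos not in polarized_positions:
                    add_divergence(pos, anc, NUCS[major_k])
                continue
        cls = classify(pos, NUCS[major_k], NUCS[minor_k])
        if cls == SubClass.SYNONYMOUS:
            Ps += 1
        elif cls == SubClass.NONSYNONYMOUS:
            Pn += 1
    return Dn, Ds, Pn, Ps
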