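"""Nei–Gojobori (1986) Ka/Ks estimation with Jukes–Cantor correction.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of the nine possible single-nucleotide changes that are synonymous; *site*
totals for a pair are the average over the two sequences.  *Differences*
between codons differing at two or three positions are averaged over all
mutational pathways, excluding pathways that pass through a stop codon.
Observed proportions are corrected for multiple hits with the one-parameter
Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3).

The method is unweighted: transitions and transversions count equally, as in
the original formulation.  No maximum-likelihood codon models are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

from Bio.Data import CodonTable

from .seq_io import CodonAlignment

NUCS = "ACGT"


class SaturationError(ValueError):
    """Observed proportion >= 3/4: Jukes-Cantor distance undefined."""


class ExcludedCodonError(ValueError):
    """Codon contains a stop, gap, or ambiguous base and cannot be counted."""


class EmptyComparisonError(ValueError):
    """No comparable codon pairs remain after exclusions."""


def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Codon → amino-acid map for an NCBI translation table; stops map to '*'."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


STANDARD_CODE = genetic_code(1)


def _check_codon(codon: str, code: dict[str, str]) -> None:
    if len(codon) != 3 or any(b not in NUCS for b in codon):
        raise ExcludedCodonError(f"codon {codon!r} contains gap/ambiguous bases")
    if code[codon] == "*":
        raise ExcludedCodonError(f"codon {codon!r} is a stop codon")


def synonymous_site_fraction(
    codon: str, code: dict[str, str] = STANDARD_CODE
) -> tuple[float, float]:
    """NG86 site counts for one codon: ``(syn_sites, nonsyn_sites)``.

    Each position contributes (number of synonymous single-nt changes)/3;
    changes to stop codons count as nonsynonymous.  The two values sum to 3.
    """
    _check_codon(codon, code)
    aa = code[codon]
    syn = 0.0
    for pos in range(3):
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if code[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def codon_difference_counts(
    codon_a: str, codon_b: str, code: dict[str, str] = STANDARD_CODE
) -> tuple[float, float]:
    """Pathway-averaged ``(syn_diffs, nonsyn_diffs)`` between two codons.

    With two (three) differing positions the counts are averaged over the
    2 (6) single-step pathways; pathways whose intermediate codons are stops
    are excluded from the average.  Raises :class:`ExcludedCodonError` if
    every pathway is excluded.
    """
    _check_codon(codon_a, code)
    _check_codon(codon_b, code)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    valid = 0
    syn_total = 0.0
    nonsyn_total = 0.0
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0.0
        ok = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            # endpoints are checked sense codons; only intermediates can be stops
            if code[nxt] == "*" and step < len(order) - 1:
                ok = False
                break
            if code[nxt] == code[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            valid += 1
            syn_total += syn
            nonsyn_total += nonsyn
    if valid == 0:
        raise ExcludedCodonError(
            f"all pathways between {codon_a} and {codon_b} pass through a stop"
        )
    return syn_total / valid, nonsyn_total / valid


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = −(3/4)·ln(1 − 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4; distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """NG86 site/difference counts with Jukes–Cantor-corrected rates."""

    syn_diffs: float
    syn_sites: float
    nonsyn_diffs: float
    nonsyn_sites: float
    n_codon_pairs: int = 0

    @property
    def ps(self) -> float:
        return self.syn_diffs / self.syn_sites

    @property
    def pn(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites

    @property
    def Ks(self) -> float:
        return jukes_cantor(self.ps)

    @property
    def Ka(self) -> float:
        return jukes_cantor(self.pn)

    @property
    def ratio(self) -> float | None:
        """Ka/Ks, or ``None`` when Ks = 0 (undefined, not infinite)."""
        if self.Ks == 0.0:
            return None
        return self.Ka / self.Ks

    def to_dict(self) -> dict:
        return {
            "syn_diffs": self.syn_diffs,
            "syn_sites": self.syn_sites,
            "nonsyn_diffs": self.nonsyn_diffs,
            "nonsyn_sites": self.nonsyn_sites,
            "ps": self.ps,
            "pn": self.pn,
            "Ks": self.Ks,
            "Ka": self.Ka,
            "ratio": self.ratio,
            "n_codon_pairs": self.n_codon_pairs,
        }


@dataclass
class WindowSeries:
    """Sliding-window Ka/Ks results; ``windows`` holds (start, end, result)."""

    window_length: int
    step: int
    windows: list[tuple[int, int, KaKsResult]] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        out = []
        for start, end, res in self.windows:
            rec = {"start": start, "end": end, "midpoint": (start + end) / 2}
            rec.update(res.to_dict())
            out.append(rec)
        return out


def _codon_pairs(
    aln: CodonAlignment,
    label_a: str,
    label_b: str,
    code: dict[str, str],
    codon_range: tuple[int, int] | None = None,
) -> list[tuple[str, str]]:
    sa, sb = aln[label_a], aln[label_b]
    off = aln.frame_offset
    lo, hi = codon_range if codon_range is not None else (0, aln.n_codons)
    pairs = []
    for i in range(lo, hi):
        ca = sa[off + 3 * i : off + 3 * i + 3]
        cb = sb[off + 3 * i : off + 3 * i + 3]
        if any(b not in NUCS for b in ca + cb):
            continue  # pairwise deletion of gapped/ambiguous codons
        if code[ca] == "*" or code[cb] == "*":
            continue
        pairs.append((ca, cb))
    return pairs


def _accumulate(pairs: list[tuple[str, str]], code: dict[str, str]) -> KaKsResult:
    syn_sites = nonsyn_sites = syn_diffs = nonsyn_diffs = 0.0
    n_used = 0
    for ca, cb in pairs:
        try:
            sd, nd = codon_difference_counts(ca, cb, code)
        except ExcludedCodonError:
            warnings.warn(f"codon pair {ca}/{cb} skipped: all pathways excluded")
            continue
        s_a, n_a = synonymous_site_fraction(ca, code)
        s_b, n_b = synonymous_site_fraction(cb, code)
        syn_sites += (s_a + s_b) / 2.0
        nonsyn_sites += (n_a + n_b) / 2.0
        syn_diffs += sd
        nonsyn_diffs += nd
        n_used += 1
    if n_used == 0:
        raise EmptyComparisonError("no comparable codon pairs after exclusions")
    return KaKsResult(syn_diffs, syn_sites, nonsyn_diffs, nonsyn_sites, n_used)


def pairwise_kaks(
    aln: CodonAlignment,
    label_a: str,
    label_b: str,
    code: dict[str, str] = STANDARD_CODE,
) -> KaKsResult:
    """Full-length NG86 Ka/Ks between two sequences of the alignment."""
    return _accumulate(_codon_pairs(aln, label_a, label_b, code), code)


def sliding_window_kaks(
    aln: CodonAlignment,
    label_a: str,
    label_b: str,
    window_length: int = 150,
    step: int = 6,
    code: dict[str, str] = STANDARD_CODE,
) -> WindowSeries:
    """Ka/Ks in sliding windows along the coding sequence.

    Window coordinates are in nucleotides over the in-frame region but are
    snapped to codon boundaries (start rounded down to a codon, length to the
    nearest multiple of 3).  Windows with Ks = 0 report the ratio as missing.
    A window longer than the alignment collapses to a single full-length
    window with a warning.
    """
    if window_length <= 0 or step <= 0:
        raise ValueError("window_length and step must be positive")
    L = aln.n_codons * 3
    wl = 3 * max(1, round(window_length / 3))
    if wl > L:
        warnings.warn(
            f"window ({wl} nt) longer than alignment ({L} nt); using one full-length window"
        )
        wl = L
    series = WindowSeries(window_length=wl, step=step)
    for start in range(0, L - wl + 1, step):
        c_lo = start // 3
        c_hi = c_lo + wl // 3
        pairs = _codon_pairs(aln, label_a, label_b, code, (c_lo, c_hi))
        try:
            res = _accumulate(pairs, code)
        except EmptyComparisonError:
            continue
        series.windows.append((c_lo * 3, c_lo * 3 + wl, res))
    return series
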