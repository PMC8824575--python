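"""Strict-parsimony polarization of substitutions on a duplicate gene pair.

Given an alignment containing the young duplicate, its parent, and outgroup
orthologs of the parental gene, every variable site between the duplicates
is assigned to the branch on which the substitution occurred: the new-gene
lineage, the parental lineage, or the pre-duplication branch.  The ancestral
state at a site is the unanimous consensus of the non-missing outgroups;
disagreement among outgroups makes the site ambiguous (ambiguity is a value,
not an error).

Duplication age is estimated from the fraction of parent-lineage synonymous
substitutions shared by the duplicate: substitutions fixed between the
speciation that isolated the focal species and the duplication event appear
in both copies, so age = t_split × (1 − shared/total) under a linear
substitution clock.  This proportional reading is an interpretation; see
docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import permutations

from scipy import stats

from .kaks import NUCS, STANDARD_CODE
from .seq_io import CodonAlignment, MISSING, SpeciesTopology

AMBIGUOUS = "?"


class Assignment(str, Enum):
    NEW = "new_lineage"
    PARENTAL = "parental_lineage"
    PRE_DUPLICATION = "pre_duplication"
    AMBIGUOUS = "ambiguous"


class SubClass(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    UNCLASSIFIED = "unclassified"


@dataclass
class SiteRecord:
    position: int  # 0-based nt position in the alignment
    ancestral: str
    new_state: str
    parental_state: str
    assignment: Assignment
    sub_class: SubClass
    multi_hit: bool = False


@dataclass
class PolarizedSubstitutions:
    """Per-site substitution assignments and (assignment × class) summaries."""

    records: list[SiteRecord] = field(default_factory=list)

    def count(self, assignment: Assignment, sub_class: SubClass | None = None) -> int:
        return sum(
            1
            for r in self.records
            if r.assignment == assignment
            and (sub_class is None or r.sub_class == sub_class)
        )

    def summary(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for a in Assignment:
            out[a.value] = {
                c.value: self.count(a, c) for c in SubClass
            }
            out[a.value]["total"] = self.count(a)
        return out

    def ancestral_map(self) -> dict[int, str]:
        return {r.position: r.ancestral for r in self.records if r.ancestral in NUCS}

    def to_table(self) -> list[dict]:
        """Per-site table with 1-based positions for human-readable reports."""
        return [
            {
                "position_1based": r.position + 1,
                "ancestral": r.ancestral,
                "new_state": r.new_state,
                "parental_state": r.parental_state,
                "assignment": r.assignment.value,
                "class": r.sub_class.value,
                "multi_hit": r.multi_hit,
            }
            for r in self.records
        ]


@dataclass
class DuplicationAge:
    shared_syn: int
    lineage_syn_total: int
    t_split: float
    age: float


class UndatableError(ValueError):
    """No lineage-specific synonymous substitutions: age is unconstrained."""


def infer_ancestral_state(states: dict[str, str], topology: SpeciesTopology) -> str:
    """Outgroup-consensus ancestral base, or ``'?'`` when ambiguous.

    All non-missing outgroups must agree (strict parsimony); missing data
    (``-``/``N``) is ignored.  Disagreement, or all outgroups missing,
    yields ambiguity.
    """
    seen = {
        states[og]
        for og in topology.outgroups
        if og in states and states[og] not in MISSING
    }
    if len(seen) == 1:
        return next(iter(seen))
    return AMBIGUOUS


def _classify_codon_subs(
    anc_codon: str, der_codon: str, code: dict[str, str]
) -> dict[int, SubClass] | None:
    """Classify each differing position between an ancestral and derived codon.

    Single differences are classified directly.  With several differences the
    substitutions are applied stepwise in an ordering that avoids stop-codon
    intermediates; each step is synonymous iff it preserves the amino acid.
    Returns ``None`` if no stop-free ordering exists or either codon is
    incomplete.
    """
    if any(b not in NUCS for b in anc_codon + der_codon):
        return None
    diff = [i for i in range(3) if anc_codon[i] != der_codon[i]]
    for order in permutations(diff):
        cur = anc_codon
        classes: dict[int, SubClass] = {}
        ok = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + der_codon[pos] + cur[pos + 1 :]
            if code[nxt] == "*" and step < len(order) - 1:
                ok = False
                break
            classes[pos] = (
                SubClass.SYNONYMOUS if code[nxt] == code[cur] else SubClass.NONSYNONYMOUS
            )
            cur = nxt
        if ok:
            return classes
    return None


def polarize_substitutions(
    aln: CodonAlignment,
    topology: SpeciesTopology,
    code: dict[str, str] = STANDARD_CODE,
) -> PolarizedSubstitutions:
    """Assign every variable site between the duplicates to a lineage.

    Per site: the copy that differs from the ancestral state carries the
    substitution; a shared derived state absent from the outgroups is a
    pre-duplication substitution; if both copies carry different derived
    states, one substitution is recorded on each lineage.  Synonymous /
    nonsynonymous classification replaces the substituted position with the
    ancestral base inside the observed codon of the relevant lineage; codons
    carrying several assigned substitutions are classified stepwise and
    flagged as multi-hit.
    """
    new_l, par_l = topology.new_label, topology.parental_label
    for lab in (new_l, par_l):
        if lab not in aln.records:
            raise ValueError(f"focal label {lab!r} missing from alignment")
    present_ogs = [og for og in topology.outgroups if og in aln.records]
    if not present_ogs:
        raise ValueError("no outgroup sequences present in the alignment")

    new_seq, par_seq = aln[new_l], aln[par_l]
    off = aln.frame_offset
    result = PolarizedSubstitutions()

    # First pass: per-site raw assignment of derived states.
    # pending[codon_index][lineage] = {pos_in_codon: (nt_position, derived_base)}
    pending: dict[int, dict[str, dict[int, tuple[int, str]]]] = {}

    def queue(codon_idx: int, lineage: str, pos_in_codon: int, nt_pos: int, base: str):
        pending.setdefault(codon_idx, {}).setdefault(lineage, {})[pos_in_codon] = (
            nt_pos,
            base,
        )

    for pos in range(off, off + aln.n_codons * 3):
        states = {l: s[pos] for l, s in aln.records.items()}
        nb, pb = states[new_l], states[par_l]
        anc = infer_ancestral_state(states, topology)
        codon_idx = (pos - off) // 3
        pos_in_codon = (pos - off) % 3

        if anc == AMBIGUOUS:
            og_called = {states[og] for og in present_ogs} - MISSING
            if not og_called:
                warnings.warn(f"outgroup column entirely missing at position {pos}")
            # a variable site, or a shared state absent from the called
            # outgroup bases (candidate pre-duplication change), is recorded
            if (nb != pb) or (nb not in MISSING and og_called and nb not in og_called):
                result.records.append(
                    SiteRecord(pos, AMBIGUOUS, nb, pb, Assignment.AMBIGUOUS,
                               SubClass.UNCLASSIFIED)
                )
            continue
        if nb in MISSING or pb in MISSING:
            if nb != pb:
                result.records.append(
                    SiteRecord(pos, anc, nb, pb, Assignment.AMBIGUOUS,
                               SubClass.UNCLASSIFIED)
                )
            continue
        if nb == anc and pb == anc:
            continue
        if nb == pb:  # shared derived state
            queue(codon_idx, "pre", pos_in_codon, pos, nb)
        else:
            if nb != anc:
                queue(codon_idx, "new", pos_in_codon, pos, nb)
            if pb != anc:
                queue(codon_idx, "par", pos_in_codon, pos, pb)

    assignment_of = {
        "new": Assignment.NEW,
        "par": Assignment.PARENTAL,
        "pre": Assignment.PRE_DUPLICATION,
    }
    # Second pass: classify queued substitutions codon by codon.  The
    # classification context is the observed codon of the carrying lineage
    # with the substituted positions restored to the ancestral base.
    for codon_idx in sorted(pending):
        for lineage, subs in pending[codon_idx].items():
            carrier = new_seq if lineage in ("new", "pre") else par_seq
            obs_codon = carrier[off + 3 * codon_idx : off + 3 * codon_idx + 3]
            anc_codon = list(obs_codon)
            for pic, (nt_pos, _base) in subs.items():
                col = {l: s[nt_pos] for l, s in aln.records.items()}
                anc_codon[pic] = infer_ancestral_state(col, topology)
            anc_codon = "".join(anc_codon)
            multi = len(subs) > 1
            classes = _classify_codon_subs(anc_codon, obs_codon, code)
            for pic, (nt_pos, base) in sorted(subs.items()):
                sub_class = (
                    classes[pic] if classes is not None else SubClass.UNCLASSIFIED
                )
                result.records.append(
                    SiteRecord(
                        nt_pos,
                        anc_codon[pic],
                        new_seq[nt_pos],
                        par_seq[nt_pos],
                        assignment_of[lineage],
                        sub_class,
                        multi_hit=multi,
                    )
                )
    result.records.sort(key=lambda r: (r.position, r.assignment.value))
    return result


def date_duplication(
    shared_syn: int, lineage_syn_total: int, t_split: float = 5.25
) -> DuplicationAge:
    """Date a duplication from shared parent-lineage synonymous substitutions.

    ``age = t_split × (1 − shared_syn/lineage_syn_total)``: substitutions
    shared by the two copies predate the duplication, so a larger shared
    fraction pushes the duplication closer to the present.  ``t_split`` is
    the speciation time in Myr (default 5.25, the focal-species split).
    """
    if lineage_syn_total <= 0:
        raise UndatableError("no lineage-specific synonymous substitutions to date with")
    if not 0 <= shared_syn <= lineage_syn_total:
        raise ValueError("shared_syn must lie in [0, lineage_syn_total]")
    age = t_split * (1.0 - shared_syn / lineage_syn_total)
    return DuplicationAge(shared_syn, lineage_syn_total, t_split, age)


def asymmetry_test(n_new: int, n_parental: int) -> tuple[float, int, float]:
    """Goodness-of-fit χ² of per-lineage substitution counts against 50:50.

    Neutrality predicts equal substitution accumulation on the two duplicate
    lineages.  No continuity correction; df = 1.
    """
    if n_new < 0 or n_parental < 0:
        raise ValueError("counts must be nonnegative")
    total = n_new + n_parental
    if total == 0:
        raise ValueError("both counts are zero; test undefined")
    exp = total / 2.0
    chi2 = (n_new - exp) ** 2 / exp + (n_parental - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p
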