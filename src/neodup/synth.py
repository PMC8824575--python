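"""Synthetic-data generators with exact, serialisable ground truth.

Every generator takes an integer seed, uses a single ``numpy`` generator per
call, and returns its dataset together with a :class:`SimTruth` record that
fully determines the expected value of every estimator run on the data.

Sequence simulation is substitution-count-driven by default: the requested
numbers of synonymous/nonsynonymous substitutions are planted at distinct
codon sites and classified by construction, so parsimony polarization has an
exact truth to recover.  A Poisson ω-targeted mode
(:func:`simulate_pair_omega`) exists for Ka/Ks estimator-recovery tests.
Population samples draw segregating-site frequencies from the neutral
site-frequency spectrum (P(i) ∝ 1/i), a genealogy-free approximation
adequate for mean-zero calibration of the SFS statistics.  Near-fixed
derived sites are planted with the non-derived remainder as missing data,
mirroring panels where the ancestral allele is undetected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kaks import NUCS, STANDARD_CODE
from .pheno import TRAIT_COLUMNS
from .popgen import harmonic
from .seq_io import CodonAlignment

SENSE_CODONS = sorted(c for c, aa in STANDARD_CODE.items() if aa != "*")


class PlacementError(RuntimeError):
    """Requested substitutions cannot be placed on the sequence."""


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    substitutions: dict = field(default_factory=dict)  # lineage -> list of site records
    polymorphisms: list = field(default_factory=list)
    omega: dict = field(default_factory=dict)
    phenotype: dict = field(default_factory=dict)

    def counts(self, lineage: str, sub_class: str | None = None) -> int:
        recs = self.substitutions.get(lineage, [])
        return sum(1 for r in recs if sub_class is None or r["class"] == sub_class)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _mutation_options(codon: str, sub_class: str) -> list[tuple[int, str]]:
    """All (position, alternative base) single-nt changes of the given class."""
    aa = STANDARD_CODE[codon]
    opts = []
    for pos in range(3):
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if STANDARD_CODE[mut] == "*":
                continue
            syn = STANDARD_CODE[mut] == aa
            if (sub_class == "synonymous") == syn:
                opts.append((pos, alt))
    return opts


def _place_substitutions(
    rng: np.random.Generator,
    ancestor: list[str],
    free_sites: list[int],
    requests: list[tuple[str, str]],  # (lineage, class)
) -> dict[str, list[dict]]:
    """Assign each requested substitution to a distinct codon site."""
    placed: dict[str, list[dict]] = {}
    pool = list(free_sites)
    rng.shuffle(pool)
    for lineage, sub_class in requests:
        for idx, site in enumerate(pool):
            opts = _mutation_options(ancestor[site], sub_class)
            if opts:
                pos, alt = opts[rng.integers(len(opts))]
                placed.setdefault(lineage, []).append(
                    {
                        "codon": site,
                        "nt_pos": 3 * site + pos,
                        "from": ancestor[site][pos],
                        "to": alt,
                        "class": sub_class,
                    }
                )
                pool.pop(idx)
                break
        else:
            raise PlacementError(
                f"no site available for a {sub_class} substitution ({lineage})"
            )
    free_sites[:] = pool
    return placed


def _apply(seq: list[str], subs: list[dict]) -> None:
    for s in subs:
        codon = seq[s["codon"]]
        pos = s["nt_pos"] % 3
        seq[s["codon"]] = codon[:pos] + s["to"] + codon[pos + 1 :]


def simulate_duplicate_pair(
    n_codons: int,
    subs_new: tuple[int, int] = (0, 0),
    subs_par: tuple[int, int] = (0, 0),
    subs_shared: tuple[int, int] = (0, 0),
    n_outgroups: int = 2,
    outgroup_extra_subs: int = 0,
    seed: int = 0,
) -> tuple[CodonAlignment, SimTruth]:
    """Simulate a duplicate pair plus outgroup orthologs with planted history.

    ``subs_*`` are ``(synonymous, nonsynonymous)`` counts for the new-gene
    lineage, the parental lineage, and the shared pre-duplication branch.
    Each substitution occupies its own codon, so classification and lineage
    assignment are exact by construction.  Outgroups carry the ancestral
    state plus ``outgroup_extra_subs`` private changes spread over the
    outgroups at otherwise untouched codons.
    """
    rng = np.random.default_rng(seed)
    total = sum(subs_new) + sum(subs_par) + sum(subs_shared) + outgroup_extra_subs
    if total > n_codons:
        raise PlacementError(f"{total} substitutions cannot occupy {n_codons} codons")
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    free = list(range(n_codons))

    requests = (
        [("new", "synonymous")] * subs_new[0]
        + [("new", "nonsynonymous")] * subs_new[1]
        + [("par", "synonymous")] * subs_par[0]
        + [("par", "nonsynonymous")] * subs_par[1]
        + [("shared", "synonymous")] * subs_shared[0]
        + [("shared", "nonsynonymous")] * subs_shared[1]
    )
    og_labels = [f"og{i + 1}" for i in range(n_outgroups)]
    for i in range(outgroup_extra_subs):
        cls = "synonymous" if rng.random() < 0.5 else "nonsynonymous"
        requests.append((og_labels[i % n_outgroups], cls))
    placed = _place_substitutions(rng, ancestor, free, requests)

    new_seq = list(ancestor)
    par_seq = list(ancestor)
    _apply(new_seq, placed.get("shared", []))
    _apply(par_seq, placed.get("shared", []))
    _apply(new_seq, placed.get("new", []))
    _apply(par_seq, placed.get("par", []))
    records = {"new": "".join(new_seq), "parent": "".join(par_seq)}
    for og in og_labels:
        og_seq = list(ancestor)
        _apply(og_seq, placed.get(og, []))
        records[og] = "".join(og_seq)

    truth = SimTruth(
        seed=seed,
        params={
            "n_codons": n_codons,
            "subs_new": list(subs_new),
            "subs_par": list(subs_par),
            "subs_shared": list(subs_shared),
            "n_outgroups": n_outgroups,
            "outgroup_extra_subs": outgroup_extra_subs,
            "ancestor": "".join(ancestor),
        },
        substitutions={k: v for k, v in placed.items()},
    )
    return CodonAlignment(records), truth


def simulate_pair_omega(
    n_codons: int,
    omega: float = 0.5,
    mutations_per_lineage: int = 600,
    seed: int = 0,
) -> tuple[CodonAlignment, SimTruth]:
    """Two sequences diverged under a target dN/dS ratio ω.

    Each lineage receives a Poisson number of proposed single-nucleotide
    changes at uniform positions; synonymous proposals are always accepted,
    nonsynonymous ones with probability ω, and proposals creating stop
    codons are rejected — so the expected estimated Ka/Ks equals ω.
    """
    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    seqs = {}
    accepted = {}
    for label in ("new", "parent"):
        seq = list(ancestor)
        n_mut = rng.poisson(mutations_per_lineage)
        n_acc = 0
        for _ in range(n_mut):
            site = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            alt = NUCS[int(rng.integers(4))]
            codon = seq[site]
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if STANDARD_CODE[mut] == "*":
                continue
            if STANDARD_CODE[mut] != STANDARD_CODE[codon] and rng.random() >= omega:
                continue
            seq[site] = mut
            n_acc += 1
        seqs[label] = "".join(seq)
        accepted[label] = n_acc
    truth = SimTruth(
        seed=seed,
        params={
            "n_codons": n_codons,
            "mutations_per_lineage": mutations_per_lineage,
            "accepted": accepted,
            "ancestor": "".join(ancestor),
        },
        omega={"new": omega, "parent": omega},
    )
    return CodonAlignment(seqs), truth


def simulate_population(
    n: int,
    n_codons: int,
    theta: float,
    near_fixed: int = 0,
    near_fixed_freq: float = 1.0,
    include_outgroup: bool = False,
    seed: int = 0,
) -> tuple[CodonAlignment, SimTruth]:
    """Within-species allele sample under the neutral frequency spectrum.

    ``theta`` is the per-locus population mutation parameter; the number of
    segregating sites is Poisson with mean θ·a1 and derived-allele counts i
    are drawn with P(i) ∝ 1/i.  ``near_fixed`` derived sites are planted at
    frequency ``near_fixed_freq`` with the remaining alleles missing ('N'),
    so the ancestral allele is absent from the sample.  When
    ``include_outgroup`` is set, a record labelled ``outgroup`` carrying the
    ancestral sequence is appended for polarized statistics.
    """
    if n < 2:
        raise ValueError("need a sample of at least two alleles")
    rng = np.random.default_rng(seed)
    L = 3 * n_codons
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    anc_nt = "".join(ancestor)
    sample = np.frombuffer((anc_nt * n).encode(), dtype="S1").reshape(n, L).copy()

    S = int(rng.poisson(theta * harmonic(n))) if theta > 0 else 0
    if S + near_fixed > L:
        raise PlacementError("more planted sites than sequence positions")
    sites = rng.choice(L, size=S + near_fixed, replace=False)
    seg_sites, fixed_sites = sites[:S], sites[S:]

    freqs = np.arange(1, n)
    p = (1.0 / freqs) / (1.0 / freqs).sum()
    planted = []
    for pos in seg_sites:
        pos = int(pos)
        anc_base = anc_nt[pos]
        alt = NUCS[int(rng.integers(4))]
        while alt == anc_base:
            alt = NUCS[int(rng.integers(4))]
        i = int(rng.choice(freqs, p=p))
        carriers = rng.choice(n, size=i, replace=False)
        sample[carriers, pos] = alt.encode()
        planted.append({"nt_pos": pos, "from": anc_base, "to": alt,
                        "derived_count": i, "kind": "segregating"})
    k_fixed = int(round(near_fixed_freq * n))
    for pos in fixed_sites:
        pos = int(pos)
        anc_base = anc_nt[pos]
        alt = NUCS[int(rng.integers(4))]
        while alt == anc_base:
            alt = NUCS[int(rng.integers(4))]
        sample[:, pos] = alt.encode()
        if k_fixed < n:
            missing = rng.choice(n, size=n - k_fixed, replace=False)
            sample[missing, pos] = b"N"
        planted.append({"nt_pos": pos, "from": anc_base, "to": alt,
                        "derived_count": k_fixed, "kind": "near_fixed"})

    records = {
        f"allele{i + 1}": sample[i].tobytes().decode() for i in range(n)
    }
    if include_outgroup:
        records["outgroup"] = anc_nt
    truth = SimTruth(
        seed=seed,
        params={"n": n, "n_codons": n_codons, "theta": theta,
                "near_fixed": near_fixed, "near_fixed_freq": near_fixed_freq,
                "ancestor": anc_nt, "S": S},
        polymorphisms=planted,
    )
    return CodonAlignment(records), truth


def simulate_mk_population(
    n: int,
    n_codons: int,
    poly_syn: int,
    poly_nonsyn: int,
    fixed_syn: int,
    fixed_nonsyn: int,
    seed: int = 0,
) -> tuple[CodonAlignment, CodonAlignment, SimTruth]:
    """Population sample with classified planted polymorphisms and divergence.

    Returns ``(pop_alignment, representative_alignment, truth)``: the
    population sample of the new gene carries exactly the requested numbers
    of synonymous/nonsynonymous segregating sites and fixed differences
    (each in its own codon, classified by construction); the representative
    alignment holds the new-gene consensus, the parental sequence, and two
    outgroups (all ancestral) ready for polarization.
    """
    rng = np.random.default_rng(seed)
    total = poly_syn + poly_nonsyn + fixed_syn + fixed_nonsyn
    if total > n_codons:
        raise PlacementError("more planted events than codons")
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    free = list(range(n_codons))
    requests = (
        [("fixed", "synonymous")] * fixed_syn
        + [("fixed", "nonsynonymous")] * fixed_nonsyn
        + [("poly", "synonymous")] * poly_syn
        + [("poly", "nonsynonymous")] * poly_nonsyn
    )
    placed = _place_substitutions(rng, ancestor, free, requests)

    consensus = list(ancestor)
    _apply(consensus, placed.get("fixed", []))
    cons_nt = "".join(consensus)
    L = 3 * n_codons
    sample = np.frombuffer((cons_nt * n).encode(), dtype="S1").reshape(n, L).copy()
    for rec in placed.get("poly", []):
        i = int(rng.integers(1, n))  # derived count 1..n-1
        carriers = rng.choice(n, size=i, replace=False)
        sample[carriers, rec["nt_pos"]] = rec["to"].encode()
        rec["derived_count"] = i

    pop = CodonAlignment(
        {f"allele{i + 1}": sample[i].tobytes().decode() for i in range(n)}
    )
    anc_nt = "".join(ancestor)
    rep = CodonAlignment(
        {"new": cons_nt, "parent": anc_nt, "og1": anc_nt, "og2": anc_nt}
    )
    truth = SimTruth(
        seed=seed,
        params={"n": n, "n_codons": n_codons, "ancestor": anc_nt,
                "poly_syn": poly_syn, "poly_nonsyn": poly_nonsyn,
                "fixed_syn": fixed_syn, "fixed_nonsyn": fixed_nonsyn},
        substitutions={"new": placed.get("fixed", [])},
        polymorphisms=placed.get("poly", []),
    )
    return pop, rep, truth


def simulate_null_genes(
    n_genes: int,
    n: int,
    n_codons: int,
    theta: float,
    seed: int = 0,
):
    """Per-gene neutrality statistics for an empirical genome-wide null.

    Simulates ``n_genes`` independent neutral loci and tabulates S, π, θ_w,
    Tajima's D, Fu & Li's D*/F*, and Fay & Wu's H (polarized against the
    true ancestral sequence) for each.
    """
    import pandas as pd

    from . import popgen

    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        sub_seed = int(rng.integers(2**31 - 1))
        aln, _ = simulate_population(
            n, n_codons, theta, include_outgroup=True, seed=sub_seed
        )
        div = popgen.diversity(aln, exclude=("outgroup",))
        fl = popgen.fu_li(aln, outgroup_label="outgroup")
        rows.append(
            {
                "gene": f"gene{g + 1}",
                "n": div.n,
                "S": div.S,
                "pi": div.pi,
                "theta_w": div.theta_w,
                "tajima_d": popgen.tajimas_d(aln, exclude=("outgroup",)),
                "fu_li_dstar": fl.dstar,
                "fu_li_fstar": fl.fstar,
                "fay_wu_h": popgen.fay_wu_h(aln, "outgroup"),
            }
        )
    return pd.DataFrame(rows)


def simulate_phenotypes(
    genotypes: list[str],
    means: dict[str, np.ndarray],
    cov: np.ndarray,
    n_per: int,
    seed: int = 0,
):
    """Multivariate-Gaussian trait populations, one block per genotype."""
    import pandas as pd

    if n_per <= 0:
        raise ValueError("n_per must be positive")
    cov = np.asarray(cov, dtype=float)
    if cov.shape[0] != cov.shape[1] or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be square and symmetric")
    if np.linalg.eigvalsh(cov).min() < -1e-9:
        raise ValueError("covariance must be positive semidefinite")
    k = cov.shape[0]
    names = TRAIT_COLUMNS if k == len(TRAIT_COLUMNS) else [f"trait{i+1}" for i in range(k)]
    rng = np.random.default_rng(seed)
    frames = []
    for g in genotypes:
        mu = np.asarray(means[g], dtype=float)
        if mu.shape != (k,):
            raise ValueError(f"mean vector for {g!r} has wrong length")
        X = rng.multivariate_normal(mu, cov, size=n_per)
        df = pd.DataFrame(X, columns=names)
        df.insert(0, "genotype", g)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
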