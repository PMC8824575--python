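import dendropy
import pytest

from neodup.seq_io import CodonAlignment, SpeciesTopology


def make_topology(
    new: str = "new", par: str = "parent", outgroups: tuple[str, ...] = ("og1", "og2")
) -> SpeciesTopology:
    newick = f"(({new},{par}),({','.join(outgroups)}));"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return SpeciesTopology(tree, (new, par), list(outgroups))


@pytest.fixture
def topology() -> SpeciesTopology:
    return make_topology()


@pytest.fixture
def tiny_alignment() -> CodonAlignment:
    # one synonymous (CTT->CTC) and one nonsynonymous (ATG->AAG) change on "new"
    return CodonAlignment(
        {
            "new": "CTCAAGGGA",
            "parent": "CTTATGGGA",
            "og1": "CTTATGGGA",
            "og2": "CTTATGGGA",
        }
    )


def write_fasta(path, records: dict[str, str]) -> str:
    with open(path, "w") as fh:
        for label, seq in records.items():
            fh.write(f">{label}\n{seq}\n")
    return str(path)
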