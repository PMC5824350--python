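import pytest

from miprimer.design import DesignConfig
from miprimer.seqio import MiRNA, SequencePanel, group_families
from miprimer.thermo import ThermoParams


@pytest.fixture(scope="session")
def params():
    return ThermoParams()


@pytest.fixture(scope="session")
def cfg():
    return DesignConfig()


@pytest.fixture(scope="session")
def mir18_panel():
    """The miR-18 single-nucleotide family plus a dissimilar singleton."""
    members = [
        MiRNA("hsa-miR-18a-5p", "UAAGGUGCAUCUAGUGCAGAUAG"),
        MiRNA("hsa-miR-18b-5p", "UAAGGUGCAUCUAGUGCAGUUAG"),
        MiRNA("hsa-miR-122-5p", "UGGAGUGUGACAAUGGUGUUUG"),
    ]
    return group_families(SequencePanel(members=members), 90.0)


@pytest.fixture(scope="session")
def let7_like_family():
    """Eight 22-mers pairwise differing at 1-2 clustered central positions.

    Substitutions sit at three adjacent sites (9-11) with varied bases, so
    every pairwise difference falls inside the 3'-terminal window of an
    overlap design anchored at the central discriminating position.
    """
    seed = "UGAGGUAGUAGGUUGUAUAGUU"
    alts = {"A": "GCU", "G": "ACU", "C": "AGU", "U": "AGC"}
    members = [MiRNA("fam-a", seed)]
    for k in range(1, 8):
        pos = 9 + (k - 1) // 3
        s = list(seed)
        s[pos] = alts[s[pos]][(k - 1) % 3]
        members.append(MiRNA(f"fam-{chr(ord('a') + k)}", "".join(s)))
    return members
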