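"""Deterministic synthetic panels, template mimics and simulated Cq data.

The generator emulates the shape of a realistic design study: a panel of
mutually dissimilar singleton miRNAs plus a set of families whose members
derive from a common seed sequence by one or two substitutions (the
single-nucleotide-family regime that makes discrimination hard).  The
default shape is 90 singletons plus 17 families totalling 30 members.

Template mimics reproduce the poly(A)-tailed universal-RT cDNA layout:
universal tag, dT stretch, then the reverse complement of the mature
sequence.  Simulated Cq wells follow a configured standard-curve line
with Gaussian noise; heterologous wells are shifted by a mismatch penalty
keyed on the in-silico discrimination class, and NTC wells amplify with a
small configured probability.  Everything is bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqio
from .design import DesignConfig, DesignResult, predict_discrimination
from .seqio import MiRNA, SequencePanel, reverse_complement

#: Published universal RT primer oligo: universal tag + oligo-dT, stored
#: as the literal string.  The dT count beyond the 24-nt tag is 19; the
#: terminal T run is 20 when the tag's own final T is included, which is
#: how the "20 dT" convention counts it.
UNIVERSAL_RT_PRIMER = "CAACTCAGGTCGTAGGCAATTCGTTTTTTTTTTTTTTTTTTTT"
RT_DT_LENGTH = len(UNIVERSAL_RT_PRIMER) - len("CAACTCAGGTCGTAGGCAATTCGT")

#: Synthetic mismatch penalties (Cq shift) per discrimination class.
#: Purely simulation knobs, not derived from any measurement.
DEFAULT_MISMATCH_PENALTY = {
    "discriminating": 8.0,
    "weak": 4.0,
    "non-discriminating": 0.5,
}


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    rng_seed: int = 0
    n_singletons: int = 90
    # 17 family groups totalling 30 members: groups of >= 2 are true
    # sequence families; size-1 groups are family-labelled miRNAs whose
    # relatives are absent from the panel (17 groups x >= 2 members cannot
    # sum to 30, so the benchmark shape requires some singleton groups).
    family_sizes: tuple[int, ...] = (2,) * 13 + (1,) * 4
    n_diffs_per_family: int = 1
    length_range: tuple[int, int] = (18, 25)
    gc_range: tuple[float, float] = (0.30, 0.70)
    cq_noise_sd: float = 0.1
    ntc_rate: float = 0.02
    similarity_threshold: float = 90.0

    def __post_init__(self):
        lo, hi = self.length_range
        if lo > hi or lo < seqio.MIN_MIRNA_LEN or hi > seqio.MAX_MIRNA_LEN:
            raise FixtureError(f"length range {self.length_range} infeasible")
        if self.gc_range[0] > self.gc_range[1]:
            raise FixtureError("empty gc range")
        if any(s < 1 for s in self.family_sizes):
            raise FixtureError("family sizes must be >= 1")
        if self.n_diffs_per_family not in (1, 2):
            raise FixtureError("n_diffs_per_family must be 1 or 2")


def _random_mirna_seq(rng: np.random.Generator, spec: FixtureSpec) -> str:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGU"), size=length))
        gc = (seq.count("G") + seq.count("C")) / length
        if spec.gc_range[0] <= gc <= spec.gc_range[1]:
            return seq
    raise FixtureError("could not sample a sequence inside the GC range")


def generate_panel(spec: FixtureSpec) -> SequencePanel:
    """Seeded panel of singletons and substitution-derived families.

    Singletons are rejection-sampled to stay below the similarity
    threshold against every previously accepted member; family members
    apply ``n_diffs_per_family`` central substitutions to a family seed
    sequence.  Ground-truth family labels are returned on the panel.
    """
    rng = np.random.default_rng(spec.rng_seed)
    members: list[MiRNA] = []
    labels: dict[str, str] = {}

    accepted: list[MiRNA] = []
    attempts = 0
    while len(accepted) < spec.n_singletons:
        attempts += 1
        if attempts > 200 * max(1, spec.n_singletons):
            raise FixtureError("singleton rejection sampling did not converge")
        cand = MiRNA(f"syn-mir-{len(accepted) + 1:03d}", _random_mirna_seq(rng, spec))
        if all(
            seqio.pairwise_similarity(cand, m) < spec.similarity_threshold
            for m in accepted
        ):
            accepted.append(cand)
    for m in accepted:
        members.append(m)
        labels[m.id] = m.id

    for fam_idx, size in enumerate(spec.family_sizes, start=1):
        fam_label = f"syn-fam-{fam_idx:02d}"
        for _ in range(200):
            seed_seq = _random_mirna_seq(rng, spec)
            seed = MiRNA(f"{fam_label}-a", seed_seq)
            if all(
                seqio.pairwise_similarity(seed, m) < spec.similarity_threshold
                for m in members
            ):
                break
        else:
            raise FixtureError("family seed sampling did not converge")
        fam_members = [seed]
        length = len(seed_seq)
        centre = length // 2
        alts = {"A": "GCU", "G": "ACU", "C": "AGU", "U": "AGC"}
        # clustered central substitutions with varied bases: every pairwise
        # difference stays within one base of the centre+1 site, so an
        # overlap design's 3'-terminal window covers it.  The middle site
        # is used most, making it the seed member's discriminating choice.
        site_alloc = [(1, 0), (1, 1), (1, 2), (0, 0), (0, 1), (2, 0), (2, 1), (0, 2), (2, 2)]
        if size - 1 > len(site_alloc):
            raise FixtureError(f"family size {size} exceeds the supported maximum of 10")
        for k in range(1, size):
            site_off, alt_i = site_alloc[k - 1]
            seq = list(seed_seq)
            for d in range(spec.n_diffs_per_family):
                p = centre + site_off + d
                seq[p] = alts[seq[p]][alt_i]
            fam_members.append(MiRNA(f"{fam_label}-{chr(ord('a') + k)}", "".join(seq)))
        for m in fam_members:
            members.append(m)
            labels[m.id] = fam_label

    return SequencePanel(members=members, family_assignment=labels)


def build_template_mimic(mirna: MiRNA, cfg: DesignConfig | None = None) -> str:
    """Single-stranded cDNA mimic: universal tag + dT stretch + rc(miRNA).

    Mirrors the synthetic templates used to validate designs in vitro:
    the universal RT primer sequence followed by the reverse complement of
    the mature miRNA (DNA alphabet), 5'->3'.
    """
    cfg = cfg or DesignConfig()
    return UNIVERSAL_RT_PRIMER + reverse_complement(mirna.dna)


def anneals_to_mimic(result: DesignResult, mirna: MiRNA, cfg: DesignConfig | None = None) -> bool:
    """In-silico annealing of a design against a template mimic.

    The forward primer's core must match the template's reverse strand
    (i.e. appear verbatim in rc(mimic)) and the reverse primer's specific
    3' part must match the template itself, both with exact 3'-terminal
    pairing -- the minimal requirement for polymerase extension.
    """
    cfg = cfg or DesignConfig()
    mimic = build_template_mimic(mirna, cfg)
    sense = reverse_complement(mimic)  # the strand the forward primer copies
    fwd_core = result.forward.segment("core") if result.forward else ""
    ok_f = bool(fwd_core) and fwd_core in sense
    rev_spec = result.reverse.segment("specific_3prime") if result.reverse else ""
    if rev_spec:
        ok_r = rev_spec in mimic
    else:
        ok_r = True  # universal reverse anneals to the tag on every mimic
    return ok_f and ok_r


@dataclass
class SimulatedWells:
    wells: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_cq(
    panel: SequencePanel,
    designs: dict[str, DesignResult],
    curve: tuple[float, float],
    spec: FixtureSpec,
    *,
    log10_copies: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0),
    replicates: int = 3,
    n_ntc: int = 0,
    cross_templates: bool = True,
    penalty: dict[str, float] | None = None,
) -> SimulatedWells:
    """Simulate a well table for the metrics module.

    Homologous wells follow Cq = intercept + slope*log10(copies) + noise;
    heterologous wells (within-family template swaps) add a mismatch
    penalty per the design's predicted discrimination class; NTC wells
    amplify with probability ``spec.ntc_rate`` at a high Cq.
    """
    slope, intercept = curve
    if slope >= 0:
        raise FixtureError("standard-curve slope must be negative")
    penalty = dict(DEFAULT_MISMATCH_PENALTY, **(penalty or {}))
    rng = np.random.default_rng(spec.rng_seed + 1)
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, spec.cq_noise_sd)) if spec.cq_noise_sd > 0 else 0.0

    for assay_id, result in designs.items():
        target = panel.get(assay_id)
        for x in log10_copies:
            for _ in range(replicates):
                rows.append(
                    {
                        "assay_id": assay_id,
                        "template_id": assay_id,
                        "cq": intercept + slope * x + noise(),
                        "is_ntc": False,
                        "log10_copies": x,
                    }
                )
        if cross_templates:
            others = [m for m in panel.family_of(assay_id) if m.id != assay_id]
            classes = predict_discrimination(result, others)
            for other in others:
                shift = penalty[classes[other.id]]
                x = log10_copies[-1]
                for _ in range(replicates):
                    rows.append(
                        {
                            "assay_id": assay_id,
                            "template_id": other.id,
                            "cq": intercept + slope * x + shift + noise(),
                            "is_ntc": False,
                            "log10_copies": x,
                        }
                    )
        for _ in range(n_ntc):
            positive = bool(rng.random() < spec.ntc_rate)
            rows.append(
                {
                    "assay_id": assay_id,
                    "template_id": "NTC",
                    "cq": (38.0 + noise()) if positive else np.nan,
                    "is_ntc": True,
                    "log10_copies": np.nan,
                }
            )
    wells = pd.DataFrame(rows, columns=["assay_id", "template_id", "cq", "is_ntc", "log10_copies"])
    truth = {"slope": slope, "intercept": intercept, "penalty": penalty, "ntc_rate": spec.ntc_rate}
    return SimulatedWells(wells=wells, truth=truth)
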