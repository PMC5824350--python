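"""Reference mature miRNA sequences used in examples and validation.

Canonical human mature sequences (miRBase) for the families that qPCR
primer-design methods are benchmarked on: the miR-18 and miR-16 families
(single- and multi-nucleotide discrimination) and the let-7 family, plus
a few common singletons.
"""

from .seqio import MiRNA, SequencePanel, group_families

MATURE_SEQUENCES = {
    "hsa-miR-18a-5p": "UAAGGUGCAUCUAGUGCAGAUAG",
    "hsa-miR-18b-5p": "UAAGGUGCAUCUAGUGCAGUUAG",
    "hsa-miR-16-5p": "UAGCAGCACGUAAAUAUUGGCG",
    "hsa-miR-195-5p": "UAGCAGCACAGAAAUAUUGGC",
    "hsa-let-7a-5p": "UGAGGUAGUAGGUUGUAUAGUU",
    "hsa-let-7b-5p": "UGAGGUAGUAGGUUGUGUGGUU",
    "hsa-let-7c-5p": "UGAGGUAGUAGGUUGUAUGGUU",
    "hsa-let-7d-5p": "AGAGGUAGUAGGUUGCAUAGUU",
    "hsa-let-7e-5p": "UGAGGUAGGAGGUUGUAUAGUU",
    "hsa-let-7f-5p": "UGAGGUAGUAGAUUGUAUAGUU",
    "hsa-let-7g-5p": "UGAGGUAGUAGUUUGUACAGUU",
    "hsa-let-7i-5p": "UGAGGUAGUAGUUUGUGCUGUU",
    "hsa-miR-9-5p": "UCUUUGGUUAUCUAGCUGUAUGA",
    "hsa-miR-122-5p": "UGGAGUGUGACAAUGGUGUUUG",
    "hsa-miR-10a-5p": "UACCCUGUAGAUCCGAAUUUGUG",
    "hsa-miR-21-5p": "UAGCUUAUCAGACUGAUGUUGA",
}


def reference_panel(ids=None, similarity_threshold: float = 90.0) -> SequencePanel:
    """A grouped panel of the reference sequences (or a subset by id)."""
    ids = list(MATURE_SEQUENCES) if ids is None else list(ids)
    panel = SequencePanel(members=[MiRNA(i, MATURE_SEQUENCES[i]) for i in ids])
    return group_families(panel, similarity_threshold)


def mir18b_forward(cfg=None):
    """Forward primer for hsa-miR-18b-5p, reconstructed by the design engine.

    The miR-18 family (18a/18b, single-nucleotide difference) is the
    canonical overlap-design benchmark; the engine's overlap procedure
    yields the forward primer whose 3'-terminal base sits on the
    discriminating nucleotide.
    """
    from .design import DesignConfig, design

    cfg = cfg or DesignConfig()
    panel = reference_panel(["hsa-miR-18a-5p", "hsa-miR-18b-5p"])
    result = design(panel.get("hsa-miR-18b-5p"), panel, cfg)
    return result.forward


def mir16_forward(cfg=None):
    """Forward primer for hsa-miR-16-5p, reconstructed by the design engine.

    miR-16-5p and miR-195-5p are treated as one family (the annotated
    miR-16 family) even though their full-length identity falls below the
    90% threshold; the forward-primer-major (FPM) procedure is the one
    validated for this family, so it is applied directly.
    """
    from .design import DesignConfig, design_fr_fpm

    cfg = cfg or DesignConfig()
    panel = reference_panel(["hsa-miR-16-5p", "hsa-miR-195-5p"])
    family = [panel.get("hsa-miR-16-5p"), panel.get("hsa-miR-195-5p")]
    result = design_fr_fpm(family[0], family, cfg)
    return result.forward
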