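# miprimer

Rule-based qPCR primer design for mature microRNAs.

Mature miRNAs are only 18–25 nt long — barely longer than a primer — so
designing specific qPCR primers for them is hard, and harder still for
miRNA *family* members that differ by a single nucleotide (let-7a vs
let-7c, miR-18a vs miR-18b). `miprimer` implements an empirical,
fully deterministic design method for the poly(A)-tailed universal
reverse-transcription assay format: miRNAs are polyadenylated and reverse
transcribed with a tag+oligo-dT primer, giving every target a common
amplicon backbone; the package then designs the qPCR primer pair on top
of that backbone. It is a library plus a thin CLI, aimed at assay
developers and bioinformaticians building miRNA qPCR panels.

## The method

Two systems cover every target:

* **uni-system** — a target-specific forward primer (the 5′ 12–18 nt of
  the mature sequence, optionally extended with bases from the degenerate
  5′ tail `CGWTSSRCRC`) paired with the fixed universal reverse primer
  `CAACTCAGGTCGTAGGCAATTCGT`. Used when the target is < 90 % identical to
  every other panel member. If dimers with the universal primer cannot be
  cleared, the reverse is replaced by a redesigned specific reverse
  (2–8 complementary 3′ nt + a 20-dT stretch + universal 5′ bases).
* **specific-FR-system** — two target-specific primers for family
  members, in three escalating variants: *overlap* (forward and reverse
  overlap by 1–2 nt exactly at a nucleotide that differs between family
  members, putting the discriminating base at both 3′ termini), *FPM*
  (forward-primer major) and *RPM* (reverse-primer major).

Every design iterates an **adjustment** step (melting temperatures
balanced to within 2 °C by extending the cooler primer) and a
**confirmation** step (self- and hetero-dimer ΔG gated at
−9.0 ± 1 kcal/mol, with tail-alternative cycling and 3′ trimming as
remediation). Thermodynamics use the unified nearest-neighbor DNA
parameters:

  Tm = 1000·ΔH / (ΔS + R·ln(C/2×10⁹)) − 273.15  (R = 1.987 cal·mol⁻¹·K⁻¹, C in nM)

Dimer ΔG37 comes from a deterministic ungapped register scan (every
contiguous Watson–Crick run at every antiparallel offset, scored as
stacks + initiation), with an optional ViennaRNA cofold backend using DNA
parameters for structured dimers. Validation arithmetic is included:
standard-curve efficiency `(10^(−1/slope) − 1)·100 %`, cross-reactivity
`10^(ΔCq/S)·100 %`, and the no-template-control false-positive rate.

## Worked example

Generate a small synthetic panel (two singletons plus one two-member
family differing at one nucleotide), design primers for every member, and
fit standard curves from simulated wells:

```
$ miprimer simulate --seed 3 --singletons 2 --families 1 --outdir sim --ntc 100
panel of 4 members -> sim
$ miprimer design --fasta sim/panel.fa --out primers.tsv --log design.log
designed 4 targets (0 failed) -> primers.tsv
```

`primers.tsv` (abridged):

```
target_id     strategy    fwd_seq                 fwd_tm  rev_seq                   rev_tm  status
syn-mir-001   UNI         TCCACACAAAATTGAACCGCCA  74.17   CAACTCAGGTCGTAGGCAATTCGT  75.44   ok
syn-fam-01-a  FR_OVERLAP  CACATGGACATCACG         60.68   CGTACCCTGGCC              59.36   ok
syn-fam-01-b  FR_OVERLAP  CACATGGACATCACA         59.22   CGTACCCTGGCT              57.63   ok
```

The singleton got a tailed forward (`TCCACAC…` is a tail fragment)
against the universal reverse, Tm-balanced to within 2 °C of its 75.4 °C.
The family members got overlap designs: their forward primers end exactly
on the nucleotide that differs (…ACG vs …ACA), and each reverse primer's
3′ end pairs that same base, so either primer blocks extension on the
sibling's template.

```
$ miprimer metrics efficiency --in sim/wells.tsv --out eff.tsv
assay_id      slope    intercept  r_squared  efficiency_pct
syn-fam-01-a  -3.3699  40.2284    0.9997     98.0371
syn-fam-01-b  -3.2865  39.8952    1.0000     101.5003
```

Efficiencies near 100 % correspond to slopes near −3.32 Cq per 10-fold
dilution (perfect doubling). `miprimer selfcheck` cross-checks the
register-scan ΔG engine against brute-force enumeration.

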