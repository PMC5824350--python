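# Methods

## Scope and model

`miprimer` designs qPCR primer pairs for mature miRNAs quantified in the
poly(A)-tailed universal-RT format. The cDNA template is
`universal tag – oligo-dT – reverse complement of the mature miRNA`; the
forward primer copies the miRNA's 5′ sequence, the reverse primer is
either the fixed universal primer or a target-specific oligo ending in
bases complementary to the miRNA's 3′ end. The design procedure is a
deterministic rule system, not an optimizer: construction rules build a
candidate pair, an adjustment step balances melting temperatures, a
confirmation step gates dimer free energies, and a fixed remediation
ladder (tail alternatives → 3′ trimming → strategy escalation) is walked
until the constraints hold or options are exhausted. Identical inputs
and configuration always give byte-identical outputs; nothing in the
design path draws random numbers.

## Thermodynamics

**Parameters.** Unified nearest-neighbor DNA/DNA parameters
(`src/miprimer/data/santalucia_unified.tsv`: per-step ΔH, ΔS, ΔG37 plus
terminal-G·C / terminal-A·T initiation and the self-complementary
symmetry term). The table is plain text and swappable; internal
consistency (ΔG37 = ΔH − 310.15·ΔS/1000 within 0.1 kcal/mol) is asserted
at load.

**Melting temperature.** Two-state duplex Tm,

    Tm = 1000·ΔH / (ΔS + 1.987·ln(C / 2×10⁹)) − 273.15,

with C the primer concentration in nM (default 250, i.e. 0.25 µM). The
2×10⁹ constant folds the nM unit scale and the two-strand factor into
one number; both it and the log base are configuration knobs. There is
no salt correction, so Tm values sit on the 1 M NaCl reference scale of
the parameter set — roughly 65–75 °C for typical 20-mers — and the
method's thresholds (59 °C target, 57/55 °C floors, 2 °C balance) are
interpreted on that same scale. In practice the floors rarely bind;
the 2 °C balance against the partner primer (the universal reverse sits
at 75.4 °C) is what drives 5′-tail growth.

**Dimer ΔG, register scan (default backend).** For strands a and b,
every antiparallel offset is scanned; each maximal run of ≥ 2
consecutive Watson–Crick pairs is scored as a two-state duplex — the sum
of its stack ΔG37 terms plus both initiation terms, plus the symmetry
correction when a self-dimer run is its own reverse complement — and the
minimum over all runs and offsets is reported. No bulges, internal
loops or dangling ends. When no run scores below zero the result is the
exact 0.0 sentinel ("no favorable duplex"), which keeps ΔG comparisons
total. The scan is verified base-by-base against an independent
brute-force enumeration in the test suite and via `miprimer selfcheck`.

**Dimer ΔG, cofold backend (optional).** ViennaRNA's cofold with the
DNA Mathews-2004 parameter file at 37 °C, reporting the MFE of the a&b
dimer (ensemble free energy available as an option). This backend
handles structured dimers with loops; it is used for the benchmark
reproduction of the cofold-based published value and is deliberately
*not* the default, so that the core engine stays dependency-light and
oracle-verifiable.

**The −9.0 ± 1 kcal/mol gate.** `pass` above the band, `fail` below it,
`review` inside it: a review value is accepted by the engine (the band
models tool-to-tool disagreement, to be cross-checked manually with a
second ΔG calculator) but surfaces as `ok_with_review` status.

## Design rules and their open choices

Choices the source rules left open were fixed once, as follows:

* **Similarity** is global-alignment identity (match +1, mismatch 0,
  gaps tie-broken against, matches / alignment columns). This reproduces
  the family/non-family split at 90 % for single-nucleotide variants.
  Family grouping is single-linkage at the threshold; labels are the
  lexicographically smallest member id, so grouping is order-invariant.
  Note the annotated miR-16 family (miR-16-5p vs miR-195-5p, 86.97 %)
  falls *below* the computed threshold — annotated families that the
  threshold misses can be designed by calling the FR procedures with an
  explicit member list.
* **Forward core length** (uni-system) is the 12–18 nt 5′ prefix whose
  Tm is closest to 59 °C, ties to the longer core.
* **Tail attachment**: bases are prepended one at a time from the tail
  expansion's 3′ end inward, so the attached fragment is always a
  contiguous suffix of the tail and the full published tail is intact
  when fully used. Expansion order is lexicographic; the degenerate
  pattern `CGWTSSRCRC` has five 2-fold positions and therefore 32
  concrete expansions, all of which the remediation loop will cycle.
* **Tm balancing** picks the *smallest* extension (tail bases on the
  forward, universal 3′-end bases on a specific reverse) that satisfies
  both the floor and the ≤ 2 °C difference (±0.1 comparison tolerance);
  if no reachable extension satisfies them the closest configuration is
  kept and the design is marked failed. Extension is monotone — a later
  rule never shrinks what an earlier rule built — which makes the loop
  a fixed-point iteration that cannot oscillate.
* **"Dimer-forming nucleotides are removed"** is implemented as
  iterative 3′ trimming of the forward core by 1 nt while the best dimer
  register involves its 3′ terminus, bounded below by 12 nt (uni) or the
  4-nt family anchor; overlap designs are not trimmed (their 3′ end must
  stay on the discriminating base).
* **Discriminating position**: among positions differing from family
  members — most members discriminated first, then most central, then
  lowest index; candidates must leave the 4-nt anchors on both sides.
* **Escalation** is strictly uni/overlap → overlap-2 → FPM (when the
  logged dimer failure implicates the reverse primer) or RPM (forward),
  never skipping. A Tm balance that cannot be met with the fixed
  universal reverse also routes to the replacement-reverse branch, since
  redesigning the reverse is the only in-method remedy there.
* **dT stretch**: 20 dT in uni replacement reverses (reducible to 15 via
  `reduce_dt_variant` when family cross-reactivity demands it); FR
  reverses default to 0 dT (pure target-complementary 3′ parts plus
  universal bases), exposed as `fr_dt`.
* `max_iterations` defaults to 64; the iteration log records every rule
  firing, Tm pair, ΔG triple and remediation attempt.

## Synthetic data

`fixtures.generate_panel` emulates a design-study panel: by default 90
singletons (18–25 nt, 30–70 % GC, rejection-sampled to stay below 90 %
identity to every accepted member) plus 17 family groups totalling 30
members (13 pairs and 4 single-member groups, since 17 groups of ≥ 2
cannot sum to 30). Family members derive from a seed sequence by 1–2
substitutions at clustered central sites with varied bases, the middle
site used most. That clustering is deliberate: it is the regime in
which an overlap design's 3′-terminal window (p−1…p+1) provably covers
every pairwise difference, so the 100 %-discrimination property can be
checked exactly. Real families with differences scattered far apart
(e.g. parts of let-7) are *not* in that regime — against such members an
overlap design yields internal ("weak") mismatches only, which is
precisely why dT-shortening exists as a cross-reactivity remedy. What
passing tests show is therefore that the rules do what they claim under
the stated family structure, not that every real family is perfectly
separable.

Simulated Cq wells follow `Cq = intercept + slope·log10(copies) + ε`
with configurable Gaussian noise; heterologous wells add a mismatch
penalty keyed on the predicted discrimination class (defaults +8 / +4 /
+0.5 Cq for discriminating / weak / non-discriminating — purely
simulation knobs, not measured values); NTC wells amplify with a small
configured probability. Everything is seeded and bit-reproducible.

The published 43-nt RT oligo is stored verbatim; its dT run is 20 when
the universal tag's own terminal T is counted (19 bases beyond the tag),
which is how the "20 dT" convention is reconciled with the string.

## Validation arithmetic

Standard curves regress mean Cq per dilution level on log10 copies
(per-replicate fit behind a flag); efficiency is
(10^(−1/slope) − 1)·100 %. Cross-reactivity is 10^(ΔCq/S)·100 % with
Cq means taken at matched template amounts; ΔCq < 0 (heterologous
earlier than homologous) is capped at 100 % and flagged as a design
failure rather than reported above unity. The formula is evaluated
literally: the folklore "ΔCq > 4 ⇒ < 5 %" holds only for slopes
shallower than about −3.01; at the canonical −3.3219, ΔCq = 4 gives
6.25 %. The NTC false-positive rate counts any amplification at any Cq.

## Benchmark reproduction and its limits

`scripts/acceptance.py` reports two published dimer energies. The
original oligo sequences behind them are not machine-readable from the
source, so the script reconstructs the primers by running this engine on
the mature family sequences and evaluates the stated conventions on the
reconstructions. Two systematic gaps follow. For hsa-miR-18b-5p-F the
overlap rule pins the forward's 3′ end to the single discriminating
position, fixing the core to `TAAGGTGCATCTAGTGCAGT`; its cofold/DNA MFE
is −10.40 kcal/mol, below the published −8.95, and any tail extension
only lowers it further — the published value evidently reflects a
different oligo or parameter variant. For hsa-miR-16-5p-F the published
−10.44 (an OligoAnalyzer self-dimer value) cannot be reproduced by a
faithful reconstruction at all, because the engine's own remediation
loop rejects tail/length choices that carry strong self-dimers; our
reconstruction scores −2.56. Both reconstructed values are reported
as computed, without adjustment.

## Known limitations

* No salt/Mg²⁺ Tm correction; Tm values are comparable within the
  method, not with salt-corrected calculators.
* The register scan ignores loops, bulges and dangles; use the cofold
  backend for structured dimers.
* No hairpin (intramolecular) energetics beyond self-dimer duplexes,
  no probe design, no genome-wide off-target search, no multiplex
  pooling, and no isomiR discrimination (out of the method's reach:
  isomiRs share termini with their canonical form).
* Tail-expansion default order is lexicographic; the original authors'
  preference is unknown, and primer sequences (not pass/fail logic)
  can depend on it.
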