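"""Nearest-neighbor thermodynamics: melting temperature and dimer free energy.

Melting temperatures come from the two-state nearest-neighbor model
(unified DNA parameters): the enthalpy H and entropy S of a primer are the
sums of its dinucleotide stacking terms plus duplex initiation, and

    Tm = 1000*H / (S + R*ln(C / 2e9)) - 273.15

with R = 1.987 cal/(mol K) and C the initial primer concentration in nM.
The 2e9 strand-factor constant and the log base are configurable.  No salt
correction is applied, so Tm sits on the 1 M NaCl reference scale of the
parameter set; the design thresholds are interpreted on that same scale.

Dimer free energies support two backends:

* a deterministic ungapped register scan (default): every contiguous
  Watson-Crick complementary run across all antiparallel offsets is scored
  as a two-state duplex (stack sum + initiation, + symmetry for
  self-complementary runs) and the minimum is reported;
* ViennaRNA cofold with DNA parameters (optional), for structured dimers
  with loops/bulges.

A ``0.0`` sentinel means "no favorable duplex".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

GAS_CONSTANT = 1.987  # cal / (mol K)
STRAND_FACTOR = 2.0e9  # nM scale constant in the Tm formula
ZERO_KELVIN_C = -273.15

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ThermoError(ValueError):
    pass


def _load_nn_table(name: str = "santalucia_unified.tsv"):
    nn: dict[str, tuple[float, float, float]] = {}
    init: dict[str, tuple[float, float, float]] = {}
    text = resources.files("miprimer.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("step"):
            continue
        step, dh, ds, dg = line.split("\t")
        row = (float(dh), float(ds), float(dg))
        if step.startswith("init") or step == "symmetry":
            init[step] = row
        else:
            nn[step.upper()] = row
    return nn, init


@dataclass
class ThermoParams:
    """Nearest-neighbor parameter set plus evaluation conditions.

    ``nn_table`` maps each of the 16 dinucleotide steps to
    (dH kcal/mol, dS cal/(mol K), dG37 kcal/mol); ``init_terms`` carries the
    initiation (terminal G*C / A*T) and symmetry corrections.  ``primer_nM``
    is the initial primer concentration C of the Tm formula;
    ``temperature_c`` is the reporting temperature for dG (37 C standard).
    """

    nn_table: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    init_terms: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    primer_nM: float = 250.0
    temperature_c: float = 37.0
    strand_factor: float = STRAND_FACTOR
    use_natural_log: bool = True

    def __post_init__(self):
        if not self.nn_table:
            self.nn_table, self.init_terms = _load_nn_table()
        if self.primer_nM <= 0:
            raise ThermoError("primer concentration must be > 0")
        self._check_consistency()

    def _check_consistency(self):
        steps = {a + b for a in "ACGT" for b in "ACGT"}
        missing = steps - set(self.nn_table)
        if missing:
            raise ThermoError(f"nn_table missing steps: {sorted(missing)}")
        t_k = self.temperature_c - ZERO_KELVIN_C
        for step, (dh, ds, dg) in {**self.nn_table, **self.init_terms}.items():
            if abs(dg - (dh - t_k * ds / 1000.0)) > 0.1:
                raise ThermoError(f"inconsistent dH/dS/dG37 for step {step}")

    def dg37(self, step: str) -> float:
        return self.nn_table[step][2]

    def init_dg(self, base: str) -> float:
        key = "init_GC" if base in "GC" else "init_AT"
        return self.init_terms[key][2]

    def symmetry_dg(self) -> float:
        return self.init_terms["symmetry"][2]


@dataclass
class DuplexResult:
    """Outcome of a duplex free-energy evaluation.

    ``delta_g`` is <= 0 or the exact 0.0 sentinel (no favorable pairing).
    ``best_register`` describes the minimizing ungapped register:
    (offset, start in a, start in b, run length); None for the sentinel or
    the cofold backend.  ``status`` is filled by :func:`dimer_check`.
    """

    delta_g: float
    best_register: tuple[int, int, int, int] | None = None
    status: str = ""
    structure: str = ""


def _validate_dna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ThermoError(f"ambiguous bases {sorted(bad)} in {seq!r}")
    return seq


def enthalpy_entropy(seq: str, params: ThermoParams) -> tuple[float, float]:
    """Two-state duplex (H, S) of a primer with its perfect complement."""
    seq = _validate_dna(seq)
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s, _ = params.nn_table[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        key = "init_GC" if terminal in "GC" else "init_AT"
        h, s, _ = params.init_terms[key]
        dh += h
        ds += s
    return dh, ds


def tm_from_enthalpy_entropy(
    h_kcal: float,
    s_cal: float,
    c_nM: float,
    *,
    strand_factor: float = STRAND_FACTOR,
    use_natural_log: bool = True,
) -> float:
    """Melting temperature (deg C) from duplex enthalpy/entropy.

    Tm = 1000*H / (S + R*ln(C/strand_factor)) - 273.15, with H in kcal/mol,
    S in cal/(mol K) and C in nM.  At C == strand_factor the concentration
    term vanishes.
    """
    if h_kcal >= 0 or s_cal >= 0:
        raise ThermoError("expected negative duplex enthalpy and entropy")
    if c_nM <= 0:
        raise ThermoError("primer concentration must be > 0")
    log = math.log if use_natural_log else math.log10
    denom = s_cal + GAS_CONSTANT * log(c_nM / strand_factor)
    if denom >= 0:
        raise ThermoError("non-physical Tm denominator >= 0")
    return 1000.0 * h_kcal / denom + ZERO_KELVIN_C


def melting_temperature(seq: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor Tm (deg C) of a primer against its complement."""
    params = params or ThermoParams()
    seq = _validate_dna(seq)
    if len(seq) < 8:
        raise ThermoError(f"sequence too short for a meaningful Tm: {seq!r}")
    return _tm_unchecked(seq, params)


def _tm_unchecked(seq: str, params: ThermoParams) -> float:
    """Tm without the length guard; intermediate construction states may be
    shorter than any sensible primer and just need a comparably low value."""
    dh, ds = enthalpy_entropy(seq, params)
    try:
        return tm_from_enthalpy_entropy(
            dh,
            ds,
            params.primer_nM,
            strand_factor=params.strand_factor,
            use_natural_log=params.use_natural_log,
        )
    except ThermoError:
        return ZERO_KELVIN_C


def _register_runs(a: str, b: str, offset: int):
    """Maximal complementary runs of a (5'->3') vs b (3'->5') at one offset.

    Position i of `a` faces position j = len(b)-1-(i-offset) of `b`.
    Yields (start_in_a, length).
    """
    n, m = len(a), len(b)
    run_start = None
    run_len = 0
    lo, hi = max(0, offset), min(n, m + offset)
    for i in range(lo, hi):
        j = m - 1 - (i - offset)
        if _COMPLEMENT[a[i]] == b[j]:
            if run_start is None:
                run_start = i
            run_len += 1
        else:
            if run_len >= 2:
                yield run_start, run_len
            run_start, run_len = None, 0
    if run_len >= 2:
        yield run_start, run_len


def duplex_delta_g(a: str, b: str, params: ThermoParams | None = None) -> DuplexResult:
    """Minimum two-state hybridization dG37 of `a` with `b` (register scan).

    Every contiguous complementary run (>= 2 bp) at every antiparallel
    offset is scored as stack sum + duplex initiation; self-complementary
    runs in a self-dimer additionally pay the symmetry correction.  The
    reported value is the minimum over all runs; 0.0 when nothing is
    favorable.
    """
    params = params or ThermoParams()
    a, b = _validate_dna(a), _validate_dna(b)
    if len(a) < 4 or len(b) < 4:
        raise ThermoError("sequences must be at least 4 nt for dimer scan")
    best = 0.0
    best_reg = None
    n, m = len(a), len(b)
    for offset in range(-(m - 1), n):
        for start, length in _register_runs(a, b, offset):
            seg = a[start : start + length]
            dg = sum(params.dg37(seg[i : i + 2]) for i in range(length - 1))
            dg += params.init_dg(seg[0]) + params.init_dg(seg[-1])
            if a == b and seg == "".join(_COMPLEMENT[c] for c in reversed(seg)):
                dg += params.symmetry_dg()
            if dg < best:
                best = dg
                j_start = m - 1 - (start + length - 1 - offset)
                best_reg = (offset, start, j_start, length)
    if best >= 0.0:
        return DuplexResult(0.0, None)
    return DuplexResult(best, best_reg)


def self_dimer_delta_g(seq: str, params: ThermoParams | None = None) -> DuplexResult:
    """Self-dimer dG37: ``duplex_delta_g(seq, seq)``."""
    return duplex_delta_g(seq, seq, params)


def _find_vienna_params(name: str) -> str:
    """Locate a ViennaRNA-shipped parameter file (e.g. dna_mathews2004.par)."""
    import os
    import sys

    if os.path.sep in name:
        return name
    candidates = [
        os.path.join(sys.prefix, "share", "ViennaRNA", name),
        os.path.join(sys.prefix, "share", "vienna-rna", name),
    ]
    for cand in candidates:
        if os.path.exists(cand):
            return cand
    raise FileNotFoundError(
        f"ViennaRNA parameter file {name!r} not found under {sys.prefix}/share"
    )


def cofold_delta_g(
    a: str,
    b: str,
    *,
    parameter_file: str = "dna_mathews2004.par",
    temperature_c: float = 37.0,
    dangles: int = 2,
    ensemble: bool = False,
) -> DuplexResult:
    """Intermolecular hybridization dG via ViennaRNA cofold, DNA parameters.

    Loads a DNA nearest-neighbor parameter file shipped with ViennaRNA
    (Mathews-style) and computes the MFE (or, with ``ensemble=True``, the
    ensemble free energy) of the a&b dimer at ``temperature_c``.  Requires
    the ViennaRNA python bindings; raises ImportError when absent.
    """
    import RNA  # deferred: optional backend

    a, b = _validate_dna(a), _validate_dna(b)
    RNA.params_load(_find_vienna_params(parameter_file))
    md = RNA.md()
    md.temperature = temperature_c
    md.dangles = dangles
    fc = RNA.fold_compound(f"{a}&{b}", md)
    structure, mfe = fc.mfe_dimer()
    if ensemble:
        fc.exp_params_rescale(mfe)
        energy = fc.pf_dimer()[3]
    else:
        energy = mfe
    if energy >= 0.0:
        return DuplexResult(0.0, None, structure=structure)
    return DuplexResult(float(energy), None, structure=structure)


def dimer_check(
    dg: float, threshold: float = -9.0, tolerance: float = 1.0
) -> str:
    """Gate a dimer dG against the acceptance threshold (-9.0 +/- 1 kcal/mol).

    * ``pass``   -- dG above the threshold and outside the uncertainty band;
      primers here need no modification.
    * ``review`` -- dG inside the band [threshold - tol, threshold + tol];
      controversial values, to be cross-checked manually with a second dG
      tool, but not a hard failure.
    * ``fail``   -- dG below threshold - tol; a stable dimer, remediate.
    """
    if tolerance < 0:
        raise ThermoError("tolerance must be >= 0")
    if dg > threshold + tolerance:
        return "pass"
    if dg >= threshold - tolerance:
        return "review"
    return "fail"
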