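"""The primer-design engine: strategy selection and the four procedures.

Two systems cover every target:

* **uni-system** -- a specific, optionally 5'-tailed forward primer paired
  with the fixed universal reverse primer.  Used when the target's
  similarity to every other panel member is below the family threshold.
  If the dimer issue cannot be cleared by modifying the forward alone, the
  universal reverse is replaced by a redesigned specific reverse
  (2-8 nt target-complementary 3' part + dT stretch + universal fragment).
* **specific-FR-system** -- two target-specific primers for family
  members, in three sequential variants: *overlap* (forward and reverse
  overlap by one, optionally two, nucleotides exactly at a discriminating
  position), *FPM* (forward-primer major: forward extended over a
  discriminating position, dimer-forming reverse shortened or replaced by
  the universal primer) and *RPM* (the mirror image).

Every design runs the same two inner steps until its constraints hold:
an **adjustment** step that balances the two melting temperatures to
within 2 deg C (extending the cooler primer: 5'-tail bases for the
forward, universal-sequence bases for the reverse), and a **confirmation**
step that gates self- and hetero-dimer dG at -9.0 +/- 1 kcal/mol, cycling
through the IUPAC 5'-tail alternatives and trimming dimer-forming 3'
nucleotides when the gate fails.  All designs are deterministic; the full
rule trail is recorded in ``iteration_log``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

from . import seqio, thermo
from .seqio import MiRNA, SequencePanel, reverse_complement, expand_iupac
from .thermo import ThermoParams, dimer_check

DEFAULT_TAIL_PATTERN = "CGWTSSRCRC"
DEFAULT_UNIVERSAL_REVERSE = "CAACTCAGGTCGTAGGCAATTCGT"

UNI = "UNI"
FR_OVERLAP = "FR_OVERLAP"
FR_FPM = "FR_FPM"
FR_RPM = "FR_RPM"


class DesignError(ValueError):
    pass


@dataclass
class DesignConfig:
    """All tunable design parameters, defaulting to the published rules."""

    tail_pattern: str = DEFAULT_TAIL_PATTERN
    universal_reverse: str = DEFAULT_UNIVERSAL_REVERSE
    tm_target: float = 59.0
    tm_floor_uni_forward: float = 57.0
    tm_floor_fr: float = 55.0
    tm_floor_replacement_reverse: float = 55.0
    tm_diff_max: float = 2.0
    tm_diff_tol: float = 0.1  # comparison tolerance on the 2 deg C rule
    dg_threshold: float = -9.0
    dg_tolerance: float = 1.0
    fwd_core_len_range: tuple[int, int] = (12, 18)
    rev_specific_len_range_uni: tuple[int, int] = (2, 8)
    min_anchor_fr: int = 4
    dt_length: int = 20
    dt_fallback: int = 15
    fr_dt: int = 0  # dT stretch in FR (two-specific-primer) reverses
    overlap_max: int = 2
    similarity_threshold: float = 90.0
    max_iterations: int = 64
    primer_nM: float = 250.0
    dg_backend: str = "register"  # or "cofold"
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.fwd_core_len_range
        if lo > hi or self.rev_specific_len_range_uni[0] > self.rev_specific_len_range_uni[1]:
            raise DesignError("empty length range")
        if self.overlap_max not in (1, 2):
            raise DesignError("overlap_max must be 1 or 2")
        if self.dt_fallback >= self.dt_length:
            raise DesignError("dt fallback must be shorter than the default dT stretch")
        for floor in (
            self.tm_floor_uni_forward,
            self.tm_floor_fr,
            self.tm_floor_replacement_reverse,
        ):
            if self.tm_target < floor:
                raise DesignError("tm_target must be >= every floor")
        if self.max_iterations <= 0:
            raise DesignError("max_iterations must be positive")

    def thermo_params(self) -> ThermoParams:
        return ThermoParams(primer_nM=self.primer_nM)

    def tail_expansions(self) -> list[str]:
        return expand_iupac(self.tail_pattern)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        for key in ("fwd_core_len_range", "rev_specific_len_range_uni"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Primer:
    """An oriented oligo assembled from labelled segments (5'->3')."""

    name: str
    role: str  # forward | reverse | universal_reverse
    segments: list[tuple[str, str]]  # (label, subsequence), 5'->3'
    tm: float = float("nan")
    self_dg: float = 0.0

    @property
    def sequence(self) -> str:
        return "".join(seq for _, seq in self.segments)

    def segment(self, label: str) -> str:
        return "".join(seq for lab, seq in self.segments if lab == label)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DesignResult:
    target_id: str
    strategy: str
    forward: Primer | None
    reverse: Primer | None
    hetero_dg: float = 0.0
    overlap_len: int = 0
    dt_used: int = 0
    status: str = "failed"  # ok | ok_with_review | failed
    iteration_log: list[dict] = field(default_factory=list)
    # final builder states, kept so variants (e.g. the 15-dT reduction)
    # can rebuild the design without re-deriving it
    _fwd_state: "_ForwardState | None" = field(default=None, repr=False)
    _rev_state: "_ReverseState | None" = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status in ("ok", "ok_with_review")

    def log(self, rule: str, **info) -> None:
        self.iteration_log.append({"rule": rule, **info})


# ---------------------------------------------------------------------------
# primer builders


@dataclass
class _ForwardState:
    """Forward primer = [tail fragment] + [target 5' prefix core]."""

    target: MiRNA
    core_len: int
    min_core: int
    tail_idx: int = 0
    tail_len: int = 0

    def build(self, cfg: DesignConfig, params: ThermoParams) -> Primer:
        tail = cfg.tail_expansions()[self.tail_idx]
        frag = tail[len(tail) - self.tail_len :] if self.tail_len else ""
        core = self.target.dna[: self.core_len]
        segments = []
        if frag:
            segments.append(("tail_fragment", frag))
        segments.append(("core", core))
        p = Primer(name=f"{self.target.id}-F", role="forward", segments=segments)
        p.tm = thermo._tm_unchecked(p.sequence, params)
        return p

    def max_tail(self, cfg: DesignConfig) -> int:
        return len(cfg.tail_pattern)


@dataclass
class _ReverseState:
    """Reverse primer = [universal 3' fragment] + [dT stretch] + [rc of a target 3' suffix].

    ``start`` is the 0-based target position of the suffix; the primer's
    3'-terminal base pairs the target exactly at ``start``.  ``start`` is
    None for the unmodified universal reverse primer.
    """

    target: MiRNA
    start: int | None
    dt: int = 0
    j: int = 0  # universal-fragment length

    def build(self, cfg: DesignConfig, params: ThermoParams) -> Primer:
        uni = cfg.universal_reverse
        if self.start is None:
            p = Primer(
                name="universal-R",
                role="universal_reverse",
                segments=[("universal_fragment", uni)],
            )
            p.tm = thermo._tm_unchecked(uni, params)
            return p
        segments = []
        if self.j:
            segments.append(("universal_fragment", uni[len(uni) - self.j :]))
        if self.dt:
            segments.append(("dT_stretch", "T" * self.dt))
        segments.append(("specific_3prime", reverse_complement(self.target.dna[self.start :])))
        p = Primer(name=f"{self.target.id}-R", role="reverse", segments=segments)
        p.tm = thermo._tm_unchecked(p.sequence, params)
        return p

    @property
    def is_universal(self) -> bool:
        return self.start is None

    def max_j(self, cfg: DesignConfig) -> int:
        return len(cfg.universal_reverse)


# ---------------------------------------------------------------------------
# elementary operations


def select_strategy(target: MiRNA, panel: SequencePanel, cfg: DesignConfig) -> str:
    """uni-system below the similarity threshold, specific-FR-system at/above."""
    sim = seqio.max_similarity(target, panel)
    return UNI if sim < cfg.similarity_threshold else FR_OVERLAP


def build_forward_core(
    target: MiRNA, cfg: DesignConfig, params: ThermoParams | None = None
) -> Primer:
    """Forward core: the target's 5' prefix, 12-18 nt, Tm closest to target.

    Length is chosen within the configured range (clamped to the target
    length) minimizing |Tm - tm_target|; ties go to the longer core.
    """
    params = params or cfg.thermo_params()
    lo, hi = cfg.fwd_core_len_range
    if len(target) < lo:
        raise DesignError(f"{target.id}: target shorter than minimum core ({lo} nt)")
    hi = min(hi, len(target))
    best = None
    for length in range(lo, hi + 1):
        tm = thermo.melting_temperature(target.dna[:length], params)
        key = (abs(tm - cfg.tm_target), -length)
        if best is None or key < best[0]:
            best = (key, length)
    state = _ForwardState(target, core_len=best[1], min_core=lo)
    return state.build(cfg, params)


def extend_tail_to_tm(
    state: _ForwardState,
    cfg: DesignConfig,
    floor: float,
    params: ThermoParams | None = None,
) -> tuple[_ForwardState, bool]:
    """Prepend 5'-tail bases (3' end of the tail inward) until Tm >= target.

    No-op when the primer already meets the floor.  Returns the new state
    and a flag telling whether the Tm target was reached (False when the
    whole tail was consumed and Tm is still short -- recorded, not raised).
    """
    params = params or cfg.thermo_params()
    primer = state.build(cfg, params)
    if primer.tm >= floor:
        return state, True
    for tl in range(state.tail_len + 1, state.max_tail(cfg) + 1):
        cand = replace(state, tail_len=tl)
        if cand.build(cfg, params).tm >= cfg.tm_target:
            return cand, True
    return replace(state, tail_len=state.max_tail(cfg)), False


def build_reverse_specific(
    target: MiRNA, k: int, dt: int, j: int, cfg: DesignConfig
) -> Primer:
    """Replacement reverse: universal 3' fragment + dT stretch + rc(3' k-mer)."""
    lo, hi = cfg.rev_specific_len_range_uni
    if not (lo <= k <= hi):
        raise DesignError(f"reverse specific part k={k} outside [{lo}, {hi}]")
    if not (0 <= j <= len(cfg.universal_reverse)):
        raise DesignError(f"universal fragment j={j} out of range")
    state = _ReverseState(target, start=len(target) - k, dt=dt, j=j)
    return state.build(cfg, cfg.thermo_params())


# ---------------------------------------------------------------------------
# adjustment + confirmation


def _balance_tms(
    fwd: _ForwardState,
    rev: _ReverseState,
    cfg: DesignConfig,
    floor: float,
    params: ThermoParams,
    rev_floor: float | None = None,
) -> tuple[_ForwardState, _ReverseState, float]:
    """Adjustment step: extend the cooler primer until the Tms agree.

    The forward grows by 5'-tail bases, a specific reverse by universal
    3'-end bases.  Extension is monotone (never shrinks what a previous
    rule built); among reachable extension pairs the one minimizing |dTm|
    is taken, preferring fewer added bases on ties, so a single pass is
    deterministic and cannot oscillate.  Returns the balanced states and
    the achieved |dTm|.
    """
    rev_floor = rev_floor if rev_floor is not None else floor
    fwd_opts = []
    for tl in range(fwd.tail_len, fwd.max_tail(cfg) + 1):
        cand = replace(fwd, tail_len=tl)
        fwd_opts.append((tl, cand, cand.build(cfg, params).tm))
    if rev.is_universal:
        rev_opts = [(0, rev, rev.build(cfg, params).tm)]
    else:
        rev_opts = []
        for j in range(rev.j, rev.max_j(cfg) + 1):
            cand = replace(rev, j=j)
            rev_opts.append((j, cand, cand.build(cfg, params).tm))
    satisfying = []
    best = None
    for tl, fs, tf in fwd_opts:
        for j, rs, tr in rev_opts:
            floor_miss = max(0.0, floor - tf) + max(0.0, rev_floor - tr)
            dtm = abs(tf - tr)
            if floor_miss == 0.0 and dtm <= cfg.tm_diff_max + cfg.tm_diff_tol:
                satisfying.append(((tl + j, tl, round(dtm, 6)), fs, rs, dtm))
            key = (round(floor_miss, 6), round(dtm, 6), tl + j, tl)
            if best is None or key < best[0]:
                best = (key, fs, rs, dtm)
    # smallest extension that satisfies both rules; otherwise the closest
    # reachable configuration (recorded as an unbalanced design)
    chosen = min(satisfying, key=lambda x: x[0]) if satisfying else best
    _, fs, rs, dtm = chosen
    return fs, rs, dtm


def _dimer_report(
    fwd: Primer, rev: Primer, cfg: DesignConfig, params: ThermoParams
) -> dict:
    """Confirmation step: self- and hetero-dimer dG with their gate status."""
    if cfg.dg_backend == "cofold":
        dg = lambda a, b: thermo.cofold_delta_g(a, b).delta_g  # noqa: E731
    else:
        dg = lambda a, b: thermo.duplex_delta_g(a, b, params).delta_g  # noqa: E731
    self_f = dg(fwd.sequence, fwd.sequence)
    self_r = dg(rev.sequence, rev.sequence)
    hetero = dg(fwd.sequence, rev.sequence)
    report = {
        "self_F": (self_f, dimer_check(self_f, cfg.dg_threshold, cfg.dg_tolerance)),
        "self_R": (self_r, dimer_check(self_r, cfg.dg_threshold, cfg.dg_tolerance)),
        "hetero": (hetero, dimer_check(hetero, cfg.dg_threshold, cfg.dg_tolerance)),
    }
    report["failures"] = [k for k in ("self_F", "self_R", "hetero") if report[k][1] == "fail"]
    report["reviews"] = [k for k in ("self_F", "self_R", "hetero") if report[k][1] == "review"]
    return report


def _forward_3prime_implicated(
    fwd: Primer, params: ThermoParams, other: Primer | None = None
) -> bool:
    """True when the forward's best dimer register involves its 3' end.

    With ``other`` given, the hetero-dimer register is inspected;
    otherwise the forward's self-dimer.
    """
    partner = other.sequence if other is not None else fwd.sequence
    res = thermo.duplex_delta_g(fwd.sequence, partner, params)
    if res.best_register is None:
        return False
    offset, start, _, length = res.best_register
    return start + length >= len(fwd.sequence) - 1


def adjust_and_confirm(
    fwd: _ForwardState,
    rev: _ReverseState,
    cfg: DesignConfig,
    floor: float,
    result: DesignResult,
    rev_floor: float | None = None,
) -> tuple[_ForwardState, _ReverseState, dict | None]:
    """Iterate Tm adjustment and dimer confirmation until both hold.

    Remediation on a dimer failure, in fixed order: (a) cycle the 5'-tail
    IUPAC expansions; (b) trim dimer-forming 3' nucleotides of the forward
    core down to its minimum length; (c) give up and let the calling
    strategy escalate.  Returns the final states plus the last dimer
    report (None when the iteration budget ran out before confirmation).
    """
    params = cfg.thermo_params()
    expansions = cfg.tail_expansions()
    report = None
    for iteration in range(cfg.max_iterations):
        fwd, rev, dtm = _balance_tms(fwd, rev, cfg, floor, params, rev_floor)
        f_p, r_p = fwd.build(cfg, params), rev.build(cfg, params)
        result.log(
            "adjustment:tm_balance",
            iteration=iteration,
            fwd=f_p.sequence,
            rev=r_p.sequence,
            tm_f=round(f_p.tm, 2),
            tm_r=round(r_p.tm, 2),
            dtm=round(dtm, 2),
        )
        report = _dimer_report(f_p, r_p, cfg, params)
        result.log(
            "confirmation:dimer",
            iteration=iteration,
            self_F=round(report["self_F"][0], 2),
            self_R=round(report["self_R"][0], 2),
            hetero=round(report["hetero"][0], 2),
            failures=list(report["failures"]),
        )
        if not report["failures"]:
            return fwd, rev, report

        # (a) next IUPAC tail alternative (only meaningful with a tail on)
        if fwd.tail_len > 0:
            resolved = False
            start_idx = fwd.tail_idx
            for step in range(1, len(expansions)):
                idx = (start_idx + step) % len(expansions)
                cand_f = replace(fwd, tail_idx=idx)
                cand_f, cand_r, _ = _balance_tms(cand_f, rev, cfg, floor, params, rev_floor)
                rep = _dimer_report(
                    cand_f.build(cfg, params), cand_r.build(cfg, params), cfg, params
                )
                result.log(
                    "remediation:tail_expansion",
                    expansion=expansions[idx],
                    failures=list(rep["failures"]),
                )
                if not rep["failures"]:
                    fwd, rev = cand_f, cand_r
                    resolved = True
                    break
            if resolved:
                continue

        # (b) trim dimer-forming 3' nucleotides of the forward core
        f_p = fwd.build(cfg, params)
        trimmed = False

        def _implicated() -> bool:
            if "self_F" in report["failures"]:
                return _forward_3prime_implicated(f_p, params)
            if "hetero" in report["failures"]:
                return _forward_3prime_implicated(f_p, params, rev.build(cfg, params))
            return False

        while (
            fwd.core_len > fwd.min_core
            and report["failures"]
            and ("self_F" in report["failures"] or "hetero" in report["failures"])
            and _implicated()
        ):
            fwd = replace(fwd, core_len=fwd.core_len - 1)
            trimmed = True
            result.log("remediation:trim_forward_3prime", core_len=fwd.core_len)
            f_p = fwd.build(cfg, params)
            report = _dimer_report(f_p, rev.build(cfg, params), cfg, params)
        if trimmed and not report["failures"]:
            continue
        if trimmed:
            continue  # re-enter the loop to re-balance after trimming

        # (c) nothing left at this level
        result.log("remediation:exhausted", failures=list(report["failures"]))
        return fwd, rev, report
    result.log("iteration_budget_exhausted")
    return fwd, rev, report


def _finalize(
    result: DesignResult,
    fwd: _ForwardState,
    rev: _ReverseState,
    report: dict | None,
    cfg: DesignConfig,
    floor: float,
    rev_floor: float | None = None,
) -> DesignResult:
    params = cfg.thermo_params()
    rev_floor = rev_floor if rev_floor is not None else floor
    f_p, r_p = fwd.build(cfg, params), rev.build(cfg, params)
    if report is not None:
        f_p.self_dg = report["self_F"][0]
        r_p.self_dg = report["self_R"][0]
        hetero = report["hetero"][0]
    else:
        f_p.self_dg = thermo.self_dimer_delta_g(f_p.sequence, params).delta_g
        r_p.self_dg = thermo.self_dimer_delta_g(r_p.sequence, params).delta_g
        hetero = thermo.duplex_delta_g(f_p.sequence, r_p.sequence, params).delta_g
    result.forward, result.reverse = f_p, r_p
    result._fwd_state, result._rev_state = fwd, rev
    result.hetero_dg = hetero
    result.dt_used = rev.dt if not rev.is_universal else 0
    tm_ok = (
        abs(f_p.tm - r_p.tm) <= cfg.tm_diff_max + cfg.tm_diff_tol
        and f_p.tm >= floor - cfg.tm_diff_tol
        and r_p.tm >= rev_floor - cfg.tm_diff_tol
    )
    dimer_ok = report is not None and not report["failures"]
    if tm_ok and dimer_ok:
        result.status = "ok_with_review" if report["reviews"] else "ok"
    else:
        result.status = "failed"
    result.log(
        "finalize",
        status=result.status,
        tm_ok=tm_ok,
        dimer_ok=dimer_ok,
        fwd=f_p.sequence,
        rev=r_p.sequence,
    )
    return result


# ---------------------------------------------------------------------------
# strategies


def design_uni(target: MiRNA, panel: SequencePanel, cfg: DesignConfig) -> DesignResult:
    """uni-system: tailed specific forward + universal reverse.

    When forward-side remediation cannot clear the dimer gate, the
    universal reverse is replaced by a redesigned specific reverse
    (2-8 nt complementary 3' part, dT stretch, universal 5' fragment)
    and the adjust/confirm loop reruns.
    """
    params = cfg.thermo_params()
    result = DesignResult(target_id=target.id, strategy=UNI, forward=None, reverse=None)
    lo, _ = cfg.fwd_core_len_range
    core = build_forward_core(target, cfg, params)
    fwd = _ForwardState(target, core_len=len(core.segment("core")), min_core=lo)
    fwd, reached = extend_tail_to_tm(fwd, cfg, cfg.tm_floor_uni_forward, params)
    result.log(
        "uni:forward_core",
        core_len=fwd.core_len,
        tail_len=fwd.tail_len,
        tm_target_reached=reached,
    )
    rev = _ReverseState(target, start=None)
    fwd, rev, report = adjust_and_confirm(
        fwd, rev, cfg, cfg.tm_floor_uni_forward, result
    )
    f_p, r_p = fwd.build(cfg, params), rev.build(cfg, params)
    balanced = (
        abs(f_p.tm - r_p.tm) <= cfg.tm_diff_max + cfg.tm_diff_tol
        and f_p.tm >= cfg.tm_floor_uni_forward - cfg.tm_diff_tol
    )
    if report is not None and not report["failures"] and balanced:
        return _finalize(result, fwd, rev, report, cfg, cfg.tm_floor_uni_forward)

    # fallback: modify both primers -- replacement specific reverse
    result.log("uni:replacement_reverse_branch")
    k_lo, k_hi = cfg.rev_specific_len_range_uni
    for k in range(k_lo, k_hi + 1):
        # restart the forward's tail from its floor state: the redesigned
        # reverse no longer forces the forward up to the universal's Tm
        fwd_k = replace(fwd, tail_len=0)
        fwd_k, _ = extend_tail_to_tm(fwd_k, cfg, cfg.tm_floor_uni_forward, params)
        rev_k = _ReverseState(target, start=len(target) - k, dt=cfg.dt_length, j=0)
        sub = DesignResult(target_id=target.id, strategy=UNI, forward=None, reverse=None)
        fwd_k, rev_k, rep = adjust_and_confirm(
            fwd_k,
            rev_k,
            cfg,
            cfg.tm_floor_uni_forward,
            sub,
            rev_floor=cfg.tm_floor_replacement_reverse,
        )
        result.iteration_log.extend(
            {**entry, "branch": f"replacement_k{k}"} for entry in sub.iteration_log
        )
        if rep is not None and not rep["failures"]:
            result.log("uni:replacement_reverse_success", k=k)
            return _finalize(
                result,
                fwd_k,
                rev_k,
                rep,
                cfg,
                cfg.tm_floor_uni_forward,
                rev_floor=cfg.tm_floor_replacement_reverse,
            )
    return _finalize(result, fwd, rev, report, cfg, cfg.tm_floor_uni_forward)


def _family_others(target: MiRNA, family) -> list[MiRNA]:
    return [m for m in family if m.id != target.id]


def choose_discriminating_position(
    target: MiRNA, family, cfg: DesignConfig
) -> int:
    """The overlap position: most-discriminating, then most-central, then lowest.

    Candidate positions must leave >= min_anchor nt on both sides (forward
    5' anchor and reverse 3' anchor).  Raises when the family contains no
    differing position at all.
    """
    others = _family_others(target, family)
    counts: dict[int, int] = {}
    for other in others:
        for p in seqio.diff_positions(target, other):
            if p < len(target):
                counts[p] = counts.get(p, 0) + 1
    if not counts:
        raise DesignError(f"{target.id}: no discriminating position within its family")
    a = cfg.min_anchor_fr
    usable = {p: c for p, c in counts.items() if p >= a - 1 and len(target) - p >= a}
    if not usable:
        usable = counts  # fall back to unconstrained if anchors cannot hold
    center = (len(target) - 1) / 2.0
    return min(usable, key=lambda p: (-usable[p], abs(p - center), p))


def design_fr_overlap(
    target: MiRNA,
    family,
    cfg: DesignConfig,
    overlap: int = 1,
) -> DesignResult:
    """specific-FR-system overlap: F and R overlap at a discriminating position.

    The forward spans the 5' end through position p (its 3'-terminal base
    IS the discriminating nucleotide); the reverse spans p through the 3'
    end (its 3'-terminal base pairs the discriminating nucleotide).  With
    ``overlap=2`` the forward is extended one base past p.
    """
    result = DesignResult(
        target_id=target.id, strategy=FR_OVERLAP, forward=None, reverse=None
    )
    p = choose_discriminating_position(target, family, cfg)
    core_len = p + 1 + (overlap - 1)
    core_len = min(core_len, len(target))
    # overlap designs must keep their 3' end at the discriminating position,
    # so the core is not trimmable (min_core == core_len)
    fwd = _ForwardState(target, core_len=core_len, min_core=core_len)
    rev = _ReverseState(target, start=p, dt=cfg.fr_dt, j=0)
    result.overlap_len = overlap
    result.log("overlap:position", p=p, overlap=overlap, core_len=core_len)
    fwd, ok = extend_tail_to_tm(fwd, cfg, cfg.tm_floor_fr, cfg.thermo_params())
    fwd, rev, report = adjust_and_confirm(fwd, rev, cfg, cfg.tm_floor_fr, result)
    return _finalize(result, fwd, rev, report, cfg, cfg.tm_floor_fr)


def _failing_side(result: DesignResult) -> str | None:
    """Which primer the logged dimer failure implicates ('forward'/'reverse')."""
    for entry in reversed(result.iteration_log):
        if entry["rule"] == "confirmation:dimer" and entry.get("failures"):
            fails = entry["failures"]
            if "self_R" in fails:
                return "reverse"
            if "self_F" in fails:
                return "forward"
            if "hetero" in fails:
                return "reverse"  # hetero involves both; FPM is tried first
    return None


def design_fr_fpm(target: MiRNA, family, cfg: DesignConfig) -> DesignResult:
    """FPM: extend the forward over a difference, shorten/replace the reverse.

    Applied when the overlap design failed on a reverse-primer dimer.  The
    reverse keeps >= min_anchor target-complementary residues or becomes
    the unmodified universal primer.
    """
    result = DesignResult(target_id=target.id, strategy=FR_FPM, forward=None, reverse=None)
    p = choose_discriminating_position(target, family, cfg)
    fwd0 = _ForwardState(target, core_len=p + 1, min_core=p + 1)
    params = cfg.thermo_params()
    fwd0, _ = extend_tail_to_tm(fwd0, cfg, cfg.tm_floor_fr, params)
    # shorten the reverse from its 3' end, keeping the anchor
    for start in range(p + 1, len(target) - cfg.min_anchor_fr + 1):
        rev = _ReverseState(target, start=start, dt=cfg.fr_dt, j=0)
        sub = DesignResult(target_id=target.id, strategy=FR_FPM, forward=None, reverse=None)
        f2, r2, rep = adjust_and_confirm(replace(fwd0), rev, cfg, cfg.tm_floor_fr, sub)
        result.iteration_log.extend(
            {**e, "branch": f"rev_start{start}"} for e in sub.iteration_log
        )
        if rep is not None and not rep["failures"]:
            result.log("fpm:shortened_reverse", start=start)
            return _finalize(result, f2, r2, rep, cfg, cfg.tm_floor_fr)
    # last resort: the universal reverse primer replaces the reverse
    result.log("fpm:universal_reverse_fallback")
    rev = _ReverseState(target, start=None)
    f2, r2, rep = adjust_and_confirm(replace(fwd0), rev, cfg, cfg.tm_floor_fr, result)
    return _finalize(result, f2, r2, rep, cfg, cfg.tm_floor_fr)


def design_fr_rpm(target: MiRNA, family, cfg: DesignConfig) -> DesignResult:
    """RPM: extend the reverse over a difference, trim the forward's 3' end.

    The mirror of FPM, applied when the forward primer causes the dimer;
    the forward keeps >= min_anchor residues of the target's 5' sequence.
    """
    result = DesignResult(target_id=target.id, strategy=FR_RPM, forward=None, reverse=None)
    p = choose_discriminating_position(target, family, cfg)
    rev = _ReverseState(target, start=p, dt=cfg.fr_dt, j=0)  # covers the difference
    for core_len in range(p, cfg.min_anchor_fr - 1, -1):
        fwd = _ForwardState(target, core_len=core_len, min_core=cfg.min_anchor_fr)
        fwd, _ = extend_tail_to_tm(fwd, cfg, cfg.tm_floor_fr, cfg.thermo_params())
        sub = DesignResult(target_id=target.id, strategy=FR_RPM, forward=None, reverse=None)
        f2, r2, rep = adjust_and_confirm(fwd, replace(rev), cfg, cfg.tm_floor_fr, sub)
        result.iteration_log.extend(
            {**e, "branch": f"fwd_core{core_len}"} for e in sub.iteration_log
        )
        if rep is not None and not rep["failures"]:
            result.log("rpm:trimmed_forward", core_len=core_len)
            return _finalize(result, f2, r2, rep, cfg, cfg.tm_floor_fr)
    result.log("rpm:exhausted")
    fwd = _ForwardState(target, core_len=cfg.min_anchor_fr, min_core=cfg.min_anchor_fr)
    f2, r2, rep = adjust_and_confirm(fwd, rev, cfg, cfg.tm_floor_fr, result)
    return _finalize(result, f2, r2, rep, cfg, cfg.tm_floor_fr)


def design(target: MiRNA, panel: SequencePanel, cfg: DesignConfig | None = None) -> DesignResult:
    """Full orchestration: strategy selection plus the escalation ladder.

    UNI (or FR overlap-1) -> overlap-2 -> FPM when the logged dimer
    failure implicates the reverse primer, RPM otherwise.  Returns the
    first success, or the last failure carrying the whole escalation
    trail.
    """
    cfg = cfg or DesignConfig()
    strategy = select_strategy(target, panel, cfg)
    if strategy == UNI:
        return design_uni(target, panel, cfg)
    family = panel.family_of(target.id)
    if len(family) == 1:  # similarity >= threshold but ungrouped panel
        family = [target] + [
            m
            for m in panel
            if m.id != target.id
            and seqio.pairwise_similarity(target, m) >= cfg.similarity_threshold
        ]
    r1 = design_fr_overlap(target, family, cfg, overlap=1)
    if r1.ok:
        return r1
    trail = list(r1.iteration_log)
    if cfg.overlap_max >= 2:
        r2 = design_fr_overlap(target, family, cfg, overlap=2)
        r2.iteration_log = trail + [{"rule": "escalate:overlap2"}] + r2.iteration_log
        if r2.ok:
            return r2
        trail = list(r2.iteration_log)
    side = _failing_side(r1) or "reverse"
    if side == "reverse":
        r3 = design_fr_fpm(target, family, cfg)
    else:
        r3 = design_fr_rpm(target, family, cfg)
    r3.iteration_log = trail + [{"rule": f"escalate:{r3.strategy}"}] + r3.iteration_log
    return r3


def reduce_dt_variant(result: DesignResult, cfg: DesignConfig) -> DesignResult:
    """Shorten the reverse primer's dT stretch from 20 to 15 residues.

    Used to cut cross-reactivity between family members when the 20-dT
    reverse cannot separate them; everything else about the design is
    preserved and the Tm balance re-confirmed.
    """
    if (
        result.reverse is None
        or result._rev_state is None
        or result._rev_state.is_universal
        or result._rev_state.dt != cfg.dt_length
    ):
        raise DesignError("result has no full-length dT stretch to reduce")
    variant = DesignResult(
        target_id=result.target_id,
        strategy=result.strategy,
        forward=None,
        reverse=None,
        overlap_len=result.overlap_len,
    )
    variant.log("dt_reduction", dt_from=cfg.dt_length, dt_to=cfg.dt_fallback)
    fwd = replace(result._fwd_state)
    rev = replace(result._rev_state, dt=cfg.dt_fallback)
    floor = (
        cfg.tm_floor_uni_forward if result.strategy == UNI else cfg.tm_floor_fr
    )
    rev_floor = (
        cfg.tm_floor_replacement_reverse if result.strategy == UNI else cfg.tm_floor_fr
    )
    fwd, rev, report = adjust_and_confirm(fwd, rev, cfg, floor, variant, rev_floor)
    return _finalize(variant, fwd, rev, report, cfg, floor, rev_floor)


def predict_discrimination(
    result: DesignResult, off_targets, cfg: DesignConfig | None = None
) -> dict[str, str]:
    """Per-off-target specificity classes for a finished design.

    For each off-target the primers are annealed in silico against the
    off-target-derived template (5'-anchored for the forward core,
    3'-anchored for the reverse specific part).  A mismatch within the
    3'-terminal 2 bases of either primer blocks extension ->
    ``discriminating``; mismatches elsewhere -> ``weak``; a perfect match
    of both primer footprints -> ``non-discriminating``.
    """
    out: dict[str, str] = {}
    fwd = result.forward
    rev = result.reverse
    core = fwd.segment("core") if fwd else ""
    rev_spec = rev.segment("specific_3prime") if rev else ""
    for off in off_targets:
        off_dna = off.dna
        terminal = False
        internal = False
        if core:
            window = off_dna[: len(core)]
            for i, (x, y) in enumerate(zip(core, window)):
                if x != y:
                    if i >= len(core) - 2:
                        terminal = True
                    else:
                        internal = True
            if len(window) < len(core):
                terminal = True  # off-target too short: 3' overhang
        if rev_spec:
            # reverse 3'-terminal base pairs the 5'-most base of the suffix
            k = len(rev_spec)
            target_suffix = seqio.reverse_complement(rev_spec)  # target sense
            off_suffix = off_dna[-k:] if len(off_dna) >= k else off_dna
            if len(off_suffix) < k:
                terminal = True
            else:
                for i, (x, y) in enumerate(zip(target_suffix, off_suffix)):
                    if x != y:
                        if i <= 1:
                            terminal = True
                        else:
                            internal = True
        if terminal:
            out[off.id] = "discriminating"
        elif internal:
            out[off.id] = "weak"
        else:
            out[off.id] = "non-discriminating"
    return out
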