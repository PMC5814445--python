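"""Somatic/pseudosomatic variant filter cascade.

Implements the post-calling filters used for a WES screen of a mature
T-cell leukemia cohort: population-frequency exclusion, damaging-prediction
enrichment, COSMIC membership, an orientation-bias (8-oxoguanine) filter on
C:G>A:T transversions, a second-caller confirmation rule for subclonal
calls, and the targeted-amplicon (TAS) quality gate.  Every rule is
inclusive at its printed boundary (``>=`` / ``<=``).

The 8-oxoG filter follows the empirical allelic-imbalance rule: a call
passes iff its tumor load (TLOD, the log odds that the alternate reads did
not arise from the reference allele) satisfies

    TLOD >= 10 + (100/3) * FoxoG

where FoxoG is the fraction of alternate-supporting read pairs in the
orientation produced by oxidative damage of guanine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "VariantCall",
    "FilterConfig",
    "FilterVerdict",
    "is_cga_class",
    "population_filter",
    "damaging_filter",
    "compute_foxog",
    "oxog_filter",
    "second_caller_filter",
    "tas_quality_filter",
    "run_cascade",
]

INDEL_CATEGORIES = frozenset(
    {"frameshift_insertion", "frameshift_deletion",
     "nonframeshift_insertion", "nonframeshift_deletion"}
)


@dataclass
class VariantCall:
    """One somatic call with the annotations the cascade consumes.

    ``pop_freqs`` maps a population-database name (1000G, ESP6500, ExAC) to
    a minor-allele frequency; an absent source means unobserved.  The
    orientation counts ``alt_f1r2``/``alt_f2r1`` are the alternate-allele
    read pairs in each sequencing orientation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    category: str = "nonsynonymous"
    vaf: float = 0.0
    depth: int = 0
    qual: float = 0.0
    alt_f1r2: int = 0
    alt_f2r1: int = 0
    tumor_load: float = 0.0
    pop_freqs: dict[str, float] = field(default_factory=dict)
    sift: float | None = None
    polyphen2: float | None = None
    provean_damaging: bool | None = None
    cosmic: bool = False
    confirmed_by_second_caller: bool | None = None
    call_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.alt_f1r2 + self.alt_f2r1 > self.depth:
            raise ValueError("alt_f1r2 + alt_f2r1 exceeds depth")
        if self.call_id is None:
            self.call_id = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_indel(self) -> bool:
        return (len(self.ref) != len(self.alt)
                or self.category in INDEL_CATEGORIES)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults are the published values."""

    popfreq_max: float = 0.01
    polyphen2_min: float = 0.957
    sift_max: float = 0.05
    tas_qual_min: float = 100.0
    tas_depth_min: int = 10
    oxo_intercept: float = 10.0
    oxo_slope: float = 100.0 / 3.0
    require_cosmic: bool = False
    apply_damaging: bool = True
    apply_popfreq: bool = True
    apply_oxog: bool = True
    apply_second_caller: bool = True
    second_caller_vaf_min: float = 0.5
    damaging_mode: str = "or"          # "or" | "and" between PolyPhen2/SIFT
    unscored_snv_passes: bool = True   # SNV with neither score available
    tas_mode: bool = False

    def __post_init__(self) -> None:
        if self.oxo_intercept < 0 or self.oxo_slope < 0:
            raise ValueError("oxo filter slope/intercept must be >= 0")
        if self.damaging_mode not in ("or", "and"):
            raise ValueError("damaging_mode must be 'or' or 'and'")


@dataclass
class FilterVerdict:
    call_id: str
    rule_results: dict[str, bool]
    passed: bool


def is_cga_class(ref: str, alt: str) -> bool:
    """True for C:G>A:T-class single-base substitutions (C>A or G>T)."""
    return (ref.upper(), alt.upper()) in {("C", "A"), ("G", "T")}


def population_filter(call: VariantCall, cfg: FilterConfig) -> bool:
    """Fail iff any recorded population MAF is >= the threshold.

    Unobserved sources count as frequency 0 (pass).
    """
    for source, maf in call.pop_freqs.items():
        if maf is None:
            continue
        if maf < 0:
            raise ValueError(f"negative MAF for {source}: {maf}")
        if maf >= cfg.popfreq_max:
            return False
    return True


def damaging_filter(call: VariantCall, cfg: FilterConfig) -> bool:
    """Damaging-prediction enrichment.

    Indels pass iff PROVEAN calls them damaging.  SNVs pass iff PolyPhen2
    >= 0.957 or SIFT <= 0.05 (OR by default; AND available).  An SNV with
    neither score is not evaluable and passes through by default.
    """
    if call.is_indel:
        return bool(call.provean_damaging)
    pp_ok = call.polyphen2 is not None and call.polyphen2 >= cfg.polyphen2_min
    sift_ok = call.sift is not None and call.sift <= cfg.sift_max
    if call.polyphen2 is None and call.sift is None:
        return cfg.unscored_snv_passes
    if cfg.damaging_mode == "and":
        return pp_ok and sift_ok
    return pp_ok or sift_ok


def compute_foxog(call: VariantCall) -> float:
    """Orientation-bias fraction of alternate reads for C:G>A:T calls.

    For C>A the artifact orientation is F2R1; for G>T it is F1R2 (the two
    strands of the same oxidized guanine).  Returns a fraction in [0, 1].
    Raises if the call has no alternate-orientation reads.
    """
    total = call.alt_f1r2 + call.alt_f2r1
    if total <= 0:
        raise ValueError("FoxoG undefined with zero oriented alt reads")
    ra = (call.ref.upper(), call.alt.upper())
    if ra == ("C", "A"):
        return call.alt_f2r1 / total
    if ra == ("G", "T"):
        return call.alt_f1r2 / total
    raise ValueError(f"FoxoG defined only for C>A / G>T calls, got {ra}")


def oxog_filter(tumor_load: float, foxog: float, cfg: FilterConfig) -> bool:
    """Pass iff tumor_load >= intercept + slope * FoxoG (inclusive)."""
    if not 0.0 <= foxog <= 1.0:
        raise ValueError(f"foxog must be in [0, 1], got {foxog}")
    return tumor_load >= cfg.oxo_intercept + cfg.oxo_slope * foxog


def _oxog_rule(call: VariantCall, cfg: FilterConfig) -> bool:
    # Only C:G>A:T substitutions are subject to the 8-oxoG mechanism;
    # calls without oriented alt reads are exempt.
    if not is_cga_class(call.ref, call.alt) or call.is_indel:
        return True
    if call.alt_f1r2 + call.alt_f2r1 == 0:
        return True
    return oxog_filter(call.tumor_load, compute_foxog(call), cfg)


def second_caller_filter(call: VariantCall, cfg: FilterConfig) -> bool:
    """Drop subclonal calls lacking confirmation by a second caller.

    Fail iff vaf < threshold and the call is explicitly unconfirmed; a call
    with no confirmation annotation (None) is not subject to the rule.
    """
    if call.confirmed_by_second_caller is None:
        return True
    if call.vaf < cfg.second_caller_vaf_min:
        return call.confirmed_by_second_caller
    return True


def tas_quality_filter(call: VariantCall, cfg: FilterConfig) -> bool:
    """Targeted-amplicon gate: qual >= 100 and depth >= 10, inclusive."""
    return call.qual >= cfg.tas_qual_min and call.depth >= cfg.tas_depth_min


def _cosmic_rule(call: VariantCall, cfg: FilterConfig) -> bool:
    return call.cosmic


def enabled_rules(cfg: FilterConfig) -> list[tuple[str, object]]:
    """The cascade's rules in their fixed application order."""
    rules: list[tuple[str, object]] = []
    if cfg.apply_popfreq:
        rules.append(("population", population_filter))
    if cfg.apply_damaging:
        rules.append(("damaging", damaging_filter))
    if cfg.require_cosmic:
        rules.append(("cosmic", _cosmic_rule))
    if cfg.apply_second_caller:
        rules.append(("second_caller", second_caller_filter))
    if cfg.apply_oxog:
        rules.append(("oxog", _oxog_rule))
    if cfg.tas_mode:
        rules.append(("tas_quality", tas_quality_filter))
    return rules


def run_cascade(
    calls: list[VariantCall], cfg: FilterConfig | None = None
) -> tuple[list[VariantCall], dict[str, int], list[FilterVerdict]]:
    """Apply every enabled rule to every call.

    Returns the surviving calls (all rules passed), a tally attributing
    each removal to the *first* failing rule in the fixed order, and the
    full per-call verdicts.  The surviving set is order-independent (it is
    the conjunction of the rule predicates); only the tally depends on the
    order.
    """
    cfg = cfg or FilterConfig()
    rules = enabled_rules(cfg)
    seen: set[str] = set()
    tally: dict[str, int] = {name: 0 for name, _ in rules}
    surviving: list[VariantCall] = []
    verdicts: list[FilterVerdict] = []
    for call in calls:
        if call.call_id in seen:
            raise ValueError(f"duplicate call id: {call.call_id}")
        seen.add(call.call_id)
        results = {name: bool(rule(call, cfg)) for name, rule in rules}
        passed = all(results.values())
        if not passed:
            first_fail = next(n for n, _ in rules if not results[n])
            tally[first_fail] += 1
        else:
            surviving.append(call)
        verdicts.append(FilterVerdict(call.call_id, results, passed))
    return surviving, tally, verdicts
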