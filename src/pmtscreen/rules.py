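"""Tiered P / M / T assessment against the EU CLP screening cutoffs.

Persistence is judged on freshwater degradation half-lives (P > 40 d,
vP > 60 d), mobility on log Koc over pH 4-9 (M < 3.0, vM < 2.0, strict
inequalities as printed in the regulation-derived scheme), and toxicity on
presence of any CLP hazard flag (CMR, aquatic toxicity, STOT RE, endocrine
disruption).  This is a screening scheme, not a full weight-of-evidence
assessment; every assessment carries that caveat in its audit trail.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .io import CompoundRecord, KnownListEntry, PropertyRecord, canonical_smiles

# tier labels
NOT_P, P, VP, UNKNOWN = "not_P", "P", "vP", "unknown"
NOT_M, M, VM = "not_M", "M", "vM"
T, NOT_ESTABLISHED = "T", "not_established"

PERSISTENCE_TIERS = (NOT_P, P, VP, UNKNOWN)
MOBILITY_TIERS = (NOT_M, M, VM, UNKNOWN)
TOXICITY_TIERS = (T, NOT_ESTABLISHED, UNKNOWN)

# hazard classes
PMT = "PMT"
VPVM = "vPvM"
PMT_AND_VPVM = "PMT_and_vPvM"
NOT_PMT_VPVM = "not_PMT_vPvM"
CANDIDATE = "candidate_PMT_vPvM"
UNRESOLVED = "unresolved"

HAZARD_CLASSES = (PMT, VPVM, PMT_AND_VPVM, NOT_PMT_VPVM, CANDIDATE, UNRESOLVED)
POSITIVE_CLASSES = (PMT, VPVM, PMT_AND_VPVM, CANDIDATE)

SCREENING_CAVEAT = (
    "screening-level assessment; does not follow full weight-of-evidence protocols"
)


@dataclass(frozen=True)
class RuleConfig:
    """Cutoffs of the screening scheme; defaults are the printed CLP values."""

    persistence_P_days: float = 40.0
    persistence_vP_days: float = 60.0
    logkoc_M: float = 3.0
    logkoc_vM: float = 2.0
    half_life_aggregation: str = "median"  # or "max" for worst case


@dataclass(frozen=True)
class CriterionTier:
    persistence: str = UNKNOWN
    mobility: str = UNKNOWN
    toxicity: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.persistence not in PERSISTENCE_TIERS:
            raise ValueError(f"bad persistence tier {self.persistence!r}")
        if self.mobility not in MOBILITY_TIERS:
            raise ValueError(f"bad mobility tier {self.mobility!r}")
        if self.toxicity not in TOXICITY_TIERS:
            raise ValueError(f"bad toxicity tier {self.toxicity!r}")


@dataclass
class HazardAssessment:
    """Per-compound screening outcome with an audit trail."""

    compound_id: str
    tier: CriterionTier
    hazard_class: str
    decided_by: str  # known_list | rules | ml_model | none
    detail: str = ""

    def __post_init__(self) -> None:
        if self.hazard_class not in HAZARD_CLASSES:
            raise ValueError(f"bad hazard class {self.hazard_class!r}")
        if self.hazard_class == CANDIDATE and self.decided_by != "ml_model":
            raise ValueError("candidate_PMT_vPvM only arises from the ML model")
        if self.decided_by == "none" and self.hazard_class != UNRESOLVED:
            raise ValueError("decided_by=none requires hazard_class=unresolved")


def aggregate_half_life(values: list[float], config: RuleConfig) -> float | None:
    if not values:
        return None
    if config.half_life_aggregation == "max":
        return max(values)
    return statistics.median(values)


def assess_persistence(props: PropertyRecord, config: RuleConfig = RuleConfig()) -> str:
    """P tier from freshwater half-lives: > 60 d vP, > 40 d P, else not_P.

    Boundary values sit on the non-persistent side of each cutoff (a 40 d
    half-life is not P; 60 d is P but not vP).  Multiple reported values are
    aggregated by the configured rule (median by default).
    """
    hl = aggregate_half_life(props.half_lives_freshwater_days, config)
    if hl is None:
        return UNKNOWN
    if hl > config.persistence_vP_days:
        return VP
    if hl > config.persistence_P_days:
        return P
    return NOT_P


def assess_mobility(props: PropertyRecord, config: RuleConfig = RuleConfig()) -> str:
    """M tier from log Koc over pH 4-9: < 2.0 vM, < 3.0 M, else not_M.

    The minimum over the reported pH range is used (the most mobile observed
    speciation — conservative for water protection).  Inequalities are
    strict: log Koc of exactly 3.0 is not M, 2.0 is not vM.
    """
    if not props.log_koc_by_ph:
        return UNKNOWN
    koc = min(v for _, v in props.log_koc_by_ph)
    if koc < config.logkoc_vM:
        return VM
    if koc < config.logkoc_M:
        return M
    return NOT_M


def assess_toxicity(props: PropertyRecord, config: RuleConfig = RuleConfig()) -> str:
    """T if any CLP hazard flag is present; otherwise not_established only
    when experimental evidence exists (absence of evidence stays unknown)."""
    if props.tox_flags:
        return T
    if props.evidence_quality == "experimental":
        return NOT_ESTABLISHED
    return UNKNOWN


def assess_tiers(props: PropertyRecord, config: RuleConfig = RuleConfig()) -> CriterionTier:
    return CriterionTier(
        persistence=assess_persistence(props, config),
        mobility=assess_mobility(props, config),
        toxicity=assess_toxicity(props, config),
    )


def combine_tiers(tier: CriterionTier) -> str:
    """Combine P/M/T tiers into a hazard class.

    PMT requires P, M and T; vPvM requires vP and vM but no toxicity;
    a compound can be both.  A definitive failure on persistence or
    mobility is negative regardless of the other tiers; otherwise missing
    data leaves the compound unresolved (routed to the ML step).
    """
    p, m, t = tier.persistence, tier.mobility, tier.toxicity
    if p == NOT_P or m == NOT_M:
        return NOT_PMT_VPVM
    if p == UNKNOWN or m == UNKNOWN:
        return UNRESOLVED
    very = p == VP and m == VM
    if t == T:
        return PMT_AND_VPVM if very else PMT
    if very:
        # vPvM needs no toxicity finding
        return VPVM
    if t == NOT_ESTABLISHED:
        # P and M satisfied below the very level, toxicity ruled not established
        return NOT_PMT_VPVM
    return UNRESOLVED  # toxicity unknown, could still be PMT


def assess_compound(
    compound_id: str, props: PropertyRecord, config: RuleConfig = RuleConfig()
) -> HazardAssessment:
    """Full rule-based assessment of one compound from its evidence record."""
    tier = assess_tiers(props, config)
    hazard_class = combine_tiers(tier)
    decided = "rules" if hazard_class != UNRESOLVED else "none"
    detail = (
        f"tiers P={tier.persistence} M={tier.mobility} T={tier.toxicity}; "
        f"{SCREENING_CAVEAT}"
    )
    return HazardAssessment(
        compound_id=compound_id,
        tier=tier,
        hazard_class=hazard_class,
        decided_by=decided,
        detail=detail,
    )


def build_known_index(known: list[KnownListEntry]) -> dict[str, str]:
    index: dict[str, str] = {}
    for entry in known:
        if entry.match_key in index and index[entry.match_key] != entry.listed_class:
            raise ValueError(f"conflicting known-list entries for {entry.match_key!r}")
        index[entry.match_key] = entry.listed_class
    return index


def lookup_known(
    record: CompoundRecord, known: list[KnownListEntry] | dict[str, str]
) -> HazardAssessment | None:
    """Match a compound against the known PMT/vPvM list.

    Matching is by canonical structure first, then CAS number.  Returns the
    listed class as an assessment decided by the known list, or None.
    """
    index = known if isinstance(known, dict) else build_known_index(known)
    keys = []
    can = canonical_smiles(record.smiles)
    if can is not None:
        keys.append(can)
    if record.cas:
        keys.append(record.cas)
    for key in keys:
        if key in index:
            return HazardAssessment(
                compound_id=record.compound_id,
                tier=CriterionTier(),
                hazard_class=index[key],
                decided_by="known_list",
                detail=f"matched known list by {'structure' if key == can else 'CAS'}",
            )
    return None
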