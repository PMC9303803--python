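"""Priority-tiered selection of the final array panel.

Tiers are admitted in priority order, each under its own MAF /
call-rate / conversion-class thresholds.  Candidate-gene tiers use a
lenient rule (low MAF floor, call rate above 0.90, CRBT admitted);
everything else requires a converted polymorphic marker.  When the
admitted pool overshoots the target size, only the lowest admitted
tier is trimmed, dropping its lowest-MAF markers first — higher tiers
are mandatory and overflowing them is an error, never a silent cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ValidationError

__all__ = ["TierRule", "SelectionPolicy", "default_policy", "select_panel", "vip_boost"]


@dataclass
class TierRule:
    """Admission rule for one priority tier.

    ``sources=None`` makes the tier a catch-all for markers not claimed
    by an earlier tier.
    """

    name: str
    sources: frozenset[str] | None
    min_maf: float = 0.05
    min_call_rate: float = 0.97
    allowed_classes: frozenset[str] = frozenset({"PHR", "NMH"})


@dataclass
class SelectionPolicy:
    tiers: list[TierRule] = field(default_factory=list)
    target_size: int = 0

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValidationError("policy admits zero tiers")
        if self.target_size <= 0:
            raise ValidationError("target_size must be positive")
        claimed: set[str] = set()
        for tier in self.tiers:
            if tier.sources is None:
                continue
            overlap = claimed & tier.sources
            if overlap:
                raise ValidationError(f"tiers overlap on sources {sorted(overlap)}")
            claimed |= tier.sources


def default_policy(target_size: int = 47712) -> SelectionPolicy:
    """The shipped tier layout: proven array markers first, then
    candidate-gene markers under the lenient rule, then the general
    pool with a raised MAF floor for the residual fill."""
    return SelectionPolicy(
        tiers=[
            TierRule("array_best", frozenset({"ukceh1"}), 0.05, 0.97),
            TierRule(
                "candidate",
                frozenset({"uoulu_candidate", "luke_candidate"}),
                0.01,
                0.90,
                frozenset({"PHR", "NMH", "CRBT"}),
            ),
            TierRule("general", None, 0.08, 0.97),
        ],
        target_size=target_size,
    )


def _admit(tier: TierRule, pool: pd.DataFrame) -> pd.DataFrame:
    ok = (
        (pool["maf"].to_numpy(dtype=float) >= tier.min_maf)
        & (pool["call_rate"].to_numpy(dtype=float) >= tier.min_call_rate)
        & pool["conversion_class"].isin(tier.allowed_classes).to_numpy()
    )
    return pool[ok]


def select_panel(
    marker_table: pd.DataFrame, policy: SelectionPolicy
) -> tuple[list[str], pd.DataFrame]:
    """Select the panel; returns (sorted marker ids, audit table).

    The audit table records, per admitted marker, the tier that claimed
    it and whether it survived residual trimming; a shortfall (pool
    smaller than target) is reported in the audit attrs, never padded.
    """
    required = {"marker_id", "source", "maf", "call_rate", "conversion_class"}
    missing = required - set(marker_table.columns)
    if missing:
        raise ValidationError(f"marker table lacks columns {sorted(missing)}")
    remaining = marker_table.copy()
    admitted_per_tier: list[pd.DataFrame] = []
    for tier in policy.tiers:
        if tier.sources is None:
            pool = remaining
        else:
            pool = remaining[remaining["source"].isin(tier.sources)]
        hits = _admit(tier, pool).copy()
        hits["tier"] = tier.name
        admitted_per_tier.append(hits)
        remaining = remaining[~remaining["marker_id"].isin(hits["marker_id"])]
    mandatory_total = sum(len(t) for t in admitted_per_tier[:-1])
    if mandatory_total > policy.target_size:
        sizes = {t["tier"].iloc[0]: len(t) for t in admitted_per_tier[:-1] if len(t)}
        raise ValidationError(
            f"mandatory tiers hold {mandatory_total} markers, exceeding "
            f"target_size {policy.target_size}: {sizes}"
        )
    last = admitted_per_tier[-1]
    room = policy.target_size - mandatory_total
    trimmed_ids: set[str] = set()
    if len(last) > room:
        # drop lowest-MAF residual markers first; ties by marker_id so
        # the fill is deterministic and nested in target_size
        order = last.sort_values(["maf", "marker_id"], ascending=[False, True])
        trimmed_ids = set(order["marker_id"].iloc[room:])
    audit = pd.concat(admitted_per_tier, ignore_index=True)
    audit["selected"] = ~audit["marker_id"].isin(trimmed_ids)
    selected = sorted(audit.loc[audit["selected"], "marker_id"])
    audit.attrs["target_size"] = policy.target_size
    audit.attrs["shortfall"] = max(0, policy.target_size - len(selected))
    return selected, audit


def vip_boost(
    marker_table: pd.DataFrame, vip_ids: list[str], factor: int = 2
) -> pd.DataFrame:
    """Probe-set replication plan for markers of special interest.

    VIP markers get ``factor`` probe sets (raising their effective call
    rate on the array); everyone else gets one.  Metadata only — no
    genotype effect is modeled.
    """
    known = set(marker_table["marker_id"])
    unknown = [v for v in vip_ids if v not in known]
    if unknown:
        raise ValidationError(f"unknown VIP marker ids: {unknown}")
    vip = set(vip_ids)
    return pd.DataFrame(
        {
            "marker_id": marker_table["marker_id"],
            "probe_count": [factor if m in vip else 1 for m in marker_table["marker_id"]],
        }
    )
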