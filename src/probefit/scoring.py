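"""Fitness-factor scores and the weighted Global Score.

Six component scores are computed per active compound-reference-target pair:

* **potency** — linear normalization of the capped median pActivity from 0
  (pActivity 5) to 1 (pActivity >= 10);
* **selectivity** — mean of three factors: the fraction of 10-fold-selective
  off-targets, a per-target-normalized information-richness term built on the
  SIC statistic, and the screened fraction of the liganded proteome;
* **cell** — binary: active (median pActivity > 5) in at least one cell line;
* **sar**, **inactive_analog**, **pains** — binary scores computed in
  :mod:`probefit.structures`.

The Global Score is the weighted arithmetic mean of the six components with
default weights (selectivity 8, potency 4, cell 2, SAR/inactive-analog/PAINS
1 each).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from probefit.ingest import ACTIVITY_THRESHOLD_PACTIVITY, AggregatedPairActivity

__all__ = [
    "DEFAULT_WEIGHTS",
    "SELECTIVE_DELTA",
    "RankedEntry",
    "ScoreVector",
    "SelectivityBreakdown",
    "Weights",
    "build_selectivity_breakdown",
    "cell_score",
    "danger_flag",
    "first_factor",
    "global_score",
    "normalize_second_factor",
    "potency_score",
    "rank_compounds",
    "second_factor_raw",
    "selectivity_information_richness",
    "selectivity_score",
    "third_factor",
]

#: Minimum pActivity difference (log units) for an off-target to count as
#: 10-fold selective.
SELECTIVE_DELTA = 1.0

ORDER_KEYS = ("global", "potency", "selectivity", "cell")


@dataclass(frozen=True)
class Weights:
    """Non-negative Global Score weights.

    ``a``..``f`` weight selectivity, potency, cell, SAR, inactive-analog and
    PAINS scores respectively.
    """

    a: float = 8.0
    b: float = 4.0
    c: float = 2.0
    d: float = 1.0
    e: float = 1.0
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in "abcdef":
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be non-negative")
        if self.total <= 0:
            raise ValueError("at least one weight must be positive")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d + self.e + self.f

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "Weights":
        known = {k: float(v) for k, v in mapping.items() if k in "abcdef"}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValueError(f"unknown weight name(s): {sorted(unknown)}")
        return cls(**known)


DEFAULT_WEIGHTS = Weights()


@dataclass(frozen=True)
class SelectivityBreakdown:
    """All intermediates of the selectivity computation for one pair."""

    n_off_targets: int
    n_selective_off_targets: int
    first_factor: float
    sic: float
    second_factor_raw: float
    second_factor_norm: float
    third_factor: float

    def __post_init__(self) -> None:
        if self.n_selective_off_targets > self.n_off_targets:
            raise ValueError("selective off-targets cannot exceed off-targets")

    @property
    def n_unselective_off_targets(self) -> int:
        return self.n_off_targets - self.n_selective_off_targets


@dataclass(frozen=True)
class ScoreVector:
    """The six component scores plus the Global Score for one pair."""

    compound_id: str
    target_accession: str
    potency: float
    selectivity: float
    cell: int
    sar: int
    inactive_analog: int
    pains: int
    global_: float

    def component(self, key: str) -> float:
        if key == "global":
            return self.global_
        if key in ("potency", "selectivity", "cell"):
            return float(getattr(self, key))
        raise ValueError(f"unknown order key: {key!r} (expected one of {ORDER_KEYS})")

    def as_radar(self) -> dict[str, float]:
        """Six axes in [0, 1] for a radar plot."""
        return {
            "potency": self.potency,
            "selectivity": self.selectivity,
            "cell": float(self.cell),
            "sar": float(self.sar),
            "inactive_analog": float(self.inactive_analog),
            "pains": float(self.pains),
        }


@dataclass(frozen=True)
class RankedEntry:
    rank: int
    compound_id: str
    value: float
    scores: ScoreVector


def potency_score(pair: AggregatedPairActivity) -> float:
    """Normalize the capped median pActivity onto [0, 1].

    Only active pairs are scored as probes; calling on an inactive pair is a
    contract violation.
    """
    if not pair.active:
        raise ValueError(
            f"potency_score requires an active pair "
            f"({pair.compound_id}/{pair.target_accession} is inactive)"
        )
    return min(1.0, max(0.0, (pair.median_pactivity - 5.0) / 5.0))


def first_factor(
    profile: Mapping[str, float], reference: str
) -> tuple[float, int, int]:
    """Fraction of tested off-targets that are 10-fold selective.

    ``profile`` maps every target the compound was screened against
    (regardless of activity outcome) to its capped median pActivity.
    Returns ``(first_factor, n_off_targets, n_selective)``; the factor is 0
    when there are no off-targets (the selectivity score is forced to 0
    upstream in that case).
    """
    if reference not in profile:
        raise ValueError(f"reference target {reference!r} absent from profile")
    ref = profile[reference]
    offs = [p for t, p in profile.items() if t != reference]
    n_off = len(offs)
    if n_off == 0:
        return 0.0, 0, 0
    n_sel = sum(1 for p in offs if ref - p >= SELECTIVE_DELTA)
    return n_sel / n_off, n_off, n_sel


def selectivity_information_richness(profile: Mapping[str, float], reference: str) -> float:
    """SIC: sum over off-targets of (pActivity_ref - pActivity_off - 1).

    Negative contributions from unselective off-targets are retained, so
    unselective data compensate for selective data.
    """
    if reference not in profile:
        raise ValueError(f"reference target {reference!r} absent from profile")
    ref = profile[reference]
    return sum(ref - p - SELECTIVE_DELTA for t, p in profile.items() if t != reference)


def second_factor_raw(sic: float, n_unselective_off_targets: int) -> float:
    """SIC divided by the number of co-modulated targets.

    The denominator counts off-targets that are *not* 10-fold selective plus
    the reference target itself.
    """
    if n_unselective_off_targets < 0:
        raise ValueError("n_unselective_off_targets must be non-negative")
    return sic / (n_unselective_off_targets + 1)


def normalize_second_factor(cohort: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize raw second factors within one reference target.

    Degenerate cohorts (singleton or all-equal) map every member to 0: no
    compound earns selectivity-information credit it cannot demonstrate.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    lo, hi = min(cohort.values()), max(cohort.values())
    if hi == lo:
        return {k: 0.0 for k in cohort}
    return {k: (v - lo) / (hi - lo) for k, v in cohort.items()}


def third_factor(n_off_targets: int, n_liganded_targets: int) -> float:
    """Screened fraction of the liganded proteome: (n_off + 1) / n_liganded.

    Clamped at 1 so the selectivity score stays within [0, 1] in the
    exhaustive-screening limit.
    """
    if n_liganded_targets < 1:
        raise ValueError("n_liganded_targets must be >= 1")
    if n_off_targets < 0:
        raise ValueError("n_off_targets must be non-negative")
    return min(1.0, (n_off_targets + 1) / n_liganded_targets)


def build_selectivity_breakdown(
    profile: Mapping[str, float],
    reference: str,
    n_liganded_targets: int,
    second_factor_norm: float = 0.0,
) -> SelectivityBreakdown:
    """Assemble all selectivity intermediates for one compound-target pair.

    ``second_factor_norm`` is a placeholder until the per-target cohort
    normalization is applied (see :func:`normalize_second_factor`).
    """
    ff, n_off, n_sel = first_factor(profile, reference)
    sic = selectivity_information_richness(profile, reference)
    raw = second_factor_raw(sic, n_off - n_sel)
    return SelectivityBreakdown(
        n_off_targets=n_off,
        n_selective_off_targets=n_sel,
        first_factor=ff,
        sic=sic,
        second_factor_raw=raw,
        second_factor_norm=second_factor_norm,
        third_factor=third_factor(n_off, n_liganded_targets),
    )


def with_second_norm(
    breakdown: SelectivityBreakdown, second_factor_norm: float
) -> SelectivityBreakdown:
    return replace(breakdown, second_factor_norm=second_factor_norm)


def selectivity_score(breakdown: SelectivityBreakdown) -> float:
    """Mean of the three selectivity factors; 0 without off-target data."""
    if breakdown.n_off_targets == 0:
        return 0.0
    return (
        breakdown.first_factor + breakdown.second_factor_norm + breakdown.third_factor
    ) / 3.0


def cell_score(cell_aggregates: Iterable[AggregatedPairActivity]) -> int:
    """1 iff the compound is active (median pActivity > 5) in any cell line."""
    return int(any(agg.active for agg in cell_aggregates))


def global_score(
    potency: float,
    selectivity: float,
    cell: float,
    sar: float,
    inactive_analog: float,
    pains: float,
    weights: Weights = DEFAULT_WEIGHTS,
) -> float:
    """Weighted arithmetic mean of the six component scores."""
    w = weights
    return (
        w.a * selectivity
        + w.b * potency
        + w.c * cell
        + w.d * sar
        + w.e * inactive_analog
        + w.f * pains
    ) / w.total


def danger_flag(breakdown: SelectivityBreakdown) -> bool:
    """True iff at least one tested off-target fails 10-fold selectivity.

    Absence of off-target data does not raise the flag: it signals an
    observed selectivity failure, not missing evidence.
    """
    return (
        breakdown.n_off_targets > 0
        and breakdown.n_selective_off_targets < breakdown.n_off_targets
    )


def rank_compounds(
    scored: Sequence[ScoreVector], order_key: str = "global"
) -> list[RankedEntry]:
    """Order compounds descending by the chosen score; ranks are 1-based.

    Ties break by ascending compound_id so outputs are bit-reproducible.
    """
    if not scored:
        raise ValueError("cannot rank an empty collection")
    if order_key not in ORDER_KEYS:
        raise ValueError(f"unknown order key: {order_key!r} (expected one of {ORDER_KEYS})")
    ordered = sorted(scored, key=lambda s: (-s.component(order_key), s.compound_id))
    return [
        RankedEntry(rank=i + 1, compound_id=s.compound_id, value=s.component(order_key), scores=s)
        for i, s in enumerate(ordered)
    ]
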