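"""Target-level aggregation: icons, minimum-standard probes, Information
Richness and liganded-proteome summaries.

Two selectivity semantics coexist deliberately. The target *selectivity icon*
asks for at least one selective off-target (an existence reading), whereas the
*minimum standard* requires 10-fold selectivity against every tested
off-target. Both are retained as stated by their respective sources rather
than harmonized; see the README.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from probefit.pipeline import ScoreRun

__all__ = [
    "DEFAULT_PROTEOME_SIZE",
    "TargetAssessment",
    "assess_targets",
    "information_richness",
    "information_richness_percentiles",
    "is_minimum_standard",
    "proteome_summary",
]

#: Curated, validated human proteome size used for default fractions;
#: configuration, never hard-coded downstream, since the count changes.
DEFAULT_PROTEOME_SIZE = 20_171

#: Potency floor for minimum-standard probes: 100 nM or better.
MINIMUM_STANDARD_PACTIVITY = 7.0


@dataclass(frozen=True)
class TargetAssessment:
    """Per-target icon booleans, probe counts and Information Richness."""

    target_accession: str
    information_richness_value: int
    information_richness_percentile: float
    selectivity_icon: bool
    potency_icon: bool
    cell_icon: bool
    minimum_standard_icon: bool
    sar_icon: bool
    inactive_analog_icon: bool
    non_pains_icon: bool
    n_active_compounds: int
    n_minimum_standard_compounds: int

    @property
    def icons(self) -> dict[str, bool]:
        return {
            "selectivity": self.selectivity_icon,
            "potency": self.potency_icon,
            "cell": self.cell_icon,
            "minimum_standard": self.minimum_standard_icon,
            "sar": self.sar_icon,
            "inactive_analog": self.inactive_analog_icon,
            "non_pains": self.non_pains_icon,
        }


def is_minimum_standard(
    median_pactivity: float,
    cell: int,
    n_off_targets: int,
    n_selective_off_targets: int,
) -> bool:
    """Minimum-standard probe: potency >= 100 nM equivalent (pActivity >= 7),
    cell-active, and 10-fold selective against *all* of >= 1 tested
    off-targets.
    """
    return (
        median_pactivity >= MINIMUM_STANDARD_PACTIVITY
        and cell == 1
        and n_off_targets >= 1
        and n_selective_off_targets == n_off_targets
    )


def information_richness(target: str, run: "ScoreRun") -> int:
    """Testing-breadth tally for one target.

    For every compound *active* against the target, count the number of
    targets that compound was tested against (including the reference).
    Equivalently: the number of active compounds plus, per compound, the
    number of *other* targets it was screened against.
    """
    if target not in {t for (_c, t) in run.bio_aggregates}:
        raise KeyError(f"unknown target: {target!r}")
    total = 0
    for (cid, tgt), agg in run.bio_aggregates.items():
        if tgt == target and agg.active:
            total += len(run.profiles[cid])
    return total


def information_richness_percentiles(values: Mapping[str, int]) -> dict[str, float]:
    """Rank-based percentile in [0, 100], ties sharing a value.

    Anchored so the most information-rich target(s) map to 100 and the least
    to 0. Degenerate cohorts where every target has equal information map to
    0 (no target can claim above-average information), except a singleton
    cohort whose only member is by definition the richest (100).
    """
    if not values:
        raise ValueError("need at least one target")
    if len(values) == 1:
        return {t: 100.0 for t in values}
    lo, hi = min(values.values()), max(values.values())
    if lo == hi:
        return {t: 0.0 for t in values}
    ordered = sorted(values.values())
    out: dict[str, float] = {}
    for t, v in values.items():
        smaller = sum(1 for x in ordered if x < v)
        greater = sum(1 for x in ordered if x > v)
        out[t] = 100.0 * smaller / (smaller + greater)
    return out


def assess_targets(run: "ScoreRun") -> dict[str, TargetAssessment]:
    """Build the per-target icon panel and Information Richness table.

    Covers every target with at least one aggregated biochemical record.
    """
    all_targets = sorted({t for (_c, t) in run.bio_aggregates})
    ir = {t: information_richness(t, run) for t in all_targets}
    pct = information_richness_percentiles(ir) if ir else {}

    out: dict[str, TargetAssessment] = {}
    for tgt in all_targets:
        scored = [p for (c, t), p in run.pairs.items() if t == tgt]
        n_min = sum(1 for p in scored if p.minimum_standard)
        out[tgt] = TargetAssessment(
            target_accession=tgt,
            information_richness_value=ir[tgt],
            information_richness_percentile=pct[tgt],
            selectivity_icon=any(
                p.breakdown.n_off_targets >= 1 and p.breakdown.n_selective_off_targets >= 1
                for p in scored
            ),
            potency_icon=any(
                p.aggregate.median_pactivity >= MINIMUM_STANDARD_PACTIVITY for p in scored
            ),
            cell_icon=any(p.scores.cell == 1 for p in scored),
            minimum_standard_icon=n_min >= 1,
            sar_icon=any(p.scores.sar == 1 for p in scored),
            inactive_analog_icon=any(p.scores.inactive_analog == 1 for p in scored),
            non_pains_icon=any(p.scores.pains == 1 for p in scored),
            n_active_compounds=len(scored),
            n_minimum_standard_compounds=n_min,
        )
    return out


def proteome_summary(run: "ScoreRun", proteome_size: int = DEFAULT_PROTEOME_SIZE) -> dict:
    """Counts and proteome fractions of nested target quality tiers.

    Tiers: liganded (>= 1 active compound) ⊇ potent (>= 1 compound at
    pActivity >= 7) ⊇ potent+selective (>= 1 potent compound 10-fold
    selective against all of >= 1 tested off-targets) ⊇ minimum standard
    (additionally cell-active).
    """
    if proteome_size < 1:
        raise ValueError("proteome_size must be positive")
    liganded = {t for (_c, t), agg in run.bio_aggregates.items() if agg.active}
    potent = {
        t
        for (_c, t), p in run.pairs.items()
        if p.aggregate.median_pactivity >= MINIMUM_STANDARD_PACTIVITY
    }
    potent_selective = {
        t
        for (_c, t), p in run.pairs.items()
        if p.aggregate.median_pactivity >= MINIMUM_STANDARD_PACTIVITY
        and p.breakdown.n_off_targets >= 1
        and p.breakdown.n_selective_off_targets == p.breakdown.n_off_targets
    }
    minimum = {t for (_c, t), p in run.pairs.items() if p.minimum_standard}

    warning = ""
    if proteome_size < len(liganded):
        warning = (
            f"proteome_size {proteome_size} is smaller than the liganded "
            f"target count {len(liganded)}"
        )
    counts = {
        "liganded": len(liganded),
        "potent": len(potent),
        "potent_selective": len(potent_selective),
        "minimum_standard": len(minimum),
    }
    return {
        "proteome_size": proteome_size,
        "counts": counts,
        "fractions": {k: v / proteome_size for k, v in counts.items()},
        "n_compounds_minimum_standard": len(
            {c for (c, _t), p in run.pairs.items() if p.minimum_standard}
        ),
        "warning": warning,
    }
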