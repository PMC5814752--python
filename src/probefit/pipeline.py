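"""End-to-end scoring pipeline: ingest -> structures -> scores -> rankings.

:func:`run_scoring` turns a collection of raw measurements plus a
compound -> SMILES map into a :class:`ScoreRun`: every active
compound-reference-target pair gets a full :class:`~probefit.scoring.ScoreVector`
with its selectivity breakdown, danger flag and minimum-standard status, and
compounds are ranked per target.

Compounds without any structure cannot be assessed on the three
structure-dependent factors; their SAR, inactive-analog and PAINS scores are
emitted as 0 with a warning (an unparseable structure, by contrast, keeps
PAINS at 1 because no alert is observable).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from probefit import structures as chem
from probefit.ingest import (
    BIOCHEMICAL,
    CELL,
    AggregatedPairActivity,
    Measurement,
    aggregate_pair,
)
from probefit.scoring import (
    DEFAULT_WEIGHTS,
    RankedEntry,
    ScoreVector,
    SelectivityBreakdown,
    Weights,
    build_selectivity_breakdown,
    cell_score,
    danger_flag,
    global_score,
    normalize_second_factor,
    potency_score,
    rank_compounds,
    with_second_norm,
)

logger = logging.getLogger(__name__)

__all__ = ["ScoredPair", "ScoreRun", "run_scoring"]


@dataclass(frozen=True)
class ScoredPair:
    """One active compound-reference-target pair with all scoring artifacts."""

    compound_id: str
    target_accession: str
    aggregate: AggregatedPairActivity
    breakdown: SelectivityBreakdown
    scores: ScoreVector
    danger: bool
    minimum_standard: bool


@dataclass
class ScoreRun:
    """All artifacts of one scoring run over a dataset."""

    pairs: dict[tuple[str, str], ScoredPair]
    bio_aggregates: dict[tuple[str, str], AggregatedPairActivity]
    cell_aggregates: dict[str, list[AggregatedPairActivity]]
    profiles: dict[str, dict[str, float]]
    rankings: dict[str, list[RankedEntry]]
    n_liganded_targets: int
    weights: Weights
    order_key: str
    scaffolds: dict[str, chem.ScaffoldAssignment] = field(default_factory=dict)
    pains: dict[str, chem.PainsResult] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def targets(self) -> list[str]:
        return sorted(self.rankings)

    def active_compounds(self, target: str) -> list[str]:
        return sorted(c for (c, t) in self.pairs if t == target)

    def probe_card(self, compound_id: str, target: str) -> dict:
        """Single-probe synopsis: scores, rank, breakdown, activity profile."""
        key = (compound_id, target)
        if key not in self.pairs:
            raise KeyError(f"no scored pair for compound {compound_id!r} on target {target!r}")
        pair = self.pairs[key]
        rank = next(e.rank for e in self.rankings[target] if e.compound_id == compound_id)
        bd = pair.breakdown
        return {
            "compound_id": compound_id,
            "target_accession": target,
            "rank": rank,
            "order_key": self.order_key,
            "scores": {**pair.scores.as_radar(), "global": pair.scores.global_},
            "selectivity_breakdown": {
                "n_off_targets": bd.n_off_targets,
                "n_selective_off_targets": bd.n_selective_off_targets,
                "first_factor": bd.first_factor,
                "sic": bd.sic,
                "second_factor_raw": bd.second_factor_raw,
                "second_factor_norm": bd.second_factor_norm,
                "third_factor": bd.third_factor,
            },
            "danger": pair.danger,
            "minimum_standard": pair.minimum_standard,
            "median_pactivity": pair.aggregate.median_pactivity,
            "mad": pair.aggregate.mad,
            "activity_profile": dict(sorted(self.profiles[compound_id].items())),
        }


def _aggregate_by_pair(
    measurements: Iterable[Measurement],
) -> tuple[dict[tuple[str, str], AggregatedPairActivity], dict[str, list[AggregatedPairActivity]]]:
    bio_groups: dict[tuple[str, str], list[Measurement]] = defaultdict(list)
    cell_groups: dict[tuple[str, str], list[Measurement]] = defaultdict(list)
    for m in measurements:
        if m.assay_kind == BIOCHEMICAL:
            bio_groups[m.pair_key].append(m)
        elif m.assay_kind == CELL:
            cell_groups[m.pair_key].append(m)
    bio = {key: aggregate_pair(group) for key, group in sorted(bio_groups.items())}
    cell: dict[str, list[AggregatedPairActivity]] = defaultdict(list)
    for (cid, _line), group in sorted(cell_groups.items()):
        cell[cid].append(aggregate_pair(group))
    return bio, dict(cell)


def run_scoring(
    measurements: Sequence[Measurement],
    structures: Optional[Mapping[str, str]] = None,
    weights: Weights = DEFAULT_WEIGHTS,
    liganded_target_count: Optional[int] = None,
    order_key: str = "global",
) -> ScoreRun:
    """Score every active compound-reference-target pair in the dataset.

    ``liganded_target_count`` overrides the default denominator of the third
    selectivity factor (distinct targets with at least one active compound in
    the loaded data).
    """
    from probefit.assess import is_minimum_standard

    structures = dict(structures or {})
    warnings: list[str] = []

    bio, cell = _aggregate_by_pair(measurements)

    profiles: dict[str, dict[str, float]] = defaultdict(dict)
    for (cid, tgt), agg in bio.items():
        profiles[cid][tgt] = agg.median_pactivity

    liganded = {tgt for (_cid, tgt), agg in bio.items() if agg.active}
    n_liganded = liganded_target_count if liganded_target_count is not None else len(liganded)
    n_liganded = max(1, n_liganded)

    # Publication ids per (compound, target), for the SAR same-publication rule.
    pubmed: dict[tuple[str, str], set[str]] = defaultdict(set)
    for m in measurements:
        if m.assay_kind == BIOCHEMICAL and m.pubmed_id:
            pubmed[m.pair_key].add(m.pubmed_id)

    compounds = sorted(profiles)
    scaffolds: dict[str, chem.ScaffoldAssignment] = {}
    pains: dict[str, chem.PainsResult] = {}
    for cid in compounds:
        smiles = structures.get(cid, "")
        if not smiles:
            continue
        scaffolds[cid] = chem.level1_scaffold(smiles, cid)
        pains[cid] = chem.pains_score(smiles, cid)
        if scaffolds[cid].error:
            warnings.append(f"{cid}: {scaffolds[cid].error}")
    missing = [cid for cid in compounds if cid not in structures or not structures[cid]]
    if missing:
        warnings.append(
            f"{len(missing)} compound(s) without structure; "
            "SAR/inactive-analog/PAINS scores emitted as 0 for them"
        )
        logger.warning(warnings[-1])

    cell_scores = {cid: cell_score(cell.get(cid, [])) for cid in compounds}

    by_target: dict[str, list[str]] = defaultdict(list)
    for (cid, tgt), agg in bio.items():
        by_target[tgt].append(cid)

    pairs: dict[tuple[str, str], ScoredPair] = {}
    rankings: dict[str, list[RankedEntry]] = {}
    for tgt in sorted(by_target):
        cohort = [cid for cid in by_target[tgt] if bio[(cid, tgt)].active]
        if not cohort:
            continue
        breakdowns = {
            cid: build_selectivity_breakdown(profiles[cid], tgt, n_liganded) for cid in cohort
        }
        raw = {cid: bd.second_factor_raw for cid, bd in breakdowns.items() if bd.n_off_targets > 0}
        norm = normalize_second_factor(raw) if raw else {}
        target_medians = {cid: bio[(cid, tgt)].median_pactivity for cid in by_target[tgt]}
        target_conflicting = {cid: bio[(cid, tgt)].conflicting for cid in by_target[tgt]}
        target_pmids = {cid: pubmed.get((cid, tgt), set()) for cid in by_target[tgt]}

        scored: list[ScoreVector] = []
        for cid in cohort:
            bd = with_second_norm(breakdowns[cid], norm.get(cid, 0.0))
            agg = bio[(cid, tgt)]
            sel = 0.0 if bd.n_off_targets == 0 else (
                (bd.first_factor + bd.second_factor_norm + bd.third_factor) / 3.0
            )
            pot = potency_score(agg)
            cel = cell_scores[cid]
            if cid in scaffolds:
                sar = chem.sar_score(cid, scaffolds, target_medians, target_pmids)
                ia = chem.inactive_analog_score(cid, scaffolds, target_medians, target_conflicting)
                pai = pains[cid].pains_score
            else:
                sar = ia = pai = 0
            vec = ScoreVector(
                compound_id=cid,
                target_accession=tgt,
                potency=pot,
                selectivity=sel,
                cell=cel,
                sar=sar,
                inactive_analog=ia,
                pains=pai,
                global_=global_score(pot, sel, cel, sar, ia, pai, weights),
            )
            scored.append(vec)
            pairs[(cid, tgt)] = ScoredPair(
                compound_id=cid,
                target_accession=tgt,
                aggregate=agg,
                breakdown=bd,
                scores=vec,
                danger=danger_flag(bd),
                minimum_standard=is_minimum_standard(
                    median_pactivity=agg.median_pactivity,
                    cell=cel,
                    n_off_targets=bd.n_off_targets,
                    n_selective_off_targets=bd.n_selective_off_targets,
                ),
            )
        rankings[tgt] = rank_compounds(scored, order_key)

    return ScoreRun(
        pairs=pairs,
        bio_aggregates=bio,
        cell_aggregates=cell,
        profiles={cid: dict(p) for cid, p in profiles.items()},
        rankings=rankings,
        n_liganded_targets=n_liganded,
        weights=weights,
        order_key=order_key,
        scaffolds=scaffolds,
        pains=pains,
        warnings=warnings,
    )
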