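"""Structure-level computations: level-1 scaffolds and PAINS alerts.

Scaffolds define the analog classes used by the SAR and inactive-analog
scores. The level-1 scaffold of a molecule is obtained by reducing its
ring-system framework (side chains removed, ring-ring linkers retained) to at
most two rings by iteratively deleting peripheral rings, following a
deterministic prioritization:

1. prefer deleting the ring with the fewest heteroatoms (heteroatom-rich
   rings tend to carry the pharmacophore);
2. then the largest ring;
3. residual ties break on the canonical SMILES of the resulting scaffold.

Frameworks with two rings or fewer are their own level-1 scaffold; acyclic
molecules have an empty scaffold and are excluded from analog matching.

PAINS alerting matches the published pan-assay-interference substructure
families (A, B and C) bundled with RDKit's filter catalog. A matched compound
gets PAINS score 0, a clean one 1. Unparseable structures default to score 1
(no alert is observable) with an error recorded for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import FilterCatalog
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "PainsResult",
    "ScaffoldAssignment",
    "inactive_analog_score",
    "largest_fragment",
    "level1_scaffold",
    "pains_score",
    "sar_score",
]

#: Reduce frameworks to at most this many rings (tree level 1 = two-ring
#: scaffold; level 0 would be the single-ring root).
LEVEL1_MAX_RINGS = 2


@dataclass(frozen=True)
class ScaffoldAssignment:
    """Canonical level-1 scaffold of a compound; empty when acyclic."""

    compound_id: str
    level1_scaffold: str
    n_rings: int
    error: str = ""

    @property
    def has_scaffold(self) -> bool:
        return bool(self.level1_scaffold)


@dataclass(frozen=True)
class PainsResult:
    compound_id: str
    alerts: tuple[str, ...] = field(default_factory=tuple)
    error: str = ""

    @property
    def pains_score(self) -> int:
        return 0 if self.alerts else 1


def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Strip salts/mixtures: keep the covalent fragment with most heavy atoms.

    Ties break on canonical SMILES for determinism.
    """
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def _ring_removal_candidates(mol: Chem.Mol) -> list[tuple[tuple[int, float, str], Chem.Mol]]:
    """Enumerate scaffolds reachable by deleting one peripheral ring.

    A ring is removable when deleting its exclusive atoms leaves a single
    connected framework with exactly one ring fewer.
    """
    ring_info = mol.GetRingInfo()
    n_rings = ring_info.NumRings()
    atom_rings = ring_info.AtomRings()
    candidates = []
    for ring_atoms in atom_rings:
        in_other = {
            a for other in atom_rings if other != ring_atoms for a in other
        }
        exclusive = [a for a in ring_atoms if a not in in_other]
        if not exclusive:
            continue  # fully fused into others; nothing to delete
        editable = Chem.RWMol(mol)
        for idx in sorted(exclusive, reverse=True):
            editable.RemoveAtom(idx)
        try:
            candidate = editable.GetMol()
            Chem.SanitizeMol(candidate)
        except Exception:
            continue
        # Re-prune now-dangling linker chains back to a framework.
        candidate = MurckoScaffold.GetScaffoldForMol(candidate)
        if candidate.GetNumAtoms() == 0:
            continue
        if len(Chem.GetMolFrags(candidate)) != 1:
            continue
        if candidate.GetRingInfo().NumRings() != n_rings - 1:
            continue
        ring = [mol.GetAtomWithIdx(a) for a in ring_atoms]
        n_hetero = sum(1 for a in ring if a.GetAtomicNum() not in (1, 6))
        # Removal preference: fewest heteroatoms, then largest ring, then
        # lexicographically smallest resulting scaffold.
        key = (n_hetero, -len(ring_atoms), Chem.MolToSmiles(candidate))
        candidates.append((key, candidate))
    return candidates


@lru_cache(maxsize=100_000)
def _level1_scaffold_smiles(smiles: str) -> tuple[str, int, str]:
    """(scaffold smiles, ring count, error) for one structure string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return "", 0, f"unparseable SMILES: {smiles!r}"
    mol = largest_fragment(mol)
    try:
        framework = MurckoScaffold.GetScaffoldForMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        return "", 0, f"scaffold computation failed: {exc}"
    n_rings = framework.GetRingInfo().NumRings()
    if n_rings == 0:
        return "", 0, ""
    current = framework
    while current.GetRingInfo().NumRings() > LEVEL1_MAX_RINGS:
        candidates = _ring_removal_candidates(current)
        if not candidates:
            break  # e.g. fully fused cage; keep the framework as-is
        current = min(candidates, key=lambda c: c[0])[1]
    return Chem.MolToSmiles(current), n_rings, ""


def level1_scaffold(smiles: str, compound_id: str = "") -> ScaffoldAssignment:
    """Compute the canonical level-1 scaffold for one structure."""
    scaffold, n_rings, error = _level1_scaffold_smiles(smiles)
    return ScaffoldAssignment(
        compound_id=compound_id, level1_scaffold=scaffold, n_rings=n_rings, error=error
    )


@lru_cache(maxsize=1)
def _pains_catalog() -> FilterCatalog.FilterCatalog:
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
    return FilterCatalog.FilterCatalog(params)


@lru_cache(maxsize=100_000)
def _pains_alerts(smiles: str) -> tuple[tuple[str, ...], str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return (), f"unparseable SMILES: {smiles!r}"
    mol = largest_fragment(mol)
    matches = _pains_catalog().GetMatches(mol)
    return tuple(sorted(entry.GetDescription() for entry in matches)), ""


def pains_score(smiles: str, compound_id: str = "") -> PainsResult:
    """Match a structure against the bundled PAINS families (A/B/C)."""
    alerts, error = _pains_alerts(smiles)
    return PainsResult(compound_id=compound_id, alerts=alerts, error=error)


def sar_score(
    compound_id: str,
    scaffolds: Mapping[str, ScaffoldAssignment],
    target_medians: Mapping[str, float],
    target_pubmed_ids: Mapping[str, frozenset[str] | set[str]],
) -> int:
    """1 iff a distinct same-scaffold compound from the same publication is
    active (pActivity > 5) on the reference target.

    ``target_medians`` maps compound -> capped median pActivity on the
    reference target (only compounds measured on it); ``target_pubmed_ids``
    maps compound -> publication ids of its records on that target.
    """
    own = scaffolds.get(compound_id)
    if own is None or not own.has_scaffold:
        return 0
    own_pmids = set(target_pubmed_ids.get(compound_id, ())) - {""}
    if not own_pmids:
        return 0
    for other_id, median in target_medians.items():
        if other_id == compound_id or median <= 5.0:
            continue
        other = scaffolds.get(other_id)
        if other is None or other.level1_scaffold != own.level1_scaffold:
            continue
        other_pmids = set(target_pubmed_ids.get(other_id, ())) - {""}
        if own_pmids & other_pmids:
            return 1
    return 0


def inactive_analog_score(
    compound_id: str,
    scaffolds: Mapping[str, ScaffoldAssignment],
    target_medians: Mapping[str, float],
    target_conflicting: Optional[Mapping[str, bool]] = None,
) -> int:
    """1 iff a distinct same-scaffold compound is inactive on the reference
    target (median pActivity < 5, or classified inactive by conflicting
    records). No same-publication restriction applies.
    """
    own = scaffolds.get(compound_id)
    if own is None or not own.has_scaffold:
        return 0
    conflicting = target_conflicting or {}
    for other_id, median in target_medians.items():
        if other_id == compound_id:
            continue
        other = scaffolds.get(other_id)
        if other is None or other.level1_scaffold != own.level1_scaffold:
            continue
        if median < 5.0 or conflicting.get(other_id, False):
            return 1
    return 0
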