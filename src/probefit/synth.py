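"""Deterministic synthetic bioactivity landscapes and hand-checked toy fixtures.

:func:`generate_landscape` emits a measurement table in the ingest dialect, a
SMILES map built by decorating known scaffolds (guaranteeing scaffold
equivalence classes for SAR tests) and a truth record with per-pair medians.
"Planted probes" are compound-target pairs constructed to dominate every
fitness factor: capped potency, 10-fold selectivity against every other
target in the landscape, maximal selectivity information, cell activity, a
same-publication same-scaffold active analog, an inactive analog, and a clean
structure. They satisfy the minimum standard by construction.

One seeded generator stream is used per artifact class (panel assignment,
activities, structures, cell data, publication ids) so changing one spec
field perturbs only its own draws.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from probefit.ingest import (
    ACTIVITY_PACTIVITY_CAP,
    ACTIVITY_THRESHOLD_PACTIVITY,
    Measurement,
)

__all__ = ["Landscape", "LandscapeSpec", "ToyFixture", "generate_landscape", "worked_toy_target"]

TABLE_COLUMNS = (
    "compound_id",
    "target_accession",
    "assay_kind",
    "cell_line_id",
    "qualifier",
    "value",
    "units",
    "activity_type",
    "pubmed_id",
)

#: Clean (alert-free) ring systems used to seed compound structures.
DEFAULT_SCAFFOLDS = (
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc2ccccc2c1",
    "c1ccc(Cc2ccccc2)cc1",
    "c1ccncc1",
    "C1CCNCC1",
    "c1ccc(-c2ccncc2)cc1",
)

#: Acyclic substituents used to decorate scaffolds.
DEFAULT_SUBSTITUENTS = ("C", "CC", "F", "Cl", "OC", "N", "C(C)C")


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of one synthetic bioactivity landscape."""

    n_targets: int = 20
    n_compounds: int = 200
    panel_size_min: int = 1
    panel_size_max: int = 8
    pactivity_range: tuple[float, float] = (3.0, 11.0)
    replicate_jitter: float = 0.15
    censored_fraction: float = 0.15
    cell_tested_fraction: float = 0.3
    replicate_max: int = 3
    scaffold_library: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    planted_probes: tuple[tuple[str, str], ...] = ()
    pubmed_pool_per_target: int = 3
    seed: int = 0

    def target_names(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_targets + 1)]

    def compound_names(self) -> list[str]:
        return [f"C{i:04d}" for i in range(1, self.n_compounds + 1)]

    def validate(self) -> None:
        if self.n_targets < 1 or self.n_compounds < 1:
            raise ValueError("landscape needs at least one target and one compound")
        if not 1 <= self.panel_size_min <= self.panel_size_max:
            raise ValueError("invalid panel size bounds")
        if not 0 <= self.censored_fraction <= 1:
            raise ValueError("censored_fraction must be in [0, 1]")
        if not self.scaffold_library:
            raise ValueError("scaffold_library must be non-empty")
        targets = set(self.target_names())
        compounds = set(self.compound_names())
        for cid, tgt in self.planted_probes:
            if tgt not in targets:
                raise ValueError(f"planted probe on unknown target {tgt!r}")
            if cid not in compounds:
                raise ValueError(f"planted probe for unknown compound {cid!r}")


@dataclass
class Landscape:
    """Generated landscape: measurement rows, structures and ground truth."""

    spec: LandscapeSpec
    rows: list[dict]
    smiles: dict[str, str]
    truth: dict

    def to_measurements(self) -> list[Measurement]:
        out = []
        for row in self.rows:
            kwargs = dict(row)
            kwargs["value"] = float(kwargs["value"])
            out.append(Measurement(**kwargs))
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write measurements.tsv, compounds.smi and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table = outdir / "measurements.tsv"
        with table.open("w") as out:
            out.write("\t".join(TABLE_COLUMNS) + "\n")
            for row in self.rows:
                out.write("\t".join(str(row.get(c, "")) for c in TABLE_COLUMNS) + "\n")
        smi = outdir / "compounds.smi"
        with smi.open("w") as out:
            for cid in sorted(self.smiles):
                out.write(f"{self.smiles[cid]} {cid}\n")
        truth = outdir / "truth.json"
        truth.write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return {"measurements": table, "smiles": smi, "truth": truth}


def _decorate(scaffold: str, substituents: Sequence[str], rng: np.random.Generator) -> str:
    """Attach substituents to random C-H positions of a scaffold."""
    mol = Chem.MolFromSmiles(scaffold)
    for sub in substituents:
        frag = Chem.MolFromSmiles(sub)
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
        ]
        if not sites:
            break
        site = int(sites[int(rng.integers(len(sites)))])
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        candidate = combined.GetMol()
        try:
            Chem.SanitizeMol(candidate)
        except Exception:
            continue
        mol = candidate
    return Chem.MolToSmiles(mol)


def _pactivity_to_nm(p: float) -> float:
    return 10.0 ** (9.0 - p)


def _emitted_pactivity(p: float) -> float:
    """pActivity as it will round-trip through the emitted table value."""
    from probefit.ingest import compute_pactivity

    return compute_pactivity(float(f"{_pactivity_to_nm(p):.10g}"))


def _bio_row(cid: str, tgt: str, qualifier: str, p: float, pmid: str) -> dict:
    return {
        "compound_id": cid,
        "target_accession": tgt,
        "assay_kind": "biochemical",
        "cell_line_id": "",
        "qualifier": qualifier,
        "value": f"{_pactivity_to_nm(p):.10g}",
        "units": "nM",
        "activity_type": "IC50",
        "pubmed_id": pmid,
    }


def _cell_row(cid: str, line: str, p: float) -> dict:
    return {
        "compound_id": cid,
        "target_accession": "",
        "assay_kind": "cell",
        "cell_line_id": line,
        "qualifier": "=",
        "value": f"{_pactivity_to_nm(p):.10g}",
        "units": "nM",
        "activity_type": "IC50",
        "pubmed_id": "",
    }


def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Generate a deterministic landscape from a validated spec."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    panel_rng, activity_rng, structure_rng, cell_rng, pubmed_rng = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    targets = spec.target_names()
    compounds = spec.compound_names()
    planted = {cid: tgt for cid, tgt in spec.planted_probes}
    lo, hi = spec.pactivity_range

    pubmed_pools = {
        tgt: [f"PM{tgt}{j}" for j in range(spec.pubmed_pool_per_target)] for tgt in targets
    }

    rows: list[dict] = []
    pair_pacts: dict[tuple[str, str], list[float]] = {}
    pair_quals: dict[tuple[str, str], list[str]] = {}
    smiles: dict[str, str] = {}

    for cid in compounds:
        scaffold = spec.scaffold_library[int(structure_rng.integers(len(spec.scaffold_library)))]
        n_subs = int(structure_rng.integers(0, 3))
        subs = [
            spec.substituents[int(structure_rng.integers(len(spec.substituents)))]
            for _ in range(n_subs)
        ]
        smiles[cid] = _decorate(scaffold, subs, structure_rng)

        if cid in planted:
            continue  # planted probes get constructed records below

        k = int(panel_rng.integers(spec.panel_size_min, min(spec.panel_size_max, spec.n_targets) + 1))
        panel = sorted(panel_rng.choice(spec.n_targets, size=k, replace=False).tolist())
        for t_index in panel:
            tgt = targets[t_index]
            base = float(activity_rng.uniform(lo, hi))
            n_rep = int(activity_rng.integers(1, spec.replicate_max + 1))
            pool = pubmed_pools[tgt]
            pmid = pool[int(pubmed_rng.integers(len(pool)))]
            pacts = []
            for _ in range(n_rep):
                p = base + float(activity_rng.normal(0.0, spec.replicate_jitter))
                p = min(max(p, 0.5), 14.0)  # keep concentrations physical
                qual = ">" if activity_rng.random() < spec.censored_fraction else "="
                rows.append(_bio_row(cid, tgt, qual, p, pmid))
                pacts.append(_emitted_pactivity(p))
                pair_quals.setdefault((cid, tgt), []).append(qual)
            pair_pacts[(cid, tgt)] = pacts
        if cell_rng.random() < spec.cell_tested_fraction:
            rows.append(_cell_row(cid, "CL001", float(cell_rng.uniform(lo, hi))))

    # Planted probes: dominate every fitness factor by construction.
    for cid, tgt in sorted(spec.planted_probes):
        pmid = f"PM_{cid}_{tgt}"
        scaffold = spec.scaffold_library[0]
        smiles[cid] = scaffold
        smiles[f"{cid}.sar"] = _decorate(scaffold, ["C"], structure_rng)
        smiles[f"{cid}.ia"] = _decorate(scaffold, ["CC"], structure_rng)
        for _ in range(2):
            rows.append(_bio_row(cid, tgt, "=", 10.0, pmid))
        pair_pacts[(cid, tgt)] = [_emitted_pactivity(10.0)] * 2
        for other in targets:
            if other == tgt:
                continue
            rows.append(_bio_row(cid, other, "=", 4.5, pmid))
            pair_pacts[(cid, other)] = [_emitted_pactivity(4.5)]
        rows.append(_cell_row(cid, "CL001", 7.0))
        rows.append(_bio_row(f"{cid}.sar", tgt, "=", 7.3, pmid))
        pair_pacts[(f"{cid}.sar", tgt)] = [_emitted_pactivity(7.3)]
        rows.append(_bio_row(f"{cid}.ia", tgt, "=", 4.3, pmid))
        pair_pacts[(f"{cid}.ia", tgt)] = [_emitted_pactivity(4.3)]

    pairs_truth = {}
    for (cid, tgt), pacts in sorted(pair_pacts.items()):
        median = min(statistics.median(pacts), ACTIVITY_PACTIVITY_CAP)
        quals = pair_quals.get((cid, tgt), ["="])
        pairs_truth[f"{cid}|{tgt}"] = {
            "median_pactivity": median,
            "n": len(pacts),
            "censored": ">" in quals,
        }

    truth = {
        "seed": spec.seed,
        "planted_probes": [list(p) for p in sorted(spec.planted_probes)],
        "planted_expected_binaries": {"cell": 1, "sar": 1, "inactive_analog": 1, "pains": 1},
        "pairs": pairs_truth,
        "active_threshold_pactivity": ACTIVITY_THRESHOLD_PACTIVITY,
    }
    return Landscape(spec=spec, rows=rows, smiles=smiles, truth=truth)


# ---------------------------------------------------------------------------
# Hand-written toy fixtures with fully hand-computed expectations.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyFixture:
    """A small worked example with hand-computed expected outputs."""

    name: str
    measurements: tuple[Measurement, ...]
    smiles: dict[str, str] = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def _bio(cid, tgt, qual, value_nm, pmid=""):
    return Measurement(
        compound_id=cid,
        target_accession=tgt,
        assay_kind="biochemical",
        qualifier=qual,
        value=value_nm,
        units="nM",
        pubmed_id=pmid,
    )


def _cell(cid, line, value_nm):
    return Measurement(
        compound_id=cid,
        target_accession="",
        assay_kind="cell",
        cell_line_id=line,
        qualifier="=",
        value=value_nm,
        units="nM",
    )


def _five_compound_kinase() -> ToyFixture:
    # Five compounds over four targets; reference analyses focus on K1.
    # Every expectation below is hand-computed from the scoring definitions.
    measurements = (
        _bio("A", "K1", "=", 10.0, "P1"),       # pActivity 8
        _bio("A", "K2", "=", 1000.0, "P1"),      # 6
        _bio("A", "K3", "=", 100000.0, "P1"),    # 4 (inactive)
        _cell("A", "CL1", 1000.0),               # cell-active
        _bio("B", "K1", "=", 100.0, "P1"),       # 7
        _bio("B", "K2", "=", 100.0, "P1"),       # 7
        _bio("C", "K1", "=", 50000.0, "P2"),     # ~4.3: inactive analog of A/B
        _bio("D", "K1", "=", 100.0, "P3"),       # 7, no off-target data
        _cell("D", "CL1", 20000.0),              # 4.7: not cell-active
        _bio("E", "K1", "=", 10.0, "P4"),        # 8
        _bio("E", "K4", "=", 10.0, "P4"),        # 8 (unselective)
        _cell("E", "CL1", 1000.0),
    )
    smiles = {
        "A": "Cc1ccc(-c2ccccc2)cc1",
        "B": "Clc1ccc(-c2ccccc2)cc1",
        "C": "c1ccc(-c2ccccc2)cc1",
        "D": "C1CCCCC1",
        "E": "O=C1CSC(=S)N1c1ccccc1",  # rhodanine: carries a PAINS alert
    }
    expected = {
        "n_liganded": 3,  # K1, K2, K4 have active compounds; K3 does not
        "K1": {
            "A": {
                "potency": 0.6,
                "selectivity": 1.0,
                "cell": 1,
                "sar": 1,
                "inactive_analog": 1,
                "pains": 1,
                "global": 15.4 / 17,
                "first_factor": 1.0,
                "sic": 4.0,
                "second_factor_raw": 4.0,
                "second_factor_norm": 1.0,
                "third_factor": 1.0,
                "danger": False,
                "minimum_standard": True,
            },
            "B": {
                "potency": 0.4,
                "selectivity": 2.0 / 9.0,
                "cell": 0,
                "sar": 1,
                "inactive_analog": 1,
                "pains": 1,
                "global": (8 * 2 / 9 + 1.6 + 3.0) / 17,
                "first_factor": 0.0,
                "sic": -1.0,
                "second_factor_raw": -0.5,
                "second_factor_norm": 0.0,
                "third_factor": 2.0 / 3.0,
                "danger": True,
                "minimum_standard": False,
            },
            "D": {
                "potency": 0.4,
                "selectivity": 0.0,
                "cell": 0,
                "sar": 0,
                "inactive_analog": 0,
                "pains": 1,
                "global": 2.6 / 17,
                "danger": False,
                "minimum_standard": False,
            },
            "E": {
                "potency": 0.6,
                "selectivity": 2.0 / 9.0,
                "cell": 1,
                "sar": 0,
                "inactive_analog": 0,
                "pains": 0,
                "global": (8 * 2 / 9 + 2.4 + 2.0) / 17,
                "danger": True,
                "minimum_standard": False,
            },
            "ranking": ["A", "B", "E", "D"],
        },
        "K2": {
            "A": {"selectivity": 0.5, "first_factor": 0.5, "sic": -2.0,
                  "second_factor_raw": -1.0, "second_factor_norm": 0.0, "third_factor": 1.0},
            "B": {"selectivity": 5.0 / 9.0, "first_factor": 0.0, "sic": -1.0,
                  "second_factor_raw": -0.5, "second_factor_norm": 1.0, "third_factor": 2.0 / 3.0},
        },
        "information_richness": {"K1": 8, "K2": 5, "K3": 0, "K4": 2},
        "information_richness_percentile": {"K1": 100.0, "K2": 200.0 / 3.0,
                                            "K3": 0.0, "K4": 100.0 / 3.0},
        "icons_K1": {
            "selectivity": True, "potency": True, "cell": True, "minimum_standard": True,
            "sar": True, "inactive_analog": True, "non_pains": True,
        },
        "proteome_counts": {"liganded": 3, "potent": 3, "potent_selective": 1,
                            "minimum_standard": 1},
    }
    return ToyFixture("five_compound_kinase", measurements, smiles, expected)


def _conflict_cases() -> ToyFixture:
    measurements = (
        _bio("EQ_ONLY", "T1", "=", 100.0),
        _bio("CONFLICT", "T1", "=", 10.0),
        _bio("CONFLICT", "T1", ">", 10000.0),
        _bio("GT_ONLY_WEAK", "T1", ">", 100000.0),
        _bio("GT_ONLY_STRONG", "T1", ">", 100.0),
        _bio("WEAK_EQ_STRONG_GT", "T1", "=", 50000.0),
        _bio("WEAK_EQ_STRONG_GT", "T1", ">", 1.0),
        _bio("CONFLICT_BOUNDARY", "T1", "=", 10.0),
        _bio("CONFLICT_BOUNDARY", "T1", ">", 9999.0),
    )
    expected = {
        "EQ_ONLY": {"active": True, "conflicting": False, "median": 7.0},
        "CONFLICT": {"active": False, "conflicting": True, "median": 6.5},
        "GT_ONLY_WEAK": {"active": False, "conflicting": False, "median": 4.0},
        "GT_ONLY_STRONG": {"active": True, "conflicting": False, "median": 7.0},
        # '='-only median 4.3 is inactive, so the '>' record cannot conflict.
        "WEAK_EQ_STRONG_GT": {"active": True, "conflicting": False},
        # '>' at 9,999 nM is below the 10 uM inactivity claim: no conflict.
        "CONFLICT_BOUNDARY": {"active": True, "conflicting": False},
    }
    return ToyFixture("conflict_cases", measurements, expected=expected)


def _no_offtarget() -> ToyFixture:
    measurements = (_bio("CPD1", "T1", "=", 10.0),)
    expected = {
        "CPD1": {
            "potency": 0.6,
            "selectivity": 0.0,
            "cell": 0,
            "sar": 0,
            "inactive_analog": 0,
            "pains": 1,
            "global": 3.4 / 17,
        }
    }
    return ToyFixture("no_offtarget", measurements, smiles={"CPD1": "CCO"}, expected=expected)


_TOY_REGISTRY = {
    "five_compound_kinase": _five_compound_kinase,
    "conflict_cases": _conflict_cases,
    "no_offtarget": _no_offtarget,
}


def worked_toy_target(name: str) -> ToyFixture:
    """Return a bundled hand-written fixture by name."""
    try:
        builder = _TOY_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_TOY_REGISTRY)}"
        ) from None
    return builder()
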