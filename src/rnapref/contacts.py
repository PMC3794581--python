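"""Protein-RNA contact extraction from 3D structures.

An amino-acid residue and an RNA base are defined to be in contact when the
centers of geometry of the residue's side chain and of the base moiety
(heavy atoms only, sugar and phosphate excluded) lie closer than a distance
cutoff. Contacts are filtered by a neighbor-set rule -- keep residues with at
least one neighboring base (``1+``), at least two (``2+``), or only the two
closest bases of residues with at least two (``2``) -- and aggregated into a
20 x 4 count table that feeds the preference-scale derivation.

Only protein-side-chain vs RNA-base pairs are considered; backbone-mediated
and intra-molecular proximities never count.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .alphabet import AA3_TO_1, AA_ORDER, BASES, DNA_RESNAMES, RNA_RESNAMES

SET_RULES = ("1+", "2+", "2")

#: Protein backbone heavy atoms excluded from side-chain centers. OXT is the
#: terminal carboxyl oxygen and is backbone by construction.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Ribose and phosphate atoms excluded from base centers (both modern OP* and
#: legacy O*P phosphate-oxygen names).
SUGAR_PHOSPHATE_ATOMS = frozenset(
    {
        "C1'", "C2'", "C3'", "C4'", "C5'",
        "O2'", "O3'", "O4'", "O5'",
        "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    }
)


class StructureFormatError(ValueError):
    """Raised when structure input cannot be parsed or contains no atoms."""


@dataclass(frozen=True)
class ResidueGroup:
    """One residue-level center-of-geometry group (side chain or base)."""

    chain: str
    resnum: int
    icode: str
    kind: str  # one-letter amino acid, or base letter in ACGU
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates, Angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def center(self) -> np.ndarray:
        return center_of_geometry(self.coords)

    def sort_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass
class StructureModel:
    """First-model, altloc-resolved view of a protein-RNA complex."""

    id: str
    protein_residues: list[ResidueGroup]
    rna_bases: list[ResidueGroup]
    skipped: Counter = field(default_factory=Counter)


@dataclass(frozen=True)
class ContactRecord:
    structure: str
    chain: str
    resnum: int
    aa: str
    base_chain: str
    base_resnum: int
    base: str
    distance: float


@dataclass
class NeighborMap:
    """Per-residue neighbor lists (base index, distance), distance-sorted."""

    model: StructureModel
    cutoff: float
    lists: list[list[tuple[int, float]]]


@dataclass
class ContactSet:
    """Contact records from one structure under a fixed cutoff and set rule."""

    structure: str
    cutoff: float
    rule: str
    records: list[ContactRecord]


@dataclass
class ContactTable:
    """Aggregated 20 x 4 observed-contact counts with provenance."""

    counts: pd.DataFrame
    cutoff: float | None
    set_rule: str
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = self.counts.reindex(index=list(AA_ORDER), columns=list(BASES))
        counts = counts.fillna(0).astype(np.int64)
        if (counts.values < 0).any():
            raise ValueError("negative contact counts")
        self.counts = counts

    @property
    def n_total(self) -> int:
        return int(self.counts.values.sum())

    def __add__(self, other: "ContactTable") -> "ContactTable":
        if (self.cutoff, self.set_rule) != (other.cutoff, other.set_rule):
            raise ValueError("cannot add tables with different cutoff/rule")
        return ContactTable(
            self.counts + other.counts,
            cutoff=self.cutoff,
            set_rule=self.set_rule,
            sources=self.sources + other.sources,
        )

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.counts.to_csv(path, sep="\t", index_label="aa")
        if sidecar:
            meta = {
                "cutoff": self.cutoff,
                "set_rule": self.set_rule,
                "n_total": self.n_total,
                "sources": list(self.sources),
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2)
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactTable":
        path = Path(path)
        counts = pd.read_csv(path, sep="\t", index_col="aa")
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            counts,
            cutoff=meta.get("cutoff"),
            set_rule=meta.get("set_rule", "unknown"),
            sources=tuple(meta.get("sources", ())),
        )


def center_of_geometry(atoms: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of coordinates (no mass weighting)."""
    coords = np.asarray(atoms, dtype=float)
    if coords.size == 0:
        raise ValueError("center of geometry of an empty atom list is undefined")
    return coords.reshape(-1, 3).mean(axis=0)


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate conformations: per atom name keep the conformer with
    the highest occupancy; ties go to altloc 'A' (then alphabetical)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        key = (atom.occ, -ord(atom.altloc or "A"))
        prev_key = (prev.occ, -ord(prev.altloc or "A"))
        if key > prev_key:
            best[atom.name] = atom
    return list(best.values())


def parse_structure(
    pdb_text: str,
    structure_id: str | None = None,
    glycine: str = "ca",
) -> StructureModel:
    """Parse PDB-format text into residue-level coordinate groups.

    Only the first model of multi-model (NMR) files is used and hydrogens are
    discarded. Protein side chains drop backbone N/CA/C/O (glycine keeps CA as
    a one-atom surrogate unless ``glycine='exclude'``); RNA bases drop sugar
    and phosphate atoms. MSE maps to Met; other non-canonical residues,
    deoxyribonucleotides and modified bases are skipped and counted in
    ``StructureModel.skipped``.
    """
    if glycine not in ("ca", "exclude"):
        raise ValueError("glycine must be 'ca' or 'exclude'")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise StructureFormatError(f"unparseable PDB input: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError("structure contains no models")
    model = st[0]
    n_atoms = sum(len(res) for chain in model for res in chain)
    if n_atoms == 0:
        raise StructureFormatError("structure contains no atoms")

    sid = structure_id or st.name or "structure"
    protein: list[ResidueGroup] = []
    bases: list[ResidueGroup] = []
    skipped: Counter = Counter()

    for chain in model:
        for residue in chain:
            name = residue.name.strip().upper()
            atoms = [a for a in _select_altlocs(residue) if not a.is_hydrogen()]
            if not atoms:
                continue
            if name in AA3_TO_1:
                aa = AA3_TO_1[name]
                side = [a for a in atoms if a.name not in BACKBONE_ATOMS]
                if not side and aa == "G" and glycine == "ca":
                    side = [a for a in atoms if a.name == "CA"]
                if not side:
                    skipped["protein_no_sidechain"] += 1
                    continue
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in side])
                protein.append(
                    ResidueGroup(chain.name, residue.seqid.num,
                                 residue.seqid.icode.strip(), aa, coords)
                )
            elif name in RNA_RESNAMES:
                base_atoms = [a for a in atoms if a.name not in SUGAR_PHOSPHATE_ATOMS]
                if not base_atoms:
                    skipped["rna_no_base_atoms"] += 1
                    continue
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in base_atoms])
                bases.append(
                    ResidueGroup(chain.name, residue.seqid.num,
                                 residue.seqid.icode.strip(), name, coords)
                )
            elif name in DNA_RESNAMES:
                skipped["dna"] += 1
            else:
                skipped["noncanonical"] += 1

    return StructureModel(sid, protein, bases, skipped)


def parse_structure_file(path: str | Path, glycine: str = "ca") -> StructureModel:
    path = Path(path)
    return parse_structure(path.read_text(), structure_id=path.stem, glycine=glycine)


def find_neighbors(model: StructureModel, cutoff: float) -> NeighborMap:
    """Bases strictly closer than ``cutoff`` to each residue's side-chain center.

    Lists are sorted by distance; exact distance ties break on the base's
    (chain, residue number, insertion code).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_res = len(model.protein_residues)
    if n_res == 0 or not model.rna_bases:
        return NeighborMap(model, cutoff, [[] for _ in range(n_res)])

    res_centers = np.array([g.center for g in model.protein_residues])
    base_centers = np.array([g.center for g in model.rna_bases])
    tree = cKDTree(base_centers)
    candidates = tree.query_ball_point(res_centers, cutoff)

    lists: list[list[tuple[int, float]]] = []
    for r, idx in enumerate(candidates):
        entries = []
        for j in idx:
            d = float(np.linalg.norm(res_centers[r] - base_centers[j]))
            if d < cutoff:  # strict: a base at exactly the cutoff is excluded
                entries.append((j, d))
        entries.sort(key=lambda e: (e[1], model.rna_bases[e[0]].sort_key()))
        lists.append(entries)
    return NeighborMap(model, cutoff, lists)


def apply_set_rule(neighbors: NeighborMap, rule: str) -> ContactSet:
    """Filter per-residue neighbor lists into contact records.

    ``1+``: all contacts of residues with >=1 neighbor; ``2+``: all contacts of
    residues with >=2 neighbors; ``2``: only the two closest contacts of
    residues with >=2 neighbors. The resulting record sets are nested:
    2 within 2+ within 1+.
    """
    if rule not in SET_RULES:
        raise ValueError(f"unknown set rule {rule!r}; expected one of {SET_RULES}")
    model = neighbors.model
    records: list[ContactRecord] = []
    for res, entries in zip(model.protein_residues, neighbors.lists):
        if rule == "1+":
            kept = entries
        elif rule == "2+":
            kept = entries if len(entries) >= 2 else []
        else:  # "2"
            kept = entries[:2] if len(entries) >= 2 else []
        for j, d in kept:
            base = model.rna_bases[j]
            records.append(
                ContactRecord(
                    structure=model.id,
                    chain=res.chain,
                    resnum=res.resnum,
                    aa=res.kind,
                    base_chain=base.chain,
                    base_resnum=base.resnum,
                    base=base.kind,
                    distance=d,
                )
            )
    return ContactSet(model.id, neighbors.cutoff, rule, records)


def compute_contacts(model: StructureModel, cutoff: float, rule: str) -> ContactSet:
    """Convenience: neighbor detection followed by the set rule."""
    return apply_set_rule(find_neighbors(model, cutoff), rule)


def aggregate_contacts(contact_sets: Iterable[ContactSet]) -> ContactTable:
    """Merge contact records from one or more structures into a count table.

    All inputs must share the same cutoff and set rule.
    """
    contact_sets = list(contact_sets)
    cutoffs = {cs.cutoff for cs in contact_sets}
    rules = {cs.rule for cs in contact_sets}
    if len(cutoffs) > 1 or len(rules) > 1:
        raise ValueError(
            f"mixed cutoffs {sorted(cutoffs)} or rules {sorted(rules)} in aggregation"
        )
    counts = pd.DataFrame(0, index=list(AA_ORDER), columns=list(BASES), dtype=np.int64)
    sources = []
    for cs in contact_sets:
        sources.append(cs.structure)
        for rec in cs.records:
            counts.at[rec.aa, rec.base] += 1
    return ContactTable(
        counts,
        cutoff=contact_sets[0].cutoff if contact_sets else None,
        set_rule=contact_sets[0].rule if contact_sets else "1+",
        sources=tuple(sources),
    )


def cutoff_sweep(
    models: StructureModel | Sequence[StructureModel],
    cutoffs: Sequence[float],
    rule: str,
) -> dict[float, ContactTable]:
    """Aggregate contact tables over a grid of cutoffs.

    Equivalent to an independent run at each cutoff; for rules ``1+`` and
    ``2+`` the total contact count is non-decreasing in the cutoff.
    """
    if isinstance(models, StructureModel):
        models = [models]
    cutoffs = list(cutoffs)
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly ascending")
    out: dict[float, ContactTable] = {}
    for cutoff in cutoffs:
        out[cutoff] = aggregate_contacts(
            compute_contacts(m, cutoff, rule) for m in models
        )
    return out


def records_to_frame(contact_sets: Iterable[ContactSet]) -> pd.DataFrame:
    """Flatten contact records into a DataFrame (TSV-ready)."""
    rows = [
        {
            "structure": r.structure,
            "chain": r.chain,
            "resnum": r.resnum,
            "aa": r.aa,
            "base_chain": r.base_chain,
            "base_resnum": r.base_resnum,
            "base": r.base,
            "distance": round(r.distance, 4),
        }
        for cs in contact_sets
        for r in cs.records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "structure", "chain", "resnum", "aa",
            "base_chain", "base_resnum", "base", "distance",
        ],
    )


def sweep_cutoff_grid(lo: float, hi: float, step: float) -> list[float]:
    """Inclusive cutoff grid, e.g. 6..10 by 0.25."""
    n = int(round((hi - lo) / step))
    grid = [round(lo + k * step, 10) for k in range(n + 1)]
    if not math.isclose(grid[-1], hi):
        grid.append(hi)
    return grid
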