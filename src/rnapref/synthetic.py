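"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generator families:

* contact tables drawn from a planted interaction potential (the exact
  inverse of the quasi-chemical derivation, so re-derived scales must
  converge to the planted values);
* toy PDB structures whose side-chain/base center-of-geometry distances are
  known by construction, as fixtures for the contact extractor;
* cognate mRNA/protein pairs with a tunable planted complementarity between
  base-class density and preference profiles, plus a non-cognate null
  re-pairing that destroys the signal.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    AA1_TO_3,
    AA_ORDER,
    BASES,
    CODONS_BY_AA,
    STOP_CODONS,
    class_count,
    validate_base_class,
)
from .contacts import ContactTable
from .profiles import CognatePair, standard_table_content
from .scales import PreferenceScale

# ---------------------------------------------------------------------------
# planted contact potentials


@dataclass
class PlantedPotential:
    """A self-consistent planted potential: P* and margins derive from one
    joint contact distribution q(i, j), so p(i,j) = x_i x_j exp(-P*) equals q
    and normalizes exactly."""

    potential: pd.DataFrame  # P*(i, j), 20 x 4
    x_aa: pd.Series
    x_base: pd.Series
    n_contacts: int
    joint: pd.DataFrame  # q(i, j), sums to 1

    @classmethod
    def from_joint(cls, joint: pd.DataFrame, n_contacts: int) -> "PlantedPotential":
        q = joint.reindex(index=list(AA_ORDER), columns=list(BASES)).astype(float)
        if (q.values <= 0).any() or not np.isfinite(q.values).all():
            raise ValueError("joint distribution must be strictly positive and finite")
        q = q / q.values.sum()
        x_aa = q.sum(axis=1)
        x_base = q.sum(axis=0)
        potential = -np.log(q / np.outer(x_aa, x_base))
        return cls(potential, x_aa, x_base, int(n_contacts), q)


def random_planted_potential(
    rng: np.random.Generator,
    n_contacts: int = 10**6,
    sigma: float = 0.3,
    concentration_aa: float = 100.0,
    concentration_base: float = 100.0,
) -> PlantedPotential:
    """Random planted potential: Dirichlet margins perturbed by a Gaussian
    log-interaction term of spread ``sigma`` (pseudo-energy units).

    The default spread gives planted preferences spanning roughly +/- 0.9,
    comparable to derived contact scales, while keeping every cell of the
    joint distribution populous enough that recovery error at 1e6 sampled
    contacts is dominated by ordinary multinomial noise.
    """
    x_aa = rng.dirichlet(np.full(20, concentration_aa))
    x_base = rng.dirichlet(np.full(4, concentration_base))
    g = rng.normal(0.0, sigma, size=(20, 4))
    q = np.outer(x_aa, x_base) * np.exp(-g)
    joint = pd.DataFrame(q, index=list(AA_ORDER), columns=list(BASES))
    return PlantedPotential.from_joint(joint, n_contacts)


def uniform_planted_potential(n_contacts: int = 10**6) -> PlantedPotential:
    """P* identically zero: contacts follow independent uniform margins."""
    q = np.full((20, 4), 1.0 / 80)
    joint = pd.DataFrame(q, index=list(AA_ORDER), columns=list(BASES))
    return PlantedPotential.from_joint(joint, n_contacts)


def gen_contact_table(
    planted: PlantedPotential, rng: np.random.Generator
) -> ContactTable:
    """Multinomial sample of ``n_contacts`` contacts from the planted joint."""
    if planted.n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    p = planted.joint.values.ravel()
    counts = rng.multinomial(planted.n_contacts, p).reshape(20, 4)
    frame = pd.DataFrame(counts, index=list(AA_ORDER), columns=list(BASES))
    return ContactTable(frame, cutoff=None, set_rule="synthetic")


# ---------------------------------------------------------------------------
# toy structures

_AXES = np.array(
    [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0, -1, 0], [0, 0, -1]],
    dtype=float,
)

#: heavy side-chain / base atom names used when padding random groups
_SIDE_NAMES = ("CB", "CG", "CD", "CE", "CZ")
_BASE_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6")


def _atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz: Sequence[float],
    element: str,
) -> str:
    padded = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {padded}{'':1s}{resname:>3s} {chain}{resnum:4d}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


@dataclass
class ToyStructure:
    """Generated PDB text plus the construction's ground truth."""

    pdb_text: str
    residue_center: np.ndarray
    bases: list[tuple[str, int, str, float]]  # (chain, resnum, base, distance)

    def neighbors_within(self, cutoff: float) -> list[tuple[str, int, str, float]]:
        """Ground-truth neighbor list (strict cutoff), distance-sorted."""
        hits = [b for b in self.bases if b[3] < cutoff]
        return sorted(hits, key=lambda b: (b[3], b[0], b[1]))


def gen_toy_structure(
    distances: Sequence[float],
    aa: str = "ALA",
    base: str | Sequence[str] = "G",
) -> ToyStructure:
    """One amino-acid residue with nucleobases at exactly the given
    center-of-geometry distances (3-decimal PDB precision).

    The residue is ``aa`` with a single side-chain atom at the origin (its
    center of geometry); base ``k`` is a single base atom placed at distance
    ``distances[k]`` along a cycling axis direction. Backbone, sugar and
    phosphate atoms are included and must be ignored by the parser. An empty
    distance list yields a structure with no RNA.
    """
    distances = [round(float(d), 3) for d in distances]
    if any(d <= 0 for d in distances):
        raise ValueError("distances must be positive")
    if aa not in AA1_TO_3.values():
        raise ValueError(f"unknown residue name {aa!r}")
    base_list = (
        [base] * len(distances) if isinstance(base, str) else [str(b) for b in base]
    )
    if len(base_list) != len(distances):
        raise ValueError("base list length must match distances")

    lines = []
    serial = 1
    # protein residue, chain A: backbone far away from the side chain center
    backbone = {"N": (-2.0, 1.0, 0.0), "CA": (-1.5, 0.0, 0.0),
                "C": (-2.5, -1.0, 0.0), "O": (-3.5, -1.0, 0.0)}
    for name, xyz in backbone.items():
        lines.append(_atom_line(serial, name, aa, "A", 1, xyz, name[0]))
        serial += 1
    lines.append(_atom_line(serial, "CB", aa, "A", 1, (0.0, 0.0, 0.0), "C"))
    serial += 1

    truth = []
    for k, (d, bname) in enumerate(zip(distances, base_list)):
        pos = _AXES[k % len(_AXES)] * d
        resnum = k + 1
        # sugar/phosphate decoys that the parser must strip
        lines.append(
            _atom_line(serial, "P", bname, "B", resnum, pos + np.array([50, 50, 50]), "P")
        )
        serial += 1
        lines.append(
            _atom_line(serial, "C1'", bname, "B", resnum, pos + np.array([50, 50, 49]), "C")
        )
        serial += 1
        lines.append(_atom_line(serial, "N9", bname, "B", resnum, pos, "N"))
        serial += 1
        truth.append(("B", resnum, bname, d))

    text = "\n".join(lines + ["END"]) + "\n"
    return ToyStructure(text, np.zeros(3), truth)


def gen_random_structure(
    rng: np.random.Generator,
    n_residues: int = 12,
    n_bases: int = 15,
    box: float = 25.0,
    max_atoms: int = 4,
) -> str:
    """Random multi-residue/multi-base PDB text for oracle cross-checks.

    Residue and base groups get 1..max_atoms heavy atoms scattered around
    random centers inside a cube of side ``box``; chain A holds the protein,
    chain B the RNA.
    """
    lines = []
    serial = 1
    aa_letters = list(AA1_TO_3)
    for r in range(n_residues):
        aa3 = AA1_TO_3[aa_letters[rng.integers(len(aa_letters))]]
        center = rng.uniform(0, box, 3)
        lines.append(_atom_line(serial, "CA", aa3, "A", r + 1, center + 1.5, "C"))
        serial += 1
        for a in range(int(rng.integers(1, max_atoms + 1))):
            xyz = np.round(center + rng.normal(0, 1.0, 3), 3)
            lines.append(
                _atom_line(serial, _SIDE_NAMES[a], aa3, "A", r + 1, xyz, "C")
            )
            serial += 1
    for b in range(n_bases):
        bname = BASES[rng.integers(4)]
        center = rng.uniform(0, box, 3)
        for a in range(int(rng.integers(1, max_atoms + 1))):
            xyz = np.round(center + rng.normal(0, 1.0, 3), 3)
            lines.append(
                _atom_line(serial, _BASE_NAMES[a], bname, "B", b + 1, xyz, "N")
            )
            serial += 1
    return "\n".join(lines + ["END"]) + "\n"


# ---------------------------------------------------------------------------
# cognate pairs with planted complementarity


@dataclass
class ComplementaritySpec:
    """Conditions for planted mRNA/protein complementarity.

    Proteins are built from alternating blocks of length ``block``; with
    strength ``s`` > 0 the blocks draw residues preferentially from the
    planting scale's most-preferring / most-avoiding ends and pick synonymous
    codons biased toward high / low content of ``base_class``, in
    anti-phase -- which is exactly the negative-R matching signature. At
    ``s = 0`` residues and synonymous codons are uniform, independent of the
    scale. Block phase and starting sign are randomized per pair so a
    non-cognate re-pairing destroys the signal, and each pair draws its
    residues from its own random ``vocabulary``-sized amino-acid subset,
    mirroring the compositional diversity of real proteomes (without it,
    every pair would share one block composition and shuffled-scale null
    correlations would be artificially sign-coherent across the proteome).
    """

    n_pairs: int = 200
    length: int = 300
    block: int = 21
    strength: float = 0.0
    base_class: str = "PUR"
    scale: PreferenceScale | None = None
    codon_usage: dict[str, float] | None = None  # optional per-codon bias
    seed: int = 0
    residue_bias: float = 1.2  # kappa: block-wise amino-acid log-weight gain
    codon_bias: float = 4.0  # lambda: within-synonym log-weight per class base
    vocabulary: int = 20  # amino-acid subset size per pair (20 = full alphabet)

    def __post_init__(self) -> None:
        validate_base_class(self.base_class)
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.block < 1 or self.length < 1 or self.n_pairs < 1:
            raise ValueError("n_pairs, length and block must be positive")
        if not 2 <= self.vocabulary <= 20:
            raise ValueError("vocabulary must lie in [2, 20]")


def default_planting_scale(base_class: str, seed: int = 0) -> PreferenceScale:
    """Seeded random planting scale, orthogonalized against the standard-table
    codon content of ``base_class`` (uniform amino-acid weighting).

    The projection removes the component the genetic code itself would
    correlate with base content, so strength-0 pairs are a genuine null for
    profile correlations against this scale.
    """
    rng = np.random.default_rng(seed + 1_000_003)
    v = rng.standard_normal(20)
    c = standard_table_content(base_class).values.reindex(list(AA_ORDER)).to_numpy()
    v = v - v.mean()
    cc = c - c.mean()
    v = v - (v @ cc) / (cc @ cc) * cc
    v = v / v.std()
    return PreferenceScale(
        base_class,
        pd.Series(v, index=list(AA_ORDER)),
        provenance={"planting": "orthogonalized-random", "seed": seed},
    )


def code_aligned_scale(base_class: str) -> PreferenceScale:
    """Planting scale maximally aligned with the genetic code: the negated,
    standardized standard-table codon content of ``base_class``.

    With this scale the planted matching rides the code's own content
    structure (the situation real interaction preference scales are in), so
    the original scale is the optimal alignment and shuffle-null p-values of
    strongly planted pair sets vanish. Contrast with
    :func:`default_planting_scale`, whose code-orthogonal construction gives
    exact strength-0 nulls but code-limited maximal matching.
    """
    c = standard_table_content(base_class).values.reindex(list(AA_ORDER))
    z = -(c - c.mean()) / c.std()
    return PreferenceScale(
        base_class, z, provenance={"planting": "code-aligned"}
    )


def _codon_distributions(
    spec: ComplementaritySpec,
) -> dict[tuple[str, int], tuple[tuple[str, ...], np.ndarray]]:
    """Cumulative synonymous-codon distributions per (amino acid, block sign)."""
    usage = spec.codon_usage or {}
    dists = {}
    for aa, codons in CODONS_BY_AA.items():
        counts = np.array([class_count(c, spec.base_class) for c in codons])
        base_w = np.array([usage.get(c, 1.0) for c in codons], dtype=float)
        for sign in (1, -1):
            w = base_w * np.exp(sign * spec.strength * spec.codon_bias * counts)
            dists[(aa, sign)] = (codons, np.cumsum(w / w.sum()))
    return dists


def gen_cognate_pairs(spec: ComplementaritySpec) -> list[CognatePair]:
    """Generate cognate pairs with planted complementarity per ``spec``."""
    rng = np.random.default_rng(spec.seed)
    scale = spec.scale or default_planting_scale(spec.base_class, spec.seed)
    z = scale.values.reindex(list(AA_ORDER)).to_numpy(dtype=float)
    if np.isnan(z).any():
        raise ValueError("planting scale must cover all 20 amino acids")
    z = (z - z.mean()) / z.std()

    codon_cum = _codon_distributions(spec)
    aa_arr = np.array(list(AA_ORDER))

    pairs = []
    for p in range(spec.n_pairs):
        start = 1 if rng.random() < 0.5 else -1
        offset = int(rng.integers(0, spec.block))
        pos = np.arange(spec.length)
        signs = start * (1 - 2 * (((pos + offset) // spec.block) % 2))

        # pair-specific amino-acid vocabulary; block bias acts within it:
        # sign +1 blocks prefer residues with negative (preferring) values
        vocab = np.sort(rng.choice(20, size=spec.vocabulary, replace=False))
        res_cum = {}
        for sign in (1, -1):
            w = np.exp(-sign * spec.strength * spec.residue_bias * z[vocab])
            res_cum[sign] = np.cumsum(w / w.sum())

        residues = np.empty(spec.length, dtype="<U1")
        for sign in (1, -1):
            idx = np.flatnonzero(signs == sign)
            if idx.size:
                draws = np.searchsorted(res_cum[sign], rng.random(idx.size))
                residues[idx] = aa_arr[vocab[draws]]

        codons = [""] * spec.length
        for sign in (1, -1):
            idx = np.flatnonzero(signs == sign)
            for aa in np.unique(residues[idx]) if idx.size else []:
                sub = idx[residues[idx] == aa]
                syn, cum = codon_cum[(aa, sign)]
                draws = np.searchsorted(cum, rng.random(sub.size))
                for j, k in zip(sub, draws):
                    codons[j] = syn[k]

        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        pairs.append(
            CognatePair(
                id=f"synth{p:04d}",
                protein="".join(residues),
                cds="".join(codons) + stop,
            )
        )
    return pairs


def gen_null_pairs(
    pairs: Sequence[CognatePair], rng: np.random.Generator
) -> tuple[list[CognatePair], list[str]]:
    """Re-assign mRNAs to random non-cognate proteins of identical length.

    Within each protein-length group the CDSs are randomly permuted;
    proteins with no length-compatible partner are passed through unchanged
    and returned in the skip list. The multiset of mRNAs is preserved.
    """
    by_length: dict[int, list[int]] = {}
    for k, pair in enumerate(pairs):
        by_length.setdefault(pair.length, []).append(k)
    out = list(pairs)
    skipped = []
    for length, idx in sorted(by_length.items()):
        if len(idx) < 2:
            skipped.extend(pairs[k].id for k in idx)
            continue
        perm = rng.permutation(len(idx))
        for slot, src in zip(idx, (idx[j] for j in perm)):
            out[slot] = replace(pairs[slot], cds=pairs[src].cds)
    return out, skipped
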