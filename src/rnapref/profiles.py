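"""Cognate mRNA/protein pairs, composition profiles and their correlation.

A cognate pair is a protein sequence together with the coding sequence (CDS)
of its mRNA, related by ``len(CDS) = 3 L + 3`` (terminal stop codon included).
For each pair two per-position series of equal length L are built: the
fraction of codon positions occupied by a base class (codon-indexed) and the
amino-acid interaction preference for that class (residue-indexed). Both are
smoothed with a centered sliding-window mean (window 21 by default) and
compared by a Pearson correlation coefficient R. Because preference is a
pseudo-energy, compositional matching shows up as *negative* R. Proteome-wide
matching is summarized by the median (R_median) and mean (<R>) of per-pair R.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import (
    AA_ORDER,
    BASE_CLASSES,
    CODON_TO_AA,
    CODONS_BY_AA,
    STOP_CODONS,
    class_count,
    validate_base_class,
)
from .scales import PreferenceScale

DEFAULT_WINDOW = 21

_AA_SET = frozenset(AA_ORDER)
_BASE_SET = frozenset("ACGU")


class ZeroVarianceError(ValueError):
    """A smoothed profile is constant; Pearson R is undefined."""


@dataclass(frozen=True)
class CognatePair:
    """A protein sequence and the validated CDS of its mRNA."""

    id: str
    protein: str
    cds: str

    def __post_init__(self) -> None:
        if len(self.cds) != 3 * len(self.protein) + 3:
            raise ValueError(
                f"{self.id}: CDS length {len(self.cds)} != 3*{len(self.protein)}+3"
            )

    @property
    def length(self) -> int:
        return len(self.protein)

    def codons(self) -> list[str]:
        """Codons of the coding region, terminal stop excluded."""
        return [self.cds[k : k + 3] for k in range(0, len(self.cds) - 3, 3)]


@dataclass
class CodonContentScale:
    """Per-amino-acid mean fraction of codon positions in a base class.

    ``missing`` flags amino acids with no codon instance in the source
    corpus (their content is undefined and absent from ``values``).
    """

    base_class: str
    values: pd.Series
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        validate_base_class(self.base_class)
        v = self.values.to_numpy(dtype=float)
        if ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValueError("codon content values must lie in [0, 1]")


@dataclass
class CorrelationSet:
    """Per-pair Pearson R values with exclusion log and summaries."""

    r: pd.Series  # id -> R over retained pairs
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def r_median(self) -> float:
        return float(self.r.median())

    @property
    def r_mean(self) -> float:
        return float(self.r.mean())

    @property
    def n_retained(self) -> int:
        return len(self.r)

    def summary(self) -> dict:
        return {
            "r_median": self.r_median,
            "r_mean": self.r_mean,
            "n_retained": self.n_retained,
            "n_excluded": len(self.excluded),
        }

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        frame = self.r.rename("R").to_frame()
        frame["status"] = "retained"
        dropped = pd.DataFrame(self.excluded, columns=["id", "status"]).set_index("id")
        dropped["R"] = np.nan
        pd.concat([frame, dropped[["R", "status"]]]).to_csv(
            path, sep="\t", index_label="id"
        )
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.summary(), indent=2)
        )


def _read_fasta(path_or_handle) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path_or_handle, "fasta")
    }


def load_pairs(
    protein_fasta,
    cds_fasta,
    window: int = DEFAULT_WINDOW,
    check_translation: bool = False,
) -> tuple[list[CognatePair], list[tuple[str, str]]]:
    """Match protein and CDS FASTA records by identifier and validate pairs.

    DNA-alphabet CDS input is accepted (T is normalized to U). Pairs are
    rejected -- with a logged reason, never fatally -- when the identifier is
    missing on one side, the ``3L+3`` length criterion fails, either sequence
    contains non-canonical letters, or the protein is shorter than the
    smoothing ``window``. With ``check_translation`` the CDS must also
    translate to the protein under the standard code.
    """
    proteins = _read_fasta(protein_fasta)
    cdss = _read_fasta(cds_fasta)
    pairs: list[CognatePair] = []
    rejections: list[tuple[str, str]] = []
    for pid in proteins:
        if pid not in cdss:
            rejections.append((pid, "missing_cds"))
    for pid in cdss:
        if pid not in proteins:
            rejections.append((pid, "missing_protein"))

    for pid in sorted(set(proteins) & set(cdss)):
        prot = proteins[pid]
        cds = cdss[pid].replace("T", "U")
        if set(prot) - _AA_SET:
            rejections.append((pid, "noncanonical_protein"))
            continue
        if set(cds) - _BASE_SET:
            rejections.append((pid, "noncanonical_cds"))
            continue
        if len(cds) != 3 * len(prot) + 3:
            rejections.append((pid, "length_criterion"))
            continue
        if len(prot) < window:
            rejections.append((pid, "shorter_than_window"))
            continue
        pair = CognatePair(pid, prot, cds)
        if check_translation:
            translated = "".join(CODON_TO_AA.get(c, "X") for c in pair.codons())
            if translated != prot or cds[-3:] not in STOP_CODONS:
                rejections.append((pid, "translation_mismatch"))
                continue
        pairs.append(pair)
    return pairs, rejections


def codon_content_scale(
    pairs: Iterable[CognatePair], base_class: str
) -> CodonContentScale:
    """Usage-weighted codon content: for each amino acid, the mean over all of
    its codon instances in the corpus of (class bases in codon)/3.

    Codons are attributed to amino acids through the standard code; stop
    codons are excluded. Amino acids with no codon instance are flagged in
    the result's ``missing`` tuple and omitted from its values.
    """
    validate_base_class(base_class)
    totals = {aa: 0.0 for aa in AA_ORDER}
    counts = {aa: 0 for aa in AA_ORDER}
    for pair in pairs:
        for codon in pair.codons():
            aa = CODON_TO_AA.get(codon)
            if aa is None:  # stop codon inside the coding region
                continue
            totals[aa] += class_count(codon, base_class) / 3.0
            counts[aa] += 1
    missing = tuple(aa for aa in AA_ORDER if counts[aa] == 0)
    if len(missing) == 20:
        raise ValueError("no codons at all: content scale undefined")
    values = pd.Series(
        {aa: totals[aa] / counts[aa] for aa in AA_ORDER if counts[aa] > 0}
    )
    return CodonContentScale(base_class, values, missing)


def standard_table_content(base_class: str) -> CodonContentScale:
    """Codon content under the standard genetic table, unweighted by usage."""
    validate_base_class(base_class)
    values = pd.Series(
        {
            aa: float(np.mean([class_count(c, base_class) / 3.0 for c in codons]))
            for aa, codons in CODONS_BY_AA.items()
        }
    )
    return CodonContentScale(base_class, values)


def mrna_content_profile(pair: CognatePair, base_class: str) -> np.ndarray:
    """Per-codon fraction of positions in ``base_class`` (length L)."""
    validate_base_class(base_class)
    members = BASE_CLASSES[base_class]
    return np.array(
        [sum(1 for b in codon if b in members) / 3.0 for codon in pair.codons()]
    )


def protein_preference_profile(pair: CognatePair, scale: PreferenceScale) -> np.ndarray:
    """Per-residue preference values (length L)."""
    lookup = scale.values
    missing = sorted(set(pair.protein) - set(lookup.index))
    if missing:
        raise KeyError(f"{pair.id}: no scale value for residue(s) {missing}")
    return lookup.reindex(list(pair.protein)).to_numpy(dtype=float)


def smooth(values: Sequence[float] | np.ndarray, window: int = DEFAULT_WINDOW,
           mode: str = "valid") -> np.ndarray:
    """Centered sliding-window mean.

    ``mode='valid'`` (default) keeps full windows only, length ``L - w + 1``.
    ``mode='shrink'`` keeps length L, shrinking the window symmetrically at
    the edges (sensitivity-check variant).
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if len(values) < window:
        raise ValueError(f"series of length {len(values)} shorter than window {window}")
    if mode == "valid":
        kernel = np.full(window, 1.0 / window)
        return np.convolve(values, kernel, mode="valid")
    if mode == "shrink":
        half = window // 2
        csum = np.concatenate([[0.0], np.cumsum(values)])
        n = len(values)
        out = np.empty(n)
        for k in range(n):
            lo, hi = max(0, k - half), min(n, k + half + 1)
            out[k] = (csum[hi] - csum[lo]) / (hi - lo)
        return out
    raise ValueError("mode must be 'valid' or 'shrink'")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises ZeroVarianceError on a constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(np.dot(xc, xc)))
    ny = float(np.sqrt(np.dot(yc, yc)))
    if nx == 0.0 or ny == 0.0:
        raise ZeroVarianceError("constant profile: Pearson R undefined")
    return float(np.dot(xc, yc) / (nx * ny))


def pair_correlation(
    pair: CognatePair,
    scale: PreferenceScale,
    base_class: str,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Pearson R between the smoothed mRNA content profile and the smoothed
    protein preference profile of one cognate pair."""
    content = smooth(mrna_content_profile(pair, base_class), window)
    pref = smooth(protein_preference_profile(pair, scale), window)
    return pearson(content, pref)


def scale_vs_codon_correlation(
    scale: PreferenceScale, codon_scale: CodonContentScale
) -> float:
    """Pearson R across the 20 amino acids between an interaction preference
    scale and a codon content scale."""
    common = scale.values.index.intersection(codon_scale.values.index)
    if len(common) < 3:
        raise ValueError("scales share too few amino acids for a correlation")
    return pearson(
        scale.values.reindex(common).to_numpy(),
        codon_scale.values.reindex(common).to_numpy(),
    )


def proteome_correlations(
    pairs: Iterable[CognatePair],
    scale: PreferenceScale,
    base_class: str,
    window: int = DEFAULT_WINDOW,
) -> CorrelationSet:
    """Per-pair R over a pair collection with summaries; zero-variance or
    sub-window pairs are excluded with a logged reason."""
    r: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []
    for pair in pairs:
        if pair.length < window:
            excluded.append((pair.id, "shorter_than_window"))
            continue
        try:
            r[pair.id] = pair_correlation(pair, scale, base_class, window)
        except ZeroVarianceError:
            excluded.append((pair.id, "zero_variance"))
    if not r:
        raise ValueError("all pairs excluded: no correlations to summarize")
    return CorrelationSet(pd.Series(r), excluded)


def profile_dump(
    pair: CognatePair,
    scale: PreferenceScale,
    base_class: str,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Smoothed profile overlay for one pair (position, mrna_value,
    protein_value), for reproducing profile-matching figures."""
    content = smooth(mrna_content_profile(pair, base_class), window)
    pref = smooth(protein_preference_profile(pair, scale), window)
    half = window // 2
    positions = np.arange(half + 1, half + 1 + len(content))
    return pd.DataFrame(
        {"position": positions, "mrna_value": content, "protein_value": pref}
    )
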