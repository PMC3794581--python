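"""Randomization significance for preference/content correlations.

The null model randomly permutes the 20 values of an interaction preference
scale over the amino acids, preserving the value multiset. Two statistics are
randomized: the single Pearson R between a scale and a codon content scale
("codon" mode), and the proteome mean <R> of per-pair profile correlations
("profiles" mode). Empirical p-values are strict exceedance fractions,
p = #{shuffles with |stat| > |stat_original|} / n_shuffles; an observed zero
is reported as "< 1/n_shuffles".

Profile-mode nulls avoid rebuilding sequence profiles per shuffle: for each
pair, with M the window-averaged one-hot residue matrix, C the centering
projector and y the smoothed content profile,

    R(s) = a . s / sqrt(s^T Q s),   a = M^T C y / ||C y||,   Q = M^T C M,

which is algebraically identical to recomputing the smoothed preference
profile for the permuted scale s and correlating. The precomputation is done
once per pair; each shuffle then costs a 20-vector contraction per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    DEFAULT_WINDOW,
    CognatePair,
    CodonContentScale,
    ZeroVarianceError,
    mrna_content_profile,
    pearson,
    smooth,
)
from .scales import PreferenceScale

_CHUNK = 10_000  # fixed shuffle chunk size; part of the deterministic stream

_VAR_EPS = 1e-14


@dataclass
class NullDistribution:
    """Shuffle-null of a correlation statistic with its empirical p-value."""

    mode: str  # "codon" | "profiles"
    n_shuffles: int
    statistics: np.ndarray  # per-shuffle R (codon) or <R> (profiles)
    original: float
    seed: int
    shuffle_sds: np.ndarray | None = None  # profiles mode: per-shuffle sd of pair R
    scales: np.ndarray | None = None  # (n_shuffles, n_aa) permuted values
    index: pd.Index | None = None  # amino-acid order of the permuted values
    extra: dict = field(default_factory=dict)

    @property
    def n_exceed(self) -> int:
        # strict exceedance; the 1e-12 guard keeps a re-drawn identity
        # permutation (|R| mathematically equal to the original) from being
        # counted through last-ulp differences between code paths
        return int(np.sum(np.abs(self.statistics) > abs(self.original) + 1e-12))

    @property
    def p_value(self) -> float:
        return self.n_exceed / self.n_shuffles

    def format_p(self) -> str:
        """Paper-style report: a raw zero becomes '< 1/n_shuffles'."""
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_shuffles:g}"
        return f"{self.p_value:g}"

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "p_value": self.p_value,
            "p_report": self.format_p(),
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "original": self.original,
            "null_mean": float(np.nanmean(self.statistics)),
            "null_sd": float(np.nanstd(self.statistics)),
            **self.extra,
        }


@dataclass
class TypicalScale:
    """The shuffled scale whose per-pair R distribution sits closest (in
    Euclidean (mean, sd) distance) to the average mean and sd over all
    shuffles."""

    scale: PreferenceScale
    mean: float
    sd: float
    target_mean: float
    target_sd: float
    distance: float
    shuffle_index: int


def shuffle_scale(scale: PreferenceScale, rng: np.random.Generator) -> PreferenceScale:
    """Uniform random permutation of the scale values over its amino acids."""
    values = scale.values.to_numpy()
    perm = rng.permutation(len(values))
    return PreferenceScale(
        scale.base_class,
        pd.Series(values[perm], index=scale.values.index),
        provenance={**scale.provenance, "shuffled": True},
    )


def _permutation_chunks(
    seed: int, n_shuffles: int, size: int
) -> Iterable[np.ndarray]:
    """Deterministic stream of permutation index chunks for a given seed.

    The chunk schedule is fixed so the same (seed, n_shuffles, size) always
    reproduces the identical shuffle sequence, independent of the consumer.
    """
    rng = np.random.default_rng(seed)
    produced = 0
    while produced < n_shuffles:
        k = min(_CHUNK, n_shuffles - produced)
        chunk = rng.permuted(
            np.tile(np.arange(size), (k, 1)), axis=1
        )
        produced += k
        yield chunk


def pvalue_codon(
    scale: PreferenceScale | pd.Series,
    codon_scale: CodonContentScale | pd.Series,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Shuffle-null for the scale-vs-codon-content Pearson R.

    Works on any shared amino-acid index (reduced alphabets included, which
    makes exhaustive-enumeration cross-checks possible in tests).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    s_vals = scale.values if isinstance(scale, PreferenceScale) else scale
    c_vals = (
        codon_scale.values
        if isinstance(codon_scale, CodonContentScale)
        else codon_scale
    )
    common = s_vals.index.intersection(c_vals.index)
    if len(common) < 3:
        raise ValueError("too few shared amino acids")
    s = s_vals.reindex(common).to_numpy(dtype=float)
    c = c_vals.reindex(common).to_numpy(dtype=float)

    cc = c - c.mean()
    c_norm = float(np.sqrt(np.dot(cc, cc)))
    if c_norm == 0.0:
        raise ZeroVarianceError("constant codon content scale")
    sc = s - s.mean()
    s_norm = float(np.sqrt(np.dot(sc, sc)))
    if s_norm == 0.0:
        raise ZeroVarianceError("constant preference scale")
    original = float(np.dot(sc, cc) / (s_norm * c_norm))

    stats = np.empty(n_shuffles)
    keep_scales = n_shuffles * len(common) <= 2_000_000
    perms_kept: list[np.ndarray] = []
    pos = 0
    for chunk in _permutation_chunks(seed, n_shuffles, len(common)):
        shuffled = s[chunk]  # (k, m): permuted value rows, norms invariant
        sc_rows = shuffled - shuffled.mean(axis=1, keepdims=True)
        stats[pos : pos + len(chunk)] = sc_rows @ cc / (s_norm * c_norm)
        if keep_scales:
            perms_kept.append(chunk)
        pos += len(chunk)

    return NullDistribution(
        mode="codon",
        n_shuffles=n_shuffles,
        statistics=stats,
        original=original,
        seed=seed,
        scales=s[np.concatenate(perms_kept)] if keep_scales else None,
        index=common,
    )


@dataclass
class _PairCache:
    """Per-pair precomputation for profile-mode shuffle nulls."""

    a: np.ndarray  # (n_aa,) M^T C y / ||C y||
    q: np.ndarray  # (n_aa, n_aa) M^T C M


def _prepare_pair(
    pair: CognatePair,
    aa_index: pd.Index,
    base_class: str,
    window: int,
) -> _PairCache | None:
    """Build the (a, Q) cache for one pair; None if its smoothed content
    profile has zero variance."""
    y = smooth(mrna_content_profile(pair, base_class), window)
    yc = y - y.mean()
    y_norm = float(np.sqrt(np.dot(yc, yc)))
    if y_norm < np.sqrt(_VAR_EPS):
        return None
    aa_pos = {aa: k for k, aa in enumerate(aa_index)}
    onehot = np.zeros((pair.length, len(aa_index)))
    for i, aa in enumerate(pair.protein):
        onehot[i, aa_pos[aa]] = 1.0
    # sliding-window mean of each one-hot column == smoothed indicator
    csum = np.vstack([np.zeros(len(aa_index)), np.cumsum(onehot, axis=0)])
    m = (csum[window:] - csum[:-window]) / window  # (L-w+1, n_aa)
    mc = m - m.mean(axis=0, keepdims=True)
    return _PairCache(a=mc.T @ yc / y_norm, q=mc.T @ mc)


def _pair_r_matrix(
    caches: Sequence[_PairCache], scale_rows: np.ndarray
) -> np.ndarray:
    """R for every (pair, scale row); NaN where the preference profile is
    constant under that scale. scale_rows: (k, n_aa). Returns (k, n_pairs)."""
    A = np.stack([c.a for c in caches])  # (n_pairs, n_aa)
    Q = np.stack([c.q for c in caches])  # (n_pairs, n_aa, n_aa)
    num = scale_rows @ A.T  # (k, n_pairs)
    # s^T Q s per (pair, shuffle)
    sq = np.einsum("pij,kj->kpi", Q, scale_rows)
    den_sq = np.einsum("kpi,ki->kp", sq, scale_rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(den_sq)
    r[den_sq <= _VAR_EPS] = np.nan
    return r


def pvalue_profiles(
    scale: PreferenceScale,
    pairs: Sequence[CognatePair],
    base_class: str,
    window: int = DEFAULT_WINDOW,
    n_shuffles: int = 1_000,
    seed: int = 0,
    subsample: int | None = None,
    keep_scales: bool = True,
) -> NullDistribution:
    """Shuffle-null for the proteome mean profile correlation <R>.

    For each shuffled scale, per-pair R is recomputed over all (or a random
    ``subsample`` of) pairs and averaged; p is the strict exceedance fraction
    of |<R>| versus |<R_original>|. Subsampling is an approximation intended
    for desk-scale runs and is recorded in the output provenance.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    pairs = list(pairs)
    rng = np.random.default_rng(seed + 1)  # independent of the shuffle stream
    if subsample is not None and subsample < len(pairs):
        keep = rng.choice(len(pairs), size=subsample, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]

    aa_index = scale.values.index
    caches = []
    excluded = []
    for pair in pairs:
        if pair.length < window:
            excluded.append((pair.id, "shorter_than_window"))
            continue
        missing = set(pair.protein) - set(aa_index)
        if missing:
            raise KeyError(f"{pair.id}: no scale value for residue(s) {sorted(missing)}")
        cache = _prepare_pair(pair, aa_index, base_class, window)
        if cache is None:
            excluded.append((pair.id, "zero_variance"))
            continue
        caches.append(cache)
    if not caches:
        raise ValueError("all pairs excluded: <R> undefined")

    s = scale.values.to_numpy(dtype=float)
    orig_r = _pair_r_matrix(caches, s[None, :])[0]
    original = float(np.nanmean(orig_r))

    means = np.empty(n_shuffles)
    sds = np.empty(n_shuffles)
    kept = [] if keep_scales else None
    pos = 0
    for chunk in _permutation_chunks(seed, n_shuffles, len(s)):
        # sub-chunk to bound the (k, n_pairs, n_aa) einsum workspace
        for lo in range(0, len(chunk), 500):
            sub = chunk[lo : lo + 500]
            r = _pair_r_matrix(caches, s[sub])
            means[pos : pos + len(sub)] = np.nanmean(r, axis=1)
            sds[pos : pos + len(sub)] = np.nanstd(r, axis=1)
            if kept is not None:
                kept.append(s[sub])
            pos += len(sub)

    return NullDistribution(
        mode="profiles",
        n_shuffles=n_shuffles,
        statistics=means,
        original=original,
        seed=seed,
        shuffle_sds=sds,
        scales=np.concatenate(kept) if kept is not None else None,
        index=aa_index,
        extra={
            "base_class": base_class,
            "window": window,
            "n_pairs": len(caches),
            "n_excluded": len(excluded),
            "subsample": subsample,
            "original_pair_r_sd": float(np.nanstd(orig_r)),
        },
    )


def typical_randomized_scale(
    null: NullDistribution, base_class: str | None = None
) -> TypicalScale:
    """Select the shuffled scale whose per-pair R mean and sd are nearest (in
    Euclidean distance) to the average mean and average sd over all shuffles.

    Ties resolve to the first shuffle encountered.
    """
    if null.mode != "profiles" or null.shuffle_sds is None:
        raise ValueError("typical-scale selection needs a profile-mode null")
    if null.n_shuffles < 2:
        raise ValueError("need at least two shuffles")
    if null.scales is None:
        raise ValueError("shuffled scales were not retained (keep_scales=False)")
    means, sds = null.statistics, null.shuffle_sds
    target = (float(np.nanmean(means)), float(np.nanmean(sds)))
    d2 = (means - target[0]) ** 2 + (sds - target[1]) ** 2
    k = int(np.argmin(d2))
    values = pd.Series(null.scales[k], index=null.index)
    scale = PreferenceScale(
        base_class or null.extra.get("base_class", "G"),
        values,
        provenance={"typical_randomized": True, "shuffle_index": k, "seed": null.seed},
    )
    return TypicalScale(
        scale=scale,
        mean=float(means[k]),
        sd=float(sds[k]),
        target_mean=target[0],
        target_sd=target[1],
        distance=float(np.sqrt(d2[k])),
        shuffle_index=k,
    )
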