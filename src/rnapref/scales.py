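"""Knowledge-based amino-acid/nucleobase interaction preference scales.

Preferences are distance-independent contact pseudo-energies with a
quasi-chemical reference state::

    P(i, c) = -ln( N_obs(i, c) / N_exp(i, c) ),
    N_exp(i, c) = x_i * x_c * N_total,

where ``N_obs(i, c)`` counts observed side-chain/base contacts between amino
acid ``i`` and base class ``c``, and ``x_i``, ``x_c`` are mole fractions of
amino acid and base class among all observed contacts. Negative values mean
the contact is enriched over the independence null, i.e. preferred.

Six scales are derived from one contact table: one per single base
(G, A, C, U, using the four-base partition) and one per merged class
(PUR = {G, A}, PYR = {C, U}, using a fresh two-class partition -- so the
PUR and PYR scales are genuinely independent quantities, not negatives or
averages of the single-base scales).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import (
    BASE_CLASSES,
    MERGED_PARTITION,
    SINGLE_PARTITION,
    validate_base_class,
)
from .contacts import ContactTable

ALL_SCALE_CLASSES = ("G", "A", "C", "U", "PUR", "PYR")


class UndefinedCellError(ValueError):
    """A required observed count is zero and no pseudocount was supplied."""


@dataclass
class MoleFractions:
    """Amino-acid and base-class mole fractions among observed contacts."""

    x_aa: pd.Series
    x_base: pd.Series

    def __post_init__(self) -> None:
        for name, vec in (("x_aa", self.x_aa), ("x_base", self.x_base)):
            v = vec.to_numpy(dtype=float)
            if (v < 0).any() or (v > 1).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")


@dataclass
class PreferenceScale:
    """Interaction preference values for one base class.

    ``values`` is indexed by one-letter amino-acid codes; it covers every
    amino acid with a nonzero contact margin in the source table (all 20 for
    any realistically dense table). More negative means stronger preference.
    """

    base_class: str
    values: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_base_class(self.base_class)
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("preference values must be finite")
        self.values = self.values.astype(float)

    def centered(self) -> pd.Series:
        """Values minus their mean (the additive gauge removed)."""
        return self.values - self.values.mean()

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        frame = self.values.rename("preference").to_frame()
        frame.to_csv(path, sep="\t", index_label="aa")
        if sidecar and self.provenance:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps({"base_class": self.base_class, **self.provenance}, indent=2)
            )

    @classmethod
    def from_tsv(cls, path: str | Path, base_class: str | None = None) -> "PreferenceScale":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col="aa")
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        bc = base_class or meta.get("base_class")
        if bc is None:
            raise ValueError("base_class not given and no sidecar metadata found")
        provenance = {k: v for k, v in meta.items() if k != "base_class"}
        return cls(bc, frame.iloc[:, 0], provenance)


def _partition_for(base_class: str) -> tuple[str, ...]:
    return MERGED_PARTITION if base_class in MERGED_PARTITION else SINGLE_PARTITION


def _class_counts(table: ContactTable, partition: tuple[str, ...]) -> pd.DataFrame:
    """Observed counts re-binned onto a base-class partition."""
    cols = {}
    for cls_name in partition:
        members = sorted(BASE_CLASSES[cls_name])
        cols[cls_name] = table.counts[members].sum(axis=1)
    return pd.DataFrame(cols)


def mole_fractions(table: ContactTable, partition: str = "single") -> MoleFractions:
    """Mole fractions of amino acids and base classes among observed contacts.

    ``partition`` is ``'single'`` (G/A/C/U) or ``'merged'`` (PUR/PYR).
    """
    if partition not in ("single", "merged"):
        raise ValueError("partition must be 'single' or 'merged'")
    n = table.n_total
    if n == 0:
        raise ValueError("empty contact table: mole fractions undefined")
    classes = SINGLE_PARTITION if partition == "single" else MERGED_PARTITION
    binned = _class_counts(table, classes)
    x_aa = binned.sum(axis=1) / n
    x_base = binned.sum(axis=0) / n
    return MoleFractions(x_aa=x_aa, x_base=x_base)


def expected_counts(fractions: MoleFractions, n_total: float) -> pd.DataFrame:
    """Quasi-chemical expectation: N_exp(i, c) = x_i * x_c * N_total."""
    return pd.DataFrame(
        np.outer(fractions.x_aa.to_numpy(), fractions.x_base.to_numpy()) * n_total,
        index=fractions.x_aa.index,
        columns=fractions.x_base.index,
    )


def derive_scale(
    table: ContactTable, base_class: str, pseudocount: float = 0.0
) -> PreferenceScale:
    """Derive one preference scale from a contact table.

    Amino acids with a zero contact margin carry no information and are
    omitted. A zero observed count for a present amino acid is an error unless
    a positive ``pseudocount`` is supplied (intended for sparse synthetic
    tables; never applied silently).
    """
    validate_base_class(base_class)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    partition = _partition_for(base_class)
    binned = _class_counts(table, partition)
    margins = binned.sum(axis=1)
    present = margins[margins > 0].index
    if len(present) == 0:
        raise ValueError("empty contact table: scale undefined")
    binned = binned.loc[present]

    n = table.n_total
    x_aa = binned.sum(axis=1) / n
    x_base = binned.sum(axis=0) / n
    n_exp = x_aa.to_numpy() * x_base[base_class] * n
    n_obs = binned[base_class].to_numpy(dtype=float) + pseudocount

    if (n_exp <= 0).any():
        bad = present[np.asarray(n_exp) <= 0][0]
        raise UndefinedCellError(f"zero expected count for ({bad}, {base_class})")
    if (n_obs <= 0).any():
        bad = present[n_obs <= 0][0]
        raise UndefinedCellError(
            f"zero observed count for ({bad}, {base_class}); "
            "supply a positive pseudocount to regularize sparse tables"
        )

    values = pd.Series(-np.log(n_obs / n_exp), index=present)
    provenance = {
        "cutoff": table.cutoff,
        "set_rule": table.set_rule,
        "n_total": n,
        "pseudocount": pseudocount,
    }
    return PreferenceScale(base_class, values, provenance)


def derive_all_scales(
    table: ContactTable, pseudocount: float = 0.0
) -> dict[str, PreferenceScale]:
    """All six scales (G, A, C, U, PUR, PYR) from one contact table."""
    return {
        cls_name: derive_scale(table, cls_name, pseudocount=pseudocount)
        for cls_name in ALL_SCALE_CLASSES
    }


def scales_to_frame(scales: dict[str, PreferenceScale]) -> pd.DataFrame:
    """Bundle scales as a 20 x n_classes table (TSV-ready)."""
    return pd.DataFrame({name: s.values for name, s in scales.items()})
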