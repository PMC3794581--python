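"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from rnapref.alphabet import AA_ORDER, BASES
from rnapref.contacts import ContactTable


def brute_force_neighbors(model, cutoff):
    """Pure-python all-pairs neighbor oracle (no spatial index).

    Returns, per protein residue, the list of (base_index, distance) with
    distance strictly below the cutoff, sorted by (distance, chain, resnum,
    icode) -- computed from first principles off the parsed model.
    """
    out = []
    base_centers = []
    for base in model.rna_bases:
        coords = base.coords
        base_centers.append(
            tuple(sum(c[k] for c in coords) / len(coords) for k in range(3))
        )
    for res in model.protein_residues:
        coords = res.coords
        center = tuple(sum(c[k] for c in coords) / len(coords) for k in range(3))
        hits = []
        for j, bc in enumerate(base_centers):
            d = math.sqrt(sum((center[k] - bc[k]) ** 2 for k in range(3)))
            if d < cutoff:
                hits.append((j, d))
        hits.sort(key=lambda e: (e[1], model.rna_bases[e[0]].sort_key()))
        out.append(hits)
    return out


def brute_force_set_rule(neighbor_lists, rule):
    """Oracle for the 1+/2+/2 rules: list of (residue_index, base_index)."""
    kept = []
    for r, hits in enumerate(neighbor_lists):
        if rule == "1+" and len(hits) >= 1:
            chosen = hits
        elif rule == "2+" and len(hits) >= 2:
            chosen = hits
        elif rule == "2" and len(hits) >= 2:
            chosen = hits[:2]
        else:
            chosen = []
        kept.extend((r, j) for j, _ in chosen)
    return kept


def make_table(cells, cutoff=8.0, rule="2+"):
    """ContactTable from a {(aa, base): count} dict."""
    counts = pd.DataFrame(0, index=list(AA_ORDER), columns=list(BASES))
    for (aa, base), n in cells.items():
        counts.at[aa, base] = n
    return ContactTable(counts, cutoff=cutoff, set_rule=rule)


@pytest.fixture
def toy_table():
    """The two-amino-acid toy: Ala {G:8, A:2}, Ser {G:2, A:8}."""
    return make_table({("A", "G"): 8, ("A", "A"): 2, ("S", "G"): 2, ("S", "A"): 8})


@pytest.fixture
def independent_table():
    """Counts with exactly independent margins: outer(1..20, (1,2,3,4))."""
    counts = pd.DataFrame(
        np.outer(np.arange(1, 21), np.array([1, 2, 3, 4])),
        index=list(AA_ORDER),
        columns=list(BASES),
    )
    return ContactTable(counts, cutoff=8.0, set_rule="2+")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
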