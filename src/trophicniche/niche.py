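"""Levins' niche breadth and Pianka's pairwise niche overlap.

Both operate on dietary proportion vectors p (non-negative, summing to
one over a shared ordered item list):

* Levins' breadth ``B = 1 / Σ pᵢ²`` (reciprocal Simpson concentration),
  standardised to ``B̂_A = (B − 1)/(n − 1)`` on [0, 1] for n items.
* Pianka's overlap ``O = Σ pᵢⱼ pᵢₖ / √(Σ pᵢⱼ² · Σ pᵢₖ²)``, the cosine
  similarity of the two diet vectors: 0 for disjoint diets, 1 for
  identical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def as_proportions(p: pd.Series, tol: float = 1e-9) -> pd.Series:
    """Validate a proportion vector (non-negative, sums to one)."""
    arr = np.asarray(p, float)
    if arr.size < 1:
        raise ValueError("empty proportion vector")
    if (arr < -tol).any():
        raise ValueError("negative proportions")
    if abs(arr.sum() - 1.0) > max(tol, 1e-9 * arr.size):
        raise ValueError(f"proportions sum to {arr.sum()!r}, not 1")
    return p


@dataclass(frozen=True)
class BreadthResult:
    species: str
    b: float
    b_std: float  # NaN when undefined (single item)
    n_items: int


def levins_breadth(p: pd.Series, species: str = "") -> BreadthResult:
    """Levins' B and its standardised form for one proportion vector.

    With a single item B = 1 and the standardisation is undefined
    (returned as NaN).
    """
    as_proportions(p)
    arr = np.asarray(p, float)
    n = arr.size
    b = 1.0 / float(np.sum(arr**2))
    b_std = (b - 1.0) / (n - 1.0) if n >= 2 else float("nan")
    return BreadthResult(species=species, b=b, b_std=b_std, n_items=n)


def align_union(pj: pd.Series, pk: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Align two item-indexed vectors on the union of their items,
    filling absences with zero."""
    union = pj.index.union(pk.index)
    return (
        pj.reindex(union, fill_value=0.0).to_numpy(float),
        pk.reindex(union, fill_value=0.0).to_numpy(float),
    )


def pianka_overlap(pj: pd.Series, pk: pd.Series) -> float:
    """Pianka's symmetric overlap of two diet-proportion vectors."""
    a, b = align_union(pj, pk)
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        raise ValueError("overlap undefined: an all-zero proportion vector")
    return float(np.sum(a * b) / denom)


def breadth_table(proportions: dict[str, pd.Series], basis: str) -> pd.DataFrame:
    rows = [
        (sp, r.b, r.b_std, r.n_items, basis)
        for sp, p in proportions.items()
        for r in [levins_breadth(p, sp)]
    ]
    return pd.DataFrame(rows, columns=["species", "b", "b_std", "n_items", "basis"])


def overlap_table(proportions: dict[str, pd.Series], basis: str) -> pd.DataFrame:
    species = list(proportions)
    rows = []
    for i, sj in enumerate(species):
        for sk in species[i + 1:]:
            rows.append(
                (sj, sk, pianka_overlap(proportions[sj], proportions[sk]), basis)
            )
    return pd.DataFrame(rows, columns=["species_1", "species_2", "overlap", "basis"])
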