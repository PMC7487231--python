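"""Diet composition from fecal contents: FO, N, V indices, PSIRI% and
trophic-guild classification.

Index definitions (per consumer species, per food item *i*):

* ``FO``   — number of samples containing *i*; ``FO%`` = 100·FO/S with S
  the species' sample count.
* ``N``    — total item count; ``V`` — total volume (mm³).
* ``N%``, ``V%`` — mean over *all* S samples of the item's per-sample
  share of count (volume), ×100.  Absent samples contribute 0.
* ``PN%``, ``PV%`` — prey-specific shares: the same mean restricted to
  the FO samples that contain the item.
* ``PSIRI% = (PN% + PV%) · FO% / 2 / 100``.

Sample-averaged shares give the index its defining identities,
``FO%·PN%/100 = N%`` (likewise for volume) and hence
``PSIRI% = (N% + V%)/2`` with ``Σᵢ PSIRI% = 100``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import FecalItemRecord

log = logging.getLogger("trophicniche")

DIET_COLUMNS = (
    "species", "taxon", "category",
    "fo", "fo_pct", "n", "n_pct", "pn_pct", "v", "v_pct", "pv_pct", "psiri_pct",
)


class EmptyDietError(ValueError):
    """No fecal records exist for the requested species."""


def psiri(pn_pct: float, pv_pct: float, fo_pct: float) -> float:
    """Prey-specific index of relative importance (%)."""
    return (pn_pct + pv_pct) * fo_pct / 2 / 100


def records_frame(records: Iterable[FecalItemRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sample_id, r.species, r.taxon, r.category, r.count, r.volume)
            for r in records
        ],
        columns=["sample_id", "species", "taxon", "category", "count", "volume"],
    )


def tabulate_diet(
    records: Iterable[FecalItemRecord], species: str
) -> pd.DataFrame:
    """Per-taxon diet composition table for one consumer species.

    Samples whose total volume is zero cannot contribute volumetric
    shares; they are excluded from V%/PV% averaging (flagged in the log)
    but still count towards FO% and the numeric indices.
    """
    df = records_frame(records)
    df = df[df["species"] == species]
    if df.empty:
        raise EmptyDietError(f"no fecal records for species {species!r}")

    # per-sample totals
    totals = df.groupby("sample_id").agg(
        total_count=("count", "sum"), total_volume=("volume", "sum")
    )
    if (totals["total_count"] <= 0).any():
        bad = totals.index[totals["total_count"] <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    zero_vol = set(totals.index[totals["total_volume"] <= 0])
    if zero_vol:
        log.warning(
            "species %s: %d sample(s) with zero total volume excluded from "
            "volumetric averaging", species, len(zero_vol)
        )

    n_samples = totals.shape[0]
    n_vol_samples = n_samples - len(zero_vol)

    # pool duplicate (sample, taxon) rows, keep one category per taxon
    pooled = df.groupby(["sample_id", "taxon"], as_index=False).agg(
        count=("count", "sum"), volume=("volume", "sum"),
        category=("category", "first"),
    )
    pooled = pooled.merge(totals, left_on="sample_id", right_index=True)
    pooled["count_share"] = pooled["count"] / pooled["total_count"]
    pooled["volume_share"] = np.where(
        pooled["total_volume"] > 0, pooled["volume"] / pooled["total_volume"], np.nan
    )

    rows = []
    for taxon, grp in pooled.groupby("taxon", sort=True):
        fo = grp.shape[0]
        fo_pct = 100.0 * fo / n_samples
        n_tot = int(grp["count"].sum())
        v_tot = float(grp["volume"].sum())
        pn_pct = 100.0 * grp["count_share"].mean()
        n_pct = 100.0 * grp["count_share"].sum() / n_samples
        vol_shares = grp["volume_share"].dropna()
        if n_vol_samples > 0 and not vol_shares.empty:
            pv_pct = 100.0 * vol_shares.mean()
            v_pct = 100.0 * vol_shares.sum() / n_vol_samples
        else:
            # item never occurred in a volume-quantifiable sample
            pv_pct = v_pct = np.nan
        rows.append(
            dict(
                species=species, taxon=taxon, category=grp["category"].iloc[0],
                fo=fo, fo_pct=fo_pct, n=n_tot, n_pct=n_pct, pn_pct=pn_pct,
                v=v_tot, v_pct=v_pct, pv_pct=pv_pct,
                psiri_pct=psiri(pn_pct, pv_pct, fo_pct),
            )
        )
    out = pd.DataFrame(rows, columns=DIET_COLUMNS)
    return out


def diet_proportions(
    diet: pd.DataFrame, basis: str = "psiri", by: str = "taxon"
) -> pd.Series:
    """Proportion vector over taxa (or categories) from a diet table.

    ``basis`` selects the composition index: ``"psiri"`` (default),
    ``"n"`` or ``"v"``.  Proportions sum to one.
    """
    col = {"psiri": "psiri_pct", "n": "n_pct", "v": "v_pct"}[basis]
    weights = diet.groupby(by)[col].sum()
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"basis {basis!r} sums to zero")
    return weights / total


@dataclass(frozen=True)
class GuildClassification:
    """Predominant / secondary diet type of a species.

    ``predominant`` holds the guild whose pooled volume share exceeds the
    predominance threshold (35% by default); ``secondary`` a guild in the
    secondary band (10–35%).  ``basis`` is the per-guild pooled V%
    breakdown used for the decision.
    """

    species: str
    predominant: str | None
    secondary: str | None
    basis: Mapping[str, float]

    @property
    def code(self) -> str:
        if self.predominant is None:
            return "indeterminate"
        code = self.predominant
        if self.secondary is not None:
            code += f"_{self.secondary}"
        return code


#: broad-guild letter codes used in classification strings
GUILD_CODES = {"fruit": "FR", "insect": "IN", "other-invertebrate": "OI"}

#: default pooling of the seven network categories into broad guilds for
#: diet-type classification (arthropod guilds count as the insectivorous
#: fraction)
DEFAULT_BROAD_GUILDS = {
    "omnivorous": "insect",
    "predators": "insect",
    "herbivorous": "insect",
    "surface-detritivorous": "insect",
    "terrestrial-detritivorous": "insect",
    "C4/CAM fruits": "fruit",
    "C3 fruits": "fruit",
}


def classify_guild(
    diet: pd.DataFrame,
    category_map: Mapping[str, str],
    predominant_threshold: float = 35.0,
    secondary_range: Sequence[float] = (10.0, 35.0),
) -> GuildClassification:
    """Classify a species' trophic guild from pooled volume shares.

    Every taxon must map to a broad guild (e.g. fruit / insect).  Shares
    are each guild's share of the species' total reconstituted volume.
    """
    species = diet["species"].iloc[0]
    unmapped = sorted(set(diet["taxon"]) - set(category_map))
    if unmapped:
        raise KeyError(f"taxa without a broad-guild mapping: {unmapped}")
    guilds = diet["taxon"].map(category_map)
    vol = diet.groupby(guilds)["v"].sum()
    shares = (100.0 * vol / vol.sum()).to_dict()

    above = {g: s for g, s in shares.items() if s > predominant_threshold}
    if not above:
        log.warning("species %s: no guild exceeds %.1f%% of volume; "
                    "classification indeterminate", species, predominant_threshold)
        return GuildClassification(species, None, None, shares)
    predominant = max(above, key=above.get)
    lo, hi = secondary_range
    secondary = [
        g for g, s in shares.items() if g != predominant and lo <= s <= hi
    ]
    secondary_guild = max(secondary, key=lambda g: shares[g]) if secondary else None
    return GuildClassification(
        species,
        GUILD_CODES.get(predominant, predominant),
        GUILD_CODES.get(secondary_guild, secondary_guild) if secondary_guild else None,
        shares,
    )
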