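"""Shared data model for the trophic-niche pipeline.

The pipeline joins three classic data streams of avian trophic ecology:

* fecal-content tables (what was eaten recently, item by item),
* blood stable-isotope values (what was assimilated over weeks, as
  δ¹³C / δ¹⁵N in ‰), and
* isotopic source groups (candidate foods summarised as per-element
  mean ± SD).

Everything downstream (diet indices, niche metrics, mixing models,
ellipses, bipartite networks) consumes these records, and all randomness
flows from a single seed via :func:`child_rng`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

ELEMENTS = ("d13c", "d15n")

#: The seven consumer-resource categories used for network construction:
#: five arthropod guilds plus fruits split by photosynthetic pathway.
DEFAULT_CATEGORIES = (
    "omnivorous",
    "predators",
    "herbivorous",
    "surface-detritivorous",
    "terrestrial-detritivorous",
    "C4/CAM fruits",
    "C3 fruits",
)


class ValidationError(ValueError):
    """A record or table violates a data-model invariant."""


class SchemaError(ValueError):
    """A table is missing a required column."""


@dataclass(frozen=True)
class FecalItemRecord:
    """One food item observed in one fecal sample.

    ``count`` is the number of individuals of the item (e.g. seeds,
    exoskeleton-bearing arthropods) and ``volume`` its reconstituted
    volume in mm³.  A record carrying neither a count nor a volume is
    meaningless and rejected.
    """

    sample_id: str
    species: str
    taxon: str
    category: str
    count: int
    volume: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"negative count for {self.taxon!r}: {self.count}")
        if self.volume < 0:
            raise ValidationError(f"negative volume for {self.taxon!r}: {self.volume}")
        if self.count == 0 and self.volume == 0:
            raise ValidationError(
                f"record for {self.taxon!r} has count = 0 and volume = 0"
            )


@dataclass(frozen=True)
class IsotopeRecord:
    """δ¹³C (‰ vs VPDB) and δ¹⁵N (‰ vs air) of one individual.

    ``group`` is either a consumer species or a source label.
    """

    individual_id: str
    group: str
    d13c: float
    d15n: float

    def __post_init__(self) -> None:
        if not self.group:
            raise ValidationError("empty group label")
        if not (np.isfinite(self.d13c) and np.isfinite(self.d15n)):
            raise ValidationError(
                f"non-finite delta value for individual {self.individual_id!r}"
            )


@dataclass(frozen=True)
class SourceGroup:
    """An isotopic source with per-element mean ± SD (‰).

    Sources are pooled groups of candidate foods (e.g. an arthropod
    guild); pooling is an input decision, not inferred here.
    """

    name: str
    guild: str
    mean: dict[str, float]
    sd: dict[str, float]
    n_specimens: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if el not in self.mean or el not in self.sd:
                raise ValidationError(f"source {self.name!r} missing element {el!r}")
            if self.sd[el] < 0:
                raise ValidationError(f"negative sd for source {self.name!r}")


@dataclass(frozen=True)
class TrophicDiscrimination:
    """Trophic discrimination factor (TDF) per element, mean ± SD in ‰.

    The systematic isotopic shift between a food source and the consumer
    tissue synthesised from it; added to source means before mixing-model
    fitting, with its uncertainty added in quadrature to source SDs.
    """

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if el not in self.mean or el not in self.sd:
                raise ValidationError(f"TDF missing element {el!r}")
            if self.sd[el] < 0:
                raise ValidationError("negative TDF sd")


#: Whole-blood TDF of an omnivorous passerine: 2.2 ± 0.1 ‰ for δ¹³C and
#: 2.6 ± 0.2 ‰ for δ¹⁵N (controlled-feeding estimate).
DEFAULT_TDF = TrophicDiscrimination(
    mean={"d13c": 2.2, "d15n": 2.6}, sd={"d13c": 0.1, "d15n": 0.2}
)


@dataclass
class AnalysisConfig:
    """Run-wide settings; every stochastic stage derives its stream from
    ``rng_seed`` (see :func:`child_rng`)."""

    tdf: TrophicDiscrimination = field(default_factory=lambda: DEFAULT_TDF)
    ci_level: float = 0.95
    bootstrap_n: int = 50
    n_null: int = 1000
    mcmc_chains: int = 4
    mcmc_iterations: int = 20_000
    mcmc_burn_frac: float = 0.5
    mcmc_thin: int = 10
    rng_seed: int = 0
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    # diet-guild thresholds (% of total volume)
    predominant_threshold: float = 35.0
    secondary_range: tuple[float, float] = (10.0, 35.0)
    # proportion basis for Levins/Pianka indices: "psiri", "n" or "v"
    proportion_basis: str = "psiri"
    # ellipse-overlap denominator: "union" (Jaccard-style) or "smaller"
    overlap_denominator: str = "union"
    # isotope-network weights: "midpoint" of the CI or posterior "mean"
    isotope_weight: str = "midpoint"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must lie in (0, 1)")
        for name in ("bootstrap_n", "n_null", "mcmc_chains", "mcmc_iterations",
                     "mcmc_thin"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from YAML (or JSON, a YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            return cls()
        tdf = raw.pop("tdf", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "tdf"})
        if tdf is not None:
            cfg = replace(cfg, tdf=TrophicDiscrimination(**tdf))
        if "categories" in raw:
            cfg = replace(cfg, categories=tuple(raw["categories"]))
        return cfg


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream.

    Stage streams are independent of the order in which stages run: each
    is keyed by the run seed plus a CRC of the stage name.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stage.encode())])
    )
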