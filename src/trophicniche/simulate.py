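"""Synthetic trophic studies with known ground truth.

The generator emulates the structure of a field study of three sympatric
thrush species feeding on seven pooled resource groups (five arthropod
guilds plus C3 and C4/CAM fruits): Gaussian isotopic source
distributions, per-species true diet proportions p* (fixed or
Dirichlet-drawn), consumer blood values drawn from exactly the mixture
likelihood the fitting module assumes, and fecal samples with
multinomial item counts and noisy per-item volumes.

Because blood is generated from the model's own likelihood, fitting the
mixing model to a synthetic study is a parameter-recovery experiment:
the known p* should be covered by the posterior credible intervals.  An
optional per-category detectability multiplier downweights soft items in
feces only, reproducing the classic discordance between fecal diets
(biased toward hard remains) and assimilated, isotope-inferred diets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_CATEGORIES,
    DEFAULT_TDF,
    ELEMENTS,
    FecalItemRecord,
    IsotopeRecord,
    SourceGroup,
    TrophicDiscrimination,
    child_rng,
)
from .mixing import correct_sources

#: default source isotopic signatures (d13c, d15n) in per-mil: C3 fruits
#: strongly depleted in 13C, C4/CAM fruits enriched, arthropod guilds in
#: between with increasing 15N toward predators.
DEFAULT_SOURCE_MEANS = {
    "omnivorous": (-23.0, 6.5),
    "predators": (-24.0, 9.0),
    "herbivorous": (-26.0, 4.0),
    "surface-detritivorous": (-21.0, 4.5),
    "terrestrial-detritivorous": (-19.0, 7.5),
    "C4/CAM fruits": (-12.0, 4.0),
    "C3 fruits": (-27.0, 1.5),
}

#: reconstituted volume of one item, mm^3 (fruits are bulky, arthropods small)
DEFAULT_UNIT_VOLUMES = {
    "omnivorous": 2.0,
    "predators": 3.0,
    "herbivorous": 1.5,
    "surface-detritivorous": 2.0,
    "terrestrial-detritivorous": 2.5,
    "C4/CAM fruits": 8.0,
    "C3 fruits": 10.0,
}

#: default true diet proportions: two similar C3-fruit-leaning consumers
#: and one predator-leaning divergent consumer, mirroring the three-thrush
#: study pattern
DEFAULT_TRUE_P = {
    "consumer_A": (0.05, 0.30, 0.07, 0.07, 0.05, 0.01, 0.45),
    "consumer_B": (0.10, 0.22, 0.15, 0.14, 0.10, 0.02, 0.27),
    "consumer_C": (0.02, 0.60, 0.03, 0.03, 0.03, 0.00, 0.29),
}


@dataclass
class ScenarioConfig:
    """Ground-truth description of one synthetic study."""

    species: tuple[str, ...] = tuple(DEFAULT_TRUE_P)
    source_names: tuple[str, ...] = DEFAULT_CATEGORIES
    source_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_MEANS)
    )
    source_sd: float = 0.8
    #: per-species true diet proportions; None draws them from a
    #: symmetric Dirichlet with the given concentration
    true_p: dict[str, tuple[float, ...]] | None = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_TRUE_P.items()}
    )
    dirichlet_alpha: float = 1.0
    tdf: TrophicDiscrimination = field(default_factory=lambda: DEFAULT_TDF)
    #: per-element residual scale sigma_j (per-mil); 1.0 matches the
    #: overall whole-blood spread reported for wild thrushes
    residual_sd: tuple[float, float] = (1.0, 1.0)
    n_consumers: int = 50
    n_fecal_samples: tuple[int, ...] = (26, 20, 4)
    mean_items_per_sample: float = 5.0
    unit_volumes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_VOLUMES)
    )
    volume_noise_sd: float = 0.3  # lognormal sigma on item volumes
    #: optional per-category fecal detectability multiplier (< 1 down-
    #: weights soft items in feces but not in blood)
    detectability: dict[str, float] | None = None
    rng_seed: int = 0

    def resolve_p(self) -> dict[str, np.ndarray]:
        k = len(self.source_names)
        if self.true_p is not None:
            out = {}
            for sp in self.species:
                p = np.asarray(self.true_p[sp], float)
                if abs(p.sum() - 1) > 1e-9 or (p < 0).any() or p.size != k:
                    raise ValueError(f"invalid true proportions for {sp!r}")
                out[sp] = p
            return out
        rng = child_rng(self.rng_seed, "true-p")
        return {
            sp: rng.dirichlet(np.full(k, self.dirichlet_alpha))
            for sp in self.species
        }


def generate_sources(config: ScenarioConfig) -> list[SourceGroup]:
    """Source groups with the scenario's means and a common SD.

    Default means keep every pair at least 2 ‰ apart on one element so
    the mixing problem is identifiable; overriding with coincident means
    is allowed but flagged.
    """
    sources = []
    for name in config.source_names:
        c, n = config.source_means[name]
        sources.append(
            SourceGroup(
                name=name, guild=name,
                mean={"d13c": float(c), "d15n": float(n)},
                sd={"d13c": config.source_sd, "d15n": config.source_sd},
            )
        )
    means = np.array([[s.mean[el] for el in ELEMENTS] for s in sources])
    dist = np.abs(means[:, None, :] - means[None, :, :]).max(axis=2)
    np.fill_diagonal(dist, np.inf)
    if (dist < 2.0).any():
        import logging
        logging.getLogger("trophicniche").warning(
            "some source pairs are closer than 2 per-mil on both elements; "
            "the mixture may be non-identifiable"
        )
    return sources


def simulate_blood(
    config: ScenarioConfig, sources: list[SourceGroup]
) -> list[IsotopeRecord]:
    """Consumer blood values drawn from the mixture likelihood."""
    corrected = correct_sources(sources, config.tdf)
    mu = np.array([[s.mean[el] for el in ELEMENTS] for s in corrected])
    om = np.array([[s.sd[el] for el in ELEMENTS] for s in corrected])
    sig = np.asarray(config.residual_sd, float)
    rng = child_rng(config.rng_seed, "blood")
    true_p = config.resolve_p()
    records = []
    for sp in config.species:
        p = true_p[sp]
        mean = p @ mu
        sd = np.sqrt((p**2) @ (om**2) + sig**2)
        vals = rng.normal(mean, sd, size=(config.n_consumers, 2))
        for i, (c, n) in enumerate(vals, start=1):
            records.append(
                IsotopeRecord(f"{sp}-{i:03d}", sp, float(c), float(n))
            )
    return records


def simulate_feces(config: ScenarioConfig) -> list[FecalItemRecord]:
    """Fecal samples: multinomial counts over categories, noisy volumes.

    Item taxa coincide with the network categories (the coarsest usable
    resolution); detectability multipliers act here only.
    """
    rng = child_rng(config.rng_seed, "feces")
    true_p = config.resolve_p()
    cats = list(config.source_names)
    det = np.array([(config.detectability or {}).get(c, 1.0) for c in cats])
    records = []
    n_fecal = config.n_fecal_samples
    if len(n_fecal) != len(config.species):
        raise ValueError("n_fecal_samples must give one count per species")
    for sp, n_samp in zip(config.species, n_fecal):
        p = true_p[sp] * det
        p = p / p.sum()
        for s in range(1, n_samp + 1):
            n_items = 1 + rng.poisson(max(config.mean_items_per_sample - 1, 0))
            counts = rng.multinomial(n_items, p)
            for cat, cnt in zip(cats, counts):
                if cnt == 0:
                    continue
                vol = (
                    cnt
                    * config.unit_volumes.get(cat, 1.0)
                    * float(rng.lognormal(0.0, config.volume_noise_sd))
                )
                records.append(
                    FecalItemRecord(
                        sample_id=f"{sp}-F{s:03d}", species=sp, taxon=cat,
                        category=cat, count=int(cnt), volume=vol,
                    )
                )
    return records


@dataclass
class SyntheticStudy:
    config: ScenarioConfig
    sources: list[SourceGroup]
    blood: list[IsotopeRecord]
    feces: list[FecalItemRecord]
    true_p: dict[str, np.ndarray]


def simulate_study(config: ScenarioConfig | None = None) -> SyntheticStudy:
    config = config or ScenarioConfig()
    sources = generate_sources(config)
    return SyntheticStudy(
        config=config,
        sources=sources,
        blood=simulate_blood(config, sources),
        feces=simulate_feces(config),
        true_p=config.resolve_p(),
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Emit the three input CSVs plus a ground-truth JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    fecal = pd.DataFrame(
        [
            (r.sample_id, r.species, r.taxon, r.category, r.count, r.volume)
            for r in study.feces
        ],
        columns=["sample_id", "species", "taxon", "category", "count", "volume"],
    )
    paths["feces"] = out / "feces.csv"
    fecal.to_csv(paths["feces"], index=False)

    iso = pd.DataFrame(
        [(r.individual_id, r.group, r.d13c, r.d15n) for r in study.blood],
        columns=["individual_id", "group", "d13c", "d15n"],
    )
    paths["isotopes"] = out / "isotopes.csv"
    iso.to_csv(paths["isotopes"], index=False)

    src = pd.DataFrame(
        [
            (s.name, s.guild, s.mean["d13c"], s.sd["d13c"],
             s.mean["d15n"], s.sd["d15n"])
            for s in study.sources
        ],
        columns=["name", "guild", "mean_d13c", "sd_d13c", "mean_d15n", "sd_d15n"],
    )
    paths["sources"] = out / "sources.csv"
    src.to_csv(paths["sources"], index=False)

    truth = {
        "rng_seed": study.config.rng_seed,
        "true_p": {sp: list(map(float, p)) for sp, p in study.true_p.items()},
        "sources": list(study.config.source_names),
    }
    paths["truth"] = out / "ground_truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
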