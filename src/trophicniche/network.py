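"""Weighted bipartite consumer-resource networks: construction, WNODF
nestedness, d′ specialization, and vaznull null-model significance.

Two networks are built per study: one whose cell weights are PSIRI%
values pooled to resource categories (the "diet" network), and one whose
weights are midpoints of the mixing model's 95% credible intervals (the
"isotope" network).  Metrics:

* **WNODF** (0–100): weighted nestedness by overlap and decreasing fill.
  Rows/columns are ordered by decreasing fill, ties broken by decreasing
  weighted marginals; a pair (upper u, lower v) contributes only when
  fill(u) > fill(v), scoring the percentage of v's filled cells that are
  strictly smaller than u's corresponding cells.  WNODF is the mean over
  all row pairs and column pairs.
* **d′** (0–1): the Kullback–Leibler distance of a consumer's resource
  use from resource availability (column marginals), standardised by the
  marginal-constrained extremes d_min and d_max.
* **vaznull**: null matrices preserving dimensions, connectance (count
  of filled cells), and total interaction quanta, with cell probability
  proportional to the product of the original marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, child_rng

log = logging.getLogger("trophicniche")

#: quanta per unit weight when discretising continuous matrices for vaznull
DEFAULT_QUANTA_SCALE = 100.0


@dataclass(frozen=True)
class InteractionMatrix:
    """Weighted consumers × resources matrix."""

    consumers: tuple[str, ...]
    resources: tuple[str, ...]
    weights: np.ndarray  # (n_consumers, n_resources), all >= 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.shape != (len(self.consumers), len(self.resources)):
            raise ValueError("weight matrix shape does not match labels")
        if (w < 0).any():
            raise ValueError("negative interaction weights")
        if (w.sum(axis=1) == 0).any():
            raise ValueError("all-zero consumer row")
        if (w.sum(axis=0) == 0).any():
            raise ValueError("all-zero resource column")
        object.__setattr__(self, "weights", w)

    @property
    def row_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.weights.sum())

    @property
    def fill(self) -> int:
        return int((self.weights > 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.consumers), columns=list(self.resources)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(float))


def build_diet_matrix(
    diet_tables: Mapping[str, pd.DataFrame],
    category_map: Mapping[str, str] | None = None,
    categories: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Diet network: PSIRI% summed into resource categories per species.

    ``category_map`` maps taxa to network categories; when omitted, the
    diet tables' own ``category`` column is used.  Row sums are 100 by
    the ΣPSIRI% identity.
    """
    frames = {}
    for species, diet in diet_tables.items():
        if category_map is not None:
            unmapped = sorted(set(diet["taxon"]) - set(category_map))
            if unmapped:
                raise KeyError(f"taxa without a category mapping: {unmapped}")
            cats = diet["taxon"].map(category_map)
        else:
            cats = diet["category"]
        frames[species] = diet.groupby(cats)["psiri_pct"].sum()
    df = pd.DataFrame(frames).T.fillna(0.0)
    if categories is not None:
        keep = [c for c in categories if c in df.columns]
        df = df[keep]
    return InteractionMatrix.from_frame(df)


def build_isotope_matrix(
    ci: pd.DataFrame, weight: str = "midpoint"
) -> InteractionMatrix:
    """Isotope network from a credible-interval table.

    ``ci`` is long-format with columns species, source, lower, upper (and
    optionally mean).  ``weight`` selects the CI midpoint (default) or
    the posterior mean.  Zero-midpoint cells are structural zeros.
    """
    ci = ci.copy()
    if weight == "midpoint":
        ci["w"] = (ci["lower"] + ci["upper"]) / 2.0
    elif weight == "mean":
        ci["w"] = ci["mean"]
    else:
        raise ValueError(f"unknown weight {weight!r}")
    wide = ci.pivot(index="species", columns="source", values="w")
    if wide.isna().any().any():
        missing = [
            (i, c) for i, c in zip(*np.where(wide.isna().to_numpy()))
        ]
        raise ValueError(f"missing species × source cells: {missing}")
    # preserve first-appearance order of species and sources
    wide = wide.reindex(index=ci["species"].unique(),
                        columns=ci["source"].unique())
    return InteractionMatrix.from_frame(wide)


# ---------------------------------------------------------------------------
# WNODF


def wnodf(matrix: InteractionMatrix | np.ndarray) -> float:
    """Weighted NODF nestedness of a matrix, 0–100."""
    m = matrix.weights if isinstance(matrix, InteractionMatrix) else np.asarray(matrix, float)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("WNODF needs at least a 2×2 matrix")
    if (m.sum(axis=1) == 0).any() or (m.sum(axis=0) == 0).any():
        raise ValueError("matrix has an all-zero row or column")
    ro = np.lexsort((-m.sum(axis=1), -(m > 0).sum(axis=1)))
    co = np.lexsort((-m.sum(axis=0), -(m > 0).sum(axis=0)))
    m = m[ro][:, co]
    return float(np.mean(_pair_scores(m) + _pair_scores(m.T)))


def _pair_scores(m: np.ndarray) -> list[float]:
    """Decreasing-fill pair scores over the rows of an ordered matrix."""
    fills = (m > 0).sum(axis=1)
    scores = []
    for i in range(m.shape[0]):
        for j in range(i + 1, m.shape[0]):
            if fills[i] <= fills[j] or fills[j] == 0:
                scores.append(0.0)
            else:
                lower = m[j]
                scores.append(
                    100.0 * np.sum((m[i] - lower > 0) & (lower > 0)) / fills[j]
                )
    return scores


# ---------------------------------------------------------------------------
# d-prime specialization


@dataclass(frozen=True)
class SpecializationResult:
    consumer: str
    d: float
    d_min: float
    d_max: float
    d_prime: float


def _kl(alloc: np.ndarray, total: float, q: np.ndarray) -> float:
    p = alloc / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def _dmax(total: float, caps: np.ndarray, q: np.ndarray) -> float:
    """Exact maximum KL distance subject to 0 ≤ alloc_j ≤ cap_j and
    Σ alloc = total.

    The KL objective is convex in the allocation, so the maximum sits at
    a vertex of the capped simplex: a set of saturated columns plus at
    most one partial column.  Vertices are enumerated exhaustively (the
    number of resources is small in consumer-resource webs); beyond 16
    columns a greedy rarest-first fill is used instead.
    """
    k = len(caps)
    if k > 16:
        alloc = np.zeros_like(q)
        rem = total
        for j in np.argsort(q, kind="stable"):
            take = min(caps[j], rem)
            alloc[j] = take
            rem -= take
            if rem <= 0:
                break
        return _kl(alloc, total, q)
    best = -np.inf
    eps = 1e-12 * max(total, 1.0)
    for mask in range(1 << k):
        sat = [j for j in range(k) if mask >> j & 1]
        s = float(sum(caps[j] for j in sat))
        if s > total + eps:
            continue
        rem = total - s
        alloc = np.zeros(k)
        alloc[sat] = caps[sat]
        if rem <= eps:
            best = max(best, _kl(alloc, total, q))
            continue
        for j in range(k):
            if mask >> j & 1 or caps[j] < rem - eps:
                continue
            alloc[j] = rem
            best = max(best, _kl(alloc, total, q))
            alloc[j] = 0.0
    return best


def _dmin_alloc(total: float, caps: np.ndarray, q: np.ndarray,
                integer: bool) -> np.ndarray:
    """Most-generalised allocation: proportional to availability.

    Continuous weights admit the exact proportional fill (d_min = 0);
    integer quanta use largest-remainder rounding followed by greedy
    single-quantum improvement sweeps.
    """
    ideal = total * q
    if not integer:
        return np.minimum(ideal, caps)  # caps never bind: total <= sum(caps)
    base = np.minimum(np.floor(ideal), caps)
    rem = int(round(total - base.sum()))
    # largest remainders first, respecting caps
    order = np.argsort(-(ideal - base), kind="stable")
    alloc = base.copy()
    for j in order:
        if rem == 0:
            break
        add = int(min(rem, caps[j] - alloc[j], 1))
        alloc[j] += add
        rem -= add
    while rem > 0:  # saturated columns forced the remainder elsewhere
        j = int(np.argmax(caps - alloc))
        alloc[j] += 1
        rem -= 1
    # greedy improvement: move single quanta while d decreases
    for _ in range(200):
        d0 = _kl(alloc, total, q)
        best = None
        for a in np.nonzero(alloc > 0)[0]:
            for b in np.nonzero(alloc < caps)[0]:
                if a == b:
                    continue
                alloc[a] -= 1
                alloc[b] += 1
                d1 = _kl(alloc, total, q)
                if d1 < d0 - 1e-12 and (best is None or d1 < best[0]):
                    best = (d1, a, b)
                alloc[a] += 1
                alloc[b] -= 1
        if best is None:
            break
        _, a, b = best
        alloc[a] -= 1
        alloc[b] += 1
    return alloc


def dprime(
    matrix: InteractionMatrix, consumer: str, integer_quanta: bool | None = None
) -> SpecializationResult:
    """Standardised Kullback–Leibler specialization of one consumer row.

    ``integer_quanta`` controls the d_min search; by default it is
    inferred from whether the matrix holds integer counts.
    """
    i = matrix.consumers.index(consumer)
    w = matrix.weights
    total = float(w[i].sum())
    if total <= 0:
        raise ValueError(f"consumer {consumer!r} has zero row total")
    caps = w.sum(axis=0)
    q = caps / caps.sum()
    if integer_quanta is None:
        integer_quanta = bool(np.allclose(w, np.round(w)))
    d = _kl(w[i], total, q)
    dmax = _dmax(total, caps, q)
    dmin = _kl(_dmin_alloc(total, caps, q, integer_quanta), total, q)
    dmax = max(dmax, d)  # the observed row is itself feasible
    dmin = min(dmin, d)
    if dmax - dmin <= 1e-12:
        log.warning("consumer %r: d_max == d_min (single usable resource); "
                    "d' defined as 0", consumer)
        dp = 0.0
    else:
        dp = (d - dmin) / (dmax - dmin)
    return SpecializationResult(consumer, d, dmin, dmax, min(max(dp, 0.0), 1.0))


def specialization_table(matrix: InteractionMatrix) -> pd.DataFrame:
    rows = [dprime(matrix, c) for c in matrix.consumers]
    return pd.DataFrame(
        [(r.consumer, r.d, r.d_min, r.d_max, r.d_prime) for r in rows],
        columns=["consumer", "d", "d_min", "d_max", "d_prime"],
    )


# ---------------------------------------------------------------------------
# vaznull null model


def quantize(matrix: InteractionMatrix, scale: float = DEFAULT_QUANTA_SCALE) -> np.ndarray:
    """Continuous weights → integer interaction quanta (round(w·scale)).

    Cells that round to zero but carry weight are kept at one quantum so
    connectance is preserved.
    """
    w = matrix.weights
    if np.allclose(w, np.round(w)):
        q = np.round(w).astype(int)
    else:
        q = np.round(w * scale).astype(int)
        q[(w > 0) & (q == 0)] = 1
    return q


def vaznull(
    matrix: InteractionMatrix,
    n_rand: int,
    seed: int,
    quanta_scale: float = DEFAULT_QUANTA_SCALE,
) -> list[np.ndarray]:
    """Generate vaznull-style null matrices (integer quanta).

    Each null preserves the dimensions, the number of filled cells and
    the grand total of the quantised original; every row and column stays
    non-empty.  Filled-cell positions are drawn with probability
    proportional to the product of the original marginal totals, then the
    remaining quanta are distributed multinomially over those cells.
    """
    w = quantize(matrix, quanta_scale)
    nr, nc = w.shape
    fill = int((w > 0).sum())
    total = int(w.sum())
    if fill < max(nr, nc):
        raise ValueError("fill too small to keep every row and column non-empty")
    rowp = w.sum(axis=1) / w.sum()
    colp = w.sum(axis=0) / w.sum()
    cellp = np.outer(rowp, colp)
    rng = child_rng(seed, "vaznull")
    nulls = []
    for _ in range(n_rand):
        nulls.append(_vaznull_one(rng, nr, nc, fill, total, rowp, colp, cellp))
    return nulls


def _vaznull_one(rng, nr, nc, fill, total, rowp, colp, cellp) -> np.ndarray:
    for _ in range(10_000):
        chosen = np.zeros((nr, nc), bool)
        # one cell per row, then cover any empty columns: this pattern
        # guarantees connectivity before topping up the fill
        for i in rng.permutation(nr):
            chosen[i, rng.choice(nc, p=colp)] = True
        for j in rng.permutation(nc):
            if not chosen[:, j].any():
                chosen[rng.choice(nr, p=rowp), j] = True
        k = int(chosen.sum())
        if k > fill:
            continue  # used more cells than the required fill; redraw
        if k < fill:
            free = cellp.copy()
            free[chosen] = 0.0
            idx = rng.choice(
                nr * nc, size=fill - k, replace=False, p=(free / free.sum()).ravel()
            )
            chosen.ravel()[idx] = True
        null = chosen.astype(int)
        pick = cellp * chosen
        null += rng.multinomial(total - fill, (pick / pick.sum()).ravel()).reshape(nr, nc)
        return null
    raise RuntimeError("could not draw an admissible null matrix")


@dataclass(frozen=True)
class NestednessResult:
    observed_wnodf: float
    null_values: np.ndarray
    null_ci: tuple[float, float]
    significant: bool


def nestedness_test(
    matrix: InteractionMatrix, config: AnalysisConfig
) -> NestednessResult:
    """Observed WNODF against the vaznull null distribution.

    Nestedness is significant when the observed value exceeds the upper
    bound of the null 95% interval.
    """
    observed = wnodf(matrix)
    nulls = np.array(
        [wnodf_raw(nm) for nm in vaznull(matrix, config.n_null, config.rng_seed)]
    )
    alpha = (1.0 - config.ci_level) / 2.0
    lo, hi = np.percentile(nulls, [100 * alpha, 100 * (1 - alpha)])
    return NestednessResult(
        observed_wnodf=observed,
        null_values=nulls,
        null_ci=(float(lo), float(hi)),
        significant=bool(observed > hi),
    )


def wnodf_raw(m: np.ndarray) -> float:
    """WNODF of a raw array that may contain empty rows/columns (null
    matrices never do, but user matrices are validated upstream)."""
    ro = np.lexsort((-m.sum(axis=1), -(m > 0).sum(axis=1)))
    co = np.lexsort((-m.sum(axis=0), -(m > 0).sum(axis=0)))
    m = np.asarray(m, float)[ro][:, co]
    return float(np.mean(_pair_scores(m) + _pair_scores(m.T)))
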