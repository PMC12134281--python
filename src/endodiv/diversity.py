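"""Alpha-diversity indices and community summaries for endophyte inventories.

Implements the index family standard in culture-based endophyte surveys:

* occurrence % — a species' colony count over all colonies, times 100;
* colonization frequency (CF%) — colonized over examined segments, times 100;
* Shannon–Wiener entropy H' = −Σ p_i ln p_i (natural log);
* Simpson's complement 1 − Σ p_i² (probability two random isolates differ);
* Camargo's index, used here in its reciprocal-richness form 1/S;
* Berger–Parker dominance N_max / N;
* Pielou-style evenness E = H' / ln S.

Also: per-tissue species overlap sets (Venn regions), PCA ordination of the
genus × tissue count matrix, and an exact integer-enumeration routine that
recovers abundance vectors consistent with a published, rounded index row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .community import TISSUES, CommunityTable, ValidationError

__all__ = [
    "DiversityProfile",
    "OverlapSets",
    "OrdinationResult",
    "occurrence_percent",
    "colonization_frequency",
    "shannon",
    "simpson_complement",
    "camargo",
    "berger_parker",
    "evenness",
    "diversity_profile",
    "profile_table",
    "tissue_overlaps",
    "reconstruct_abundances",
    "pca_ordination",
    "round_value",
]

#: decimal places per index used when formatting "as printed" rows
DEFAULT_ROUNDING: dict[str, int] = {
    "shannon": 2,
    "simpson_complement": 3,
    "camargo": 3,
    "berger_parker": 2,
    "evenness": 3,
    "cf_percent": 1,
}


class UndefinedInputError(ValueError):
    """The statistic is mathematically undefined for this input."""


def round_value(x: float, decimals: int, mode: str = "half_up") -> float:
    """Round to a fixed number of decimals with an explicit tie/truncation rule.

    ``half_up`` matches the convention of most published tables; ``truncate``
    drops trailing digits (some printed values, e.g. 1/6 shown as 0.16, are
    truncations rather than roundings).
    """
    rounding = {"half_up": ROUND_HALF_UP, "truncate": ROUND_DOWN}[mode]
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=rounding))


def _clean(abundances: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(abundances), dtype=float)
    if arr.size and (arr < 0).any():
        raise ValidationError("abundances must be non-negative")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise UndefinedInputError("diversity indices need at least one positive abundance")
    return arr


def occurrence_percent(species_count: int, total_count: int) -> float:
    """Colony count of one species as a percentage of all colonies."""
    if total_count <= 0:
        raise UndefinedInputError("total_count must be positive")
    if not 0 <= species_count <= total_count:
        raise ValidationError("need 0 <= species_count <= total_count")
    return 100.0 * species_count / total_count


def colonization_frequency(colonized: int, examined: int, decimals: int | None = 1) -> float:
    """CF% — segments yielding an endophyte over segments plated, times 100."""
    if examined <= 0:
        raise UndefinedInputError("examined must be positive")
    if colonized < 0 or colonized > examined:
        raise ValidationError(
            f"segments colonized ({colonized}) outside [0, {examined}]"
        )
    cf = 100.0 * colonized / examined
    return round_value(cf, decimals) if decimals is not None else cf


def shannon(abundances: Iterable[float]) -> float:
    """Shannon–Wiener H' in nats; invariant to permutation and scaling."""
    arr = _clean(abundances)
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def simpson_complement(abundances: Iterable[float]) -> float:
    """1 − Σ p_i²: chance that two randomly drawn isolates differ in species."""
    arr = _clean(abundances)
    p = arr / arr.sum()
    return float(1.0 - (p**2).sum())


def camargo(richness_S: int) -> float:
    """Reciprocal richness 1/S (the form used in endophyte survey tables)."""
    if richness_S < 1:
        raise UndefinedInputError("richness must be >= 1")
    return 1.0 / richness_S


def berger_parker(abundances: Iterable[float]) -> float:
    """Dominance N_max / N of the single most abundant species."""
    arr = _clean(abundances)
    return float(arr.max() / arr.sum())


def evenness(shannon_H: float, richness_S: int) -> float | None:
    """E = H'/ln S, in [0, 1]; None (undefined) when S < 2."""
    if richness_S < 2:
        return None
    if shannon_H < 0:
        raise ValidationError("Shannon entropy cannot be negative")
    return shannon_H / math.log(richness_S)


# -- per-plant profiles ---------------------------------------------------


@dataclass(frozen=True)
class DiversityProfile:
    """All indices for one plant's endophyte community.

    Full-precision values are stored; ``as_printed`` applies per-index
    decimals. ``no_data`` marks plants that yielded no isolates (reported
    as dashes, never as zero diversity).
    """

    plant: str
    abundance_N: int
    richness_S: int
    shannon_H: float | None
    simpson_complement: float | None
    camargo: float | None
    berger_parker: float | None
    evenness_E: float | None
    rounding: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_ROUNDING))

    @property
    def no_data(self) -> bool:
        return self.richness_S == 0

    def as_printed(self, mode: str = "half_up") -> dict[str, float | str | None]:
        def fmt(key: str, value: float | None):
            if value is None:
                return None
            return round_value(value, self.rounding.get(key, 3), mode=mode)

        return {
            "plant": self.plant,
            "abundance_N": self.abundance_N if not self.no_data else None,
            "richness_S": self.richness_S if not self.no_data else None,
            "shannon": fmt("shannon", self.shannon_H),
            "simpson_complement": fmt("simpson_complement", self.simpson_complement),
            "camargo": fmt("camargo", self.camargo),
            "berger_parker": fmt("berger_parker", self.berger_parker),
            "evenness": fmt("evenness", self.evenness_E),
        }


def diversity_profile(
    table: CommunityTable,
    plant: str,
    rounding: Mapping[str, int] | None = None,
) -> DiversityProfile:
    """Assemble the full index profile for one plant in a community table."""
    if plant not in {r.plant for r in table.isolates}:
        raise KeyError(f"plant {plant!r} not present in table")
    vec = table.abundance_vector(plant)
    rnd = dict(DEFAULT_ROUNDING)
    if rounding:
        rnd.update(rounding)
    if not vec:
        return DiversityProfile(plant, 0, 0, None, None, None, None, None, rnd)
    S = len(vec)
    H = shannon(vec)
    return DiversityProfile(
        plant=plant,
        abundance_N=int(sum(vec)),
        richness_S=S,
        shannon_H=H,
        simpson_complement=simpson_complement(vec),
        camargo=camargo(S),
        berger_parker=berger_parker(vec),
        evenness_E=evenness(H, S),
        rounding=rnd,
    )


def profile_table(
    table: CommunityTable,
    rounding: Mapping[str, int] | None = None,
    printed: bool = True,
) -> pd.DataFrame:
    """One profile row per plant (printed-rounding or full precision)."""
    rows = []
    for plant in table.plants:
        prof = diversity_profile(table, plant, rounding=rounding)
        if printed:
            rows.append(prof.as_printed())
        else:
            rows.append(
                {
                    "plant": prof.plant,
                    "abundance_N": prof.abundance_N,
                    "richness_S": prof.richness_S,
                    "shannon": prof.shannon_H,
                    "simpson_complement": prof.simpson_complement,
                    "camargo": prof.camargo,
                    "berger_parker": prof.berger_parker,
                    "evenness": prof.evenness_E,
                }
            )
    return pd.DataFrame(rows)


# -- tissue overlaps (Venn regions) --------------------------------------


@dataclass(frozen=True)
class OverlapSets:
    """Per-tissue morphospecies sets and exclusive Venn-region sizes."""

    tissue_sets: Mapping[str, frozenset[str]]
    regions: Mapping[frozenset[str], int]

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.tissue_sets.values():
            out |= s
        return frozenset(out)

    def intersection_size(self, tissues: Iterable[str]) -> int:
        tissues = list(tissues)
        sets = [self.tissue_sets.get(t, frozenset()) for t in tissues]
        if not sets:
            return 0
        return len(frozenset.intersection(*sets))


def tissue_overlaps(table: CommunityTable) -> OverlapSets:
    """Species sets per tissue and the 2^k − 1 exclusive Venn regions.

    A region keyed by a tissue subset T counts species found in exactly
    the tissues of T; regions therefore partition the union.
    """
    tissue_sets: dict[str, set[str]] = {t: set() for t in TISSUES}
    for rec in table.isolates:
        if rec.colony_count > 0:
            tissue_sets[rec.tissue].add(rec.taxon.morphospecies_id)
    membership: dict[str, frozenset[str]] = {}
    for t, species in tissue_sets.items():
        for sp in species:
            membership[sp] = membership.get(sp, frozenset()) | {t}
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(TISSUES) + 1):
        for combo in combinations(TISSUES, r):
            regions[frozenset(combo)] = 0
    for sp, where in membership.items():
        regions[where] += 1
    return OverlapSets(
        tissue_sets={t: frozenset(s) for t, s in tissue_sets.items()},
        regions=regions,
    )


# -- reconstruction of abundance vectors from printed indices -------------


def _partitions(total: int, parts: int, cap: int):
    """Non-increasing positive integer vectors of length `parts` summing to `total`."""
    if parts == 1:
        if 1 <= total <= cap:
            yield (total,)
        return
    lo = -(-total // parts)  # ceil: first part is the max
    for head in range(min(cap, total - parts + 1), lo - 1, -1):
        for tail in _partitions(total - head, parts - 1, head):
            yield (head,) + tail


def reconstruct_abundances(
    richness_S: int,
    index_targets: Mapping[str, float],
    n_range: tuple[int, int] = (1, 30),
    rounding: Mapping[str, int] | None = None,
    rounding_mode: str = "half_up",
) -> list[tuple[int, ...]]:
    """Enumerate integer abundance vectors matching a printed index row.

    Searches all non-increasing positive integer vectors of length
    ``richness_S`` with total abundance in ``n_range`` and keeps those
    whose indices, rounded to the per-index decimals implied by the
    printed targets, equal every supplied target. Targets may include
    ``shannon``, ``simpson_complement`` and ``berger_parker``.

    Returns the matches sorted by (total, vector); exact published rows
    can thereby be recovered from rounded values alone.
    """
    lo, hi = n_range
    if lo > hi or lo < 1:
        raise ValidationError(f"empty or invalid N range {n_range}")
    if richness_S < 1:
        raise UndefinedInputError("richness must be >= 1")
    funcs = {
        "shannon": shannon,
        "simpson_complement": simpson_complement,
        "berger_parker": berger_parker,
    }
    unknown = set(index_targets) - set(funcs)
    if unknown:
        raise ValueError(f"unknown index target(s) {sorted(unknown)}")

    def decimals_of(key: str, target: float) -> int:
        if rounding and key in rounding:
            return rounding[key]
        # infer from the printed representation of the target
        text = repr(float(target))
        return len(text.split(".")[1]) if "." in text else 0

    matches: list[tuple[int, ...]] = []
    for total in range(max(lo, richness_S), hi + 1):
        for vec in _partitions(total, richness_S, total):
            ok = True
            for key, target in index_targets.items():
                dec = decimals_of(key, target)
                got = round_value(funcs[key](vec), dec, mode=rounding_mode)
                if got != round_value(float(target), dec, mode=rounding_mode):
                    ok = False
                    break
            if ok:
                matches.append(vec)
    return sorted(set(matches), key=lambda v: (sum(v), v))


# -- ordination -----------------------------------------------------------


@dataclass(frozen=True)
class OrdinationResult:
    """PCA of the genus × tissue count matrix (genera as observations)."""

    genera: list[str]
    tissues: list[str]
    scores: np.ndarray          # genera × components
    loadings: np.ndarray        # tissues × components
    explained_variance_ratio: np.ndarray


class DegenerateInputError(ValueError):
    """The matrix has no variance to ordinate."""


def genus_tissue_matrix(table: CommunityTable) -> pd.DataFrame:
    """Colony-count matrix, genera in rows, the four tissues in columns."""
    df = table.to_frame()
    if df.empty:
        return pd.DataFrame(columns=list(TISSUES))
    mat = df.pivot_table(
        index="genus", columns="tissue", values="colony_count", aggfunc="sum", fill_value=0
    )
    return mat.reindex(columns=list(TISSUES), fill_value=0)


def pca_ordination(table: CommunityTable, n_components: int | None = None) -> OrdinationResult:
    """Principal components of the centered genus × tissue count matrix.

    Columns (tissues) are mean-centered but not scaled — all entries share
    colony-count units. Component signs are fixed deterministically: the
    largest-magnitude loading of each component is made positive.
    """
    mat = genus_tissue_matrix(table)
    if mat.shape[0] < 2:
        raise DegenerateInputError("need at least two genera for ordination")
    X = mat.to_numpy(dtype=float)
    if np.allclose(X, X.mean(axis=0)):
        raise DegenerateInputError("all-constant matrix has no variance")
    k = n_components or min(X.shape)
    k = min(k, min(X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # tissues × components
    # deterministic sign: dominant loading positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return OrdinationResult(
        genera=list(mat.index),
        tissues=list(mat.columns),
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
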