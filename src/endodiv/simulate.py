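"""Seeded generators for synthetic endophyte-survey and bioassay inputs.

Each generator is a pure function of its parameter record (which carries
the seed), uses its own ``numpy.random.Generator`` stream, and produces
output that passes the corresponding reader's validation, so every
pipeline stage can be exercised without external data.

The community generator emulates the structure of a culture-based survey:
per plant and tissue, a fixed number of surface-sterilised segments is
"plated", each colonized independently with a per-tissue probability;
colonized segments yield species drawn from a skewed species-abundance
distribution (geometric or log-series) or a uniform one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import (
    TISSUES,
    CommunityTable,
    IsolateRecord,
    SegmentTally,
    TaxonRecord,
    ValidationError,
)
from .bioassay import _four_pl

__all__ = [
    "CommunitySimParams",
    "DoseResponseSimParams",
    "simulate_community",
    "simulate_dose_response",
    "simulate_dpph",
]


@dataclass(frozen=True)
class CommunitySimParams:
    """Study design for a synthetic multi-plant, multi-tissue survey.

    ``abundance_model`` is one of ``"even"``, ``"geometric"`` (relative
    abundance of species i proportional to ratio^i) or ``"log_series"``
    (proportional to alpha^i / i). ``colonization_p`` is a single
    probability or a per-tissue mapping. Twelve segments per tissue is the
    package's survey-design default (it gives CF% a granularity of a few
    percent per plant, typical for small culture-based surveys).
    """

    n_plants: int = 4
    tissues: tuple[str, ...] = TISSUES
    species_pool: int = 10
    abundance_model: str = "geometric"
    model_param: float = 0.7
    segments_per_tissue: int = 12
    colonization_p: float | Mapping[str, float] = 0.4
    n_genera: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.species_pool < 1:
            raise ValidationError("species_pool must be >= 1")
        if self.n_plants < 1:
            raise ValidationError("n_plants must be >= 1")
        if self.segments_per_tissue < 1:
            raise ValidationError("segments_per_tissue must be >= 1")
        unknown = set(self.tissues) - set(TISSUES)
        if unknown:
            raise ValidationError(f"unknown tissue(s) {sorted(unknown)}")
        if self.abundance_model not in ("even", "geometric", "log_series"):
            raise ValidationError(f"unknown abundance model {self.abundance_model!r}")
        for t in self.tissues:
            p = self._p(t)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"colonization probability {p} outside [0, 1]")

    def _p(self, tissue: str) -> float:
        if isinstance(self.colonization_p, Mapping):
            return float(self.colonization_p.get(tissue, 0.0))
        return float(self.colonization_p)

    def species_probabilities(self) -> np.ndarray:
        i = np.arange(1, self.species_pool + 1, dtype=float)
        if self.abundance_model == "even":
            w = np.ones_like(i)
        elif self.abundance_model == "geometric":
            w = self.model_param ** i
        else:  # log_series
            w = self.model_param ** i / i
        return w / w.sum()


def simulate_community(params: CommunitySimParams) -> CommunityTable:
    """Draw a synthetic survey table (isolates + segment tallies)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    probs = params.species_probabilities()
    genera = [f"Genus{1 + (i % max(2, params.n_genera)):02d}" for i in range(params.species_pool)]
    taxa = [
        TaxonRecord(morphospecies_id=f"Species sp.{i + 1}", genus=genera[i])
        for i in range(params.species_pool)
    ]
    isolates: list[IsolateRecord] = []
    tallies: list[SegmentTally] = []
    for pi in range(params.n_plants):
        plant = f"Plant {pi + 1:02d}"
        location = "PAWD" if pi % 2 == 0 else "NCAH"
        for tissue in params.tissues:
            n_col = int(rng.binomial(params.segments_per_tissue, params._p(tissue)))
            tallies.append(
                SegmentTally(
                    plant=plant,
                    tissue=tissue,
                    segments_examined=params.segments_per_tissue,
                    segments_colonized=n_col,
                )
            )
            if n_col == 0:
                continue
            species_idx = rng.choice(params.species_pool, size=n_col, p=probs)
            counts = np.bincount(species_idx, minlength=params.species_pool)
            for i, n in enumerate(counts):
                if n > 0:
                    isolates.append(
                        IsolateRecord(
                            plant=plant,
                            location=location,
                            tissue=tissue,
                            taxon=taxa[i],
                            colony_count=int(n),
                        )
                    )
    return CommunityTable(
        isolates=isolates, tallies=tallies, provenance=f"simulated(seed={params.seed})"
    )


@dataclass(frozen=True)
class DoseResponseSimParams:
    """True 4PL parameters and noise level for a synthetic MTT experiment.

    The default concentration ladder spans the 1–500 µg/mL range typical
    of crude-extract cytotoxicity screens; multiplicative noise acts on
    viability, mimicking well-to-well proportional error.
    """

    true_lower: float = 0.0
    true_upper: float = 100.0
    true_hill: float = 1.0
    true_ic50: float = 41.75
    concentrations: tuple[float, ...] = (1.0, 5.0, 25.0, 50.0, 125.0, 250.0, 500.0)
    noise_sd_pct: float = 0.0
    replicates: int = 3
    untreated_absorbance: float = 0.8
    cell_line: str = "A549"
    seed: int = 0

    def validate(self) -> None:
        if self.true_ic50 <= 0:
            raise ValidationError("true_ic50 must be positive")
        if self.noise_sd_pct < 0:
            raise ValidationError("noise_sd_pct must be non-negative")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if any(c <= 0 for c in self.concentrations):
            raise ValidationError("concentrations must be positive")
        if self.untreated_absorbance <= 0:
            raise ValidationError("untreated_absorbance must be positive")


def simulate_dose_response(params: DoseResponseSimParams) -> pd.DataFrame:
    """Synthetic MTT records (long format, one row per well).

    Viability is the 4PL evaluated at each concentration times (1 + ε),
    ε ~ N(0, noise_sd_pct/100). Absorbances are back-computed against the
    fixed untreated absorbance so the viability transform round-trips
    exactly at zero noise. Columns match the MTT reader contract:
    cell_line, concentration_ug_ml, replicate, absorbance,
    untreated_absorbance.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    c = np.asarray(params.concentrations, dtype=float)
    true_v = _four_pl(c, params.true_lower, params.true_upper, params.true_hill, params.true_ic50)
    for rep in range(1, params.replicates + 1):
        eps = rng.normal(0.0, params.noise_sd_pct / 100.0, size=c.size)
        v = true_v * (1.0 + eps)
        for ci, vi in zip(c, v):
            rows.append(
                {
                    "cell_line": params.cell_line,
                    "concentration_ug_ml": float(ci),
                    "replicate": rep,
                    "absorbance": float(params.untreated_absorbance * vi / 100.0),
                    "untreated_absorbance": params.untreated_absorbance,
                }
            )
    return pd.DataFrame(rows)


def simulate_dpph(
    true_scavenging_pct: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    control_absorbance: float = 0.8,
    replicates: int = 1,
) -> pd.DataFrame:
    """Synthetic DPPH absorbance pairs hitting given scavenging targets.

    Sample absorbance is T = C·(1 − s/100) plus optional additive Gaussian
    absorbance noise; the noise-free transform returns the targets exactly.
    Columns: sample_id, replicate, absorbance, control_absorbance.
    """
    targets = np.asarray(list(true_scavenging_pct), dtype=float)
    if (targets > 100).any():
        raise ValidationError("scavenging targets cannot exceed 100%")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for i, s in enumerate(targets):
        for rep in range(1, replicates + 1):
            t = control_absorbance * (1.0 - s / 100.0)
            t_noisy = max(t + rng.normal(0.0, noise_sd), 0.0) if noise_sd else t
            rows.append(
                {
                    "sample_id": f"sample{i + 1:02d}",
                    "replicate": rep,
                    "absorbance": float(t_noisy),
                    "control_absorbance": control_absorbance,
                }
            )
    return pd.DataFrame(rows)
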