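"""Pipeline assembly: Table-3 style profiles, overlap/ordination exports.

``run_pipeline`` is deterministic for fixed inputs + config and always
emits a validation section: published index rows that violate the hard
mathematical bounds (H' ≤ ln S, 1 − D' ≤ 1 − 1/S, BP ≥ 1/S) are reported
as warnings, never silently dropped — inconsistent printed tables are a
real occurrence and worth surfacing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import diversity
from .community import CommunityTable, load_fixture, load_fixture_frame, read_community

logger = logging.getLogger("endodiv")


@dataclass
class RunConfig:
    isolates_path: str | None = None          # None -> packaged Table-1 fixture
    tallies_path: str | None = None
    reference_indices_path: str | None = None  # None -> packaged Table-3 fixture
    rounding: Mapping[str, int] = field(default_factory=dict)
    alpha: float = 0.05
    out_dir: str = "endodiv_report"
    seed: int = 0
    make_figures: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def validate_reference_indices(indices: pd.DataFrame, richness: Mapping[str, int]) -> list[str]:
    """Check published index rows against the hard diversity bounds."""
    warnings: list[str] = []
    for _, row in indices.iterrows():
        plant = row["plant"]
        S = richness.get(plant)
        if S is None or S < 1 or pd.isna(row.get("shannon")):
            continue
        if S >= 1 and row["shannon"] > math.log(S) + 5e-3:
            warnings.append(
                f"{plant}: printed Shannon {row['shannon']} exceeds ln(S)={math.log(S):.4f} for S={S}"
            )
        if S >= 1 and not pd.isna(row.get("simpson_complement")):
            if row["simpson_complement"] > 1 - 1 / S + 5e-3:
                warnings.append(
                    f"{plant}: printed Simpson complement {row['simpson_complement']} exceeds 1-1/S for S={S}"
                )
        if S >= 1 and not pd.isna(row.get("berger_parker")):
            if row["berger_parker"] < 1 / S - 5e-3:
                warnings.append(
                    f"{plant}: printed Berger-Parker {row['berger_parker']} is below 1/S for S={S}"
                )
        if not pd.isna(row.get("camargo")):
            implied = 1 / row["camargo"]
            if abs(implied - S) > 0.5 + 5e-2 * S:
                warnings.append(
                    f"{plant}: printed Camargo {row['camargo']} implies S~{implied:.1f} but table lists S={S}"
                )
    return warnings


def run_pipeline(config: RunConfig) -> dict:
    """Run the diversity pipeline and write CSV/JSON artifacts.

    Returns the report bundle as a dict (also written to report.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.isolates_path is None:
        table = load_fixture("table1_isolates")
    else:
        table = read_community(config.isolates_path, tallies_path=config.tallies_path)
    logger.info("loaded %d isolate records from %s", len(table.isolates), table.provenance)

    profiles = diversity.profile_table(table, rounding=config.rounding, printed=True)
    profiles_full = diversity.profile_table(table, rounding=config.rounding, printed=False)
    profiles.to_csv(out / "diversity_profiles.csv", index=False)
    profiles_full.to_csv(out / "diversity_profiles_full_precision.csv", index=False)

    overlaps = diversity.tissue_overlaps(table)
    overlap_payload = {
        "tissue_richness": {t: len(s) for t, s in overlaps.tissue_sets.items()},
        "union_richness": len(overlaps.union),
        "regions": {
            "+".join(sorted(k)): v for k, v in sorted(overlaps.regions.items(), key=lambda kv: sorted(kv[0]))
        },
    }

    ordination_payload = None
    try:
        ordination = diversity.pca_ordination(table)
        ordination_payload = {
            "genera": ordination.genera,
            "tissues": ordination.tissues,
            "explained_variance_ratio": [float(x) for x in ordination.explained_variance_ratio],
            "scores": [[float(v) for v in row] for row in ordination.scores],
            "loadings": [[float(v) for v in row] for row in ordination.loadings],
        }
    except diversity.DegenerateInputError as exc:
        logger.warning("ordination skipped: %s", exc)

    richness = {p: len(table.abundance_vector(p)) for p in table.plants}
    if config.reference_indices_path is None:
        reference = load_fixture_frame("table3_indices")
    else:
        reference = pd.read_csv(config.reference_indices_path)
    warnings = validate_reference_indices(reference, richness)
    for w in warnings:
        logger.warning("reference index check: %s", w)

    report = {
        "n_isolate_records": len(table.isolates),
        "n_plants": len(table.plants),
        "profiles": profiles.to_dict(orient="records"),
        "overlaps": overlap_payload,
        "ordination": ordination_payload,
        "validation_warnings": warnings,
        "seed": config.seed,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "overlaps.json").write_text(json.dumps(overlap_payload, indent=2))

    if config.make_figures and ordination_payload is not None:
        _write_figures(out, ordination_payload)
    return report


def _write_figures(out: Path, ordination_payload: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = ordination_payload["scores"]
    if len(ordination_payload["explained_variance_ratio"]) < 2:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [row[0] for row in scores]
    ys = [row[1] for row in scores]
    ax.scatter(xs, ys, s=18)
    for name, x, y in zip(ordination_payload["genera"], xs, ys):
        ax.annotate(name, (x, y), fontsize=6)
    evr = ordination_payload["explained_variance_ratio"]
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.set_title("Genus x tissue ordination")
    fig.tight_layout()
    fig.savefig(out / "ordination.png", dpi=150)
    plt.close(fig)
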