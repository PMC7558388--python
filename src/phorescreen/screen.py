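"""End-to-end virtual screening pipeline with selectivity labeling.

The pipeline runs, in order: molecular-weight filter → protonation
adjustment → conformer generation → per-model matching → selectivity
labeling.  A molecule matching the four-point consensus model is a
candidate non-selective bradykinin-receptor ligand; the five-point B1/B2
models refine the label when they also match.  Receptor-side checks
(docking, steric clashes) are out of scope and flagged for external
follow-up in the report instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .chemio import Molecule, molecular_weight, weight_filter
from .confgen import ConformerError, generate_conformers
from .featperc import assign_protonation
from .matcher import MatchResult, match_molecule
from .phmodel import BUILTIN_MODEL_NAMES, PharmacophoreModel, builtin_model

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "MoleculeRecord",
    "ScreenReport",
    "run_screen",
    "classify_selectivity",
    "LABELS",
]

LABELS = (
    "non_selective_candidate",
    "b1_biased",
    "b2_biased",
    "consensus_only",
    "no_match",
    "filtered_out",
    "conformer_failure",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Screen parameters; defaults mirror the drug-database screen setup."""

    mw_lo: float = 200.0
    mw_hi: float = 600.0
    n_conformers: int = 200
    seed: int = 0
    tolerance: float | None = None  # None -> each model's own tolerances
    models: tuple[str, ...] = BUILTIN_MODEL_NAMES
    out_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.mw_lo >= self.mw_hi:
            raise ValueError(f"mw_lo={self.mw_lo} must be < mw_hi={self.mw_hi}")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        unknown = set(self.models) - set(BUILTIN_MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        if "bk_consensus" not in self.models:
            raise ValueError("the screen requires the bk_consensus model")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "mw_lo": self.mw_lo,
                "mw_hi": self.mw_hi,
                "n_conformers": self.n_conformers,
                "seed": self.seed,
                "tolerance": self.tolerance,
                "models": list(self.models),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def classify_selectivity(
    consensus: MatchResult,
    b1: MatchResult | None = None,
    b2: MatchResult | None = None,
) -> str:
    """Selectivity label from the per-model match outcomes.

    Fulfilling the four common points alone already qualifies a molecule as
    a non-selective candidate; the receptor-specific P5 models refine the
    label toward B1 or B2 when exactly one of them also matches.
    """
    if not consensus.matched:
        return "no_match"
    m1 = bool(b1 and b1.matched)
    m2 = bool(b2 and b2.matched)
    if m1 and not m2:
        return "b1_biased"
    if m2 and not m1:
        return "b2_biased"
    if m1 and m2:
        return "non_selective_candidate"
    # consensus only: non-selective per the common-point logic
    return "consensus_only"


#: consensus_only is reported as a non-selective candidate in summaries.
NON_SELECTIVE_LABELS = ("non_selective_candidate", "consensus_only")


@dataclass
class MoleculeRecord:
    name: str
    mw: float
    passed_filter: bool
    n_conformers: int
    matches: dict[str, MatchResult]
    label: str
    error: str = ""


@dataclass
class ScreenReport:
    records: list[MoleculeRecord]
    config: ScreenConfig
    metadata: dict = field(default_factory=dict)

    def record(self, name: str) -> MoleculeRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def labels(self) -> dict[str, str]:
        return {r.name: r.label for r in self.records}

    def hits(self) -> list[MoleculeRecord]:
        return [r for r in self.records if r.label in NON_SELECTIVE_LABELS + ("b1_biased", "b2_biased")]

    # -- tabular / file output ---------------------------------------------
    _COLUMNS = (
        "name",
        "mw",
        "passed_filter",
        "n_conformers",
        "label",
        "flag_for_docking",
        "consensus_matched",
        "consensus_max_dev",
        "consensus_best_conformer",
        "b1_matched",
        "b2_matched",
        "error",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            cons = r.matches.get("bk_consensus")
            rows.append(
                {
                    "name": r.name,
                    "mw": round(r.mw, 2),
                    "passed_filter": r.passed_filter,
                    "n_conformers": r.n_conformers,
                    "label": r.label,
                    "flag_for_docking": r.label in NON_SELECTIVE_LABELS + ("b1_biased", "b2_biased"),
                    "consensus_matched": bool(cons and cons.matched),
                    "consensus_max_dev": round(cons.max_deviation, 3) if cons and cons.matched else "",
                    "consensus_best_conformer": cons.best_conformer if cons and cons.matched else "",
                    "b1_matched": bool(r.matches.get("bk_b1") and r.matches["bk_b1"].matched),
                    "b2_matched": bool(r.matches.get("bk_b2") and r.matches["bk_b2"].matched),
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows, columns=list(self._COLUMNS))

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write the report CSV and a structured-text run summary."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        self.to_frame().to_csv(csv_path, index=False)
        summary_path = prefix.with_suffix(".summary.json")
        counts = {label: 0 for label in LABELS}
        for r in self.records:
            counts[r.label] += 1
        summary = {"metadata": self.metadata, "label_counts": counts}
        summary_path.write_text(json.dumps(summary, indent=2) + "\n")
        return csv_path, summary_path


def run_screen(library: list[Molecule], config: ScreenConfig) -> ScreenReport:
    """Screen a molecule library against the configured pharmacophore models."""
    models: dict[str, PharmacophoreModel] = {m: builtin_model(m) for m in config.models}
    retained, excluded = weight_filter(library, config.mw_lo, config.mw_hi)
    excluded_names = {m.name for m in excluded}

    records: list[MoleculeRecord] = []
    for mol in library:
        mw = molecular_weight(mol)
        if mol.name in excluded_names:
            logger.info("filtered out %s (MW %.1f)", mol.name, mw)
            records.append(
                MoleculeRecord(mol.name, mw, False, 0, {}, "filtered_out")
            )
            continue
        protonated = assign_protonation(mol)
        try:
            ensemble = generate_conformers(
                protonated, config.n_conformers, config.seed
            )
        except ConformerError as exc:
            logger.warning("conformer generation failed for %s: %s", mol.name, exc)
            records.append(
                MoleculeRecord(mol.name, mw, True, 0, {}, "conformer_failure", str(exc))
            )
            continue
        matches = {
            name: match_molecule(ensemble, model, tolerance=config.tolerance)
            for name, model in models.items()
        }
        label = classify_selectivity(
            matches["bk_consensus"], matches.get("bk_b1"), matches.get("bk_b2")
        )
        logger.info("%s: %s", mol.name, label)
        records.append(
            MoleculeRecord(mol.name, mw, True, len(ensemble), matches, label)
        )

    report = ScreenReport(
        records=records,
        config=config,
        metadata={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_molecules": len(library),
            "models": list(config.models),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    if config.out_prefix:
        report.write(config.out_prefix)
    return report
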