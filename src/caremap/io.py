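"""Readers/writers for assessment CSV, recommendation JSON/CSV, and run configs.

The assessment CSV is one row per subject: ``subject_id``, the 28 individual
indicator columns, the 8 family indicator columns (both in registry order),
and optionally the demographic columns ``age, gender, living_arrangement,
health_status``. All validation failures are reported with row context.
Output files are written atomically (temp file + rename) so a failing run
never leaves a partial artifact.
"""
from __future__ import annotations

import csv
import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .community import HighRiskPolicy, assemble_community_matrix, community_profile, flag_high_risk
from .errors import CaremapError, ConfigError, PortraitError
from .portraits import DEMOGRAPHIC_FIELDS, DualPortrait, validate_portrait
from .recommend import (
    RecommendationList,
    SimilarityConfig,
    StratificationThresholds,
    recommend,
    stage1_candidates,
)
from .registry import IndicatorRegistry, load_registry
from .rules import MappingMatrix, load_mapping_matrix


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_assessments(
    path: str | Path,
    individual_registry: Optional[IndicatorRegistry] = None,
    family_registry: Optional[IndicatorRegistry] = None,
) -> list[DualPortrait]:
    """Read and validate an assessment CSV into dual portraits, order preserved."""
    ind_reg = individual_registry or load_registry("individual_v1")
    fam_reg = family_registry or load_registry("family_v1")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PortraitError(f"{path}: empty file, expected a header row")
        header = set(reader.fieldnames)
        required = ["subject_id", *ind_reg.ids, *fam_reg.ids]
        missing = [c for c in required if c not in header]
        if missing:
            raise PortraitError(f"{path}: missing required columns {missing}")
        duals = []
        for n, row in enumerate(reader, start=2):  # header is line 1
            try:
                sid = (row.get("subject_id") or "").strip()
                if not sid:
                    raise PortraitError("empty subject_id")
                individual = validate_portrait(ind_reg, sid, [row[c] for c in ind_reg.ids])
                family = validate_portrait(fam_reg, sid, [row[c] for c in fam_reg.ids])
                demographics = {
                    k: row[k] for k in DEMOGRAPHIC_FIELDS if k in header and (row[k] or "") != ""
                }
                duals.append(
                    DualPortrait(individual, family, demographics=demographics or None)
                )
            except CaremapError as exc:
                raise PortraitError(f"{path}: row {n}: {exc}") from None
    return duals


def write_assessments(
    path: str | Path,
    duals: Sequence[DualPortrait],
    individual_registry: Optional[IndicatorRegistry] = None,
    family_registry: Optional[IndicatorRegistry] = None,
) -> None:
    """Write dual portraits as an assessment CSV (inverse of read_assessments)."""
    ind_reg = individual_registry or load_registry("individual_v1")
    fam_reg = family_registry or load_registry("family_v1")
    demo_cols = [
        k
        for k in DEMOGRAPHIC_FIELDS
        if any(d.demographics and k in d.demographics for d in duals)
    ]
    buf_rows = []
    for d in duals:
        row = [d.subject_id, *d.individual.scores, *d.family.scores]
        row += [(d.demographics or {}).get(k, "") for k in demo_cols]
        buf_rows.append(row)
    out = []
    header = ["subject_id", *ind_reg.ids, *fam_reg.ids, *demo_cols]
    import io as _io

    sink = _io.StringIO()
    writer = csv.writer(sink)
    writer.writerow(header)
    writer.writerows(buf_rows)
    _atomic_write_text(path, sink.getvalue())


def recommendations_to_json(reclist: RecommendationList) -> str:
    return json.dumps(reclist.to_dict(), indent=2, ensure_ascii=False) + "\n"


def recommendations_to_csv(reclist: RecommendationList) -> str:
    """Flat CSV export: one row per recommendation, triggers ';'-joined."""
    import io as _io

    sink = _io.StringIO()
    writer = csv.writer(sink)
    writer.writerow(
        [
            "subject_id", "rank", "label", "category", "intensity_grade",
            "priority_level", "severity", "family_deficit", "support", "total",
            "triggers",
        ]
    )
    for rank, rec in enumerate(reclist.recommendations, start=1):
        writer.writerow(
            [
                reclist.subject_id, rank, rec.item.label, rec.item.category,
                rec.intensity_grade, rec.priority_level,
                f"{rec.score.severity_component:.6f}",
                f"{rec.score.family_deficit_component:.6f}",
                f"{rec.score.support_component:.6f}",
                f"{rec.score.total:.6f}",
                ";".join(f"{k}:{i}:{s}" for k, i, s in rec.triggers),
            ]
        )
    return sink.getvalue()


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML/JSON."""

    registry_individual: str = "individual_v1"
    registry_family: str = "family_v1"
    rules_individual: str = "individual_demo"
    rules_family: str = "family_v1"
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    thresholds: StratificationThresholds = field(default_factory=StratificationThresholds)
    high_risk: HighRiskPolicy = field(default_factory=HighRiskPolicy)
    output_format: str = "json"

    def __post_init__(self) -> None:
        if self.output_format not in ("json", "csv"):
            raise ConfigError(f"unknown output format {self.output_format!r}")

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["similarity"]["weights"] = list(doc["similarity"]["weights"])
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        sim = doc.pop("similarity", {})
        if isinstance(sim, dict) and "weights" in sim:
            sim["weights"] = tuple(sim["weights"])
        thr = doc.pop("thresholds", {})
        risk = doc.pop("high_risk", {})
        known = {f.name for f in dataclasses.fields(cls)} - {
            "similarity", "thresholds", "high_risk"
        }
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            similarity=SimilarityConfig(**sim) if isinstance(sim, dict) else sim,
            thresholds=StratificationThresholds(**thr) if isinstance(thr, dict) else thr,
            high_risk=HighRiskPolicy(**risk) if isinstance(risk, dict) else risk,
            **doc,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_dict(yaml.safe_load(text))

    def load_matrices(self) -> tuple[MappingMatrix, MappingMatrix]:
        ind_reg = load_registry(self.registry_individual)
        fam_reg = load_registry(self.registry_family)
        return (
            load_mapping_matrix(self.rules_individual, ind_reg),
            load_mapping_matrix(self.rules_family, fam_reg),
        )


def run_recommend(
    assessments_path: str | Path,
    subject_id: str,
    config: Optional[RunConfig] = None,
    out_path: Optional[str | Path] = None,
) -> RecommendationList:
    """Recommend for one subject of an assessment file; optionally write it.

    The remaining subjects in the file form the collaborative-filtering
    population. Raises :class:`CaremapError` if the subject is absent.
    """
    config = config or RunConfig()
    ind_reg = load_registry(config.registry_individual)
    fam_reg = load_registry(config.registry_family)
    duals = read_assessments(assessments_path, ind_reg, fam_reg)
    by_id = {d.subject_id: d for d in duals}
    if subject_id not in by_id:
        raise CaremapError(
            f"subject {subject_id!r} not found in {assessments_path} "
            f"({len(duals)} subjects)"
        )
    ind_matrix, fam_matrix = config.load_matrices()
    target = by_id[subject_id]
    population = [d for d in duals if d.subject_id != subject_id]
    reclist = recommend(
        target, population, ind_matrix, fam_matrix, config.similarity, config.thresholds
    )
    if out_path is not None:
        if config.output_format == "csv":
            _atomic_write_text(out_path, recommendations_to_csv(reclist))
        else:
            _atomic_write_text(out_path, recommendations_to_json(reclist))
    return reclist


def run_summary(
    assessments_path: str | Path,
    config: Optional[RunConfig] = None,
    out_path: Optional[str | Path] = None,
) -> dict:
    """Community planning view over an assessment file.

    Produces per-indicator score distributions for both portrait kinds, the
    high-risk subject list under the configured policy (individual portraits),
    and aggregate stage-1 service demand counts by category.
    """
    config = config or RunConfig()
    ind_reg = load_registry(config.registry_individual)
    fam_reg = load_registry(config.registry_family)
    duals = read_assessments(assessments_path, ind_reg, fam_reg)
    if not duals:
        raise CaremapError(f"{assessments_path}: no subjects to summarize")
    ind_matrix_c = assemble_community_matrix([d.individual for d in duals])
    fam_matrix_c = assemble_community_matrix([d.family for d in duals])
    ind_matrix, fam_matrix = config.load_matrices()

    demand: dict[str, int] = {}
    for d in duals:
        for cand in stage1_candidates(d, ind_matrix, fam_matrix):
            demand[cand.item.category] = demand.get(cand.item.category, 0) + 1

    summary = {
        "n_subjects": len(duals),
        "individual_profile": community_profile(ind_matrix_c, ind_reg)
        .reset_index()
        .to_dict(orient="records"),
        "family_profile": community_profile(fam_matrix_c, fam_reg)
        .reset_index()
        .to_dict(orient="records"),
        "high_risk_policy": dataclasses.asdict(config.high_risk),
        "high_risk_subjects": flag_high_risk(ind_matrix_c, config.high_risk),
        "service_demand_by_category": dict(sorted(demand.items())),
    }
    if out_path is not None:
        _atomic_write_text(out_path, json.dumps(summary, indent=2, ensure_ascii=False) + "\n")
    return summary
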