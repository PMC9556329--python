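"""Delimited-text formats, panel files, and run configuration.

All tables are UTF-8, comma-delimited, one header line, empty field =
missing value.  Abundance files carry the timepoint in a single leading
comment line (``# timepoint: pre``).  Panel definitions are YAML listing
tubes (id + ordered marker list) and exclusion rules (lists of signed
markers).  These dialects exist because the source data for this kind of
analysis are access-restricted; the simulator writes them and every reader
validates them strictly, reporting offending line numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import AbundanceMatrix
from .panel import PanelDefinition, Tube, parse_feature_id
from .selection import FeatureSelectionResult, SelectionConfig
from .model import ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_abundance", "write_abundance",
    "read_cohort", "write_cohort",
    "read_panel", "write_panel",
    "read_variants", "write_variants",
    "write_selection_result", "read_selection_result",
    "SplitSpec", "RunConfig",
]


# ------------------------------------------------------------- abundance

def write_abundance(matrix: AbundanceMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# timepoint: {matrix.timepoint}\n")
        matrix.data.to_csv(fh, index_label="sample_id", lineterminator="\n")


def read_abundance(path, panel: PanelDefinition | None = None,
                   strict_exclusions: bool = False) -> AbundanceMatrix:
    """Read an abundance table, validating values and (optionally) the panel.

    With a panel supplied, feature columns are checked against tube
    membership, and combinations matching an impossible-combination rule
    are flagged with a warning (raw cytometry exports do contain such
    artifact columns; the feature-filtering stage removes them).  Pass
    ``strict_exclusions=True`` to reject them outright.
    """
    path = Path(path)
    timepoint = "pre"
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        offset = 0
        if first.startswith("#"):
            timepoint = first.split(":", 1)[1].strip()
            offset = 1
        else:
            fh.seek(0)
        df = pd.read_csv(fh, index_col="sample_id", dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        combo = parse_feature_id(col)
        if panel is not None:
            tube = panel.tube(combo.tube)
            if tuple(m for m, _ in combo.signs) != tube.markers:
                raise ValueError(
                    f"{path}: column {col!r} does not match tube "
                    f"{combo.tube} marker order"
                )
            if panel.is_excluded(combo):
                msg = (f"{path}: column {col!r} matches an "
                       "impossible-combination exclusion rule")
                if strict_exclusions:
                    raise ValueError(msg)
                logger.warning(msg)
        try:
            values[col] = df[col].astype(float)
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric abundance in column {col!r}: {err}")
    arr = values.to_numpy()
    bad = np.argwhere(arr < 0)
    if bad.size:
        i, j = bad[0]
        # +2 for header, +offset for the comment line, +1 for 1-based lines
        raise ValueError(
            f"{path}: negative abundance at line {i + 2 + offset} "
            f"(sample {values.index[i]!r}, column {values.columns[j]!r})"
        )
    return AbundanceMatrix(data=values, timepoint=timepoint)


# ---------------------------------------------------------------- cohort

_COHORT_COLS = [
    "patient_id", "stage", "histology", "tps_group", "egfr_alk_positive",
    "surgery", "resection", "viable_percent", "dfs_time", "dfs_event",
    "os_time", "os_event",
]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[_COHORT_COLS].to_csv(Path(path), index=False, lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(_COHORT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient ids")
    no_surgery = df["surgery"] == 0
    if df.loc[no_surgery, "viable_percent"].notna().any():
        raise ValueError(f"{path}: viable_percent present without surgery")
    return df.set_index("patient_id", drop=False)


# ----------------------------------------------------------------- panel

def write_panel(panel: PanelDefinition, path) -> None:
    doc = {
        "tubes": [
            {"id": t.tube_id, "markers": list(t.markers)} for t in panel.tubes
        ],
        "exclusion_rules": [sorted(rule) for rule in panel.exclusion_rules],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_panel(path) -> PanelDefinition:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    tubes = tuple(
        Tube(tube_id=t["id"], markers=tuple(t["markers"])) for t in doc["tubes"]
    )
    rules = tuple(frozenset(r) for r in doc.get("exclusion_rules", []))
    return PanelDefinition(tubes=tubes, exclusion_rules=rules)


# -------------------------------------------------------------- variants

def write_variants(variants: pd.DataFrame, path) -> None:
    cols = ["patient_id", "protein_affecting_mutations", "other_mutations",
            "covered_coding_bases"]
    variants[cols].to_csv(Path(path), index=False, lineterminator="\n")


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    needed = {"patient_id", "protein_affecting_mutations", "covered_coding_bases"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant table missing columns {sorted(missing)}")
    return df.set_index("patient_id", drop=False)


# ------------------------------------------------------------- selection

def write_selection_result(result: FeatureSelectionResult, path) -> None:
    path = Path(path)
    cfg = dataclasses.asdict(result.config)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# " + json.dumps({"config": cfg,
                                    "stage_counts": result.stage_counts},
                                   sort_keys=True) + "\n")
        result.table.to_csv(fh, index=False, lineterminator="\n")


def read_selection_result(path) -> FeatureSelectionResult:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        meta = json.loads(header.lstrip("# "))
        table = pd.read_csv(fh)
    return FeatureSelectionResult(
        table=table, stage_counts=meta["stage_counts"],
        config=SelectionConfig(**meta["config"]),
    )


# --------------------------------------------------------- configuration

@dataclass
class SplitSpec:
    """Training / test-1 / test-2 sample assignment.

    Test set 2 holds samples without an MPR assessment (no resection /
    radiographic progression); the three sets must be pairwise disjoint.
    """

    training: list[str]
    test1: list[str]
    test2: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = [set(self.training), set(self.test1), set(self.test2)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"split sets overlap: {sorted(overlap)[:5]}"
                    )


@dataclass
class RunConfig:
    """Everything one pipeline run needs, derived from one global seed."""

    seed: int = 0
    out_dir: str = "run"
    # simulation (used when no input paths are given)
    n_patients: int = 181
    panel_markers: int | None = 5     # truncate default panel tubes for speed
    n_populations: int = 40
    effects: dict = field(default_factory=dict)        # feature_id -> d
    post_effects: dict = field(default_factory=dict)
    # or load from files
    cohort_path: str | None = None
    abundance_pre_path: str | None = None
    abundance_post_path: str | None = None
    variants_path: str | None = None
    panel_path: str | None = None
    # stage options
    detection_min_fraction: float = 0.50
    prevalence_threshold: float = 0.85
    training_fraction: float = 57 / 111
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ci_method: str = "clopper_pearson"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sel = SelectionConfig(**doc.pop("selection", {}))
        mdl = ModelConfig(**doc.pop("model", {}))
        return cls(selection=sel, model=mdl, **doc)

    def to_dict(self) -> dict:
        """Config echo for manifests; omits out_dir (the manifest's home)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d
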