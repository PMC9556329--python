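"""Marker-combination feature construction and filtering.

The immunome of a sample is the vector of percent abundances over all
observed marker combinations across the tubes of the panel.  This module
takes an abundance matrix (samples x combination features) and applies, in
the order the analysis pipeline uses them:

1. restriction to *observed* phenotypes (detected in at least one sample),
2. removal of biologically impossible combinations via the panel's
   exclusion rules,
3. a detection filter (drop combinations detected in less than a given
   fraction of samples; the pipeline default is 50%),
4. a prevalence split: features present in at least 85% of training
   samples are *prevalent*, all others *non-prevalent* — the two strata
   are filtered and capped separately downstream.

All filters use inclusive (>=) boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelDefinition, parse_feature_id

__all__ = [
    "AbundanceMatrix",
    "PrevalenceSplit",
    "observed_phenotypes",
    "apply_exclusion_rules",
    "filter_by_detection",
    "split_by_prevalence",
]

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Samples x marker-combination percent abundances.

    ``data`` is a DataFrame indexed by sample id with feature-id columns of
    the form ``TUBE:Marker1+Marker2-...``; values are percent abundances in
    [0, 100].  A feature is *detected* in a sample when its value is
    strictly positive.  ``timepoint`` labels the draw ('pre' or 'post').
    """

    data: pd.DataFrame
    timepoint: str = "pre"

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes[:5]}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("negative abundance values")
        # every column must parse as a combination id
        for col in self.data.columns:
            parse_feature_id(col)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    def detected(self) -> pd.DataFrame:
        """Boolean detection indicator matrix (value > 0)."""
        return self.data > 0

    def detection_fraction(self) -> pd.Series:
        """Per-feature fraction of samples in which the feature is detected."""
        return self.detected().mean(axis=0)

    def restrict(self, feature_ids) -> "AbundanceMatrix":
        """A new matrix keeping only *feature_ids*, in current column order."""
        keep = [c for c in self.data.columns if c in set(feature_ids)]
        return AbundanceMatrix(data=self.data[keep].copy(), timepoint=self.timepoint)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(
            data=self.data.loc[list(sample_ids)].copy(), timepoint=self.timepoint
        )

    def tube_closure(self, tube_id: str) -> pd.Series:
        """Per-sample abundance sum over this tube's columns.

        On simulated data, before any zero-inflation mask, the exhaustive
        +/- partition of a tube sums to 100 for every sample.
        """
        cols = [c for c in self.data.columns if c.startswith(tube_id + ":")]
        return self.data[cols].sum(axis=1)


@dataclass
class PrevalenceSplit:
    """Partition of a feature set into prevalent / non-prevalent strata."""

    prevalent: list[str]
    non_prevalent: list[str]
    threshold: float
    prevalence: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        overlap = set(self.prevalent) & set(self.non_prevalent)
        if overlap:
            raise ValueError(f"strata overlap: {sorted(overlap)[:5]}")


def observed_phenotypes(matrix: AbundanceMatrix) -> list[str]:
    """Feature ids detected (value > 0) in at least one sample."""
    if matrix.n_samples == 0:
        raise ValueError("empty abundance matrix")
    det = matrix.detected().any(axis=0)
    return [c for c in matrix.feature_ids if det[c]]


def apply_exclusion_rules(feature_ids, panel: PanelDefinition) -> list[str]:
    """Drop combinations matching any impossible-combination rule.

    A rule (a set of signed markers, e.g. {CD3+, CD19+}) removes every
    combination whose signature contains all of the rule's signed markers.
    Rules referencing markers absent from a combination's tube are ignored
    for that tube (and logged once).  The result is independent of rule
    order.
    """
    kept = []
    skipped_rules: set[tuple[str, frozenset]] = set()
    for fid in feature_ids:
        combo = parse_feature_id(fid)
        tube_markers = set(panel.tube(combo.tube).markers)
        excluded = False
        for rule in panel.exclusion_rules:
            rule_markers = {s[:-1] for s in rule}
            if not rule_markers <= tube_markers:
                key = (combo.tube, rule)
                if key not in skipped_rules:
                    skipped_rules.add(key)
                    logger.info(
                        "exclusion rule %s not applicable in tube %s "
                        "(markers absent); ignored there",
                        sorted(rule), combo.tube,
                    )
                continue
            if combo.matches_rule(rule):
                excluded = True
                break
        if not excluded:
            kept.append(fid)
    logger.info(
        "exclusion rules removed %d of %d features", len(list(feature_ids)) - len(kept),
        len(list(feature_ids)),
    )
    return kept


def filter_by_detection(matrix: AbundanceMatrix, min_fraction: float) -> AbundanceMatrix:
    """Keep features detected in at least ``min_fraction`` of samples."""
    if not 0 <= min_fraction <= 1:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    frac = matrix.detection_fraction()
    keep = [c for c in matrix.feature_ids if frac[c] >= min_fraction]
    logger.info(
        "detection filter (>= %.0f%%): %d -> %d features",
        100 * min_fraction, len(matrix.feature_ids), len(keep),
    )
    return AbundanceMatrix(data=matrix.data[keep].copy(), timepoint=matrix.timepoint)


def split_by_prevalence(matrix: AbundanceMatrix, threshold: float = 0.85) -> PrevalenceSplit:
    """Partition features into prevalent (detection >= threshold) and the rest."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    frac = matrix.detection_fraction()
    prevalent = [c for c in matrix.feature_ids if frac[c] >= threshold]
    non_prevalent = [c for c in matrix.feature_ids if frac[c] < threshold]
    logger.info(
        "prevalence split at %.0f%%: %d prevalent, %d non-prevalent",
        100 * threshold, len(prevalent), len(non_prevalent),
    )
    return PrevalenceSplit(
        prevalent=prevalent, non_prevalent=non_prevalent,
        threshold=threshold, prevalence=frac,
    )
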