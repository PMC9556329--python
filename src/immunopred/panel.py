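"""Multi-tube flow-cytometry panel definitions and marker-combination identities.

A panel is an ordered collection of tubes; each tube carries an ordered list
of surface markers (at most ten per tube on the clinical instrument this
emulates).  A *marker combination* is a full +/- sign assignment over one
tube's markers and identifies one cell phenotype, e.g. ``CD3+CD19-CD4+``.
Combinations are always tube-scoped: the same signature observed in two
tubes is two distinct features, because the surrounding marker context
differs.

Exclusion rules declare sign patterns that are biologically impossible
(the canonical example being a cell staining both CD3+ and CD19+, i.e. a
T-cell and a B-cell lineage marker simultaneously); any combination whose
signature contains *all* signed markers of a rule is dropped from the
feature universe.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "MarkerCombination",
    "Tube",
    "PanelDefinition",
    "parse_feature_id",
    "default_panel",
    "MAX_MARKERS_PER_TUBE",
]

MAX_MARKERS_PER_TUBE = 10

_SIGNED = re.compile(r"([A-Za-z0-9_.]+)([+-])")
_MARKER_NAME = re.compile(r"^[A-Za-z0-9_.]+$")


@dataclass(frozen=True)
class MarkerCombination:
    """One phenotype: a tube id plus a +/- sign for every marker in the tube."""

    tube: str
    signs: tuple[tuple[str, str], ...]  # ((marker, '+'|'-'), ...) in tube order

    @property
    def feature_id(self) -> str:
        return f"{self.tube}:" + "".join(m + s for m, s in self.signs)

    def matches_rule(self, rule: frozenset[str]) -> bool:
        """True if this signature contains every signed marker of *rule*."""
        have = {m + s for m, s in self.signs}
        return rule <= have

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.feature_id


def parse_feature_id(feature_id: str) -> MarkerCombination:
    """Parse ``TUBE:Marker1+Marker2-...`` into a :class:`MarkerCombination`."""
    tube, sep, sig = feature_id.partition(":")
    if not sep or not tube or not sig:
        raise ValueError(f"malformed feature id {feature_id!r}")
    signs = tuple((m, s) for m, s in _SIGNED.findall(sig))
    reconstructed = "".join(m + s for m, s in signs)
    if reconstructed != sig:
        raise ValueError(f"malformed signature in feature id {feature_id!r}")
    return MarkerCombination(tube=tube, signs=signs)


@dataclass(frozen=True)
class Tube:
    tube_id: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError(f"tube {self.tube_id}: empty marker list")
        if len(self.markers) > MAX_MARKERS_PER_TUBE:
            raise ValueError(
                f"tube {self.tube_id}: {len(self.markers)} markers exceeds "
                f"the {MAX_MARKERS_PER_TUBE}-marker limit"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"tube {self.tube_id}: duplicate marker names")
        for m in self.markers:
            # '+'/'-' are the signature sign characters, so marker names
            # must not contain them (write HLA-DR as HLADR)
            if not _MARKER_NAME.match(m):
                raise ValueError(
                    f"tube {self.tube_id}: invalid marker name {m!r} "
                    "(letters, digits, '_', '.' only)"
                )

    def all_combinations(self):
        """Every +/- assignment over this tube's markers (2^k signatures)."""
        for signs in itertools.product("+-", repeat=len(self.markers)):
            yield MarkerCombination(
                tube=self.tube_id, signs=tuple(zip(self.markers, signs))
            )

    def combination(self, signature: dict[str, str]) -> MarkerCombination:
        missing = set(self.markers) - set(signature)
        if missing:
            raise ValueError(f"signature missing markers {sorted(missing)}")
        return MarkerCombination(
            tube=self.tube_id, signs=tuple((m, signature[m]) for m in self.markers)
        )


@dataclass
class PanelDefinition:
    """Tubes plus exclusion rules, the combination-feature universe."""

    tubes: tuple[Tube, ...]
    exclusion_rules: tuple[frozenset[str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [t.tube_id for t in self.tubes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tube ids in panel")
        all_markers = {m for t in self.tubes for m in t.markers}
        for rule in self.exclusion_rules:
            for signed in rule:
                marker = signed[:-1]
                if signed[-1] not in "+-":
                    raise ValueError(f"exclusion rule entry {signed!r} lacks a sign")
                if marker not in all_markers:
                    raise ValueError(
                        f"exclusion rule references marker {marker!r} "
                        "absent from every tube"
                    )

    def tube(self, tube_id: str) -> Tube:
        for t in self.tubes:
            if t.tube_id == tube_id:
                return t
        raise KeyError(f"no tube {tube_id!r} in panel")

    @property
    def n_universe(self) -> int:
        """Size of the full combination universe: sum of 2^k over tubes."""
        return sum(2 ** len(t.markers) for t in self.tubes)

    def is_excluded(self, combo: MarkerCombination) -> bool:
        tube_markers = set(self.tube(combo.tube).markers)
        for rule in self.exclusion_rules:
            # A rule only binds in tubes that carry all of its markers.
            if {s[:-1] for s in rule} <= tube_markers and combo.matches_rule(rule):
                return True
        return False


# Illustrative marker names for the default 14-tube x 10-marker panel.  The
# first tube carries the classic lineage markers so that the default
# CD3+/CD19+ impossible-combination rule binds somewhere; remaining names
# are drawn from common NK / T / myeloid immunophenotyping reagents.
_DEFAULT_TUBES = [
    ("T01", ["CD45", "CD3", "CD19", "CD4", "CD8", "CD56", "CD16", "CD14", "HLADR", "CD25"]),
    ("T02", ["CD45", "CD3", "CD56", "NKG2D", "NKG2A", "CD94", "CD127", "CD161", "ILT2", "CD57"]),
    ("T03", ["CD45", "CD3", "CD56", "KIR2DL1", "KIR2DL2", "KIR3DL1", "NKp46", "NKp30", "CD69", "CD38"]),
    ("T04", ["CD45", "CD3", "TCRgd", "TCRab", "CD4", "CD8", "CD27", "CD28", "CD45RA", "CCR7"]),
    ("T05", ["CD45", "CD14", "CD16", "CD11b", "CD11c", "CD33", "CD66b", "HLADR", "CD15", "CD13"]),
    ("T06", ["CD45", "CD3", "CD4", "CD25", "CD127", "FoxP3s", "CTLA4", "PD1", "ICOS", "CD39"]),
    ("T07", ["CD45", "CD8", "CD3", "PD1", "TIM3", "LAG3", "TIGIT", "CD160", "2B4", "CD244"]),
    ("T08", ["CD45", "CD19", "CD20", "CD27", "CD38", "IgD", "IgM", "CD24", "CD21", "CD10"]),
    ("T09", ["CD45", "CD56", "CD16", "CD57", "CD62L", "CX3CR1", "CD27h", "Perforin", "GranzymeB", "Ki67"]),
    ("T10", ["CD45", "CD3", "Va24", "Vb11", "CD1d", "CD161", "CD56", "CD4", "CD8", "DNneg"]),
    ("T11", ["CD45", "CD34", "CD38", "CD90", "CD45RA", "CD10", "CD7", "CD123", "CD33", "Lin"]),
    ("T12", ["CD45", "CD123", "CD11c", "HLADR", "CD1c", "CD141", "CD303", "CD304", "CD86", "CD83"]),
    ("T13", ["CD45", "CD3", "CD56", "ILT2", "NKG2C", "NKG2A", "KIR2DL1", "CD8", "CD57", "FcRg"]),
    ("T14", ["CD45", "CD15", "CD16", "CD62L", "CD11b", "CD10", "CD64", "CD32", "CXCR4", "CXCR2"]),
]


def default_panel(n_markers: int | None = None) -> PanelDefinition:
    """The shipped 14-tube, 10-marker panel with the CD3+/CD19+ exclusion rule.

    Parameters
    ----------
    n_markers
        Optionally truncate every tube to its first *n_markers* markers.
        Useful for small, fast feature universes in simulations and tests
        (``2^k`` signatures per tube grows quickly).
    """
    tubes = []
    for tid, markers in _DEFAULT_TUBES:
        use = markers if n_markers is None else markers[:n_markers]
        tubes.append(Tube(tube_id=tid, markers=tuple(use)))
    rules = (frozenset({"CD3+", "CD19+"}),)
    return PanelDefinition(tubes=tuple(tubes), exclusion_rules=rules)
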