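"""Domain model for a two-cartridge methylation-specific qPCR assay.

The assay measures DNA methylation of a fixed 9-gene panel in circulating
cell-free DNA.  Each blood sample is bisulfite converted and split across two
PCR detection cartridges; every cartridge carries 4-5 target genes plus the
ACTB reference used for input normalization.  This module holds the shared
domain types (panel, cartridge layout, Ct measurements, sample runs, algorithm
constants) and structural validation used by every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

#: Cycle-threshold sentinel assigned when no amplification signal is detected.
NO_SIGNAL_CT = 45.0

GROUP_LABELS = ("cancer", "benign", "normal", "unknown")
MATRICES = ("plasma", "serum")


class CtmethError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(CtmethError):
    """Input refers to genes/columns/labels outside the configured schema."""


class StructuralError(CtmethError):
    """Input is structurally incomplete or inconsistent (missing/duplicate cells)."""


class ConfigurationError(CtmethError):
    """Panel/layout/calibration configuration is invalid or incomplete."""


class CalibrationError(CtmethError):
    """Calibration cannot be built from the supplied replicates."""


class InvalidRunError(CtmethError):
    """A sample run cannot be scored (e.g. reference gene gave no signal)."""


class InputError(CtmethError):
    """Statistical operation received unusable input (empty group, mismatched lengths)."""


def canonical_gene(name: str) -> str:
    """Canonical gene spelling: surrounding whitespace stripped, upper-cased."""
    return str(name).strip().upper()


@dataclass(frozen=True)
class GenePanel:
    """The methylation marker panel: 9 target genes plus one reference gene."""

    targets: tuple[str, ...] = (
        "HOXB4",
        "RASGRF2",
        "AKR1B1",
        "TM6SF1",
        "COL6A2",
        "HIST1H3C",
        "TMEFF2",
        "RASSF1",
        "ZNF671",
    )
    reference: str = "ACTB"

    def __post_init__(self) -> None:
        targets = tuple(canonical_gene(g) for g in self.targets)
        reference = canonical_gene(self.reference)
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "reference", reference)
        if len(targets) != 9:
            raise ConfigurationError(
                f"panel must have exactly 9 target genes, got {len(targets)}"
            )
        if len(set(targets)) != len(targets):
            raise ConfigurationError("panel target genes must be unique")
        if reference in targets:
            raise ConfigurationError(
                f"reference gene {reference!r} must not be among the targets"
            )

    def resolve(self, name: str) -> str:
        """Resolve *name* case-insensitively against the panel, or raise SchemaError."""
        gene = canonical_gene(name)
        if gene == self.reference or gene in self.targets:
            return gene
        raise SchemaError(f"unknown gene {name!r}: not in panel or reference")


DEFAULT_PANEL = GenePanel()


@dataclass(frozen=True)
class CartridgeLayout:
    """Assignment of the panel's target genes to PCR detection cartridges.

    Every cartridge additionally carries the reference gene; the target genes
    partition across cartridges with no overlap.  The shipped default mirrors
    the assay as run: cartridge A = AKR1B1, TM6SF1, ZNF671, TMEFF2 and
    cartridge B = COL6A2, HIST1H3C, RASGRF2, HOXB4, RASSF1, with ACTB in both.
    """

    cartridges: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "A": ("AKR1B1", "TM6SF1", "ZNF671", "TMEFF2"),
            "B": ("COL6A2", "HIST1H3C", "RASGRF2", "HOXB4", "RASSF1"),
        }
    )

    def __post_init__(self) -> None:
        canon = {
            str(cid): tuple(canonical_gene(g) for g in genes)
            for cid, genes in self.cartridges.items()
        }
        object.__setattr__(self, "cartridges", canon)
        if not canon:
            raise ConfigurationError("layout must define at least one cartridge")

    @property
    def cartridge_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.cartridges))

    def all_targets(self) -> tuple[str, ...]:
        return tuple(g for cid in self.cartridge_ids for g in self.cartridges[cid])

    def cartridge_of(self, gene: str) -> str:
        gene = canonical_gene(gene)
        for cid in self.cartridge_ids:
            if gene in self.cartridges[cid]:
                return cid
        raise SchemaError(f"gene {gene!r} not assigned to any cartridge")

    def validate_against(self, panel: GenePanel) -> None:
        """Check that this layout is a disjoint cover of the panel's targets."""
        seen: list[str] = []
        for cid in self.cartridge_ids:
            genes = self.cartridges[cid]
            if panel.reference in genes:
                raise ConfigurationError(
                    f"reference gene {panel.reference} is implicit in every "
                    f"cartridge and must not be listed in cartridge {cid}"
                )
            seen.extend(genes)
        if len(seen) != len(set(seen)):
            raise ConfigurationError("a target gene appears in more than one cartridge")
        if set(seen) != set(panel.targets):
            missing = set(panel.targets) - set(seen)
            extra = set(seen) - set(panel.targets)
            raise ConfigurationError(
                f"layout does not cover the panel exactly (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        # The shipped two-cartridge configuration must split 9 targets as 4 + 5.
        if len(self.cartridge_ids) == 2 and len(panel.targets) == 9:
            sizes = sorted(len(self.cartridges[c]) for c in self.cartridge_ids)
            if sizes != [4, 5]:
                raise ConfigurationError(
                    f"two-cartridge layout must split the 9 targets 4+5, got {sizes}"
                )


DEFAULT_LAYOUT = CartridgeLayout()
DEFAULT_LAYOUT.validate_against(DEFAULT_PANEL)


@dataclass(frozen=True)
class CtMeasurement:
    """One gene's cycle threshold in one cartridge run.

    ``no_signal`` marks reactions with no detectable amplification; these carry
    the sentinel Ct of 45 so downstream arithmetic never branches on missing
    values.  Indeterminate (beyond-45-cycle) amplification is mapped to the
    same sentinel.
    """

    gene: str
    cartridge_id: str
    ct: float
    no_signal: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", canonical_gene(self.gene))
        object.__setattr__(self, "cartridge_id", str(self.cartridge_id))
        object.__setattr__(self, "ct", float(self.ct))
        if self.no_signal:
            if self.ct != NO_SIGNAL_CT:
                raise StructuralError(
                    f"no-signal measurement must carry Ct={NO_SIGNAL_CT}, got {self.ct}"
                )
        elif not (0.0 < self.ct < NO_SIGNAL_CT):
            raise StructuralError(
                f"Ct must lie in (0, {NO_SIGNAL_CT}) for detected signals, got {self.ct}"
            )

    @classmethod
    def no_signal_measurement(cls, gene: str, cartridge_id: str) -> "CtMeasurement":
        return cls(gene=gene, cartridge_id=cartridge_id, ct=NO_SIGNAL_CT, no_signal=True)


@dataclass(frozen=True)
class SampleRun:
    """A sample's complete two-cartridge set of Ct measurements plus metadata."""

    sample_id: str
    measurements: tuple[CtMeasurement, ...]
    subject_id: Optional[str] = None
    group_label: str = "unknown"
    matrix: str = "plasma"
    draw_day: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if self.group_label not in GROUP_LABELS:
            raise SchemaError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )
        if self.matrix not in MATRICES:
            raise SchemaError(f"matrix must be one of {MATRICES}, got {self.matrix!r}")
        if self.draw_day is not None:
            object.__setattr__(self, "draw_day", int(self.draw_day))

    def measurement(self, cartridge_id: str, gene: str) -> CtMeasurement:
        gene = canonical_gene(gene)
        for m in self.measurements:
            if m.cartridge_id == cartridge_id and m.gene == gene:
                return m
        raise StructuralError(
            f"sample {self.sample_id!r}: no measurement for cell ({cartridge_id}, {gene})"
        )


@dataclass(frozen=True)
class AlgorithmConstants:
    """Tunable constants of the cumulative-methylation algorithm.

    no_signal_ct
        Ct sentinel for undetected reactions (cycles).
    censor_offset
        ΔCt units added to the historical 300-copy replicate median to form the
        per-gene censoring bound; 13 cycles corresponds to a quantitation floor
        of 300 x 2^-13 ~ 0.04 copies.
    m_scale
        Numerator of the per-gene methylation transform M = m_scale / ΔCt.
    cm_threshold
        Locked cumulative-methylation cutoff used to call a sample positive.
    """

    no_signal_ct: float = NO_SIGNAL_CT
    censor_offset: float = 13.0
    m_scale: float = 1200.0
    cm_threshold: float = 38.5

    def __post_init__(self) -> None:
        for name in ("no_signal_ct", "censor_offset", "m_scale", "cm_threshold"):
            if not float(getattr(self, name)) > 0.0:
                raise ConfigurationError(f"constant {name} must be strictly positive")


DEFAULT_CONSTANTS = AlgorithmConstants()


def expected_cells(layout: CartridgeLayout, panel: GenePanel) -> tuple[tuple[str, str], ...]:
    """Every (cartridge_id, gene) cell a complete run must cover, reference included."""
    cells = []
    for cid in layout.cartridge_ids:
        for gene in layout.cartridges[cid]:
            cells.append((cid, gene))
        cells.append((cid, panel.reference))
    return tuple(cells)


def validate_sample_run(
    run: SampleRun,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
    panel: GenePanel = DEFAULT_PANEL,
) -> SampleRun:
    """Validate *run* against the layout and return it with canonical gene names.

    Gene names are resolved case-insensitively.  Raises :class:`SchemaError`
    for genes outside the panel, :class:`StructuralError` for missing or
    duplicated (cartridge, gene) cells, naming the offending cell.
    """
    layout.validate_against(panel)
    expected = set(expected_cells(layout, panel))
    seen: dict[tuple[str, str], CtMeasurement] = {}
    for m in run.measurements:
        gene = panel.resolve(m.gene)
        cell = (m.cartridge_id, gene)
        if cell not in expected:
            raise SchemaError(
                f"sample {run.sample_id!r}: gene {gene} is not assigned to "
                f"cartridge {m.cartridge_id}"
            )
        if cell in seen:
            raise StructuralError(
                f"sample {run.sample_id!r}: duplicate measurement for cell {cell}"
            )
        seen[cell] = replace(m, gene=gene)
    missing = expected - set(seen)
    if missing:
        cell = sorted(missing)[0]
        raise StructuralError(
            f"sample {run.sample_id!r}: missing measurement for cell {cell} "
            f"({len(missing)} cell(s) missing in total)"
        )
    ordered = tuple(seen[cell] for cell in sorted(seen))
    return replace(run, measurements=ordered)


def make_sample_run(
    sample_id: str,
    ct_by_cell: Mapping[tuple[str, str], float],
    no_signal_cells: Iterable[tuple[str, str]] = (),
    **metadata,
) -> SampleRun:
    """Convenience constructor from a {(cartridge, gene): ct} mapping."""
    no_sig = {(str(c), canonical_gene(g)) for c, g in no_signal_cells}
    measurements = []
    for (cid, gene), ct in ct_by_cell.items():
        cell = (str(cid), canonical_gene(gene))
        if cell in no_sig:
            measurements.append(CtMeasurement.no_signal_measurement(cell[1], cell[0]))
        else:
            measurements.append(CtMeasurement(gene=cell[1], cartridge_id=cell[0], ct=ct))
    return SampleRun(sample_id=sample_id, measurements=tuple(measurements), **metadata)
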