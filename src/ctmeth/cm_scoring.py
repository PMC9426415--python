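"""Cumulative-methylation (CM) scoring for two-cartridge methylation qPCR runs.

The score is computed in four steps.  (1) Each target gene's Ct is normalized
to the ACTB reference measured in the *same* cartridge, ΔCt = Ct_gene -
Ct_ACTB; undetected reactions carry the Ct = 45 sentinel.  If any gene shows
ΔCt below 1 anywhere in the analysis batch, a per-gene nonnegative integer
shift constant is added to every sample (and to that gene's calibration
median) so the minimum lands at >= 1.  (2) ΔCt values higher than the gene's
censoring bound — the historical replicate median ΔCt at 300 spiked copies
plus a fixed offset of 13 cycles — are set to 0: such signals sit below the
~0.04-copy quantitation floor.  (3) Per-gene methylation M = 1200 / ΔCt, with
censored genes contributing M = 0.  (4) CM is the sum of M over the 9-gene
panel.

Because the same shift constant is applied to sample ΔCt and to the
calibration median, the censoring decision is identical on the raw and the
shifted scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core_model import (
    DEFAULT_CONSTANTS,
    DEFAULT_LAYOUT,
    DEFAULT_PANEL,
    AlgorithmConstants,
    CalibrationError,
    CartridgeLayout,
    ConfigurationError,
    CtmethError,
    GenePanel,
    InputError,
    InvalidRunError,
    SampleRun,
    canonical_gene,
    validate_sample_run,
)


class UndefinedCVError(CtmethError):
    """Coefficient of variation is undefined (zero mean)."""


@dataclass(frozen=True)
class CalibrationTable:
    """Per-gene historical replicate median ΔCt at 300 spiked copies.

    ``shift_constant`` holds the per-gene integer shifts of the current
    analysis batch (0 until a batch requires one); the censoring bound for a
    gene on the shifted scale is ``median + shift + censor_offset``.
    """

    median_delta_ct_300: Mapping[str, float]
    shift_constant: Mapping[str, int] = field(default_factory=dict)
    censor_offset: float = 13.0

    def __post_init__(self) -> None:
        medians = {canonical_gene(g): float(v) for g, v in self.median_delta_ct_300.items()}
        shifts = {canonical_gene(g): int(v) for g, v in self.shift_constant.items()}
        for gene, k in shifts.items():
            if k < 0:
                raise ConfigurationError(f"shift constant for {gene} must be >= 0, got {k}")
            if gene not in medians:
                raise ConfigurationError(f"shift constant for unknown gene {gene}")
        object.__setattr__(self, "median_delta_ct_300", medians)
        object.__setattr__(self, "shift_constant", shifts)
        object.__setattr__(self, "censor_offset", float(self.censor_offset))

    def median(self, gene: str) -> float:
        gene = canonical_gene(gene)
        try:
            return self.median_delta_ct_300[gene]
        except KeyError:
            raise ConfigurationError(f"calibration has no entry for gene {gene}") from None

    def shift(self, gene: str) -> int:
        return self.shift_constant.get(canonical_gene(gene), 0)

    def censoring_bound(self, gene: str) -> float:
        """Censoring bound on the shifted ΔCt scale: shifted median + offset."""
        return self.median(gene) + self.shift(gene) + self.censor_offset

    def with_shifts(self, shifts: Mapping[str, int]) -> "CalibrationTable":
        return replace(self, shift_constant=dict(shifts))

    def covers(self, panel: GenePanel) -> bool:
        return all(g in self.median_delta_ct_300 for g in panel.targets)


@dataclass(frozen=True)
class SampleScore:
    """Per-gene ΔCt (post-shift, post-censor), per-gene M, and the CM sum."""

    sample_id: str
    delta_ct: Mapping[str, float]
    methylation: Mapping[str, float]
    cumulative_methylation: float
    censored: Mapping[str, bool]
    valid: bool = True
    invalid_reason: Optional[str] = None
    subject_id: Optional[str] = None
    group_label: str = "unknown"
    matrix: str = "plasma"
    draw_day: Optional[int] = None

    @property
    def cm(self) -> float:
        return self.cumulative_methylation


def delta_ct(ct_gene: float, ct_reference: float, no_signal_ct: float = 45.0) -> float:
    """Step-1 normalization: Ct_gene - Ct_ACTB from the same cartridge.

    Raises :class:`InvalidRunError` if the reference itself gave no signal
    (Ct at the sentinel), since the whole cartridge is then unquantifiable.
    """
    ct_gene = float(ct_gene)
    ct_reference = float(ct_reference)
    if not (math.isfinite(ct_gene) and math.isfinite(ct_reference)):
        raise InputError("Ct values must be finite")
    if ct_reference >= no_signal_ct:
        raise InvalidRunError("reference gene gave no signal; cartridge is invalid")
    return ct_gene - ct_reference


def compute_gene_shifts(
    delta_ct_by_gene: Mapping[str, Sequence[float]],
) -> dict[str, int]:
    """Per-gene smallest nonnegative integer k with min(ΔCt) + k >= 1.

    Genes whose batch minimum is already >= 1 get k = 0.  The identical k must
    be added to that gene's calibration median before censoring, which is what
    :meth:`CalibrationTable.with_shifts` records.
    """
    shifts: dict[str, int] = {}
    for gene, values in delta_ct_by_gene.items():
        values = list(values)
        if not values:
            raise InputError(f"no ΔCt values supplied for gene {gene}")
        lo = min(float(v) for v in values)
        shifts[canonical_gene(gene)] = 0 if lo >= 1.0 else int(math.ceil(1.0 - lo))
    return shifts


def censor_low_signal(
    shifted_delta_ct: float, gene: str, calibration: CalibrationTable
) -> float:
    """Step-2 censoring: ΔCt strictly above the gene's bound is set to 0."""
    bound = calibration.censoring_bound(gene)
    value = float(shifted_delta_ct)
    return 0.0 if value > bound else value


def gene_methylation(delta_ct_value: float, m_scale: float = 1200.0) -> float:
    """Step-3 transform M = m_scale / ΔCt; the censored sentinel 0 maps to M = 0."""
    value = float(delta_ct_value)
    if value < 0.0:
        raise InputError(
            "ΔCt must be nonnegative after shifting/censoring; run the batch "
            "shift before computing methylation"
        )
    return 0.0 if value == 0.0 else m_scale / value


def raw_delta_cts(
    run: SampleRun,
    panel: GenePanel = DEFAULT_PANEL,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
    constants: AlgorithmConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Raw (unshifted) ΔCt per target gene, each against its own cartridge's ACTB.

    Raises :class:`InvalidRunError` if any cartridge's reference is no-signal.
    """
    out: dict[str, float] = {}
    for cid in layout.cartridge_ids:
        ref = run.measurement(cid, panel.reference)
        if ref.no_signal:
            raise InvalidRunError(
                f"sample {run.sample_id!r}: reference {panel.reference} gave no "
                f"signal in cartridge {cid}"
            )
        for gene in layout.cartridges[cid]:
            m = run.measurement(cid, gene)
            out[gene] = delta_ct(m.ct, ref.ct, constants.no_signal_ct)
    return {g: out[g] for g in panel.targets}


def score_sample(
    run: SampleRun,
    calibration: CalibrationTable,
    constants: AlgorithmConstants = DEFAULT_CONSTANTS,
    panel: GenePanel = DEFAULT_PANEL,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
) -> SampleScore:
    """Score one validated run: ΔCt -> shift -> censor -> M -> CM.

    A sample whose reference gene is no-signal in any cartridge is returned
    with ``valid=False`` and NaN CM rather than scored from the surviving
    cartridge, since CM is defined over all 9 genes.
    """
    run = validate_sample_run(run, layout, panel)
    if not calibration.covers(panel):
        raise ConfigurationError("calibration does not cover every panel target")
    meta = dict(
        subject_id=run.subject_id,
        group_label=run.group_label,
        matrix=run.matrix,
        draw_day=run.draw_day,
    )
    try:
        raw = raw_delta_cts(run, panel, layout, constants)
    except InvalidRunError as err:
        return SampleScore(
            sample_id=run.sample_id,
            delta_ct={},
            methylation={},
            cumulative_methylation=float("nan"),
            censored={},
            valid=False,
            invalid_reason=str(err),
            **meta,
        )
    shifted = {g: raw[g] + calibration.shift(g) for g in panel.targets}
    adjusted = {g: censor_low_signal(shifted[g], g, calibration) for g in panel.targets}
    methylation = {g: gene_methylation(adjusted[g], constants.m_scale) for g in panel.targets}
    censored = {g: adjusted[g] == 0.0 for g in panel.targets}
    cm = float(sum(methylation.values()))
    return SampleScore(
        sample_id=run.sample_id,
        delta_ct=adjusted,
        methylation=methylation,
        cumulative_methylation=cm,
        censored=censored,
        valid=True,
        invalid_reason=None,
        **meta,
    )


def score_batch(
    runs: Sequence[SampleRun],
    calibration: CalibrationTable,
    constants: AlgorithmConstants = DEFAULT_CONSTANTS,
    panel: GenePanel = DEFAULT_PANEL,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
) -> tuple[list[SampleScore], CalibrationTable]:
    """Score an analysis batch, computing batch-level shift constants first.

    Returns the scores (run order preserved; invalid runs flagged, not
    dropped) together with the calibration table updated with the shifts
    actually applied.
    """
    if not runs:
        raise InputError("batch must contain at least one run")
    per_gene: dict[str, list[float]] = {g: [] for g in panel.targets}
    for run in runs:
        try:
            raw = raw_delta_cts(
                validate_sample_run(run, layout, panel), panel, layout, constants
            )
        except InvalidRunError:
            continue
        for g, v in raw.items():
            per_gene[g].append(v)
    usable = {g: v for g, v in per_gene.items() if v}
    shifts = compute_gene_shifts(usable) if usable else {}
    shifted_calibration = calibration.with_shifts(shifts)
    scores = [
        score_sample(run, shifted_calibration, constants, panel, layout) for run in runs
    ]
    return scores, shifted_calibration


def build_calibration(
    replicate_runs: Sequence[SampleRun],
    panel: GenePanel = DEFAULT_PANEL,
    constants: AlgorithmConstants = DEFAULT_CONSTANTS,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
) -> CalibrationTable:
    """Build a calibration table from replicate runs of 300 spiked copies.

    The per-gene entry is the median of raw ΔCt across replicates (mean of the
    two middle values for even counts).  Requires at least 3 replicates with a
    quantifiable reference; shift constants start at 0 and are filled in when
    a study batch is scored.
    """
    per_gene: dict[str, list[float]] = {g: [] for g in panel.targets}
    n_usable = 0
    for run in replicate_runs:
        try:
            raw = raw_delta_cts(
                validate_sample_run(run, layout, panel), panel, layout, constants
            )
        except InvalidRunError:
            continue
        n_usable += 1
        for g, v in raw.items():
            per_gene[g].append(v)
    if n_usable < 3:
        raise CalibrationError(
            f"calibration requires >= 3 usable replicate runs, got {n_usable}"
        )
    medians = {g: float(np.median(v)) for g, v in per_gene.items()}
    return CalibrationTable(
        median_delta_ct_300=medians,
        shift_constant={g: 0 for g in panel.targets},
        censor_offset=constants.censor_offset,
    )


def replicate_cv(values: Iterable[float]) -> float:
    """Percent coefficient of variation across replicates: 100 * sd / mean.

    Uses the sample standard deviation (n-1 denominator).  Raises
    :class:`UndefinedCVError` when the mean is zero and :class:`InputError`
    for fewer than two values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InputError("CV requires at least two replicate values")
    mean = float(arr.mean())
    if mean == 0.0:
        raise UndefinedCVError("CV undefined: replicate mean is zero")
    return float(arr.std(ddof=1) / mean * 100.0)
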