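"""Synthetic qPCR Ct data with the statistical structure the pipeline assumes.

The generator emulates the assay's measurement chain in its simplest faithful
form: a reaction containing an expected number of methylated template copies
draws an integer molecule count k ~ Poisson(copies); zero molecules produce a
no-signal reaction (Ct = 45); otherwise the measured Ct is the gene's
amplification intercept (Ct of a single template copy, nested preamplification
folded in) minus log2(k), plus Gaussian instrument noise whose standard
deviation depends on the sample matrix (plasma is tighter than serum).  A
sample is split equally across the two detection cartridges, halving the
effective copies any single cartridge sees; ACTB measures total background
cfDNA, shared at the sample level across the two cartridges.

Four study designs are provided: spike-in replicates at fixed copy numbers,
case/control cohorts (with the assay's observed ACTB Ct ranges per class),
paired duplicate runs for two users, and longitudinal serial draws driven by a
latent tumor-burden trajectory.  All generators are pure functions of
(design, seed): a seed is mandatory, never taken from the clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_LAYOUT,
    DEFAULT_PANEL,
    CartridgeLayout,
    ConfigurationError,
    CtMeasurement,
    GenePanel,
    InputError,
    SampleRun,
    NO_SIGNAL_CT,
)

#: Gaussian Ct noise (cycles) calibrated so replicate CM CV at 300 spiked
#: copies sits inside the observed bands: 7.1-10.9% in plasma, 19.0-36.1% in serum.
PLASMA_CT_SD = 0.30
SERUM_CT_SD = 1.00

#: Per-gene amplification intercepts: Ct of one effective template copy with
#: the 20-cycle nested preamplification folded in.  Targets amplify more
#: efficiently than the single-round ACTB reference, putting 300-copy
#: calibration medians near 2.7-3.4 ΔCt.  This keeps every censoring bound
#: (median + 13) below 45 - max ACTB Ct, so a no-signal reaction (Ct 45) is
#: always censored rather than scored — the consistency the algorithm's
#: censoring rule presumes.
DEFAULT_INTERCEPTS: Mapping[str, float] = {
    "HOXB4": 33.1,
    "RASGRF2": 33.5,
    "AKR1B1": 33.0,
    "TM6SF1": 33.6,
    "COL6A2": 32.9,
    "HIST1H3C": 33.3,
    "TMEFF2": 33.6,
    "RASSF1": 32.9,
    "ZNF671": 33.4,
    "ACTB": 38.0,
}

#: Effective background-cfDNA ACTB copies seen per cartridge in a normal
#: matrix; 2^15 copies puts ACTB Ct near 23 cycles, mid normal range.
DEFAULT_ACTB_COPIES = 32768.0


def _require_seed(seed) -> int:
    if seed is None:
        raise InputError("a seed is mandatory for every generator entry point")
    return int(seed)


@dataclass(frozen=True)
class NoiseModel:
    """qPCR measurement noise: Poisson molecule sampling + Gaussian Ct noise."""

    intercepts: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    ct_noise_sd: float = PLASMA_CT_SD
    actb_copies: float = DEFAULT_ACTB_COPIES

    def __post_init__(self) -> None:
        if not self.ct_noise_sd > 0:
            raise ConfigurationError("ct_noise_sd must be strictly positive")
        if not self.actb_copies > 0:
            raise ConfigurationError("actb_copies must be strictly positive")

    def intercept(self, gene: str) -> float:
        try:
            return float(self.intercepts[gene])
        except KeyError:
            raise ConfigurationError(f"no amplification intercept for gene {gene}") from None

    @classmethod
    def plasma(cls) -> "NoiseModel":
        return cls(ct_noise_sd=PLASMA_CT_SD)

    @classmethod
    def serum(cls) -> "NoiseModel":
        return cls(ct_noise_sd=SERUM_CT_SD)

    @classmethod
    def for_matrix(cls, matrix: str) -> "NoiseModel":
        if matrix == "plasma":
            return cls.plasma()
        if matrix == "serum":
            return cls.serum()
        raise ConfigurationError(f"unknown matrix {matrix!r}")


def simulate_ct(
    expected_copies: float,
    gene: str,
    noise: NoiseModel,
    rng: np.random.Generator,
    cartridge_id: str = "A",
) -> CtMeasurement:
    """Simulate one reaction's Ct for a gene at the given expected copy number.

    k ~ Poisson(expected_copies); k = 0 emits no-signal (Ct 45); otherwise
    Ct = intercept - log2(k) + Normal(0, sd), clipped to the open (0, 45).
    """
    if expected_copies < 0:
        raise InputError("expected_copies must be >= 0")
    k = int(rng.poisson(expected_copies))
    if k == 0:
        return CtMeasurement.no_signal_measurement(gene, cartridge_id)
    ct = noise.intercept(gene) - math.log2(k) + rng.normal(0.0, noise.ct_noise_sd)
    ct = min(max(ct, 0.01), NO_SIGNAL_CT - 0.01)
    return CtMeasurement(gene=gene, cartridge_id=cartridge_id, ct=ct)


def _simulate_run(
    sample_id: str,
    target_copies: Mapping[str, float],
    actb_copies_per_cartridge: float,
    noise: NoiseModel,
    rng: np.random.Generator,
    panel: GenePanel,
    layout: CartridgeLayout,
    **metadata,
) -> SampleRun:
    """One complete two-cartridge run; targets at the given per-cartridge copies."""
    measurements = []
    for cid in layout.cartridge_ids:
        for gene in layout.cartridges[cid]:
            measurements.append(
                simulate_ct(target_copies.get(gene, 0.0), gene, noise, rng, cid)
            )
        measurements.append(
            simulate_ct(actb_copies_per_cartridge, panel.reference, noise, rng, cid)
        )
    return SampleRun(sample_id=sample_id, measurements=tuple(measurements), **metadata)


@dataclass(frozen=True)
class SpikeDesign:
    """Replicate spike-in experiment: fully methylated DNA at fixed copy numbers."""

    seed: int
    copies_per_condition: tuple[float, ...] = (0.0, 75.0, 150.0, 300.0, 600.0)
    replicates_per_condition: int = 11
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        _require_seed(self.seed)
        if any(c < 0 for c in self.copies_per_condition):
            raise ConfigurationError("spiked copies must be >= 0")
        if self.replicates_per_condition < 2:
            raise ConfigurationError("need >= 2 replicates per condition")
        if self.matrix not in ("plasma", "serum"):
            raise ConfigurationError(f"unknown matrix {self.matrix!r}")


def simulate_spike_replicates(
    design: SpikeDesign,
    panel: GenePanel = DEFAULT_PANEL,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
    noise: Optional[NoiseModel] = None,
) -> tuple[list[SampleRun], pd.DataFrame]:
    """Simulate replicate runs per spiked-copy condition, with a truth table.

    Each spiked genome copy carries every target gene, and the converted pool
    is split equally between the two cartridges, so each target sees
    copies / 2 expected template molecules per cartridge.  ACTB comes from the
    fixed background cfDNA of the carrier matrix.
    """
    noise = noise or NoiseModel.for_matrix(design.matrix)
    rng = np.random.default_rng(_require_seed(design.seed))
    runs: list[SampleRun] = []
    truth_rows = []
    for copies in design.copies_per_condition:
        per_cartridge = copies / 2.0
        for rep in range(design.replicates_per_condition):
            sid = f"spike_{int(copies)}c_r{rep + 1:02d}"
            run = _simulate_run(
                sid,
                {g: per_cartridge for g in panel.targets},
                noise.actb_copies,
                noise,
                rng,
                panel,
                layout,
                matrix=design.matrix,
            )
            runs.append(run)
            truth_rows.append({"sample_id": sid, "spiked_copies": copies, "replicate": rep + 1})
    return runs, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class CohortDesign:
    """Case/control cohort: shedding cancers vs. near-zero-background controls.

    A cancer sample sheds detectable ctDNA with probability ``detection_rate``;
    shedding samples activate each panel gene with probability
    ``active_gene_rate`` (at least one forced) and draw per-gene methylated
    copies from a log-normal.  Controls (benign + normal) carry low-level
    background methylation with probability ``background_rate`` (0 by default:
    most real controls score exactly CM = 0).  ACTB Ct is drawn uniformly
    within the class-specific observed ranges.
    """

    seed: int
    n_cancer: int = 40
    n_benign: int = 17
    n_normal: int = 9
    matrix: str = "plasma"
    detection_rate: float = 0.8
    copies_log_mean: float = math.log(150.0)
    copies_log_sd: float = 1.0
    active_gene_rate: float = 0.6
    background_rate: float = 0.0
    background_log_mean: float = math.log(6.0)
    background_log_sd: float = 0.8
    background_active_gene_rate: float = 0.25
    actb_ct_range_cancer: tuple[float, float] = (16.0, 27.8)
    actb_ct_range_normal: tuple[float, float] = (21.0, 27.4)

    def __post_init__(self) -> None:
        _require_seed(self.seed)
        for lo, hi in (self.actb_ct_range_cancer, self.actb_ct_range_normal):
            if not (0.0 < lo <= hi < 45.0):
                raise ConfigurationError("ACTB Ct ranges must lie within (0, 45)")
        for name in ("n_cancer", "n_benign", "n_normal"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("detection_rate", "background_rate", "active_gene_rate",
                     "background_active_gene_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be a probability")

    @classmethod
    def for_target_auc(cls, auc: float, seed: int, **kwargs) -> "CohortDesign":
        """Design whose true AUC equals *auc* by construction.

        With zero control background, controls score CM = 0 and a shedding
        cancer scores CM > 0, so the true AUC (ties counted 1/2) is
        (1 + detection_rate) / 2; hence detection_rate = 2*auc - 1.
        """
        if not 0.5 <= auc <= 1.0:
            raise ConfigurationError("target AUC must be in [0.5, 1.0]")
        return cls(seed=seed, detection_rate=2.0 * auc - 1.0, background_rate=0.0, **kwargs)

    @classmethod
    def null(cls, seed: int, shed_rate: float = 0.3, **kwargs) -> "CohortDesign":
        """Design with identical generation for cases and controls (true AUC 0.5)."""
        return cls(
            seed=seed,
            detection_rate=shed_rate,
            background_rate=shed_rate,
            copies_log_mean=cls.background_log_mean,
            copies_log_sd=cls.background_log_sd,
            active_gene_rate=cls.background_active_gene_rate,
            actb_ct_range_cancer=cls.actb_ct_range_normal,
            **kwargs,
        )


def _draw_sample_copies(
    rng: np.random.Generator,
    panel: GenePanel,
    shed_rate: float,
    log_mean: float,
    log_sd: float,
    active_rate: float,
) -> dict[str, float]:
    """Per-cartridge expected methylated copies per gene for one sample."""
    if rng.random() >= shed_rate:
        return {}
    active = [g for g in panel.targets if rng.random() < active_rate]
    if not active:
        active = [panel.targets[rng.integers(len(panel.targets))]]
    # total copies split over two cartridges -> half per cartridge measurement
    return {g: rng.lognormal(log_mean, log_sd) / 2.0 for g in active}


def simulate_cohort(
    design: CohortDesign,
    panel: GenePanel = DEFAULT_PANEL,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
    noise: Optional[NoiseModel] = None,
) -> tuple[list[SampleRun], list[str]]:
    """Simulate a labelled case/control cohort; returns (runs, labels)."""
    noise = noise or NoiseModel.for_matrix(design.matrix)
    rng = np.random.default_rng(_require_seed(design.seed))
    actb_alpha = noise.intercept(panel.reference)
    runs: list[SampleRun] = []
    labels: list[str] = []
    groups = (
        [("cancer", i) for i in range(design.n_cancer)]
        + [("benign", i) for i in range(design.n_benign)]
        + [("normal", i) for i in range(design.n_normal)]
    )
    for label, i in groups:
        if label == "cancer":
            copies = _draw_sample_copies(
                rng, panel, design.detection_rate,
                design.copies_log_mean, design.copies_log_sd, design.active_gene_rate,
            )
            actb_range = design.actb_ct_range_cancer
        else:
            copies = _draw_sample_copies(
                rng, panel, design.background_rate,
                design.background_log_mean, design.background_log_sd,
                design.background_active_gene_rate,
            )
            actb_range = design.actb_ct_range_normal
        # sample-level latent cfDNA load, measured once per cartridge
        actb_ct = rng.uniform(*actb_range)
        actb_copies = 2.0 ** (actb_alpha - actb_ct)
        sid = f"{label}_{i + 1:03d}"
        runs.append(
            _simulate_run(
                sid, copies, actb_copies, noise, rng, panel, layout,
                subject_id=sid, group_label=label, matrix=design.matrix,
            )
        )
        labels.append(label)
    return runs, labels


def simulate_interuser(
    runs: Sequence[SampleRun],
    user_noise_sd: float,
    seed: int,
    noise: Optional[NoiseModel] = None,
    resample_molecules: bool = True,
) -> list[tuple[SampleRun, SampleRun]]:
    """Duplicate each run into a (user A, user B) aliquot pair.

    Each user independently remeasures the aliquot: detected Ct values are
    perturbed with Gaussian noise of sd ``user_noise_sd``; when
    ``resample_molecules`` is set, the implied template copies (2^(intercept -
    Ct)) are re-drawn through the Poisson layer so borderline signals can flip
    to no-signal between users.  No-signal reactions stay no-signal.
    """
    if user_noise_sd < 0:
        raise InputError("user_noise_sd must be >= 0")
    noise = noise or NoiseModel.plasma()
    rng = np.random.default_rng(_require_seed(seed))

    def remeasure(run: SampleRun, tag: str) -> SampleRun:
        measurements = []
        for m in run.measurements:
            if m.no_signal:
                measurements.append(m)
                continue
            if resample_molecules:
                implied = 2.0 ** (noise.intercept(m.gene) - m.ct)
                k = int(rng.poisson(implied))
                if k == 0:
                    measurements.append(
                        CtMeasurement.no_signal_measurement(m.gene, m.cartridge_id)
                    )
                    continue
                ct = noise.intercept(m.gene) - math.log2(k)
            else:
                ct = m.ct
            if user_noise_sd > 0:
                ct += rng.normal(0.0, user_noise_sd)
            ct = min(max(ct, 0.01), NO_SIGNAL_CT - 0.01)
            measurements.append(
                CtMeasurement(gene=m.gene, cartridge_id=m.cartridge_id, ct=ct)
            )
        return SampleRun(
            sample_id=f"{run.sample_id}_{tag}",
            measurements=tuple(measurements),
            subject_id=run.subject_id,
            group_label=run.group_label,
            matrix=run.matrix,
            draw_day=run.draw_day,
        )

    return [(remeasure(run, "A"), remeasure(run, "B")) for run in runs]


TRAJECTORY_PATTERNS = ("response", "progression", "stable")


def simulate_longitudinal(
    n_patients: int,
    seed: int,
    patterns: Sequence[str] = TRAJECTORY_PATTERNS,
    draws_per_patient: int = 5,
    cycle_days: int = 21,
    panel: GenePanel = DEFAULT_PANEL,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
    noise: Optional[NoiseModel] = None,
    matrix: str = "serum",
    decay_halflife_days: float = 18.0,
    regrowth_halflife_days: float = 25.0,
) -> tuple[list[SampleRun], pd.DataFrame]:
    """Serial on-treatment draws driven by a latent tumor-burden trajectory.

    Draws occur at baseline (day 0) and immediately before each treatment
    cycle (every ``cycle_days`` days).  The latent burden follows the assigned
    pattern: "response" decays exponentially, "progression" decays to a nadir
    at the second cycle then regrows, "stable" stays at baseline.  Burden
    drives per-gene methylated copies of a fixed per-patient active gene set.
    Returns the runs plus a truth table (patient, day, pattern, burden).
    """
    if draws_per_patient < 2:
        raise InputError("need >= 2 draws per patient")
    unknown = sorted(set(patterns) - set(TRAJECTORY_PATTERNS))
    if unknown:
        raise ConfigurationError(f"unknown trajectory patterns {unknown}")
    noise = noise or NoiseModel.for_matrix(matrix)
    rng = np.random.default_rng(_require_seed(seed))
    decay = math.log(2.0) / decay_halflife_days
    regrow = math.log(2.0) / regrowth_halflife_days
    runs: list[SampleRun] = []
    truth_rows = []
    for p in range(n_patients):
        pattern = patterns[p % len(patterns)]
        subject = f"pt{p + 1:02d}"
        baseline_burden = rng.lognormal(math.log(400.0), 0.5)
        n_active = int(rng.integers(3, 7))
        active = list(rng.choice(panel.targets, size=n_active, replace=False))
        actb_ct = rng.uniform(18.0, 26.0)
        actb_copies = 2.0 ** (noise.intercept(panel.reference) - actb_ct)
        nadir_day = 2 * cycle_days
        for d in range(draws_per_patient):
            day = d * cycle_days
            if pattern == "response":
                burden = baseline_burden * math.exp(-decay * day)
            elif pattern == "progression":
                if day <= nadir_day:
                    burden = baseline_burden * math.exp(-decay * day)
                else:
                    nadir = baseline_burden * math.exp(-decay * nadir_day)
                    burden = nadir * math.exp(regrow * (day - nadir_day))
            else:  # stable
                burden = baseline_burden
            copies = {g: burden / n_active / 2.0 for g in active}
            sid = f"{subject}_d{day:03d}"
            runs.append(
                _simulate_run(
                    sid, copies, actb_copies, noise, rng, panel, layout,
                    subject_id=subject, group_label="cancer", matrix=matrix,
                    draw_day=day,
                )
            )
            truth_rows.append(
                {"subject_id": subject, "draw_day": day, "pattern": pattern,
                 "latent_burden": burden}
            )
    return runs, pd.DataFrame(truth_rows)
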