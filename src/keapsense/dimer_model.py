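"""Closed-form model of KEAP1 dimer composition and stress-inactivated activity.

KEAP1 represses NRF2 as an obligate homodimer.  In a heterozygote carrying one
wild-type allele and one sensor-dead allele (e.g. C226S/C613S, which cannot form
the oxidative-stress disulfide), random pairing of monomers produces a mixed
pool of WT/WT, WT/mut and mut/mut dimers in Hardy-Weinberg proportions.  Under
oxidative stress the WT homodimer pool is partially inactivated; how the mixed
heterodimer behaves depends on which of two hypotheses holds:

* **monomer inactivation** — modifying a single monomer kills the dimer's
  E3-ligase activity, so heterodimers are vulnerable through their WT member;
* **dimer inactivation** — both monomers must be modified, so heterodimers
  (whose mutant member can never be modified) stay fully active.

The two hypotheses predict different total cellular KEAP1 activities, which can
be compared against an activity estimate inverted from a calibration curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type checkers
    from .calibration import ActivityEstimate

__all__ = [
    "Hypothesis",
    "HeterodimerMode",
    "DimerPopulation",
    "InactivationSetting",
    "ActivityPrediction",
    "HypothesisVerdict",
    "dimer_composition",
    "infer_homodimer_inactivation",
    "heterodimer_inactivated_fraction",
    "predict_total_activity",
    "evaluate_hypotheses",
]

_SUM_TOL = 1e-12


class Hypothesis(str, Enum):
    """Which pattern of monomer modification abolishes dimer activity."""

    MONOMER = "monomer"
    DIMER = "dimer"


class HeterodimerMode(str, Enum):
    """Arithmetic used for the heterodimer term under monomer inactivation.

    ``PAPER_LINEAR`` halves the WT-homodimer inactivated fraction (a dimer with
    one WT member carries half the modifiable material, treated linearly).
    ``BINOMIAL`` back-solves the per-monomer modification probability p from
    1 - (1-p)^2 = f_inact and applies p to the heterodimer's single WT member.
    """

    PAPER_LINEAR = "paper_linear"
    BINOMIAL = "binomial"


def _check_fraction(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class DimerPopulation:
    """Fractions of WT/WT, WT/mut and mut/mut dimers in one genotype."""

    f_wt_homo: float
    f_het: float
    f_mut_homo: float

    def __post_init__(self) -> None:
        for name in ("f_wt_homo", "f_het", "f_mut_homo"):
            _check_fraction(getattr(self, name), name)
        total = self.f_wt_homo + self.f_het + self.f_mut_homo
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"dimer fractions must sum to 1, got {total!r}")


@dataclass(frozen=True)
class InactivationSetting:
    """Stress strength plus the hypothesis/arithmetic under evaluation.

    ``f_inact`` is the fraction of the WT-homodimer pool inactivated by the
    stress, inferred empirically from the all-WT animal (dimer-level quantity).
    """

    f_inact: float
    hypothesis: Hypothesis
    mode: HeterodimerMode = HeterodimerMode.PAPER_LINEAR

    def __post_init__(self) -> None:
        _check_fraction(self.f_inact, "f_inact")
        object.__setattr__(self, "hypothesis", Hypothesis(self.hypothesis))
        object.__setattr__(self, "mode", HeterodimerMode(self.mode))


@dataclass(frozen=True)
class ActivityPrediction:
    """Predicted total KEAP1 activity with per-dimer-class contributions."""

    total_activity: float
    contrib_mut_homo: float
    contrib_wt_homo: float
    contrib_het: float
    setting: InactivationSetting
    population: DimerPopulation

    def __post_init__(self) -> None:
        parts = self.contrib_mut_homo + self.contrib_wt_homo + self.contrib_het
        if abs(self.total_activity - parts) > _SUM_TOL:
            raise ValueError("total_activity must equal the sum of contributions")
        _check_fraction(self.total_activity, "total_activity")


class Selection(str, Enum):
    MONOMER = "monomer"
    DIMER = "dimer"
    BOTH = "both"
    NEITHER = "neither"


@dataclass(frozen=True)
class HypothesisVerdict:
    """Both hypothesis predictions judged against one activity estimate."""

    prediction_monomer: float
    prediction_dimer: float
    estimate: "ActivityEstimate"
    within_ci: dict[Hypothesis, bool]
    selected: Selection


def dimer_composition(wt_allele_fraction: float) -> DimerPopulation:
    """Dimer pool fractions under random pairing of monomers.

    With WT monomer fraction ``w``, random assortment gives w^2 WT homodimers,
    2w(1-w) heterodimers and (1-w)^2 mutant homodimers — the same pairing rule
    as Hardy-Weinberg genotype frequencies.  A balanced heterozygote (w = 0.5)
    yields the 25% / 50% / 25% pool.
    """
    w = _check_fraction(wt_allele_fraction, "wt_allele_fraction")
    return DimerPopulation(
        f_wt_homo=w * w,
        f_het=2.0 * w * (1.0 - w),
        f_mut_homo=(1.0 - w) * (1.0 - w),
    )


def infer_homodimer_inactivation(activity_wt_animal: float) -> float:
    """Inactivated fraction of the WT-homodimer pool, from the all-WT animal.

    In an animal whose entire KEAP1 pool is WT homodimer, residual activity a
    implies the stress inactivated 1 - a of the pool.
    """
    a = _check_fraction(activity_wt_animal, "activity_wt_animal")
    return 1.0 - a


def heterodimer_inactivated_fraction(setting: InactivationSetting) -> float:
    """Fraction of WT/mut heterodimers inactivated by the stress.

    Under dimer inactivation the answer is 0 regardless of mode: the mutant
    member carries no functional sensor, so the "both members modified"
    condition can never be met.  Under monomer inactivation the heterodimer is
    vulnerable through its single WT member; ``paper_linear`` halves the
    homodimer-level inactivated fraction, ``binomial`` uses the per-monomer
    modification probability p = 1 - sqrt(1 - f_inact).
    """
    if setting.hypothesis is Hypothesis.DIMER:
        return 0.0
    if setting.mode is HeterodimerMode.PAPER_LINEAR:
        return setting.f_inact / 2.0
    return 1.0 - math.sqrt(1.0 - setting.f_inact)


def predict_total_activity(
    population: DimerPopulation, setting: InactivationSetting
) -> ActivityPrediction:
    """Total KEAP1 activity of a mixed dimer pool under one hypothesis.

    Mutant homodimers are insensitive to the stress and stay fully active.
    WT homodimers keep 1 - f_inact of their activity — an empirical, dimer-level
    quantity that does not depend on the hypothesis.  Only the heterodimer term
    differs between hypotheses.
    """
    het_inact = heterodimer_inactivated_fraction(setting)
    contrib_mut = population.f_mut_homo
    contrib_wt = population.f_wt_homo * (1.0 - setting.f_inact)
    contrib_het = population.f_het * (1.0 - het_inact)
    total = contrib_mut + contrib_wt + contrib_het
    if 1.0 < total < 1.0 + 1e-9:  # float round-off; the exact sum is <= 1
        contrib_het -= total - 1.0
        total = 1.0
    return ActivityPrediction(
        total_activity=total,
        contrib_mut_homo=contrib_mut,
        contrib_wt_homo=contrib_wt,
        contrib_het=contrib_het,
        setting=setting,
        population=population,
    )


def evaluate_hypotheses(
    population: DimerPopulation,
    f_inact: float,
    estimate: "ActivityEstimate",
    mode: HeterodimerMode = HeterodimerMode.PAPER_LINEAR,
) -> HypothesisVerdict:
    """Judge both hypotheses against a calibration-derived activity estimate.

    A hypothesis is supported when its predicted total activity falls inside
    the estimate's confidence interval; ``selected`` records which one(s).
    """
    if estimate.ci_low > estimate.ci_high:
        raise ValueError(
            f"degenerate confidence interval: [{estimate.ci_low}, {estimate.ci_high}]"
        )
    predictions = {
        h: predict_total_activity(
            population, InactivationSetting(f_inact, h, mode)
        ).total_activity
        for h in Hypothesis
    }
    within = {
        h: estimate.ci_low <= p <= estimate.ci_high for h, p in predictions.items()
    }
    if within[Hypothesis.MONOMER] and within[Hypothesis.DIMER]:
        selected = Selection.BOTH
    elif within[Hypothesis.MONOMER]:
        selected = Selection.MONOMER
    elif within[Hypothesis.DIMER]:
        selected = Selection.DIMER
    else:
        selected = Selection.NEITHER
    return HypothesisVerdict(
        prediction_monomer=predictions[Hypothesis.MONOMER],
        prediction_dimer=predictions[Hypothesis.DIMER],
        estimate=estimate,
        within_ci=within,
        selected=selected,
    )
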