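"""Seeded synthetic datasets mirroring the mouse-cohort study design.

Three table generators emulate the measurements the analysis consumes:

* a graded-KEAP1 calibration series (protein levels 100/40/19/5% of wild type,
  the dosage ladder built from hypomorphic alleles), with lognormal
  multiplicative noise on the mRNA fold-changes — RT-qPCR fold-changes are
  ratio-scale, so noise acts on the log scale and group geometric means
  converge to the noiseless curve;
* a stress-cohort observation table: for each genotype the dimer pool is
  composed by random pairing, total KEAP1 activity is computed under a chosen
  ground-truth hypothesis, and the activity is pushed through the ground-truth
  calibration curve to an expected fold-change, then perturbed by noise;
* a variant table containing the seven human sensor-region variants reported
  from population whole-genome panels, plus seeded decoy substitutions at
  non-sensor positions.

One root seed drives everything; each table derives its own child stream so
adding a table never shifts another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint
from .dimer_model import (
    HeterodimerMode,
    Hypothesis,
    InactivationSetting,
    dimer_composition,
    predict_total_activity,
)
from .sensor_variants import _AA1, SensorMap

__all__ = [
    "GroundTruth",
    "DEFAULT_LEVELS",
    "REPORTED_SENSOR_VARIANTS",
    "generate_calibration_dataset",
    "generate_stress_cohort",
    "generate_variant_table",
]

#: KEAP1 protein levels (percent of wild type) of the graded genetic series.
DEFAULT_LEVELS: tuple[float, ...] = (100.0, 40.0, 19.0, 5.0)

#: The seven human KEAP1 sensor-region variants reported from the
#: TMM 54KJPN / gnomAD population panels.
REPORTED_SENSOR_VARIANTS: tuple[str, ...] = (
    "His225Tyr",
    "Arg614Gly",
    "Arg614Trp",
    "Arg614Gln",
    "Cys622Ser",
    "Cys622Arg",
    "Cys624Tyr",
)

# Child-stream keys: stable per table so tables are independent of each other.
_STREAM_CALIBRATION = 0
_STREAM_COHORT = 1
_STREAM_VARIANTS = 2


@dataclass(frozen=True)
class GroundTruth:
    """Simulation truth for the calibration and cohort generators.

    ``curve_slope`` is the log-log slope of the true calibration curve
    (negative; -1 means mRNA doubles when KEAP1 halves).  ``f_inact_true`` is
    the fraction of the WT-homodimer pool the stress inactivates.
    ``noise_sd_log`` is the log-scale SD of the multiplicative measurement
    noise; the default 0.25 is a tuning stand-in chosen so synthetic
    confidence intervals resemble the ±13-percentage-point width the real
    measurements support, not a measured value.  ``n_replicates`` defaults to
    the RT-qPCR group size of 5 animals.
    """

    curve_slope: float = -1.0
    f_inact_true: float = 0.74
    hypothesis_true: Hypothesis = Hypothesis.MONOMER
    mode_true: HeterodimerMode = HeterodimerMode.PAPER_LINEAR
    noise_sd_log: float = 0.25
    n_replicates: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.curve_slope >= 0:
            raise ValueError("curve_slope must be negative (repression)")
        object.__setattr__(self, "hypothesis_true", Hypothesis(self.hypothesis_true))
        object.__setattr__(self, "mode_true", HeterodimerMode(self.mode_true))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    def true_mrna(self, level_pct: float) -> float:
        """Noiseless fold-change of the ground-truth curve at a KEAP1 level."""
        return float((100.0 / level_pct) ** abs(self.curve_slope))


def generate_calibration_dataset(
    truth: GroundTruth,
    levels: tuple[float, ...] | list[float] = DEFAULT_LEVELS,
    gene: str = "Nqo1",
) -> list[CalibrationPoint]:
    """Replicate calibration measurements on the graded-KEAP1 series."""
    if any(lv <= 0 for lv in levels):
        raise ValueError("levels must be positive percentages")
    rng = truth.rng(_STREAM_CALIBRATION)
    points: list[CalibrationPoint] = []
    for level in levels:
        eps = rng.normal(0.0, truth.noise_sd_log, size=truth.n_replicates)
        for r, e in enumerate(eps, start=1):
            points.append(
                CalibrationPoint(
                    keap1_level=float(level),
                    mrna_rel=truth.true_mrna(level) * float(np.exp(e)),
                    replicate_id=f"L{level:g}_r{r}",
                    gene=gene,
                )
            )
    return points


def generate_stress_cohort(
    truth: GroundTruth,
    genotypes: list[dict] | None = None,
    gene: str = "Nqo1",
) -> pd.DataFrame:
    """Observation table for stressed cohorts of differing *Keap1* genotypes.

    Each genotype dict carries ``wt_allele_fraction`` and ``label``.  The
    default cohort matches the study design: an all-WT stressed group (from
    which the WT-homodimer inactivated fraction is inferred) and a balanced
    heterozygote stressed group.  Activity is mapped to expected mRNA through
    the ground-truth curve at level = activity * 100%.
    """
    if genotypes is None:
        genotypes = [
            {"wt_allele_fraction": 1.0, "label": "WT_stressed"},
            {"wt_allele_fraction": 0.5, "label": "het_stressed"},
        ]
    rng = truth.rng(_STREAM_COHORT)
    rows = []
    for geno in genotypes:
        pop = dimer_composition(geno["wt_allele_fraction"])
        setting = InactivationSetting(
            truth.f_inact_true, truth.hypothesis_true, truth.mode_true
        )
        activity = predict_total_activity(pop, setting).total_activity
        expected = truth.true_mrna(max(activity, 1e-12) * 100.0)
        eps = rng.normal(0.0, truth.noise_sd_log, size=truth.n_replicates)
        for r, e in enumerate(eps, start=1):
            rows.append(
                {
                    "gene": gene,
                    "condition_label": geno["label"],
                    "wt_allele_fraction": geno["wt_allele_fraction"],
                    "mrna_rel": expected * float(np.exp(e)),
                    "replicate_id": f"{geno['label']}_r{r}",
                }
            )
    return pd.DataFrame(rows)


def generate_variant_table(
    n_decoys: int = 0, seed: int = 1, sensor_map: SensorMap | None = None
) -> pd.DataFrame:
    """Variant table: the seven reported sensor-region variants plus decoys.

    Decoys are substitutions at positions disjoint from every sensor and
    neighbor position, with random plausible amino-acid changes and small
    random allele frequencies; rows are seeded and reproducible.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    smap = sensor_map or SensorMap()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_VARIANTS,))
    )
    rows = [
        {
            "gene": "KEAP1",
            "protein_change": pc,
            "panel": "TMM_54KJPN",
            "allele_frequency": float(rng.uniform(1e-6, 1e-4)),
        }
        for pc in REPORTED_SENSOR_VARIANTS
    ]
    excluded = (
        set(smap.oxidative_cys)
        | set(smap.electrophile_cys)
        | set(smap.oxidative_neighbor_basic)
    )
    candidates = [p for p in range(10, 601) if p not in excluded]
    positions = rng.choice(candidates, size=n_decoys, replace=False)
    aa_pool = sorted(_AA1 - {"C", "H", "R", "K"})  # keep decoys off sensor chemistry
    for pos in positions:
        ref, alt = rng.choice(aa_pool, size=2, replace=False)
        rows.append(
            {
                "gene": "KEAP1",
                "protein_change": f"{ref}{int(pos)}{alt}",
                "panel": "TMM_54KJPN",
                "allele_frequency": float(rng.uniform(1e-6, 1e-4)),
            }
        )
    return pd.DataFrame(rows)
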