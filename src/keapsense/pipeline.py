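"""End-to-end orchestration: calibration fit, activity estimation, hypothesis
evaluation and variant screening, with machine-readable reports.

The dimer analysis runs the full inference chain: fit the calibration curve
from the graded-KEAP1 table, estimate residual activity (with bootstrap CI)
for every stressed condition, infer the WT-homodimer inactivated fraction from
the all-WT stressed condition, predict total activity under both inactivation
hypotheses, and select the hypothesis whose prediction falls inside the
observed confidence interval.  The variant screen parses a protein-variant
table, classifies each substitution against the sensor residue map and
evaluates its fail-safe consequence.

Reports are written as JSON (sorted keys, fractions, deterministic for fixed
seed and inputs) and TSV (percentages for human reading); each JSON report
embeds the config hash and seed for audit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import calibration as cal
from .dimer_model import (
    HeterodimerMode,
    InactivationSetting,
    Hypothesis,
    dimer_composition,
    evaluate_hypotheses,
    infer_homodimer_inactivation,
    predict_total_activity,
)
from .sensor_variants import (
    SensorMap,
    VariantCategory,
    VariantParseError,
    classify_variant,
    count_by_category,
    failsafe_oxidative,
    parse_protein_variant,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "DataError",
    "run_dimer_analysis",
    "run_variant_screen",
    "read_calibration_tsv",
    "read_observation_tsv",
]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input tables present but unusable (CLI exit code 3)."""


@dataclass(frozen=True)
class RunConfig:
    calibration_tsv: str | None = None
    observation_tsv: str | None = None
    variant_tsv: str | None = None
    gene: str = "Nqo1"
    wt_allele_fraction: float = 0.5
    mode: HeterodimerMode = HeterodimerMode.PAPER_LINEAR
    n_boot: int = 2000
    seed: int = 1
    wt_condition_label: str = "WT_stressed"
    outdir: str = "."

    def __post_init__(self) -> None:
        if not (0.0 <= self.wt_allele_fraction <= 1.0):
            raise ConfigError("wt_allele_fraction must lie in [0, 1]")
        object.__setattr__(self, "mode", HeterodimerMode(self.mode))

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _require_file(path: str | None, what: str) -> Path:
    if path is None:
        raise ConfigError(f"{what} path is not configured")
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"{what} file not found: {p}")
    return p


def read_calibration_tsv(path: str | Path, gene: str | None = None) -> list[cal.CalibrationPoint]:
    """Read a calibration table (gene, genotype_label, keap1_level_pct, mrna_rel, replicate_id)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "keap1_level_pct", "mrna_rel", "replicate_id"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"calibration table missing columns: {sorted(missing)}")
    if gene is not None:
        df = df[df["gene"] == gene]
    if df.empty:
        raise DataError("calibration table has no usable rows")
    return [
        cal.CalibrationPoint(
            keap1_level=float(r.keap1_level_pct),
            mrna_rel=float(r.mrna_rel),
            replicate_id=str(r.replicate_id),
            gene=str(r.gene),
        )
        for r in df.itertuples()
    ]


def read_observation_tsv(path: str | Path, gene: str | None = None) -> pd.DataFrame:
    """Read an observation table (gene, condition_label, mrna_rel, replicate_id)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition_label", "mrna_rel", "replicate_id"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"observation table missing columns: {sorted(missing)}")
    if gene is not None:
        df = df[df["gene"] == gene]
    if df.empty:
        raise DataError("observation table has no usable rows")
    return df


def _write_json(report: dict, path: Path) -> None:
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def run_dimer_analysis(config: RunConfig) -> dict:
    """Run the full dimer-inactivation inference; returns the verdict report.

    The all-WT stressed condition (``config.wt_condition_label``) anchors the
    WT-homodimer inactivated fraction; every other condition is evaluated
    against both hypothesis predictions for the configured genotype.
    """
    cal_path = _require_file(config.calibration_tsv, "calibration TSV")
    obs_path = _require_file(config.observation_tsv, "observation TSV")
    points = read_calibration_tsv(cal_path, gene=config.gene)
    obs = read_observation_tsv(obs_path, gene=config.gene)

    conditions = list(dict.fromkeys(obs["condition_label"]))
    if config.wt_condition_label not in conditions:
        raise ConfigError(
            f"all-WT stressed condition {config.wt_condition_label!r} absent from "
            "observation table; the inactivated fraction cannot be inferred"
        )

    curve = cal.fit_calibration(points)
    estimates = {}
    for i, label in enumerate(conditions):
        reps = obs.loc[obs["condition_label"] == label, "mrna_rel"].tolist()
        estimates[label] = cal.estimate_activity_ci(
            points,
            reps,
            n_boot=config.n_boot,
            seed=config.seed + i,
            gene=config.gene,
            condition_label=label,
        )

    f_inact = infer_homodimer_inactivation(
        estimates[config.wt_condition_label].activity_point
    )
    population = dimer_composition(config.wt_allele_fraction)

    predictions = {}
    for h in Hypothesis:
        pred = predict_total_activity(
            population, InactivationSetting(f_inact, h, config.mode)
        )
        predictions[h.value] = {
            "total_activity": pred.total_activity,
            "contrib_mut_homo": pred.contrib_mut_homo,
            "contrib_wt_homo": pred.contrib_wt_homo,
            "contrib_het": pred.contrib_het,
        }

    verdicts = {}
    for label, est in estimates.items():
        if label == config.wt_condition_label:
            continue
        v = evaluate_hypotheses(population, f_inact, est, config.mode)
        verdicts[label] = {
            "prediction_monomer": v.prediction_monomer,
            "prediction_dimer": v.prediction_dimer,
            "within_ci": {h.value: ok for h, ok in v.within_ci.items()},
            "selected": v.selected.value,
        }

    report = {
        "analysis": "dimer_inactivation",
        "config_hash": config.digest(),
        "seed": config.seed,
        "gene": config.gene,
        "mode": config.mode.value,
        "units": "fractions in [0,1]",
        "population": {
            "f_wt_homo": population.f_wt_homo,
            "f_het": population.f_het,
            "f_mut_homo": population.f_mut_homo,
        },
        "f_inact": f_inact,
        "calibration_curve": {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "residual_sd": curve.residual_sd,
            "n_points": curve.n_points,
        },
        "estimates": {
            label: {
                "activity_point": e.activity_point,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_boot": e.n_boot,
            }
            for label, e in estimates.items()
        },
        "predictions": predictions,
        "verdicts": verdicts,
    }

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(report, outdir / "dimer_analysis.json")
    rows = []
    for label, v in verdicts.items():
        for h in Hypothesis:
            rows.append(
                {
                    "condition": label,
                    "hypothesis": h.value,
                    "mode": config.mode.value,
                    "prediction_pct": 100.0 * predictions[h.value]["total_activity"],
                    "estimate_pct": 100.0 * estimates[label].activity_point,
                    "ci_low_pct": 100.0 * estimates[label].ci_low,
                    "ci_high_pct": 100.0 * estimates[label].ci_high,
                    "within_ci": v["within_ci"][h.value],
                    "selected": v["selected"],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "dimer_analysis.tsv", sep="\t", index=False)
    return report


def run_variant_screen(config: RunConfig, sensor_map: SensorMap | None = None) -> dict:
    """Parse, classify and fail-safe-evaluate a variant table; returns the report.

    Malformed rows are collected and reported; the run fails only when no row
    parses at all.
    """
    var_path = _require_file(config.variant_tsv, "variant TSV")
    df = pd.read_csv(var_path, sep="\t")
    if "protein_change" not in df.columns:
        raise DataError("variant table missing 'protein_change' column")
    smap = sensor_map or SensorMap()

    parsed, failures, records = [], [], []
    for row in df.itertuples():
        try:
            variant = parse_protein_variant(str(row.protein_change))
        except VariantParseError as exc:
            failures.append({"row": row.Index, "text": str(row.protein_change), "error": str(exc)})
            continue
        cls = classify_variant(variant, smap)
        lost = {variant.position} & set(smap.oxidative_cys)
        fs = failsafe_oxidative(lost, smap)
        parsed.append(variant)
        records.append(
            {
                "protein_change": str(row.protein_change),
                "position": variant.position,
                "ref_aa": variant.ref_aa,
                "alt_aa": variant.alt_aa,
                "category": cls.category.value,
                "destroys_thiol": cls.destroys_thiol,
                "destroys_basicity": cls.destroys_basicity,
                "failsafe_functional": fs.functional,
                "intact_parts": ",".join(sorted(fs.intact_parts)),
            }
        )
    if not parsed:
        raise DataError("no parseable variants in table")

    counts = count_by_category(parsed, smap)
    summary = {cat.value: n for cat, n in counts.items()}
    summary["oxidative_affecting"] = (
        counts[VariantCategory.OXIDATIVE_SENSOR_CYS]
        + counts[VariantCategory.OXIDATIVE_NEIGHBOR_BASIC]
    )

    report = {
        "analysis": "variant_screen",
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_input_rows": int(len(df)),
        "n_parsed": len(parsed),
        "parse_failures": failures,
        "variants": records,
        "category_counts": summary,
    }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(report, outdir / "variant_screen.json")
    pd.DataFrame(records).to_csv(outdir / "variant_screen.tsv", sep="\t", index=False)
    return report
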