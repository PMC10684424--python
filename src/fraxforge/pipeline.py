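"""End-to-end driver: synthetic registry -> national incidence -> calibrated
models -> original-vs-updated comparison report.

The pipeline is a pure function of its configuration (which includes the
seed): the same config produces byte-identical artifacts, recorded in a
manifest of SHA-256 hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import incidence_synthesis as isyn
from . import model_comparison as mc
from . import probability_engine as pe
from . import synthetic_data as sd
from .tables import SEXES

log = logging.getLogger("fraxforge")

DEFAULT_CITIES = [
    ["Belem", "Northeast", 0.6],
    ["Vitoria", "Southeast", 1.0],
    ["Joinville", "South", 1.4],
]


@dataclass
class PipelineConfig:
    seed: int = 1
    cities: list = field(default_factory=lambda: [list(c) for c in DEFAULT_CITIES])
    region_weights: dict = field(
        default_factory=lambda: {"Southeast": 0.42, "Northeast": 0.28, "South": 0.14}
    )
    person_years_per_band: float = 250_000.0
    breakpoints: dict = field(
        default_factory=lambda: {"male": [62.0, 87.0], "female": [62.0, 82.0]}
    )
    total_population_50plus: int = 50_000_000
    gompertz_a: float = 0.004
    gompertz_b: float = 0.085
    sex_offsets: dict = field(
        default_factory=lambda: {"male": 0.45, "female": 0.0}
    )
    #: fracture-incidence scale of the 'updated' model relative to the original
    updated_incidence_scale: float = 0.55
    time_step: str = "annual"
    zero_policy: str = "exclude"
    ti_method: str = "percentile"
    comparison_ages: list = field(default_factory=lambda: [50, 60, 70, 80])
    output_dir: str = "fraxforge_output"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: sd.GroundTruthIncidence
    samples: list
    combined_rates: "isyn.AgeSexRateTable"
    fits: dict
    smoothed_hip: "isyn.AgeSexRateTable"
    burden: isyn.NationalBurden
    mof_tables: dict
    life_tables: dict
    risk_model: pe.RiskFactorModel
    model_original: pe.CalibratedModel
    model_updated: pe.CalibratedModel
    report: mc.ComparisonReport
    pairs: "mc.pd.DataFrame"
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage and (optionally) write all artifacts plus a manifest."""
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage synth: generating city incidence (seed=%d)", config.seed)
    truth = sd.GroundTruthIncidence.default()
    samples = sd.generate_city_incidence(
        truth,
        [tuple(c) for c in config.cities],
        config.person_years_per_band,
        config.seed,
    )
    log.info("stage synth: %d city/sex/band samples", len(samples))

    weights = isyn.RegionWeights(config.region_weights)
    combined = isyn.combine_regions(samples, weights)
    fits = isyn.fit_both_sexes(
        combined,
        {s: tuple(b) for s, b in config.breakpoints.items()},
        zero_policy=config.zero_policy,
    )
    smoothed = isyn.smoothed_rate_table(fits)
    demography = sd.generate_demography(config.total_population_50plus)
    burden = isyn.estimate_national_counts(smoothed, demography)
    log.info(
        "stage incidence: national burden %.0f (men %.0f, women %.0f)",
        burden.total,
        burden.men,
        burden.women,
    )

    ratios = {sex: sd.generate_ratio_table(sex) for sex in SEXES}
    mof_tables = isyn.impute_mof_rates(smoothed, ratios)
    life_tables = {
        sex: sd.generate_life_table(
            config.gompertz_a, config.gompertz_b, config.sex_offsets[sex], sex
        )
        for sex in SEXES
    }
    risk_model = sd.generate_risk_factor_model(config.seed + 1)

    model_original = pe.calibrate(
        smoothed, mof_tables["mof"], life_tables, risk_model
    )
    model_updated = pe.calibrate(
        smoothed.scaled(config.updated_incidence_scale),
        mof_tables["mof"].scaled(config.updated_incidence_scale),
        life_tables,
        risk_model,
    )
    log.info("stage calibrate: two models calibrated")

    report, pairs = mc.compare_models(
        model_original,
        model_updated,
        ages=tuple(config.comparison_ages),
        step=config.time_step,
        ti_method=config.ti_method,
    )
    log.info("stage compare: %d scenario pairs", len(pairs))

    manifest: dict = {"config": config.to_dict(), "files": {}}
    if write:
        sd.write_city_incidence_csv(samples, out / "city_incidence.csv", config.seed)
        sd.write_demography_csv(demography, out / "demography.csv", config.seed)
        for sex, lt in life_tables.items():
            sd.write_life_table_csv(lt, out / f"life_table_{sex}.csv", config.seed)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
        combined.frame.to_csv(out / "combined_rates.csv", index=False)
        smoothed.frame.to_csv(out / "smoothed_hip_rates.csv", index=False)
        mof_tables["mof"].frame.to_csv(out / "mof_rates.csv", index=False)
        for sex, fit in fits.items():
            fit.to_json(out / f"piecewise_fit_{sex}.json")
        with open(out / "national_burden.json", "w") as fh:
            json.dump(
                {
                    "men": burden.men,
                    "women": burden.women,
                    "total": burden.total,
                    "male_share": burden.male_share,
                },
                fh,
                indent=1,
            )
        sd.write_risk_factor_model_json(
            risk_model, out / "risk_factor_model.json", config.seed + 1
        )
        model_original.to_json(out / "model_original.json")
        model_updated.to_json(out / "model_updated.json")
        pairs.to_csv(out / "paired_probabilities.csv", index=False)
        report.to_json(out / "comparison_report.json")
        (out / "comparison_report.txt").write_text(report.to_text())
        config.to_json(out / "config.json")
        for p in sorted(out.iterdir()):
            if p.name != "manifest.json" and p.is_file():
                manifest["files"][p.name] = _sha256(p)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        log.info("stage write: %d artifacts in %s", len(manifest["files"]), out)

    return PipelineResult(
        config=config,
        truth=truth,
        samples=samples,
        combined_rates=combined,
        fits=fits,
        smoothed_hip=smoothed,
        burden=burden,
        mof_tables=mof_tables,
        life_tables=life_tables,
        risk_model=risk_model,
        model_original=model_original,
        model_updated=model_updated,
        report=report,
        pairs=pairs,
        manifest=manifest,
    )
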