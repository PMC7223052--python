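"""End-to-end orchestration: simulate -> filter -> score -> fit -> index.

Each stage hands off through plain files (CSV/JSON) so it can also be run
standalone; a manifest records the seed, a hash of the effective
configuration and the SHA-256 of every artifact, making reruns verifiable
as bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cohort as cohort_mod
from . import index as index_mod
from . import scoring as scoring_mod
from .filtering import apply_inclusion
from .model import DEFAULT_MODEL, ModelSpec
from .params import PopulationParams
from .sem import fit_from_data, save_model

log = logging.getLogger("pwbi.pipeline")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    out_dir: str = "pwbi_run"
    n: int = 1659
    seed: int = 1
    population: dict = field(default_factory=dict)   # PopulationParams overrides
    model_spec_path: str | None = None
    exclusions: str = "random"                       # "random" | "exact" | "none"
    exact_counts: tuple[int, int, int] = (57, 169, 185)
    age_range: tuple[float, float] = (10.0, 14.0)
    kidmed_floor: bool = True
    srmr_diagonal: bool = True
    log_level: str = "INFO"

    def population_params(self) -> PopulationParams:
        return PopulationParams.from_dict(self.population)

    def model_spec(self) -> ModelSpec:
        if self.model_spec_path:
            return ModelSpec.from_yaml(self.model_spec_path)
        return DEFAULT_MODEL

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir, "n": self.n, "seed": self.seed,
            "population": self.population,
            "model_spec_path": self.model_spec_path,
            "exclusions": self.exclusions,
            "exact_counts": list(self.exact_counts),
            "age_range": list(self.age_range),
            "kidmed_floor": self.kidmed_floor,
            "srmr_diagonal": self.srmr_diagonal,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key {k!r}")
            if k in ("exact_counts", "age_range"):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk).

    Artifacts: ``cohort.csv``, ``exclusion_log.json``, ``indicators.csv``,
    ``model.json``, ``reports.csv``, plus ``manifest.json``.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s :: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.population_params()
    spec = config.model_spec()

    log.info("stage=simulate n=%d seed=%d", config.n, config.seed)
    cohort = cohort_mod.generate_cohort(params, config.n, config.seed, spec)
    if config.exclusions == "random":
        cohort = cohort_mod.inject_exclusions(cohort, params, config.seed + 1)
    elif config.exclusions == "exact":
        cohort = cohort_mod.inject_exclusions_exact(cohort, *config.exact_counts)
    cohort_path = out / "cohort.csv"
    cohort_mod.write_cohort(cohort, cohort_path)

    log.info("stage=filter")
    kept, excl_log = apply_inclusion(cohort, config.age_range)
    excl_path = out / "exclusion_log.json"
    excl_log.to_json(excl_path)
    log.info("stage=filter enrolled=%d final=%d", excl_log.n_enrolled, excl_log.n_final)

    log.info("stage=score")
    indicators = scoring_mod.score_cohort(kept, kidmed_floor=config.kidmed_floor)
    ind_path = out / "indicators.csv"
    indicators.to_csv(ind_path, index=False, lineterminator="\n")

    log.info("stage=fit")
    fitted, result = fit_from_data(
        indicators, spec, options={"srmr_diagonal": config.srmr_diagonal}
    )
    log.info("stage=fit chi2=%.2f df=%d rmsea=%.4f cfi=%.4f srmr=%.4f",
             result.chi_square, result.df, result.rmsea, result.cfi, result.srmr)

    log.info("stage=index")
    scores, stats, skipped = index_mod.score_index(indicators, fitted, spec=spec)
    reports_path = out / "reports.csv"
    scores.to_csv(reports_path, index=False, lineterminator="\n", float_format="%.6f")
    model_path = out / "model.json"
    save_model(fitted, result, model_path,
               extra={"reference": stats.to_dict(), "skipped_students": skipped,
                      "seed": config.seed})

    artifacts = {
        "cohort": cohort_path, "exclusion_log": excl_path,
        "indicators": ind_path, "model": model_path, "reports": reports_path,
    }
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "artifacts": {k: {"path": p.name, "sha256": _sha256(p)}
                      for k, p in artifacts.items()},
        "n_final": excl_log.n_final,
        "converged": result.converged,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
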