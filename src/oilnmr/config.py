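"""Run configuration: one YAML-serialisable object drives the whole study."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic_oils import AcquisitionSettings, OilSpec, StudyDesign

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on.

    ``oil_overrides`` maps oil names to partial OilSpec fields (T2 centres,
    fractions, log width) layered over the default library. Split counts are
    calibration sizes per series label; the remainder of each group
    validates. ``include_pure`` controls whether 0 %/100 % samples enter the
    regression sets.
    """

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    oil_overrides: dict = field(default_factory=dict)
    simca_calibration_counts: dict = field(default_factory=lambda: {
        "AO": 15, "AO-SO": 42, "AO-CO": 42, "AO-RO": 42,
    })
    simca_alpha: float = 0.05
    simca_max_components: int = 7
    # one common component count keeps the class distances comparable (class
    # models of such oils typically retain 5-7 PCs); None re-enables per-class
    # Q2 selection
    simca_n_components: int | None = 7
    cv_folds: int = 7
    plsr_max_latent: int = 10
    include_pure: bool = True
    svr_grid: dict | None = None  # None = DEFAULT_SVR_GRID
    write_decays: bool = False
    outdir: str = "oilnmr-run"

    def validate(self) -> None:
        if not 0 < self.simca_alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.plsr_max_latent < 1:
            raise ValueError("plsr_max_latent must be positive")
        available = {
            "AO": len(self.design.ao_brands) * self.design.pure_ao_replicates,
        }
        per_series = len(self.design.mixture_levels) * self.design.mixture_replicates
        for adt in self.design.adulterants:
            available[f"AO-{adt}"] = per_series
        for label, want in self.simca_calibration_counts.items():
            if label not in available:
                raise ValueError(f"split names unknown group {label!r}")
            if want <= 0:
                raise ValueError(f"calibration count for {label!r} must be positive")
            if want >= available[label]:
                raise ValueError(
                    f"group {label!r}: calibration count {want} leaves no validation "
                    f"samples out of {available[label]}")

    def to_yaml(self, path: str | Path) -> None:
        def listify(d: dict) -> dict:
            return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

        payload = listify(asdict(self))
        payload["design"] = listify(asdict(self.design))
        payload["acquisition"] = asdict(self.acquisition)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    payload: dict = {}
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    payload.update(overrides)
    design_kw = payload.pop("design", {})
    acq_kw = payload.pop("acquisition", {})
    if isinstance(design_kw, StudyDesign):
        design = design_kw
    else:
        if "ao_brands" in design_kw:
            design_kw["ao_brands"] = tuple(design_kw["ao_brands"])
        if "adulterants" in design_kw:
            design_kw["adulterants"] = tuple(design_kw["adulterants"])
        if "mixture_levels" in design_kw:
            design_kw["mixture_levels"] = tuple(design_kw["mixture_levels"])
        design = StudyDesign(**design_kw)
    acquisition = acq_kw if isinstance(acq_kw, AcquisitionSettings) else AcquisitionSettings(**acq_kw)
    config = RunConfig(design=design, acquisition=acquisition, **payload)
    config.validate()
    return config
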