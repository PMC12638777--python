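"""Scenario configuration and model parameters.

``ScenarioConfig`` gathers every threshold and factor of the pipeline in
one place so scenarios and sensitivity sweeps are config-only changes.
YAML round-trips carry a ``schema_version`` key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = 1


@dataclass
class N2OParams:
    """Parameters of the exponential direct-N2O response and the IPCC
    indirect pathway.

    The four exponential-model parameters are calibration constants of the
    fitted emission-response curve; the shipped defaults are synthetic
    placeholders chosen to give field-plausible magnitudes (~0.45 kg
    N2O-N ha-1 yr-1 unfertilised, ~2.5 kg at 200 kg N ha-1) and should be
    replaced with fitted values for real-data use. Indirect factors are the
    IPCC 2006 defaults (EF4 volatilisation, EF5 leaching, FracGASF,
    FracLEACH).
    """

    mu0: float = -1.2
    sigma0: float = 0.8944271909999159  # sigma0^2 = 0.8
    mu1: float = 0.008
    sigma1: float = 0.0022
    ef_volatilization: float = 0.010
    ef_leaching: float = 0.0075
    frac_volatilized: float = 0.10
    frac_leached: float = 0.30

    def validate(self) -> None:
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigma0 and sigma1 must be positive")
        for name in (
            "ef_volatilization", "ef_leaching",
            "frac_volatilized", "frac_leached",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class ScenarioConfig:
    """All thresholds, factors and switches of one scenario run.

    ``use_mode`` I (intensify mosaic) / E (extensify pure);
    ``switch_strategy`` HC (highest calorie yield) / HS (highest current
    harvested area); ``reveg_option`` N (natural regrowth everywhere) / NA
    (regrowth inside biodiversity-priority or water-scarce areas,
    afforestation elsewhere).
    """

    use_mode: str = "I"
    switch_strategy: str = "HC"
    reveg_option: str = "N"
    slope_threshold_deg: float = 8.0
    z_min: float = -2.0
    z_max: float = -0.5
    z_center: float = -1.25
    z_sigma: float = 0.375
    frag_max_patch_px: int = 1
    frag_same_class_only: bool = False
    elevation_max_m: float = 800.0
    npcd_window: int = 13
    mosaic_crop_fraction: float = 0.5
    harvest_rate: float = 1.0
    waste: float = 0.17
    veg_pulse_share: float = 0.10
    gwp100_n2o: float = 273.0
    branch_factor: float = 1.2
    forestry_emis_reveg_tco2_ha: float = 0.30
    forestry_emis_mosaic_tco2_ha: float = 0.15
    amortization_yr: int = 30
    plantation_richness_factor: float = 0.71
    mosaic_richness_factor: float = 1.30
    cap_mosaic_richness: bool = True
    degradation_risk_min: int = 2
    seed: int = 0
    n2o: N2OParams = field(default_factory=N2OParams)

    def validate(self) -> None:
        if self.use_mode not in ("I", "E"):
            raise ValueError("use_mode must be 'I' or 'E'")
        if self.switch_strategy not in ("HC", "HS"):
            raise ValueError("switch_strategy must be 'HC' or 'HS'")
        if self.reveg_option not in ("N", "NA"):
            raise ValueError("reveg_option must be 'N' or 'NA'")
        if self.npcd_window < 3 or self.npcd_window % 2 == 0:
            raise ValueError("npcd_window must be odd and >= 3")
        for name in ("harvest_rate", "waste", "veg_pulse_share",
                     "mosaic_crop_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("branch_factor", "gwp100_n2o", "amortization_yr",
                     "plantation_richness_factor", "mosaic_richness_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.n2o.validate()

    @property
    def scenario_name(self) -> str:
        return f"{self.use_mode}-{self.switch_strategy}-{self.reveg_option}"

    def replace(self, **kw) -> "ScenarioConfig":
        data = asdict(self)
        n2o_kw = {
            k: v for k, v in kw.items() if k in N2OParams.__dataclass_fields__
        }
        data.update({k: v for k, v in kw.items() if k not in n2o_kw})
        data["n2o"].update(n2o_kw)
        data["n2o"] = N2OParams(**data["n2o"])
        cfg = ScenarioConfig(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["schema_version"] = SCHEMA_VERSION
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text())
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        n2o = N2OParams(**data.pop("n2o", {}))
        cfg = cls(n2o=n2o, **data)
        cfg.validate()
        return cfg
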