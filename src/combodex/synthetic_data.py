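"""Synthetic combination-screen generator with known ground truth.

Every analysis stage in the pipeline can be exercised against data whose
generating parameters are known exactly:

* single agents follow the median-effect model (Dm, m) with
  multiplicative lognormal replicate noise,
* fixed-ratio combinations follow one of three ground-truth interaction
  modes — ``loewe`` (dose additivity, the CI = 1 null), ``bliss``
  (probabilistic independence, the delta-Bliss = 0 null) or
  ``potency_shift`` (component doses act as if multiplied by
  ``interaction_strength`` s, which makes the true CI equal 1/s at every
  effect level),
* marker panels are drawn around configured group means, and qPCR Ct
  tables are built to encode configured fold changes exactly in the
  noise-free case.

All draws come from a numpy PCG64 ``default_rng`` seeded from the config,
so identical configs give identical records.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.optimize import brentq

from combodex.errors import ConfigError
from combodex.markers import MarkerPanel, QPCRMeasurement
from combodex.median_effect import MedianEffectFit, effect_at_dose
from combodex.plate_io import WellRecord

INTERACTION_MODES = ("loewe", "bliss", "potency_shift")


class DrugParams(BaseModel):
    """Median-effect ground truth for one agent."""

    model_config = ConfigDict(frozen=True)

    name: str
    dm: float = Field(gt=0)
    m: float = Field(gt=0)

    def fit(self) -> MedianEffectFit:
        return MedianEffectFit(dm=self.dm, m=self.m, r=1.0, n_points=0)


class MarkerSpec(BaseModel):
    units: str = "fold_of_control"
    group_means: dict[str, float]
    cv: float = Field(default=0.0, ge=0.0, lt=0.5)

    @field_validator("group_means")
    @classmethod
    def _nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        if any(x < 0 for x in v.values()):
            raise ValueError("group means must be non-negative")
        return v


class QPCRSpec(BaseModel):
    #: fold change per non-control group (2^-ddCt scale)
    group_folds: dict[str, float]
    ct_reference: float = Field(default=16.0, ge=1.0, le=45.0)
    ct_target_control: float = Field(default=24.0, ge=1.0, le=45.0)
    ct_noise_sd: float = Field(default=0.0, ge=0.0)

    @field_validator("group_folds")
    @classmethod
    def _positive(cls, v: dict[str, float]) -> dict[str, float]:
        if any(x <= 0 for x in v.values()):
            raise ValueError("fold changes must be positive")
        return v


class SyntheticConfig(BaseModel):
    """Full specification of one synthetic screen.

    Defaults mirror the packaged study design: a 10:1 fixed-ratio
    combination, six-point single-agent dose grids, biological
    triplicates, and 5 % multiplicative replicate noise.
    """

    drug_a: DrugParams
    drug_b: DrugParams
    #: mixing weights of the fixed-ratio design (normalized internally)
    ratio: tuple[float, float] = (10.0, 1.0)
    dose_grid_a: tuple[float, ...]
    dose_grid_b: tuple[float, ...]
    #: combination TOTAL doses (component doses follow from ratio)
    dose_grid_combo: tuple[float, ...]
    interaction_mode: str = "loewe"
    interaction_strength: float = Field(default=1.0, gt=0.0)
    noise_cv: float = Field(default=0.05, ge=0.0, lt=0.5)
    n_replicates: int = Field(default=3, ge=1)
    seed: int = 0
    marker_spec: dict[str, MarkerSpec] = Field(default_factory=dict)
    qpcr_spec: dict[str, QPCRSpec] = Field(default_factory=dict)

    @field_validator("dose_grid_a", "dose_grid_b", "dose_grid_combo")
    @classmethod
    def _increasing_positive(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(d <= 0 for d in v):
            raise ValueError("dose grids must be strictly positive")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("dose grids must be strictly increasing")
        return v

    @field_validator("interaction_mode")
    @classmethod
    def _known_mode(cls, v: str) -> str:
        if v not in INTERACTION_MODES:
            raise ValueError(
                f"unknown interaction_mode {v!r}; expected one of {INTERACTION_MODES}")
        return v

    def weights(self) -> tuple[float, float]:
        s = self.ratio[0] + self.ratio[1]
        return self.ratio[0] / s, self.ratio[1] / s


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Study-like default screen: agents with the potency gap and dose
    grids of the packaged Q/GEM design, 10:1 fixed ratio, n = 3, 5 % CV."""
    base = dict(
        drug_a=DrugParams(name="Q", dm=85.0, m=1.3),
        drug_b=DrugParams(name="GEM", dm=6.5, m=1.0),
        ratio=(10.0, 1.0),
        dose_grid_a=(10.0, 20.0, 40.0, 80.0, 100.0),
        dose_grid_b=(1.0, 2.0, 4.0, 8.0, 10.0),
        dose_grid_combo=(11.0, 22.0, 44.0, 88.0, 110.0),
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


# ------------------------------------------------------------------ Loewe

def loewe_effect(
    fit_a: MedianEffectFit, fit_b: MedianEffectFit, d1: float, d2: float
) -> float:
    """Effect of a dose pair under Loewe additivity.

    Solves d1/Dx1(fa) + d2/Dx2(fa) = 1 for fa by bracketed root finding;
    the residual is strictly decreasing in fa for positive slopes, so the
    root is unique.  Reduces to the single-agent effect when one dose is
    zero.
    """
    if d1 < 0 or d2 < 0 or d1 + d2 <= 0:
        raise ValueError("doses must be non-negative with positive sum")
    if fit_a.m <= 0 or fit_b.m <= 0:
        raise ValueError("Loewe additivity requires positive slopes")
    if d2 == 0:
        return effect_at_dose(fit_a, d1)
    if d1 == 0:
        return effect_at_dose(fit_b, d2)

    # solve in log10-odds: uniformly well-conditioned even when the root
    # sits very close to fa = 0 or 1, where the fa-space residual is steep
    def residual(t: float) -> float:
        odds = 10.0 ** t
        dx1 = fit_a.dm * odds ** (1.0 / fit_a.m)
        dx2 = fit_b.dm * odds ** (1.0 / fit_b.m)
        return d1 / dx1 + d2 / dx2 - 1.0

    t = brentq(residual, -30.0, 30.0, xtol=1e-12, maxiter=200)
    odds = 10.0 ** t
    return float(odds / (1.0 + odds))


def _true_combo_effect(config: SyntheticConfig, total_dose: float) -> float:
    wa, wb = config.weights()
    d1, d2 = total_dose * wa, total_dose * wb
    fa_fit = config.drug_a.fit()
    fb_fit = config.drug_b.fit()
    mode = config.interaction_mode
    if mode == "loewe":
        return loewe_effect(fa_fit, fb_fit, d1, d2)
    if mode == "bliss":
        ea = effect_at_dose(fa_fit, d1)
        eb = effect_at_dose(fb_fit, d2)
        return ea + eb - ea * eb
    if mode == "potency_shift":
        s = config.interaction_strength
        return loewe_effect(fa_fit, fb_fit, d1 * s, d2 * s)
    raise ConfigError(f"unknown interaction_mode {mode!r}")


# ------------------------------------------------------------- simulation

def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # separate deterministic stream per output table
    return np.random.default_rng([config.seed, stream])


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.log(1.0 + cv)
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_single_agent(config: SyntheticConfig, drug: str = "a") -> list[WellRecord]:
    """Well records for one agent: dose-0 controls plus n replicates per
    grid dose, viability = 100*(1 - fa) times multiplicative noise."""
    if drug not in ("a", "b"):
        raise ValueError("drug selector must be 'a' or 'b'")
    params = config.drug_a if drug == "a" else config.drug_b
    grid = config.dose_grid_a if drug == "a" else config.dose_grid_b
    rng = _rng(config, 1 if drug == "a" else 2)
    records: list[WellRecord] = []
    doses = [0.0] + list(grid)
    for dose in doses:
        fa = 0.0 if dose == 0 else effect_at_dose(params.fit(), dose)
        clean = 100.0 * (1.0 - fa)
        noise = _noise_factors(rng, config.noise_cv, config.n_replicates)
        for rep in range(config.n_replicates):
            records.append(
                WellRecord(agent_a=params.name if dose > 0 else "control",
                           dose_a=dose, replicate=rep + 1,
                           response=max(0.0, clean * noise[rep]),
                           response_kind="percent_viability")
            )
    return records


def simulate_combination(config: SyntheticConfig) -> list[WellRecord]:
    """Fixed-ratio combination wells with the configured interaction mode
    as ground truth."""
    rng = _rng(config, 3)
    wa, wb = config.weights()
    records: list[WellRecord] = []
    for total in config.dose_grid_combo:
        fa = _true_combo_effect(config, total)
        clean = 100.0 * (1.0 - fa)
        noise = _noise_factors(rng, config.noise_cv, config.n_replicates)
        for rep in range(config.n_replicates):
            records.append(
                WellRecord(agent_a=config.drug_a.name, dose_a=total * wa,
                           agent_b=config.drug_b.name, dose_b=total * wb,
                           replicate=rep + 1,
                           response=max(0.0, clean * noise[rep]),
                           response_kind="percent_viability")
            )
    return records


def simulate_screen(config: SyntheticConfig) -> list[WellRecord]:
    """Controls + both single agents + combination, one tidy table."""
    return (simulate_single_agent(config, "a")
            + [r for r in simulate_single_agent(config, "b") if r.dose_a > 0]
            + simulate_combination(config))


def simulate_markers(config: SyntheticConfig) -> list[MarkerPanel]:
    """Marker panels with replicate values drawn around the configured
    group means at the configured CV (exactly the means when CV = 0)."""
    rng = _rng(config, 4)
    panels = []
    for marker in sorted(config.marker_spec):
        spec = config.marker_spec[marker]
        groups = {}
        for group in spec.group_means:
            mean = spec.group_means[group]
            noise = _noise_factors(rng, spec.cv, config.n_replicates)
            groups[group] = [float(mean * f) for f in noise]
        panels.append(MarkerPanel(marker=marker, units=spec.units, groups=groups))
    return panels


def simulate_qpcr(config: SyntheticConfig) -> list[QPCRMeasurement]:
    """Ct tables constructed so 2^-ddCt recovers the configured folds:
    Ct_target(group) = Ct_target(control) - log2(fold) (+ optional
    Gaussian Ct noise)."""
    rng = _rng(config, 5)
    out: list[QPCRMeasurement] = []
    for gene in sorted(config.qpcr_spec):
        spec = config.qpcr_spec[gene]
        groups = {"control": 0.0}
        groups.update({g: math.log2(f) for g, f in spec.group_folds.items()})
        for group, logfold in groups.items():
            ct_clean = spec.ct_target_control - logfold
            for _ in range(config.n_replicates):
                jitter = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0
                out.append(QPCRMeasurement(group=group, target=gene,
                                           ct_target=ct_clean + jitter,
                                           ct_reference=spec.ct_reference))
    return out
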