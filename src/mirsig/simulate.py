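"""Synthetic qPCR cohort generator.

Emulates a TaqMan-style array-card experiment on plasma extracellular-vesicle
RNA: ~754 microRNA assays measured on a patient and a control group, with a
small set of planted group-differential assays, per-sample global Ct offsets
(library/loading effects), Gaussian measurement noise, right-censoring of
weak signals as "Undetermined", exogenous spike-in assays and the two
hemolysis-marker assays (miR-23a, miR-451).

The additive model on the Ct (log2-expression) scale, for assay ``f`` and
sample ``s``::

    Ct[f, s] = baseline(f) - effect(f) * 1[s is patient] + offset(s) + eps

with ``eps ~ Normal(0, noise_sd)``.  A positive effect means *lower* Ct,
i.e. higher expression, in patients (expression is proportional to
``2**(-Ct)``).  Values above the censoring limit are recorded as
Undetermined.  Spike-ins carry no group effect and no sample offset, so
normalization against them is exactly recoverable.  Hemolysis is simulated
by lowering Ct(miR-451) in affected samples so that the miR-23a/miR-451
cycle difference exceeds the QC threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ConfigurationError, CtMatrix, SampleSheet

# Planted signature assays: three up-regulated in patients (lower Ct) and one
# down-regulated, mirroring a typical small diagnostic panel.
DEFAULT_SIGNATURE_EFFECTS: dict[str, float] = {
    "hsa-miR-412-3p": 3.0,
    "hsa-miR-507": 3.0,
    "hsa-miR-1203": 3.0,
    "hsa-miR-362-3p": -3.0,
}

SPIKEIN_NAMES = ("ath-miR-159a", "cel-miR-254", "osa-miR-414")
SPIKEIN_BASELINE_CT = 20.0

HEMOLYSIS_MARKER_A = "miR-23a"  # stable in plasma
HEMOLYSIS_MARKER_B = "miR-451"  # red-blood-cell enriched
MARKER_BASELINES = {HEMOLYSIS_MARKER_A: 24.0, HEMOLYSIS_MARKER_B: 20.0}
# Ct(miR-451) is lowered by this much in hemolyzed samples; baseline delta is
# 4 cycles, so hemolyzed samples show delta = 12 > the fail threshold of 7.
HEMOLYSIS_SHIFT = 8.0


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the discovery-cohort structure used throughout the
    tests: 754 assays, 16 patients vs 22 controls, four planted assays with
    a 3-cycle group effect, 0.5-cycle measurement noise and 0.5-cycle
    per-sample offsets.
    """

    n_assays: int = 754
    n_patients: int = 16
    n_controls: int = 22
    signature_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_EFFECTS)
    )
    baseline_ct_range: tuple[float, float] = (20.0, 33.0)
    # Planted assays draw baselines from a narrower range so that they remain
    # quantifiable (Ct <= 33) after effects up to +-4 cycles plus noise.
    signature_baseline_range: tuple[float, float] = (22.0, 27.0)
    sample_offset_sd: float = 0.5
    noise_sd: float = 0.5
    censor_informative_at: float = 33.0
    censor_undetermined_at: float = 40.0
    n_spikeins: int = 3
    hemolysis_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_assays, self.n_patients, self.n_controls, self.n_spikeins) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.sample_offset_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if not self.censor_informative_at < self.censor_undetermined_at:
            raise ConfigurationError(
                "censor_informative_at must be below censor_undetermined_at"
            )
        if not 0 <= self.hemolysis_fraction <= 1:
            raise ConfigurationError("hemolysis_fraction must be in [0, 1]")
        n_fixed = (
            len(self.signature_effects)
            + len(MARKER_BASELINES)
            + min(self.n_spikeins, len(SPIKEIN_NAMES))
        )
        if n_fixed > self.n_assays:
            raise ConfigurationError(
                f"{n_fixed} named assays exceed n_assays={self.n_assays}"
            )


@dataclass
class Truth:
    """The planted structure of a synthetic cohort."""

    effects: dict[str, float]
    hemolyzed_samples: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"effects": self.effects, "hemolyzed_samples": self.hemolyzed_samples},
                indent=2,
            )
        )


@dataclass
class SyntheticCohort:
    ct_matrix: CtMatrix
    sample_sheet: SampleSheet
    truth: Truth

    def write(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ct_matrix": str(out / "ct_matrix.tsv"),
            "sample_sheet": str(out / "samples.csv"),
            "truth": str(out / "truth.json"),
        }
        self.ct_matrix.to_tsv(paths["ct_matrix"])
        self.sample_sheet.to_csv(paths["sample_sheet"])
        self.truth.to_json(paths["truth"])
        return paths


def _platform(config: SimulationConfig) -> tuple[pd.Index, np.ndarray, tuple[str, ...]]:
    """Assay universe and per-assay baseline Ct values.

    Baselines are an assay property shared between cohorts measured on the
    same platform, so they are drawn from a stream keyed only on the config
    seed (independent of the per-cohort sample stream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA55A]))
    spikeins = SPIKEIN_NAMES[: min(config.n_spikeins, len(SPIKEIN_NAMES))]
    named = (
        list(config.signature_effects) + list(MARKER_BASELINES) + list(spikeins)
    )
    n_fill = config.n_assays - len(named)
    fillers = [f"miR-sim-{i:04d}" for i in range(n_fill)]
    names = pd.Index(named + fillers, name="assay")

    lo, hi = config.baseline_ct_range
    slo, shi = config.signature_baseline_range
    baselines = np.empty(config.n_assays)
    k = len(config.signature_effects)
    baselines[:k] = rng.uniform(slo, shi, size=k)
    for j, m in enumerate(MARKER_BASELINES.values()):
        baselines[k + j] = m
    baselines[k + 2 : len(named)] = SPIKEIN_BASELINE_CT
    baselines[len(named):] = rng.uniform(lo, hi, size=n_fill)
    return names, baselines, spikeins


def _draw_cohort(
    config: SimulationConfig,
    effects: dict[str, float],
    n_patients: int,
    n_controls: int,
    sample_seed: int,
    cohort: str,
    id_prefix: str,
) -> SyntheticCohort:
    names, baselines, spikeins = _platform(config)
    unknown = set(effects) - set(names)
    if unknown:
        raise ConfigurationError(
            f"planted assays not in the assay universe: {sorted(unknown)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(sample_seed), 0x5EED]))

    n = n_patients + n_controls
    sample_ids = [f"{id_prefix}-P{i + 1:02d}" for i in range(n_patients)] + [
        f"{id_prefix}-C{i + 1:02d}" for i in range(n_controls)
    ]
    is_patient = np.array([1] * n_patients + [0] * n_controls, dtype=float)

    offsets = rng.normal(0.0, config.sample_offset_sd, size=n)
    hemolyzed = rng.random(n) < config.hemolysis_fraction
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_assays, n))

    effect_vec = np.array([effects.get(a, 0.0) for a in names])
    offset_free = np.array([a in spikeins for a in names])

    ct = (
        baselines[:, None]
        - effect_vec[:, None] * is_patient[None, :]
        + np.where(offset_free[:, None], 0.0, offsets[None, :])
        + noise
    )
    if hemolyzed.any() and HEMOLYSIS_MARKER_B in names:
        b = names.get_loc(HEMOLYSIS_MARKER_B)
        ct[b, hemolyzed] -= HEMOLYSIS_SHIFT

    values = pd.DataFrame(ct, index=names, columns=sample_ids)
    values = values.mask(values > config.censor_undetermined_at)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": ["patient"] * n_patients + ["control"] * n_controls,
                "cohort": cohort,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    ) if n else SampleSheet(
        pd.DataFrame({"group": [], "cohort": []}, index=pd.Index([], name="sample_id"))
    )

    truth = Truth(
        effects=dict(effects),
        hemolyzed_samples=[s for s, h in zip(sample_ids, hemolyzed) if h],
    )
    return SyntheticCohort(CtMatrix(values, spikeins), sheet, truth)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a seeded discovery-style cohort; same seed, same output."""
    config.validate()
    return _draw_cohort(
        config,
        config.signature_effects,
        config.n_patients,
        config.n_controls,
        sample_seed=config.seed,
        cohort="discovery",
        id_prefix="D",
    )


def simulate_validation_cohort(
    config: SimulationConfig,
    truth: Truth,
    n_patients: int | None = None,
    n_controls: int | None = None,
    seed: int | None = None,
    effects_override: dict[str, float] | None = None,
) -> SyntheticCohort:
    """New samples from the same platform and planted effects, fresh noise.

    The assay universe (names and baselines) is that of ``config``; planted
    effects default to those recorded in ``truth``.  Offsets, noise and
    hemolysis status are redrawn under a new seed.
    """
    config.validate()
    effects = dict(truth.effects if effects_override is None else effects_override)
    return _draw_cohort(
        config,
        effects,
        config.n_patients if n_patients is None else n_patients,
        config.n_controls if n_controls is None else n_controls,
        sample_seed=(config.seed + 1_000_003) if seed is None else seed,
        cohort="validation",
        id_prefix="V",
    )


def with_overrides(config: SimulationConfig, **kwargs) -> SimulationConfig:
    return replace(config, **kwargs)
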