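"""Synthetic data with known ground truth for every pipeline input.

Three generators emulate the statistical structure the analysis assumes:

* :func:`generate_intensity_matrix` — a two-group LC-MS-like sample x
  metabolite matrix: log-normal baseline intensities, a planted fraction
  of differential metabolites with additive log2-scale effects (split
  between up and down), and per-entry missingness (completely-at-random
  by default, or abundance-biased left-censoring).
* :func:`generate_panel` — a quantified plasma panel (glucose, lactate,
  beta-HB, NADH) as zero-truncated normal draws around group means with a
  stated coefficient of variation.
* :func:`generate_flux_scenario` — a strictly positive flux vector that
  satisfies every internal pseudo-steady-state balance exactly, plus the
  boundary concentrations it implies under the concentration-to-rate
  proxy, with optional multiplicative measurement noise.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space

from .chemometrics import METABOLITE_CLASSES, IntensityMatrix
from .flux import (
    FluxResults,
    NetworkModel,
    NetworkError,
    build_stoich_matrix,
)

__all__ = [
    "SyntheticMetabolomeConfig",
    "SyntheticTruth",
    "PanelScenario",
    "DEFAULT_PANEL_SCENARIO",
    "generate_intensity_matrix",
    "generate_panel",
    "generate_flux_scenario",
]


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {fieldname}: {msg}")


@dataclass(frozen=True)
class SyntheticMetabolomeConfig:
    """World definition for the synthetic untargeted metabolome.

    ``effect_log2`` is the magnitude of the planted between-group log2
    difference; a (lo, hi) tuple draws each effect uniformly in that
    range.  ``base_log_mean`` / ``base_log_sd`` are on the log2 scale
    (intensities are 2**x); ``up_fraction`` controls how planted effects
    split between up- and down-regulation.
    """

    n_per_group: int = 6
    n_metabolites: int = 300
    frac_differential: float = 0.2
    effect_log2: float | tuple[float, float] = 2.0
    base_log_mean: float = 20.0
    base_log_sd: float = 0.8
    missing_rate: float = 0.1
    missing_mode: str = "mcar"  # or "censor": abundance-biased
    up_fraction: float = 0.5
    n_classes: int = len(METABOLITE_CLASSES)
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_per_group >= 3, "n_per_group", "must be >= 3")
        _check(self.n_metabolites >= 1, "n_metabolites", "must be >= 1")
        _check(0 <= self.frac_differential <= 1, "frac_differential", "must be in [0, 1]")
        _check(0 <= self.missing_rate < 1, "missing_rate", "must be in [0, 1)")
        _check(self.missing_mode in ("mcar", "censor"), "missing_mode", "must be mcar or censor")
        _check(0 <= self.up_fraction <= 1, "up_fraction", "must be in [0, 1]")
        _check(self.base_log_sd > 0, "base_log_sd", "must be > 0")
        _check(1 <= self.n_classes <= len(METABOLITE_CLASSES), "n_classes",
               f"must be in [1, {len(METABOLITE_CLASSES)}]")
        eff = self.effect_log2
        if isinstance(eff, tuple):
            _check(len(eff) == 2 and 0 <= eff[0] <= eff[1], "effect_log2",
                   "range must satisfy 0 <= lo <= hi")
        else:
            _check(eff >= 0, "effect_log2", "must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth carried alongside generated data."""

    differential_effects: dict[str, float] = field(default_factory=dict)
    panel_group_means: dict[str, dict[str, float]] = field(default_factory=dict)
    true_fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def differential_ids(self) -> set[str]:
        return set(self.differential_effects)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def generate_intensity_matrix(
    config: SyntheticMetabolomeConfig,
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Generate a two-group intensity matrix with planted differentials.

    Samples are labelled ``low``/``high``; planted metabolites get a
    signed log2-scale group-mean shift of magnitude ``effect_log2``
    (positive = higher in the high group).  Missing entries are NaN.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_per_group, config.n_metabolites

    met_ids = [f"M{j + 1:04d}" for j in range(p)]
    sample_ids = [f"low_{i + 1}" for i in range(n)] + [f"high_{i + 1}" for i in range(n)]
    groups = pd.Series(["low"] * n + ["high"] * n, index=sample_ids)
    classes = pd.Series(
        rng.choice(METABOLITE_CLASSES[: config.n_classes], size=p), index=met_ids
    )

    n_diff = round(config.frac_differential * p)
    diff_idx = rng.choice(p, size=n_diff, replace=False)
    n_up = round(config.up_fraction * n_diff)
    signs = np.array([1.0] * n_up + [-1.0] * (n_diff - n_up))
    if isinstance(config.effect_log2, tuple):
        mags = rng.uniform(config.effect_log2[0], config.effect_log2[1], size=n_diff)
    else:
        mags = np.full(n_diff, float(config.effect_log2))
    effects = np.zeros(p)
    effects[diff_idx] = signs * mags

    base = rng.normal(config.base_log_mean, 2.0, size=p)  # metabolite-level spread
    group_sign = np.where(groups.to_numpy() == "high", 0.5, -0.5)  # +/- half effect
    log2x = (
        base[None, :]
        + np.outer(group_sign, effects)
        + rng.normal(0.0, config.base_log_sd, size=(2 * n, p))
    )
    values = pd.DataFrame(np.exp2(log2x), index=sample_ids, columns=met_ids)

    if config.missing_rate > 0:
        if config.missing_mode == "mcar":
            mask = rng.random(size=values.shape) < config.missing_rate
        else:
            # left-censoring: probability decreases with global intensity rank,
            # mean probability equals missing_rate
            flat = values.to_numpy().ravel()
            pct = stats.rankdata(flat).reshape(values.shape) / flat.size
            prob = np.clip(2 * config.missing_rate * (1 - pct), 0, 1)
            mask = rng.random(size=values.shape) < prob
        values = values.mask(mask)

    truth = SyntheticTruth(
        differential_effects={met_ids[j]: float(effects[j]) for j in sorted(diff_idx)}
    )
    matrix = IntensityMatrix(values, groups, classes, group_order=("low", "high"))
    return matrix, truth


# ---------------------------------------------------------------------------
# quantified panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelScenario:
    """Group means, CV and per-group n for the quantified plasma panel.

    ``group_means`` maps metabolite -> {"low": mean, "high": mean} in
    umol/mL plasma; values are drawn from a normal truncated at zero with
    sd = CV * mean.
    """

    group_means: Mapping[str, Mapping[str, float]]
    cv: float = 0.15
    n_per_group: int = 8
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_per_group >= 2, "n_per_group", "must be >= 2")
        _check(self.cv >= 0, "cv", "must be >= 0")
        for met, means in self.group_means.items():
            for grp in ("low", "high"):
                _check(grp in means, "group_means", f"{met}: missing group {grp!r}")
                _check(means[grp] > 0, "group_means", f"{met}/{grp}: mean must be > 0")


#: Stated world for the four-metabolite plasma panel (umol/mL):
#: high-elevation glucose +37%, lactate -32%, beta-HB -33%, NADH ~unchanged.
DEFAULT_PANEL_SCENARIO = PanelScenario(
    group_means={
        "glucose": {"low": 5.0, "high": 5.0 * 1.37},
        "lactate": {"low": 2.5, "high": 2.5 * 0.68},
        "beta_HB": {"low": 0.45, "high": 0.45 * 0.67},
        "NADH": {"low": 0.05, "high": 0.05},
    },
    cv=0.15,
    n_per_group=8,
    seed=0,
)


def generate_panel(scenario: PanelScenario = DEFAULT_PANEL_SCENARIO) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the long-format panel table (individual, group, metabolite,
    concentration) from a scenario; zero-truncated normal per group."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for met, means in scenario.group_means.items():
        for grp in ("low", "high"):
            mu = float(means[grp])
            sd = scenario.cv * mu
            if sd == 0:
                vals = np.full(scenario.n_per_group, mu)
            else:
                a = (0.0 - mu) / sd  # truncate at zero
                vals = stats.truncnorm.rvs(
                    a, np.inf, loc=mu, scale=sd, size=scenario.n_per_group,
                    random_state=rng,
                )
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "individual": f"{grp}_{i + 1}",
                        "group": grp,
                        "metabolite": met,
                        "concentration": float(v),
                    }
                )
    truth = SyntheticTruth(
        panel_group_means={m: dict(v) for m, v in scenario.group_means.items()}
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# flux scenario
# ---------------------------------------------------------------------------

def generate_flux_scenario(
    network: NetworkModel,
    seed: int = 0,
    noise_frac: float = 0.0,
    reference_concentration: float = 5.0,
    max_tries: int = 1000,
) -> tuple[FluxResults, dict[str, float]]:
    """Sample a ground-truth flux vector and the measurements it implies.

    A random positive vector is projected onto the null space of the
    internal pseudo-steady-state balance rows and rescaled so the
    reference reaction carries flux 100; candidates with nonpositive
    irreversible fluxes are rejected and resampled.  Boundary
    concentrations are then the inverse of the concentration-to-rate
    proxy, C_m = |S_m . r| / scale * C_ref, with multiplicative log-normal
    noise of scale ``noise_frac``.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if not network.boundary_ids:
        raise NetworkError("network has no boundary_measured node")
    rng = np.random.default_rng(seed)
    S = build_stoich_matrix(network)
    S_int = S.loc[network.internal_ids].to_numpy() if network.internal_ids else np.zeros(
        (0, len(network.reaction_ids))
    )
    N = null_space(S_int) if S_int.size else np.eye(len(network.reaction_ids))
    if N.shape[1] == 0:
        raise NetworkError("internal balances admit only the zero flux vector")
    ref_idx = network.reaction_ids.index(network.reference_reaction_id)
    irreversible = np.array([not r.reversible for r in network.reactions])

    scale = 100.0
    for _ in range(max_tries):
        z = rng.lognormal(mean=2.0, sigma=1.0, size=len(network.reaction_ids))
        r = N @ (N.T @ z)  # exact projection onto the balance null space
        if r[ref_idx] <= 0:
            continue
        r = r * (scale / r[ref_idx])
        if (r[irreversible] <= 1e-9).any():
            continue
        break
    else:
        raise NetworkError(
            "could not sample a positive steady-state flux vector; "
            "network may admit none"
        )

    fluxes = pd.Series(r, index=network.reaction_ids, name="flux")
    truth = FluxResults(
        fluxes=fluxes,
        residual_norm=float(np.linalg.norm(S_int @ r)) if S_int.size else 0.0,
        rank=int(np.linalg.matrix_rank(S_int)) if S_int.size else 0,
        n_equations=S_int.shape[0],
        n_unknowns=len(network.reaction_ids),
        determinacy="underdetermined",
        normalized=True,
        network=network,
        scale=scale,
    )

    ref_rxn = network.reactions[ref_idx]
    ref_mets = [m for m, _ in ref_rxn.substrates if m in set(network.boundary_ids)]
    measurements: dict[str, float] = {}
    for met in network.boundary_ids:
        if met in ref_mets:
            c = reference_concentration
        else:
            rate = float(S.loc[met].to_numpy() @ r)
            c = abs(rate) / scale * reference_concentration
        if noise_frac > 0:
            c *= float(np.exp(noise_frac * rng.standard_normal()))
        measurements[met] = c
    return truth, measurements
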