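"""Synthetic trial data with planted structure.

The real trial (43 chickpea genotypes, four environments, two
replicates) deposits no per-plot data, so every downstream stage is
exercised on simulated tables whose statistical structure matches the
analysis assumptions:

* :func:`simulate_trial` draws an additive genotype + G×E + residual
  model around configurable per-treatment means — the structure a
  balanced two-way ANOVA and the entry-mean heritability estimator
  assume.
* :func:`simulate_yield_pairs` draws cluster-structured (Yp, YSI) blobs
  and sets Ys = Yp·YSI, giving yield pairs with a known tolerance-group
  partition for recovery scoring.

All randomness flows through :func:`numpy.random.default_rng` (PCG64);
a fixed seed reproduces tables bit-for-bit.  Out-of-range draws are
truncated, not resampled, so the draw count — and hence the stream —
never depends on the drawn values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ENVIRONMENTS, TrialTable, YieldPairTable

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass(frozen=True)
class TrialSimConfig:
    """Configuration for the additive genotype/treatment/G×E trial model.

    ``treatment_means`` maps trait -> environment -> mean (trait units);
    SDs apply to every trait.  Defaults mirror the trial design:
    43 genotypes, 2 replicates.
    """

    treatment_means: Mapping[str, Mapping[str, float]]
    n_genotypes: int = 43
    n_replicates: int = 2
    sd_genotype: float = 1.0
    sd_gxe: float = 0.5
    sd_residual: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1 or self.n_replicates < 1:
            raise ConfigError("genotype and replicate counts must be positive")
        for sd in (self.sd_genotype, self.sd_gxe, self.sd_residual):
            if sd < 0:
                raise ConfigError("standard deviations must be non-negative")
        for trait, envs in self.treatment_means.items():
            for env, mean in envs.items():
                if env not in ENVIRONMENTS:
                    raise ConfigError(f"unknown environment {env!r} for trait {trait!r}")
                if not np.isfinite(mean):
                    raise ConfigError(f"non-finite mean for {trait!r}/{env!r}")


@dataclass(frozen=True)
class ClusterSimConfig:
    """Configuration for cluster-structured (Yp, Ys) yield pairs.

    Each genotype in group ``c`` draws Yp ~ N(mean_yp[c], sd_yp_within²)
    truncated to be positive, and YSI ~ N(mean_ysi[c], sd_ysi_within²)
    truncated to (0.01, 1.2); Ys = Yp·YSI.
    """

    group_sizes: Sequence[int]
    mean_ysi: Sequence[float]
    mean_yp: Sequence[float]
    sd_yp_within: float = 12.0
    sd_ysi_within: float = 0.03
    stress: str = "heat"
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.group_sizes)
        if not (len(self.mean_ysi) == len(self.mean_yp) == k):
            raise ConfigError("group_sizes, mean_ysi and mean_yp must have equal length")
        if any(s < 1 for s in self.group_sizes):
            raise ConfigError("group sizes must be positive")
        if any(not 0 < y < 1.2 for y in self.mean_ysi):
            raise ConfigError("group mean YSI must lie in (0, 1.2)")
        if any(y <= 0 for y in self.mean_yp):
            raise ConfigError("group mean Yp must be positive")
        if self.sd_yp_within < 0 or self.sd_ysi_within < 0:
            raise ConfigError("within-group SDs must be non-negative")

    @property
    def n_genotypes(self) -> int:
        return int(sum(self.group_sizes))


def _genotype_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_trial(config: TrialSimConfig) -> TrialTable:
    """Draw a balanced trial table from the additive random-effects model.

    value(g, e, r, trait) = mean(trait, e) + G_g + (GE)_ge + eps_ger with
    G ~ N(0, sd_genotype²), GE ~ N(0, sd_gxe²), eps ~ N(0, sd_residual²).
    Genotype effects are shared across the environments of a trait.
    Negative simulated values are truncated at 0 with a logged count.
    """
    rng = np.random.default_rng(config.seed)
    genos = _genotype_ids(config.n_genotypes)
    rows: list[pd.DataFrame] = []
    n_truncated = 0
    for trait in sorted(config.treatment_means):
        env_means = config.treatment_means[trait]
        envs = [e for e in ENVIRONMENTS if e in env_means]
        ng, ne, nr = config.n_genotypes, len(envs), config.n_replicates
        g_eff = rng.normal(0.0, config.sd_genotype, size=ng)
        ge_eff = rng.normal(0.0, config.sd_gxe, size=(ng, ne))
        eps = rng.normal(0.0, config.sd_residual, size=(ng, ne, nr))
        means = np.array([env_means[e] for e in envs])
        values = means[None, :, None] + g_eff[:, None, None] + ge_eff[:, :, None] + eps
        neg = values < 0
        n_truncated += int(neg.sum())
        values = np.where(neg, 0.0, values)
        gi, ei, ri = np.meshgrid(np.arange(ng), np.arange(ne), np.arange(nr), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "genotype": np.array(genos)[gi.ravel()],
                    "environment": np.array(envs)[ei.ravel()],
                    "replicate": ri.ravel() + 1,
                    "trait": trait,
                    "value": values.ravel(),
                }
            )
        )
    if n_truncated:
        logger.warning("simulate_trial: truncated %d negative draw(s) at 0", n_truncated)
    return TrialTable(pd.concat(rows, ignore_index=True))


def simulate_yield_pairs(config: ClusterSimConfig) -> YieldPairTable:
    """Draw cluster-structured yield pairs with the planted group recorded.

    The returned table carries a ``true_group`` column (1-based planted
    group index) for recovery scoring; population means Ȳp, Ȳs follow
    from the generated per-genotype values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genotypes
    group = np.repeat(np.arange(len(config.group_sizes)) + 1, list(config.group_sizes))
    mean_yp = np.repeat(list(config.mean_yp), list(config.group_sizes))
    mean_ysi = np.repeat(list(config.mean_ysi), list(config.group_sizes))
    yp = rng.normal(mean_yp, config.sd_yp_within)
    ysi = rng.normal(mean_ysi, config.sd_ysi_within)
    n_trunc = int((yp <= 0).sum() + ((ysi < 0.01) | (ysi > 1.2)).sum())
    if n_trunc:
        logger.warning("simulate_yield_pairs: truncated %d out-of-range draw(s)", n_trunc)
    yp = np.clip(yp, 1e-6, None)
    ysi = np.clip(ysi, 0.01, 1.2)
    df = pd.DataFrame(
        {
            "genotype": _genotype_ids(n),
            "Yp": yp,
            "Ys": yp * ysi,
            "true_group": group,
        }
    )
    return YieldPairTable(df, stress=config.stress)


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

#: Protein means (%) per treatment: both normal sowings at the reported
#: normal-condition mean, heat and combined-stress sowings at their
#: reported means.  Residual SD fixed at 0.5 %; genotype and G×E SDs are
#: modest, matching the low-to-medium heritability of protein content.
_PAPER_PROTEIN = TrialSimConfig(
    treatment_means={"protein": {"N1": 20.26, "N2": 20.26, "SI": 22.19, "SNI": 21.94}},
    n_genotypes=43,
    n_replicates=2,
    sd_genotype=0.4,
    sd_gxe=0.2,
    sd_residual=0.5,
)

#: Heat-stress tolerance groups: sizes follow the reported four-cluster
#: partition (11 tolerant, 5 moderately tolerant, 12 moderately
#: susceptible, 15 susceptible).  Group means are fixtures chosen so the
#: groups carry the reported qualitative profile — the tolerant group
#: has the highest GMP/STI/Ys, the moderately tolerant the highest YSI
#: and lowest TOL/SSI, the moderately susceptible the highest Yp and
#: TOL, the susceptible the highest SSI — with ≥4-SD separation for
#: recoverability.
_PAPER_HEAT_CLUSTERS = ClusterSimConfig(
    group_sizes=(11, 5, 12, 15),
    mean_ysi=(0.55, 0.70, 0.32, 0.20),
    mean_yp=(280.0, 190.0, 310.0, 215.0),
    sd_yp_within=12.0,
    sd_ysi_within=0.03,
    stress="heat",
)

#: Combined heat-drought groups: sizes (22 tolerant, 2 moderately
#: tolerant, 12 moderately susceptible, 7 susceptible).  The tiny
#: moderately tolerant group pairs the highest Ys and YSI with a low Yp.
_PAPER_SNI_CLUSTERS = ClusterSimConfig(
    group_sizes=(22, 2, 12, 7),
    mean_ysi=(0.45, 0.75, 0.25, 0.10),
    mean_yp=(280.0, 170.0, 320.0, 260.0),
    sd_yp_within=12.0,
    sd_ysi_within=0.03,
    stress="combined",
)

PRESETS: dict[str, TrialSimConfig | ClusterSimConfig] = {
    "paper_protein": _PAPER_PROTEIN,
    "paper_heat_clusters": _PAPER_HEAT_CLUSTERS,
    "paper_sni_clusters": _PAPER_SNI_CLUSTERS,
}


def get_preset(name: str, seed: int | None = None) -> TrialSimConfig | ClusterSimConfig:
    """Return a named preset config, optionally re-seeded."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}")
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def simulate_preset(name: str, seed: int = 0) -> TrialTable | YieldPairTable:
    """Simulate a named preset with the given seed."""
    cfg = get_preset(name, seed)
    if isinstance(cfg, TrialSimConfig):
        return simulate_trial(cfg)
    return simulate_yield_pairs(cfg)
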