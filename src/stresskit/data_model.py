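"""Domain tables for multi-environment crop stress trials.

The pipeline moves between a small set of tabular containers:

``TrialTable``
    Long-format plot observations: genotype x environment x replicate x
    trait.  Environments carry the trial's fixed labels — two normal
    sowings (``N1``, ``N2``), a late sowing with irrigation that imposes
    terminal heat stress (``SI``) and a late sowing without irrigation
    that imposes combined heat-drought stress (``SNI``).

``YieldPairTable``
    Per-genotype replicate-mean yields under one normal/stress
    environment pair of the same season: (Ypi, Ysi).

``IndexTable``
    The nine-column per-genotype tolerance-index table
    (Ys, Yp, STI, TOL, GMP, MP, HARM, SSI, YSI) plus the scalar stress
    intensity.

All containers wrap validated :class:`pandas.DataFrame` objects and read
and write plain comma-separated, UTF-8, decimal-point CSV.  Lines
starting with ``#`` are treated as comments on input so pipeline outputs
can carry provenance headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed environment labels of the trial design.
ENVIRONMENTS: tuple[str, ...] = ("N1", "N2", "SI", "SNI")

#: Treatment class carried by each environment.
TREATMENT_CLASS: Mapping[str, str] = {
    "N1": "normal",
    "N2": "normal",
    "SI": "heat",
    "SNI": "combined",
}

#: Traits expressed as percentages, constrained to [0, 100].
PERCENT_TRAITS: frozenset[str] = frozenset({"protein", "HI"})

TRIAL_COLUMNS: tuple[str, ...] = ("genotype", "environment", "replicate", "trait", "value")

#: Column order of the wide per-genotype index table.
INDEX_COLUMNS: tuple[str, ...] = ("Ys", "Yp", "STI", "TOL", "GMP", "MP", "HARM", "SSI", "YSI")


class SchemaError(ValueError):
    """A required column is missing or cannot be mapped."""


class ValidationError(ValueError):
    """Table content violates a domain invariant; message names the rows."""


def _read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", encoding="utf-8", **kwargs)


def _fail_rows(problem: str, rows: Sequence[int]) -> str:
    shown = ", ".join(str(r) for r in list(rows)[:10])
    more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
    return f"{problem} at row(s) {shown}{more}"


@dataclass
class TrialTable:
    """Validated long-format trial observations.

    Parameters
    ----------
    data
        DataFrame with columns ``genotype, environment, replicate,
        trait, value``.  Validated on construction: keys must be unique,
        environments must be among the trial labels, replicates positive
        integers, values non-negative (and within [0, 100] for
        percentage traits).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(TRIAL_COLUMNS)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["environment"] = df["environment"].astype(str)
        df["trait"] = df["trait"].astype(str)

        bad_env = df.index[~df["environment"].isin(ENVIRONMENTS)]
        if len(bad_env):
            raise ValidationError(
                _fail_rows(f"environment not in {ENVIRONMENTS}", list(bad_env))
            )

        rep = pd.to_numeric(df["replicate"], errors="coerce")
        bad_rep = df.index[rep.isna() | (rep < 1) | (rep != rep.round())]
        if len(bad_rep):
            raise ValidationError(_fail_rows("replicate must be a positive integer", list(bad_rep)))
        df["replicate"] = rep.astype(int)

        val = pd.to_numeric(df["value"], errors="coerce")
        bad_val = df.index[val.isna()]
        if len(bad_val):
            raise ValidationError(_fail_rows("non-numeric value", list(bad_val)))
        df["value"] = val.astype(float)

        neg = df.index[df["value"] < 0]
        if len(neg):
            raise ValidationError(_fail_rows("negative trait value", list(neg)))
        pct = df["trait"].isin(PERCENT_TRAITS)
        over = df.index[pct & (df["value"] > 100)]
        if len(over):
            raise ValidationError(_fail_rows("percentage trait outside [0, 100]", list(over)))

        dup = df.duplicated(subset=["genotype", "environment", "replicate", "trait"])
        if dup.any():
            raise ValidationError(
                _fail_rows("duplicate (genotype, environment, replicate, trait) key", list(df.index[dup]))
            )
        object.__setattr__(self, "data", df)

    # -- accessors ---------------------------------------------------------

    @property
    def environments(self) -> list[str]:
        present = set(self.data["environment"])
        return [e for e in ENVIRONMENTS if e in present]

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    def subset(self, environment: str | None = None, trait: str | None = None) -> pd.DataFrame:
        """Return the raw rows for one environment and/or trait."""
        df = self.data
        if environment is not None:
            df = df[df["environment"] == environment]
        if trait is not None:
            df = df[df["trait"] == trait]
        return df

    def genotype_means(self, environment: str, trait: str) -> pd.Series:
        """Replicate-mean trait value per genotype in one environment."""
        df = self.subset(environment, trait)
        return df.groupby("genotype")["value"].mean()

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, schema: Mapping[str, str] | None = None) -> "TrialTable":
        """Read a long-format trial CSV.

        ``schema`` optionally maps file column names onto the canonical
        ``genotype, environment, replicate, trait, value`` names.
        """
        df = _read_csv(path)
        if schema:
            df = df.rename(columns=dict(schema))
        return cls(df)

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        write_table(self.data, path, header_comment)


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a DataFrame as UTF-8 CSV, optionally with a ``#`` header line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


# canonical alias names used by the CLI
def read_trial_csv(path: str | Path, schema: Mapping[str, str] | None = None) -> TrialTable:
    """Read and validate a long-format trial CSV (see :meth:`TrialTable.from_csv`)."""
    return TrialTable.from_csv(path, schema)


def write_trial_csv(table: TrialTable, path: str | Path) -> None:
    table.to_csv(path)


@dataclass
class YieldPairTable:
    """Per-genotype (Ypi, Ysi) replicate-mean yields for one stress episode.

    ``data`` holds columns ``genotype, Yp, Ys`` (optionally
    ``true_group`` for simulated tables).  Population means are always
    recomputed from the per-genotype means, never stored.
    """

    data: pd.DataFrame
    stress: str = "heat"

    def __post_init__(self) -> None:
        for c in ("genotype", "Yp", "Ys"):
            if c not in self.data.columns:
                raise SchemaError(f"yield-pair table missing column {c!r}")
        if self.stress not in ("heat", "combined"):
            raise ValidationError(f"stress label must be 'heat' or 'combined', got {self.stress!r}")
        df = self.data.reset_index(drop=True).copy()
        df["genotype"] = df["genotype"].astype(str)
        if (df["Yp"] <= 0).any():
            bad = list(df.index[df["Yp"] <= 0])
            raise ValidationError(_fail_rows("retained genotypes require Ypi > 0", bad))
        object.__setattr__(self, "data", df)

    @property
    def ybar_p(self) -> float:
        """Population mean yield under the normal environment (g/plot)."""
        return float(self.data["Yp"].mean())

    @property
    def ybar_s(self) -> float:
        """Population mean yield under the stress environment (g/plot)."""
        return float(self.data["Ys"].mean())

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path: str | Path, stress: str = "heat") -> "YieldPairTable":
        return cls(_read_csv(path), stress=stress)

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        write_table(self.data, path, header_comment)


@dataclass
class IndexTable:
    """Wide per-genotype tolerance-index table plus the stress-intensity scalar."""

    data: pd.DataFrame  # genotype + the nine index columns
    si: float
    stress: str = "heat"

    def __post_init__(self) -> None:
        missing = [c for c in ("genotype", *INDEX_COLUMNS) if c not in self.data.columns]
        if missing:
            raise SchemaError(f"index table missing column(s): {', '.join(missing)}")
        df = self.data.loc[:, ["genotype", *INDEX_COLUMNS]].reset_index(drop=True)
        object.__setattr__(self, "data", df)

    def matrix(self) -> pd.DataFrame:
        """The nine numeric index columns, indexed by genotype."""
        return self.data.set_index("genotype")[list(INDEX_COLUMNS)]

    @classmethod
    def from_csv(cls, path: str | Path, stress: str = "heat") -> "IndexTable":
        df = _read_csv(path)
        si = 1.0 - df["Ys"].mean() / df["Yp"].mean()
        return cls(df, si=float(si), stress=stress)

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        write_table(self.data, path, header_comment)


def pair_yields(
    trial: TrialTable,
    normal_env: str,
    stress_env: str,
    trait: str = "GY",
) -> YieldPairTable:
    """Build the per-genotype (Ypi, Ysi) table for one stress episode.

    Ypi and Ysi are replicate means of ``trait`` in ``normal_env`` and
    ``stress_env``.  Genotypes observed in only one of the two
    environments, and genotypes with Ypi = 0 (for which SSI and YSI are
    undefined), are dropped with a logged warning; the population means
    are taken over retained genotypes only.
    """
    for env in (normal_env, stress_env):
        if env not in trial.environments:
            raise ValidationError(f"environment {env!r} absent from trial table")
    if TREATMENT_CLASS[stress_env] == "normal":
        raise ValidationError(f"{stress_env!r} is a normal environment, not a stress environment")

    yp = trial.genotype_means(normal_env, trait)
    ys = trial.genotype_means(stress_env, trait)
    common = yp.index.intersection(ys.index)
    dropped = sorted(set(yp.index).symmetric_difference(ys.index))
    if dropped:
        logger.warning(
            "pair_yields: dropping %d genotype(s) missing in %s or %s: %s",
            len(dropped), normal_env, stress_env, ", ".join(dropped[:5]),
        )
    df = pd.DataFrame({"genotype": common, "Yp": yp[common].values, "Ys": ys[common].values})
    zero = df["Yp"] <= 0
    if zero.any():
        logger.warning(
            "pair_yields: excluding %d genotype(s) with Ypi = 0 (indices undefined): %s",
            int(zero.sum()), ", ".join(df.loc[zero, "genotype"].head(5)),
        )
        df = df[~zero].reset_index(drop=True)
    if df.empty:
        raise ValidationError("no genotype observed in both environments")
    return YieldPairTable(df, stress=TREATMENT_CLASS[stress_env])


@dataclass
class PCAResult:
    """Correlation-matrix PCA summary in printed-table shape.

    ``contributions`` holds, per variable and dimension, the squared
    unit-eigenvector loading times 100 (each dimension's column sums to
    100); ``variance_explained`` is 100·λ/p.
    """

    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    cumulative_variance: np.ndarray
    contributions: pd.DataFrame  # variables x dimensions, percent
    loadings: pd.DataFrame  # variables x dimensions, unit eigenvectors

    @property
    def n_variables(self) -> int:
        return self.contributions.shape[0]

    def summary(self, n_dims: int = 3) -> pd.DataFrame:
        """Variables-by-dimensions contribution table with eigenvalue and
        variance rows appended, mirroring the printed PCA table layout."""
        dims = self.contributions.columns[:n_dims]
        body = self.contributions[dims].copy()
        extra = pd.DataFrame(
            [self.eigenvalues[: len(dims)], self.variance_explained[: len(dims)],
             self.cumulative_variance[: len(dims)]],
            index=["Eigenvalue", "Variance explained (%)", "Total variance (%)"],
            columns=dims,
        )
        return pd.concat([body, extra])


@dataclass
class ClusterResult:
    """Hierarchical clustering outcome.

    ``assignment`` maps genotype to cluster id (1..k); ``merge_history``
    is the (n-1, 4) linkage matrix (members merged, height, size);
    ``labels`` maps cluster ids to tolerance classes once labelled.
    """

    assignment: pd.Series  # index genotype -> cluster id
    merge_history: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(self.assignment.nunique())

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def members(self, cluster_id: int) -> list[str]:
        return sorted(self.assignment.index[self.assignment == cluster_id])

    def label_of(self, genotype: str) -> str:
        if not self.labels:
            raise ValueError("clusters are not labelled yet")
        return self.labels[int(self.assignment[genotype])]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"genotype": self.assignment.index, "cluster": self.assignment.values})
        if self.labels:
            df["label"] = [self.labels[int(c)] for c in df["cluster"]]
        return df.sort_values("genotype").reset_index(drop=True)


@dataclass
class AnovaResult:
    """Two-way (or one-way) fixed-effects ANOVA table."""

    table: pd.DataFrame  # index: factor names + residual; columns df, sum_sq, mean_sq, F, p

    def __getitem__(self, factor: str) -> pd.Series:
        return self.table.loc[factor]

    @property
    def ms_error(self) -> float:
        return float(self.table.loc["residual", "mean_sq"])

    @property
    def df_error(self) -> float:
        return float(self.table.loc["residual", "df"])


@dataclass
class HeritabilityResult:
    """Entry-mean broad-sense heritability for one environment x trait."""

    environment: str
    trait: str
    sigma2_g: float
    sigma2_e: float
    n_replicates: int
    h2: float
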