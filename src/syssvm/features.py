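"""Assembly, imputation and scaling of the 34-column feature matrix.

Each scored unit is a (sample, gene) pair described by 10 molecular features
(damaging-alteration counts, total exonic mutation burden and gene copy
number) joined with 24 systems-level gene properties broadcast across
samples. Missing systems-level values are imputed group-wise (known cancer
genes vs the rest of the mutated genes) with medians for continuous and
modes for categorical properties; every feature is then scaled to zero mean
and unit variance.

The exact feature composition is a versioned schema artifact; the default
schema encodes the chromatin state as an 8-level one-hot and the
evolutionary origin as a 7-age-class one-hot, for 34 columns in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOLECULAR_FEATURES = [
    "cnv_gain",
    "cnv_loss",
    "translocation",
    "inversion",
    "insertion",
    "truncating",
    "non_truncating_damaging",
    "gain_of_function",
    "total_exonic_mutations",
    "copy_number",
]

SYSTEMS_CONTINUOUS = [
    "gene_length",
    "domain_count",
    "ppi_degree",
    "ppi_betweenness",
    "mirna_count",
    "expression_breadth",
]

SYSTEMS_BOOLEAN = ["is_duplicated", "is_ohnolog", "ppi_hub"]

CHROMATIN_STATES = [
    "active_tss",
    "weak_active",
    "transcribed",
    "enhancer",
    "bivalent",
    "polycomb_repressed",
    "heterochromatin",
    "quiescent",
]

# ordered old -> young
EVOLUTIONARY_ORIGINS = [
    "cellular_organisms",
    "eukaryota",
    "opisthokonta",
    "metazoa",
    "chordata",
    "vertebrata",
    "mammalia",
]

SYSTEMS_CATEGORICAL = {
    "chromatin_state": CHROMATIN_STATES,
    "evolutionary_origin": EVOLUTIONARY_ORIGINS,
}

SYSTEMS_PROPERTY_COLUMNS = SYSTEMS_CONTINUOUS + SYSTEMS_BOOLEAN + list(SYSTEMS_CATEGORICAL)


class ImputationError(ValueError):
    """A group has no observed value for a property that needs imputation."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, versioned description of the feature matrix columns."""

    name: str = "default-34"
    molecular: tuple[str, ...] = tuple(MOLECULAR_FEATURES)
    continuous: tuple[str, ...] = tuple(SYSTEMS_CONTINUOUS)
    boolean: tuple[str, ...] = tuple(SYSTEMS_BOOLEAN)
    categorical: tuple[tuple[str, tuple[str, ...]], ...] = tuple(
        (k, tuple(v)) for k, v in SYSTEMS_CATEGORICAL.items()
    )

    @property
    def categorical_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.categorical)

    @property
    def feature_names(self) -> list[str]:
        names = list(self.molecular) + list(self.continuous) + list(self.boolean)
        for col, levels in self.categorical:
            names.extend(f"{col}__{lvl}" for lvl in levels)
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "molecular": list(self.molecular),
            "continuous": list(self.continuous),
            "boolean": list(self.boolean),
            "categorical": {k: list(v) for k, v in self.categorical},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            name=d.get("name", "custom"),
            molecular=tuple(d["molecular"]),
            continuous=tuple(d["continuous"]),
            boolean=tuple(d["boolean"]),
            categorical=tuple((k, tuple(v)) for k, v in d["categorical"].items()),
        )


DEFAULT_SCHEMA = FeatureSchema()


def _mode(series: pd.Series):
    """Most frequent non-missing value; ties broken lexicographically."""
    counts = series.dropna().value_counts()
    if counts.empty:
        return None
    best = counts.max()
    return sorted(counts[counts == best].index.tolist(), key=str)[0]


def impute_missing(
    props: pd.DataFrame,
    training_genes: set[str],
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Group-wise imputation of missing systems-level properties.

    Continuous properties receive the median, boolean and categorical
    properties the mode, computed separately for known cancer genes
    (``training_genes``) and the rest of the mutated genes. Idempotent.
    """
    out = props.copy()
    in_group = out.index.isin(training_genes)
    groups = {"known_cancer_genes": in_group, "rest": ~in_group}
    categorical_cols = [c for c, _ in schema.categorical]
    for col in out.columns:
        if not out[col].isna().any():
            continue
        for gname, mask in groups.items():
            sub = out.loc[mask, col]
            missing = sub.isna()
            if not missing.any():
                continue
            observed = sub.dropna()
            if observed.empty:
                raise ImputationError(
                    f"property {col!r} has no observed value in group {gname!r}"
                )
            if col in schema.continuous:
                fill = float(observed.median())
            elif col in schema.boolean or col in categorical_cols:
                fill = _mode(observed)
            else:
                fill = float(observed.median())
            out.loc[mask & out[col].isna(), col] = fill
    return out


@dataclass
class ScalingParams:
    """Per-feature means and population standard deviations."""

    means: pd.Series
    sds: pd.Series
    cohort_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "sd": self.sds}).rename_axis("feature")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cohort_id: str = "") -> "ScalingParams":
        return cls(means=frame["mean"], sds=frame["sd"], cohort_id=cohort_id)


def scale_features(
    matrix: pd.DataFrame, params: ScalingParams | None = None, cohort_id: str = ""
) -> tuple[pd.DataFrame, ScalingParams]:
    """Scale each feature to zero mean, unit variance (population sd).

    With ``params`` supplied the stored statistics are applied instead
    (validation-cohort mode). Zero-variance columns are scaled to all zeros
    with a warning.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix must be fully imputed before scaling")
    if params is None:
        means = matrix.mean(axis=0)
        sds = matrix.std(axis=0, ddof=0)
        params = ScalingParams(means=means, sds=sds, cohort_id=cohort_id)
    else:
        missing = [c for c in matrix.columns if c not in params.means.index]
        if missing:
            raise ValueError(f"scaling params lack features: {missing}")
    constant = params.sds.reindex(matrix.columns) == 0
    if constant.any():
        logger.warning(
            "zero-variance feature(s) scaled to zeros: %s",
            ", ".join(matrix.columns[constant]),
        )
    sds_safe = params.sds.reindex(matrix.columns).replace(0.0, np.nan)
    scaled = (matrix - params.means.reindex(matrix.columns)) / sds_safe
    scaled = scaled.fillna(0.0)
    return scaled, params


def unscale_features(scaled: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Inverse of :func:`scale_features` for non-constant columns."""
    return scaled * params.sds.reindex(scaled.columns) + params.means.reindex(scaled.columns)


def encode_systems_properties(
    props: pd.DataFrame, schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Encode imputed raw properties into the schema's numeric columns."""
    cols = {}
    for col in schema.continuous:
        cols[col] = props[col].astype(float)
    for col in schema.boolean:
        cols[col] = props[col].astype(float)
    for col, levels in schema.categorical:
        values = props[col].astype(str)
        unknown = set(values.unique()) - set(levels)
        if unknown:
            raise ValueError(f"unknown {col} level(s): {sorted(unknown)}")
        for lvl in levels:
            cols[f"{col}__{lvl}"] = (values == lvl).astype(float)
    return pd.DataFrame(cols, index=props.index)


def assemble_feature_matrix(
    profiles: pd.DataFrame,
    props: pd.DataFrame,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Join molecular profiles with encoded systems-level properties.

    ``profiles`` is indexed by (sample_id, gene_id) with the schema's
    molecular columns; ``props`` is the imputed raw property table indexed by
    gene. Returns one row per profile with exactly ``schema.n_features``
    columns; a profiled gene absent from ``props`` is a hard error.
    """
    if props.isna().any().any():
        raise ValueError("properties must be imputed before assembly")
    genes = profiles.index.get_level_values("gene_id")
    missing = sorted(set(genes) - set(props.index))
    if missing:
        raise KeyError(
            f"{len(missing)} profiled gene(s) absent from the property table: "
            f"{missing[:10]}"
        )
    encoded = encode_systems_properties(props, schema)
    mol = profiles[list(schema.molecular)].astype(float)
    sys_part = encoded.loc[genes].set_axis(profiles.index)
    matrix = pd.concat([mol, sys_part], axis=1)[schema.feature_names]
    assert matrix.shape[1] == schema.n_features
    return matrix


def correlation_report(
    matrix: pd.DataFrame, threshold: float = 0.9
) -> pd.DataFrame:
    """Pairs of features with |Spearman rho| above ``threshold``."""
    from scipy.stats import spearmanr

    values = matrix.to_numpy(dtype=float)
    rho = spearmanr(values).statistic
    rho = np.atleast_2d(rho)
    names = list(matrix.columns)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = rho[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                rows.append({"feature_a": names[i], "feature_b": names[j], "spearman_rho": r})
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "spearman_rho"])
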