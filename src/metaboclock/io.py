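"""Validated tabular I/O, pipeline configuration, and seed derivation.

The pipeline's clinical axis is a *cohort table* (one row per subject:
age, sex, cohort label, smoking status, serum CEA, optional tumor mutation
flags) and its molecular axis is a *feature matrix* (subjects x metabolic
features, intensities on a log-like scale).  Both are carried as pandas
DataFrames indexed by ``subject_id``; the readers here validate and
canonicalize them.  Pathway membership is read from GMT-style files into a
:class:`PathwayMap`.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metaboclock")

COHORTS = ("healthy", "APL", "CRC_I", "CRC_II", "CRC_III")
CRC_COHORTS = ("CRC_I", "CRC_II", "CRC_III")
DISEASED_COHORTS = ("APL",) + CRC_COHORTS
SEXES = ("male", "female")
MUTATIONS = ("kras", "nras", "braf")

#: Missing-value spellings recognized on read; internally everything missing
#: is pandas NA / NaN, never a numeric sentinel.
NA_VALUES = ("", "NA", "NaN", "nan")

_COHORT_ALIASES = {"normal": "healthy", "control": "healthy"}
_SEX_ALIASES = {"m": "male", "f": "female"}


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


# ---------------------------------------------------------------------------
# seeds


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by stage-name hashing.

    Deterministic across runs and platforms, so each pipeline stage is
    independently reproducible.  Result is < 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# dialect helpers


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _canon_cohort(value: str) -> str:
    key = str(value).strip().replace("-", "_").replace(" ", "_")
    key = _COHORT_ALIASES.get(key.lower(), key)
    for canon in COHORTS:
        if key.lower() == canon.lower():
            return canon
    raise SchemaError(
        f"unrecognized cohort value {value!r}; expected one of {COHORTS}"
    )


def _canon_sex(value: str) -> str:
    key = str(value).strip().lower()
    key = _SEX_ALIASES.get(key, key)
    if key not in SEXES:
        raise SchemaError(f"unrecognized sex value {value!r}; expected one of {SEXES}")
    return key


# ---------------------------------------------------------------------------
# cohort table


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table (TSV/CSV by extension).

    Required columns: ``subject_id, age, sex, cohort``.  Optional columns:
    ``smoker, cea, kras, nras, braf``.  Returns a DataFrame indexed by
    ``subject_id`` with canonicalized categorical values; optional fields
    stay missing where the file left them missing.
    """
    df = pd.read_csv(
        path, sep=_sep_for(path), dtype=str, na_values=list(NA_VALUES),
        keep_default_na=False,
    )
    required = ["subject_id", "age", "sex", "cohort"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    return validate_cohort_table(df)


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize and validate an in-memory cohort table."""
    df = df.copy()
    dup = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dup:
        raise SchemaError(f"duplicated subject_id values: {dup}")

    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = df.loc[ages.isna() | ~np.isfinite(ages), "subject_id"].tolist()
    if bad:
        raise SchemaError(f"non-numeric or non-finite age for subjects: {bad}")
    if (ages <= 0).any():
        bad = df.loc[ages <= 0, "subject_id"].tolist()
        raise SchemaError(f"non-positive age for subjects: {bad}")
    df["age"] = ages.astype(float)
    df["sex"] = df["sex"].map(_canon_sex)
    df["cohort"] = df["cohort"].map(_canon_cohort)

    for col in ("smoker",) + MUTATIONS:
        if col in df.columns:
            df[col] = _to_boolean(df[col], col)
    if "cea" in df.columns:
        cea = pd.to_numeric(df["cea"], errors="coerce")
        if ((cea < 0) & cea.notna()).any():
            bad = df.loc[(cea < 0) & cea.notna(), "subject_id"].tolist()
            raise SchemaError(f"negative CEA for subjects: {bad}")
        df["cea"] = cea.astype(float)

    flagged = pd.Series(False, index=df.index)
    for col in MUTATIONS:
        if col in df.columns:
            flagged |= df[col].notna()
    off_target = flagged & ~df["cohort"].isin(CRC_COHORTS)
    if off_target.any():
        logger.warning(
            "stage=read_cohort n=%d subjects carry mutation flags outside CRC "
            "cohorts: %s", off_target.sum(),
            df.loc[off_target, "subject_id"].head(5).tolist(),
        )
    return df.set_index("subject_id")


def _to_boolean(col: pd.Series, name: str) -> pd.Series:
    if col.dtype == bool:
        return col.astype("boolean")
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}

    def conv(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        try:
            return mapping[str(v).strip().lower()]
        except KeyError:
            raise SchemaError(f"unparseable boolean {v!r} in column {name!r}")

    return col.map(conv).astype("boolean")


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=True, index_label="subject_id",
              float_format="%.12g")


# ---------------------------------------------------------------------------
# feature matrix


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide subjects x features intensity matrix.

    First column is ``subject_id``; every other column is one metabolic
    feature.  ``""``, ``NA`` and ``NaN`` cells become missing values.
    """
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None or len(header) < 2:
        raise SchemaError("feature matrix has zero feature columns")
    feats = header[1:]
    dup = sorted({f for f in feats if feats.count(f) > 1})
    if dup:
        raise SchemaError(f"duplicated feature columns: {dup}")

    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(NA_VALUES),
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    if df.index.duplicated().any():
        raise SchemaError(
            f"duplicated subject_id values: "
            f"{df.index[df.index.duplicated()].unique().tolist()}"
        )
    df = df.astype(float)
    n_missing = int(df.isna().sum().sum())
    logger.info("stage=read_features n_subjects=%d n_features=%d n_missing=%d",
                df.shape[0], df.shape[1], n_missing)
    return df


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=True, index_label="subject_id",
              float_format="%.12g")


def missing_fraction(features: pd.DataFrame) -> pd.Series:
    """Per-feature fraction of missing cells."""
    return features.isna().mean(axis=0)


def align_cohort_features(
    cohort: pd.DataFrame, features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join-check a cohort table against a feature matrix.

    Every subject in the feature matrix must appear in the cohort table;
    rows are returned in the cohort table's order, restricted to subjects
    with measured features.
    """
    orphans = features.index.difference(cohort.index).tolist()
    if orphans:
        raise SchemaError(f"subjects in feature matrix but not cohort table: {orphans}")
    keep = cohort.index.intersection(features.index)
    dropped = cohort.index.difference(features.index)
    if len(dropped):
        logger.warning("stage=align reason=no_features n_dropped=%d", len(dropped))
    return cohort.loc[keep], features.loc[keep]


# ---------------------------------------------------------------------------
# pathway map (GMT)


@dataclass(frozen=True)
class PathwayMap:
    """Pathway id -> member feature ids, with optional display names."""

    members: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def restrict_to(self, feature_ids: Iterable[str]) -> "PathwayMap":
        """Intersect members with ``feature_ids``; drop emptied pathways."""
        avail = frozenset(feature_ids)
        members, names = {}, {}
        for pid, mem in self.members.items():
            inter = mem & avail
            if inter:
                members[pid] = inter
                if pid in self.names:
                    names[pid] = self.names[pid]
            else:
                logger.warning("stage=pathway_map reason=empty_intersection "
                               "pathway=%s dropped", pid)
        return PathwayMap(members, names)


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Parse a GMT file: ``pathway_id <TAB> description <TAB> member...``."""
    members: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, raw = fields[0], fields[1], fields[2:]
            mem = frozenset(m for m in raw if m)
            if len(mem) < len([m for m in raw if m]):
                logger.warning("stage=read_gmt pathway=%s duplicate members "
                               "deduplicated", pid)
            if pid in members:
                raise SchemaError(f"line {lineno}: duplicated pathway id {pid!r}")
            members[pid] = mem
            names[pid] = desc
    if not members:
        raise SchemaError("no pathways in file")
    return PathwayMap(members, names)


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, mem in pmap.members.items():
            desc = pmap.names.get(pid, pid)
            fh.write("\t".join([pid, desc, *sorted(mem)]) + "\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Tunable parameters for the whole analysis pipeline.

    Defaults reproduce the study conditions: 75/25 stratified train/test
    split of healthy subjects, elastic-net mixing 0.5 with penalty chosen by
    10-fold CV over a 100-point log grid, 2.5/97.5% delta-age quantiles,
    30x-coverage bootstrap to incidences 760/10,023 (advanced precancerous
    lesions) and 65/10,023 (colorectal cancer, all stages), 10,000
    enrichment bootstraps and 100 permutation-null models.
    """

    # feature screening
    min_abs_r: float = 0.1
    max_q: float = 0.05
    multiple_testing: str = "bh"           # or "bonferroni"
    min_completeness: float = 0.5
    # pathway scores
    pathway_weights: str = "correlation"   # or "uniform"
    # clock
    train_fraction: float = 0.75
    l1_ratio: float = 0.5
    n_lambdas: int = 100
    cv_folds: int = 10
    identified_metabolites: tuple[str, ...] | None = None  # None -> simulator's nine
    # delta-age subgroups
    q_lo: float = 0.025
    q_hi: float = 0.975
    threshold_reference: str = "test"      # or "all_healthy"
    # CRC screening
    cea_cutoff_nonsmoker: float = 5.0
    cea_cutoff_smoker: float = 10.0
    missing_cea: str = "keep"              # or "demote"
    coverage: int = 30
    apl_incidence: tuple[int, int] = (760, 10023)
    crc_incidence: tuple[int, int] = (65, 10023)
    # inference
    enrichment_bootstrap: int = 10_000
    subgroup_bootstrap: int = 10_000
    n_null_models: int = 100
    null_selection: str = "rank"           # or "threshold"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 < self.q_lo < self.q_hi < 1.0:
            raise ValueError("quantile pair must satisfy 0 < q_lo < q_hi < 1")
        for name in ("n_lambdas", "cv_folds", "coverage",
                     "enrichment_bootstrap", "subgroup_bootstrap",
                     "n_null_models"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for num, den in (self.apl_incidence, self.crc_incidence):
            if not 0 < num < den:
                raise ValueError("incidence numerator/denominator must satisfy "
                                 "0 < num < den")
        if self.multiple_testing not in ("bh", "bonferroni"):
            raise ValueError("multiple_testing must be 'bh' or 'bonferroni'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("apl_incidence", "crc_incidence", "identified_metabolites"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["apl_incidence"] = list(self.apl_incidence)
        d["crc_incidence"] = list(self.crc_incidence)
        if self.identified_metabolites is not None:
            d["identified_metabolites"] = list(self.identified_metabolites)
        return d


def write_manifest(path: str | Path, stage: str, seed: int,
                   inputs: Mapping[str, str], outputs: Mapping[str, str],
                   extra: Mapping | None = None) -> None:
    """Write a JSON run manifest recording inputs, seed and package version."""
    from metaboclock import __version__

    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs": dict(inputs),
        "outputs": dict(outputs),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
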