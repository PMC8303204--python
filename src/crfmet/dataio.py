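"""Typed containers and delimited-text I/O for cohort and metabolomics data.

The package works on three in-memory objects:

* :class:`MetaboliteMatrix` — samples × analytes intensities with explicit
  below-limit-of-detection (LOD) and missing states, plus per-analyte
  annotation (platform, identification status, pathway membership).
* :class:`PhenotypeTable` — per-participant sex, age, menopausal status,
  peak oxygen uptake (VO2peak, mL·kg⁻¹·min⁻¹) and 21 phenotypical/clinical
  covariates.
* :class:`ScoreMatrix` — rank-based inverse-normal (Van der Waerden)
  transformed and optionally confounder-residualized variables.

All serialization is delimited text (TSV by default, "." decimal separator)
so that every artifact the pipeline writes can be inspected and re-read
without loss (reals round-trip to better than 1e-12 relative error).

Below-LOD is deliberately a distinct state from missing: LOD cells take
part in rank-based transforms (tied at the bottom of the ranking) whereas
missing cells propagate as missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "MajorPathway",
    "Sex",
    "MenopausalStatus",
    "COVARIATE_NAMES",
    "IMPUTABLE_COVARIATES",
    "ValidationError",
    "AnalyteAnnotation",
    "MetaboliteMatrix",
    "PhenotypeTable",
    "ScoreMatrix",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_results",
    "read_results",
]

DEFAULT_LOD_TOKEN = "<LOD"
DEFAULT_SEP = "\t"
#: format preserving doubles exactly on a text round trip
FLOAT_FMT = "%.17g"


class Platform(str, enum.Enum):
    """Analytical platform an analyte was measured on.

    Enum order doubles as the tie-break order when several platforms share
    the same quantitative rank for a duplicated chemical.
    """

    NMR = "nmr"
    GCXGC_MS = "gcxgc_ms"
    GC_MS_FA = "gc_ms_fa"
    LCMS_P180 = "lcms_p180"
    LCMS_AMINO = "lcms_amino"
    LCMS_BILE = "lcms_bile"


PLATFORM_ORDER = {p.value: i for i, p in enumerate(Platform)}


class MajorPathway(str, enum.Enum):
    AMINO_ACID = "amino_acid"
    CARBOHYDRATE = "carbohydrate"
    COFACTORS_VITAMINS = "cofactors_vitamins"
    ENERGY = "energy"
    LIPID = "lipid"
    MAMMALIAN_MICROBIAL = "mammalian_microbial"
    NUCLEOTIDE = "nucleotide"
    XENOBIOTICS = "xenobiotics"
    UNKNOWN = "unknown"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class MenopausalStatus(str, enum.Enum):
    PRE = "pre"
    POST = "post"
    NOT_APPLICABLE = "not_applicable"


#: the 21 phenotypical/clinical covariates carried by a PhenotypeTable
COVARIATE_NAMES = (
    "lbm",        # lean body mass, kg
    "fm_pct",     # fat mass, % of body weight
    "vatm",       # visceral adipose tissue mass, kg
    "bmc",        # bone mineral content, kg
    "height",     # cm
    "hb",         # hemoglobin
    "glucose",
    "insulin",
    "hba1c",
    "tg",         # triglycerides
    "hdl",
    "ldl",
    "hr_rest",
    "bp_sys",
    "bp_dia",
    "pwv",        # pulse wave velocity
    "vc_max",     # maximal vital capacity
    "fev1",
    "aee",        # activity energy expenditure, kcal/day
    "total_met",
    "hei_nvs",    # diet-quality index
)

#: covariates for which missing values are tolerated (imputed later)
IMPUTABLE_COVARIATES = ("aee", "pwv")


class ValidationError(ValueError):
    """Aggregated validation failure: carries every problem found."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def _require(condition: bool, message: str, problems: list[str]) -> None:
    if not condition:
        problems.append(message)


@dataclass(frozen=True)
class AnalyteAnnotation:
    """Metadata for one analyte column.

    ``quantitative_rank`` orders platforms by how quantitative the
    measurement is (1 = most quantitative); it drives the resolution of
    cross-platform duplicate analytes. Unidentified analytes (no MSI level
    1/2 annotation) carry ``major_pathway='unknown'``.
    """

    analyte_id: str
    platform: Platform
    quantitative_rank: int = 1
    identified: bool = True
    major_pathway: MajorPathway = MajorPathway.UNKNOWN
    specific_pathway: str = ""
    duplicate_group: str = ""

    def __post_init__(self):
        problems: list[str] = []
        _require(self.quantitative_rank >= 1,
                 f"{self.analyte_id}: quantitative_rank must be >= 1", problems)
        if not self.identified and self.major_pathway != MajorPathway.UNKNOWN:
            problems.append(
                f"{self.analyte_id}: unidentified analyte must have unknown pathway")
        if problems:
            raise ValidationError(problems)


@dataclass
class MetaboliteMatrix:
    """Samples × analytes intensity grid with LOD/missing semantics.

    ``values`` holds nonnegative floats with NaN in every cell that carries
    no number (below-LOD or missing); ``below_lod`` is True exactly where
    the cell is below the limit of detection. Cells that are NaN in
    ``values`` and False in ``below_lod`` are missing.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    analytes: list[AnalyteAnnotation]

    def __post_init__(self):
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def annotation(self, analyte_id: str) -> AnalyteAnnotation:
        return self._index[analyte_id]

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte_id": [a.analyte_id for a in self.analytes],
                "platform": [a.platform.value for a in self.analytes],
                "quantitative_rank": [a.quantitative_rank for a in self.analytes],
                "identified": [a.identified for a in self.analytes],
                "major_pathway": [a.major_pathway.value for a in self.analytes],
                "specific_pathway": [a.specific_pathway for a in self.analytes],
                "duplicate_group": [a.duplicate_group for a in self.analytes],
            }
        ).set_index("analyte_id", drop=False)

    def detected(self) -> pd.DataFrame:
        """Boolean mask of cells carrying a numeric (detected) value.

        Missing and below-LOD cells both count as *not* detected; this
        definition feeds the detection-frequency filter and is the
        documented, configurable convention of the package.
        """
        return self.values.notna()

    def subset_analytes(self, keep: Sequence[str]) -> "MetaboliteMatrix":
        keep = list(keep)
        kept = [a for a in self.analytes if a.analyte_id in set(keep)]
        return MetaboliteMatrix(self.values[keep].copy(),
                                self.below_lod[keep].copy(), kept)

    def subset_samples(self, keep: Sequence[str]) -> "MetaboliteMatrix":
        keep = list(keep)
        return MetaboliteMatrix(self.values.loc[keep].copy(),
                                self.below_lod.loc[keep].copy(),
                                list(self.analytes))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        dup_samples = self.values.index[self.values.index.duplicated()].unique()
        _require(len(dup_samples) == 0,
                 f"duplicate sample ids: {sorted(map(str, dup_samples))}", problems)
        dup_analytes = self.values.columns[self.values.columns.duplicated()].unique()
        _require(len(dup_analytes) == 0,
                 f"duplicate analyte ids: {sorted(map(str, dup_analytes))}", problems)
        ann_ids = [a.analyte_id for a in self.analytes]
        _require(len(set(ann_ids)) == len(ann_ids),
                 "duplicate analyte ids in annotation", problems)
        missing_ann = sorted(set(self.values.columns) - set(ann_ids))
        _require(not missing_ann,
                 f"annotation missing analytes: {missing_ann}", problems)
        _require(self.values.shape == self.below_lod.shape
                 and list(self.values.columns) == list(self.below_lod.columns)
                 and list(self.values.index) == list(self.below_lod.index),
                 "below_lod mask does not align with values", problems)
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(float) < 0).any():
                problems.append("negative intensities present")
        if not problems:
            # LOD cells must not carry a number
            if (self.below_lod.to_numpy(bool) & self.values.notna().to_numpy()).any():
                problems.append("below-LOD cell carries a numeric value")
        if problems:
            raise ValidationError(problems)
        self._index = {a.analyte_id: a for a in self.analytes}


@dataclass
class PhenotypeTable:
    """Per-participant phenotype data.

    ``data`` is indexed by sample id with columns ``sex``, ``age``,
    ``menopausal_status``, ``vo2peak`` and the 21 covariates of
    :data:`COVARIATE_NAMES`. Missing values (NaN) are only legal in the
    imputable covariates (AEE, PWV).
    """

    data: pd.DataFrame

    def __post_init__(self):
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def sex_labels(self) -> pd.Series:
        return self.data["sex"]

    def subset(self, sex: Sex | str) -> "PhenotypeTable":
        sex = Sex(sex).value
        return PhenotypeTable(self.data[self.data["sex"] == sex].copy())

    def covariates(self) -> pd.DataFrame:
        return self.data[list(COVARIATE_NAMES)]

    def validate(self) -> None:
        problems: list[str] = []
        required = ["sex", "age", "menopausal_status", "vo2peak", *COVARIATE_NAMES]
        missing_cols = [c for c in required if c not in self.data.columns]
        _require(not missing_cols, f"missing columns: {missing_cols}", problems)
        if missing_cols:
            raise ValidationError(problems)
        dup = self.data.index[self.data.index.duplicated()].unique()
        _require(len(dup) == 0, f"duplicate sample ids: {sorted(map(str, dup))}", problems)
        bad_sex = set(self.data["sex"]) - {s.value for s in Sex}
        _require(not bad_sex, f"invalid sex labels: {sorted(bad_sex)}", problems)
        bad_meno = set(self.data["menopausal_status"]) - {m.value for m in MenopausalStatus}
        _require(not bad_meno, f"invalid menopausal status: {sorted(bad_meno)}", problems)
        males = self.data["sex"] == Sex.M.value
        if (self.data.loc[males, "menopausal_status"] != MenopausalStatus.NOT_APPLICABLE.value).any():
            offenders = self.data.index[males & (
                self.data["menopausal_status"] != MenopausalStatus.NOT_APPLICABLE.value)]
            problems.append(f"male samples with menopausal status: {list(offenders)}")
        if (self.data["vo2peak"] <= 0).any() or self.data["vo2peak"].isna().any():
            problems.append("vo2peak must be positive and present")
        age = self.data["age"]
        if age.isna().any() or (age < 18).any() or (age > 80).any():
            problems.append("age must lie in [18, 80]")
        non_imputable = [c for c in COVARIATE_NAMES if c not in IMPUTABLE_COVARIATES]
        na_cols = [c for c in non_imputable if self.data[c].isna().any()]
        _require(not na_cols, f"missing values in non-imputable covariates: {na_cols}",
                 problems)
        if problems:
            raise ValidationError(problems)


@dataclass
class ScoreMatrix:
    """Van der Waerden scores (optionally residualized) for a variable set."""

    scores: pd.DataFrame
    adjustment_set: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.scores.columns)

    def validate(self) -> None:
        problems: list[str] = []
        if not np.isfinite(self.scores.to_numpy(float)).all():
            problems.append("non-finite scores present")
        if self.adjustment_set:
            means = self.scores.mean(axis=0)
            off = means[means.abs() > 1e-8]
            _require(off.empty,
                     f"residualized columns with nonzero mean: {list(off.index)}",
                     problems)
        if problems:
            raise ValidationError(problems)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_annotation_frame(ann: pd.DataFrame) -> list[AnalyteAnnotation]:
    analytes = []
    for _, row in ann.iterrows():
        analytes.append(AnalyteAnnotation(
            analyte_id=str(row["analyte_id"]),
            platform=Platform(row["platform"]),
            quantitative_rank=int(row["quantitative_rank"]),
            identified=_as_bool(row["identified"]),
            major_pathway=MajorPathway(row["major_pathway"]),
            specific_pathway="" if pd.isna(row.get("specific_pathway", "")) else str(row.get("specific_pathway", "")),
            duplicate_group="" if pd.isna(row.get("duplicate_group", "")) else str(row.get("duplicate_group", "")),
        ))
    return analytes


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in {"true", "1", "yes"}


def read_metabolite_table(matrix_path: str | Path, annotation_path: str | Path,
                          lod_token: str = DEFAULT_LOD_TOKEN,
                          sep: str = DEFAULT_SEP) -> MetaboliteMatrix:
    """Read an intensity matrix (samples in rows) plus its annotation table.

    Cells equal to ``lod_token`` become below-LOD; empty cells become
    missing. Validation failures are aggregated into one
    :class:`ValidationError` naming every offender.
    """
    raw = pd.read_csv(matrix_path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    lod = raw == lod_token
    values = raw.mask(lod | (raw == ""), np.nan)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValidationError([f"non-numeric cell in matrix: {exc}"]) from exc
    ann = pd.read_csv(annotation_path, sep=sep, dtype=str, keep_default_na=False)
    analytes = _parse_annotation_frame(ann)
    return MetaboliteMatrix(values, lod.astype(bool), analytes)


def write_metabolite_table(matrix: MetaboliteMatrix, matrix_path: str | Path,
                           annotation_path: str | Path,
                           lod_token: str = DEFAULT_LOD_TOKEN,
                           sep: str = DEFAULT_SEP) -> None:
    out = matrix.values.map(lambda v: "" if pd.isna(v) else FLOAT_FMT % v)
    out = out.mask(matrix.below_lod, lod_token)
    out.index.name = "sample_id"
    out.to_csv(matrix_path, sep=sep)
    matrix.annotation_frame().to_csv(annotation_path, sep=sep, index=False)


def read_phenotype_table(path: str | Path, sep: str = DEFAULT_SEP) -> PhenotypeTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotype_table(pheno: PhenotypeTable, path: str | Path,
                          sep: str = DEFAULT_SEP) -> None:
    out = pheno.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, float_format=FLOAT_FMT)


def write_results(obj, path: str | Path, sep: str = DEFAULT_SEP) -> None:
    """Serialize any result object (or DataFrame) as delimited text.

    Result objects expose ``to_frame()``; re-reading with
    :func:`read_results` reproduces reals to 1e-12 relative error and
    integers/flags exactly.
    """
    frame = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    frame.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_results(result_type, path: str | Path, sep: str = DEFAULT_SEP):
    """Re-read a result written by :func:`write_results`.

    ``result_type`` must provide a ``from_frame`` classmethod; pass
    ``pd.DataFrame`` to get the raw table back.
    """
    frame = pd.read_csv(path, sep=sep)
    if result_type is pd.DataFrame:
        return frame
    return result_type.from_frame(frame)
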