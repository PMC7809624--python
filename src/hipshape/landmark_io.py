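"""Data model and file I/O for landmark configurations, covariates and genotype dosages.

Three tabular inputs drive the pipeline:

* landmark coordinate files — one ordered planar point configuration per
  subject, either in a *wide* CSV layout (``id,x1,y1,...,xN,yN``) or a *long*
  TSV layout (``subject, point_index, x, y`` with 1-based point indices);
* a covariate table (age in years, sex coded female=0 / male=1, height in cm,
  weight in kg, BMI in kg/m² — derived from height and weight when absent);
* a genotype dosage table (per-SNP effect-allele dosage in [0, 2] per subject),
  read either from a TSV or from a VCF (``DS`` FORMAT field when present,
  otherwise the ALT-allele count from ``GT``).

All writers emit full-precision decimal floats so that write → read round
trips are bit identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "CovariateTable",
    "GenotypeDosageTable",
    "CohortDataset",
    "DEFAULT_N_POINTS",
    "read_landmarks",
    "write_landmarks",
    "read_covariates",
    "write_covariates",
    "read_dosages",
    "write_dosages",
]

#: Number of outline points used by the reference proximal-femur markup.
DEFAULT_N_POINTS = 53

# Sex coding used throughout (configurable at the file level by recoding
# before import, but this is the canonical convention).
SEX_FEMALE = 0
SEX_MALE = 1


@dataclass(frozen=True)
class LandmarkSet:
    """One subject's ordered planar landmark configuration.

    Parameters
    ----------
    subject_id:
        Unique subject identifier.
    points:
        Array of shape ``(n_points, 2)`` holding ordered ``(x, y)``
        coordinates in arbitrary planar units (pixels or mm); units are
        removed later by Procrustes scaling.
    """

    subject_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(
                f"subject {self.subject_id!r}: points must be an (n, 2) array, "
                f"got shape {pts.shape}"
            )
        if pts.shape[0] < 3:
            raise ValueError(
                f"subject {self.subject_id!r}: need at least 3 landmark points"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError(
                f"subject {self.subject_id!r}: non-finite coordinate encountered"
            )
        if self.centroid_size_of(pts) <= 0.0:
            raise ValueError(
                f"subject {self.subject_id!r}: degenerate configuration "
                "(all points coincident)"
            )
        object.__setattr__(self, "points", pts)

    @staticmethod
    def centroid_size_of(points: np.ndarray) -> float:
        centred = points - points.mean(axis=0)
        return float(np.sqrt((centred**2).sum()))

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def centroid_size(self) -> float:
        return self.centroid_size_of(self.points)


def read_landmarks(
    path: str | Path,
    dialect: str = "wide",
    n_points: int | None = DEFAULT_N_POINTS,
) -> list[LandmarkSet]:
    """Read landmark configurations from a wide CSV or long TSV file.

    ``n_points`` is the expected point count per subject (``None`` accepts any
    uniform count).  A subject with the wrong number of points is a hard
    error naming the subject; a non-numeric coordinate is a hard error naming
    the offending row.
    """
    path = Path(path)
    if dialect == "wide":
        sets = _read_landmarks_wide(path)
    elif dialect == "long":
        sets = _read_landmarks_long(path)
    else:
        raise ValueError(f"unknown landmark dialect {dialect!r}")
    counts = {s.n_points for s in sets}
    if len(counts) > 1:
        raise ValueError(f"inconsistent point counts across subjects: {sorted(counts)}")
    if n_points is not None and sets and sets[0].n_points != n_points:
        bad = sets[0].subject_id
        raise ValueError(
            f"subject {bad!r}: expected {n_points} landmark points, "
            f"found {sets[0].n_points}"
        )
    return sets


def _read_landmarks_wide(path: Path) -> list[LandmarkSet]:
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 7 or (df.shape[1] - 1) % 2 != 0:
        raise ValueError(
            f"{path}: wide landmark CSV needs an id column plus x/y column pairs"
        )
    n_pts = (df.shape[1] - 1) // 2
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row[0])
        try:
            coords = np.asarray(row[1:], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric coordinate at row {row_no} (subject {sid!r})"
            ) from exc
        if not np.all(np.isfinite(coords)):
            raise ValueError(
                f"{path}: missing/non-finite coordinate at row {row_no} "
                f"(subject {sid!r})"
            )
        out.append(LandmarkSet(sid, coords.reshape(n_pts, 2)))
    return out


def _read_landmarks_long(path: Path) -> list[LandmarkSet]:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str},
                     float_precision="round_trip")
    required = {"subject", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long landmark TSV needs columns {sorted(required)}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} value at row {row}")
        df[col] = vals
    out = []
    counts = df.groupby("subject", sort=False)["point_index"].count()
    expected = int(counts.iloc[0])
    for sid, grp in df.groupby("subject", sort=False):
        grp = grp.sort_values("point_index")
        idx = grp["point_index"].to_numpy()
        if len(idx) != expected or not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(
                f"{path}: subject {sid!r} has an incomplete or duplicated "
                f"point sequence ({len(idx)} points, expected {expected})"
            )
        out.append(LandmarkSet(str(sid), grp[["x", "y"]].to_numpy()))
    return out


def write_landmarks(
    sets: Sequence[LandmarkSet], path: str | Path, dialect: str = "wide"
) -> None:
    """Write landmark configurations; inverse of :func:`read_landmarks`."""
    path = Path(path)
    if not sets:
        raise ValueError("no landmark sets to write")
    n_pts = sets[0].n_points
    if dialect == "wide":
        cols = ["id"]
        for i in range(1, n_pts + 1):
            cols += [f"x{i}", f"y{i}"]
        rows = [[s.subject_id, *s.points.ravel().tolist()] for s in sets]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    elif dialect == "long":
        recs = []
        for s in sets:
            for i, (x, y) in enumerate(s.points, start=1):
                recs.append((s.subject_id, i, x, y))
        pd.DataFrame(recs, columns=["subject", "point_index", "x", "y"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown landmark dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateTable:
    """Per-subject covariates: age (years), sex (0=female, 1=male),
    height (cm), weight (kg) and BMI (kg/m², derived when absent)."""

    data: pd.DataFrame  # index: subject id; columns: age, sex, height, weight, bmi

    COLUMNS = ("age", "sex", "height", "weight", "bmi")

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns and c != "bmi"]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        if "bmi" not in df.columns:
            df["bmi"] = np.nan
        derive = df["bmi"].isna() & df["height"].notna() & df["weight"].notna()
        df.loc[derive, "bmi"] = df.loc[derive, "weight"] / (
            df.loc[derive, "height"] / 100.0
        ) ** 2
        self.data = df[list(self.COLUMNS)]
        self._validate()

    def _validate(self) -> None:
        df = self.data
        for col in ("age", "height", "weight", "bmi"):
            if (df[col].dropna() < 0).any():
                raise ValueError(f"negative values in covariate {col!r}")
        sexes = set(df["sex"].dropna().unique())
        if not sexes <= {SEX_FEMALE, SEX_MALE}:
            raise ValueError(f"sex must be coded 0/1, found {sorted(sexes)}")
        complete = df.dropna(subset=["height", "weight", "bmi"])
        expected = complete["weight"] / (complete["height"] / 100.0) ** 2
        bad = (complete["bmi"] - expected).abs() > 0.1
        if bad.any():
            sid = complete.index[bad][0]
            raise ValueError(
                f"subject {sid!r}: BMI inconsistent with height/weight "
                f"(> 0.1 kg/m² discrepancy)"
            )

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def subset(self, ids: Iterable[str]) -> "CovariateTable":
        return CovariateTable(self.data.loc[list(ids)])


_COV_FILE_COLS = {"height_cm": "height", "weight_kg": "weight"}


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str},
                     float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError(f"{path}: covariate TSV needs an 'id' column")
    df = df.rename(columns=_COV_FILE_COLS).set_index("id")
    return CovariateTable(df)


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    out = table.data.rename(columns={v: k for k, v in _COV_FILE_COLS.items()})
    out.index.name = "id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Genotype dosages
# ---------------------------------------------------------------------------

_INFO_COLS = [
    "effect_allele",
    "other_allele",
    "eaf_declared",
    "eaf_observed",
    "n_AA",
    "n_Aa",
    "n_aa",
]


@dataclass
class GenotypeDosageTable:
    """Per-SNP effect-allele dosages with allele metadata.

    ``info`` is indexed by SNP id with columns ``effect_allele``,
    ``other_allele``, ``eaf_declared`` (as stated in the source file, NaN when
    absent), ``eaf_observed`` (recomputed as ``mean(dosage) / 2``) and
    optional hard genotype counts ``n_AA`` / ``n_Aa`` / ``n_aa`` (``n_aa``
    counts effect-allele homozygotes).  ``dosages`` is indexed by SNP id with
    one column per subject; NaN marks a missing call.
    """

    info: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        info = self.info.copy()
        for col in _INFO_COLS:
            if col not in info.columns:
                info[col] = np.nan
        self.info = info[_INFO_COLS]
        dos = self.dosages.astype(float)
        vals = dos.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = self.dosages.index[
                ((dos < 0) | (dos > 2)).any(axis=1).to_numpy()
            ][0]
            raise ValueError(f"SNP {bad!r}: dosage outside [0, 2]")
        if not self.info.index.equals(dos.index):
            raise ValueError("info and dosage tables disagree on SNP ids")
        self.dosages = dos
        self.info["eaf_observed"] = self.observed_eaf()
        self._check_counts()

    def _check_counts(self) -> None:
        have = self.info.dropna(subset=["n_AA", "n_Aa", "n_aa"])
        for snp, row in have.iterrows():
            d = self.dosages.loc[snp].dropna()
            n = row[["n_AA", "n_Aa", "n_aa"]].sum()
            if int(n) != len(d):
                raise ValueError(
                    f"SNP {snp!r}: genotype counts sum to {int(n)} "
                    f"but {len(d)} dosages are typed"
                )
            mean = (row["n_Aa"] + 2 * row["n_aa"]) / n
            if abs(mean - d.mean()) > 1e-6:
                raise ValueError(
                    f"SNP {snp!r}: genotype counts inconsistent with mean dosage"
                )

    @property
    def snp_ids(self) -> list[str]:
        return [str(i) for i in self.info.index]

    @property
    def subject_ids(self) -> list[str]:
        return [str(c) for c in self.dosages.columns]

    def observed_eaf(self) -> pd.Series:
        return self.dosages.mean(axis=1, skipna=True) / 2.0

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=1)

    def flip_effect_allele(self, snp_id: str) -> None:
        """Swap effect/other allele for one SNP; dosages become ``2 - d``.

        Applying the flip twice restores the original table exactly.
        """
        row = self.info.loc[snp_id].copy()
        self.info.loc[snp_id, "effect_allele"] = row["other_allele"]
        self.info.loc[snp_id, "other_allele"] = row["effect_allele"]
        if np.isfinite(row["eaf_declared"]):
            self.info.loc[snp_id, "eaf_declared"] = 1.0 - row["eaf_declared"]
        if np.isfinite(row["n_AA"]):
            self.info.loc[snp_id, "n_AA"] = row["n_aa"]
            self.info.loc[snp_id, "n_aa"] = row["n_AA"]
        self.dosages.loc[snp_id] = 2.0 - self.dosages.loc[snp_id]
        self.info.loc[snp_id, "eaf_observed"] = (
            self.dosages.loc[snp_id].mean(skipna=True) / 2.0
        )

    def subset_subjects(self, ids: Iterable[str]) -> "GenotypeDosageTable":
        dos = self.dosages[list(ids)]
        info = self.info.copy()
        # hard counts no longer describe the subset; drop them
        info[["n_AA", "n_Aa", "n_aa"]] = np.nan
        return GenotypeDosageTable(info, dos)


_DOSAGE_META_COLS = ["snp_id", "effect_allele", "other_allele", "eaf",
                     "n_AA", "n_Aa", "n_aa"]


def read_dosages(path: str | Path, format: str = "tsv",
                 effect_alleles: dict[str, str] | None = None) -> GenotypeDosageTable:
    """Read a genotype dosage table from TSV or VCF.

    For VCF input, dosages come from the ``DS`` FORMAT field when present and
    otherwise from the ALT-allele count of ``GT``.  ``effect_alleles``
    optionally maps SNP id to the desired effect allele; when the configured
    effect allele equals REF, dosages are flipped to ``2 - d``.  An effect
    allele matching neither REF nor ALT is a hard error.
    """
    if format == "tsv":
        return _read_dosages_tsv(Path(path))
    if format == "vcf":
        return _read_dosages_vcf(Path(path), effect_alleles or {})
    raise ValueError(f"unknown dosage format {format!r}")


def _read_dosages_tsv(path: Path) -> GenotypeDosageTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str},
                     float_precision="round_trip")
    if "snp_id" not in df.columns:
        raise ValueError(f"{path}: dosage TSV needs a 'snp_id' column")
    df = df.set_index("snp_id")
    meta = [c for c in _DOSAGE_META_COLS[1:] if c in df.columns]
    subj_cols = [c for c in df.columns if c not in meta]
    info = df[meta].rename(columns={"eaf": "eaf_declared"})
    dosages = df[subj_cols].astype(float)
    return GenotypeDosageTable(info, dosages)


def write_dosages(table: GenotypeDosageTable, path: str | Path) -> None:
    info = table.info.rename(columns={"eaf_declared": "eaf"})
    cols = ["effect_allele", "other_allele", "eaf", "n_AA", "n_Aa", "n_aa"]
    out = pd.concat([info[cols], table.dosages], axis=1)
    out = out.dropna(axis=1, how="all")
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t")


def _read_dosages_vcf(path: Path, effect_alleles: dict[str, str]) -> GenotypeDosageTable:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is preinstalled
        raise ImportError("reading VCF dosages requires cyvcf2") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    info_rows, dosage_rows, ids = [], [], []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"SNP {snp_id!r}: multi-allelic records are not supported")
        ref, alt = var.REF, var.ALT[0]
        ds = None
        try:
            ds_field = var.format("DS")
        except KeyError:
            ds_field = None
        if ds_field is not None:
            ds = np.asarray(ds_field, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gt < 0).any(axis=1), np.nan,
                          (gt > 0).sum(axis=1)).astype(float)
        finite = ds[np.isfinite(ds)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError(f"SNP {snp_id!r}: dosage outside [0, 2]")
        ea = effect_alleles.get(snp_id, alt)
        if ea == alt:
            oa = ref
        elif ea == ref:
            oa = alt
            ds = 2.0 - ds
        else:
            raise ValueError(
                f"SNP {snp_id!r}: effect allele {ea!r} matches neither "
                f"REF ({ref!r}) nor ALT ({alt!r})"
            )
        ids.append(snp_id)
        info_rows.append({"effect_allele": ea, "other_allele": oa})
        dosage_rows.append(ds)
    info = pd.DataFrame(info_rows, index=pd.Index(ids, name="snp_id"))
    dosages = pd.DataFrame(dosage_rows, index=info.index, columns=samples)
    return GenotypeDosageTable(info, dosages)


# ---------------------------------------------------------------------------
# Cohort dataset
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """Landmarks + covariates + genotypes for one timepoint.

    Analyses use complete cases only: a subject enters only if present in all
    three components after an inner join on subject id.
    """

    landmarks: list[LandmarkSet]
    covariates: CovariateTable
    genotypes: GenotypeDosageTable
    timepoint: str = ""

    def complete_case_ids(self) -> list[str]:
        lm = [s.subject_id for s in self.landmarks]
        cov = set(self.covariates.subject_ids)
        gen = set(self.genotypes.subject_ids)
        return [s for s in lm if s in cov and s in gen]

    def complete_cases(self) -> "CohortDataset":
        ids = self.complete_case_ids()
        idset = set(ids)
        return CohortDataset(
            landmarks=[s for s in self.landmarks if s.subject_id in idset],
            covariates=self.covariates.subset(ids),
            genotypes=self.genotypes.subset_subjects(ids),
            timepoint=self.timepoint,
        )
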