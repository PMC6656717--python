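"""Read, write and validate the three cohort tables.

The pipeline works on three tab-separated inputs:

* an SNV annotation table (rsid, gene, risk/other allele, reference-panel
  risk-allele frequency and chromosome count),
* a genotype matrix of risk-allele counts (subjects x SNVs, values 0/1/2/NA),
* a phenotype table with per-subject covariates and longitudinal visit
  weights in wide ``weight_y<time>`` columns.

Genotypes are stored internally as RISK-allele counts everywhere: 2 means
homozygous for the risk allele (MM), 1 heterozygous (Mm), 0 homozygous for
the protective allele (mm).  VCF input is re-oriented to this convention on
load.  Missing genotypes are NaN.

The TSV dialect is tab-separated UTF-8 with ``NA`` for missing values; a
bare ``.`` is rejected as malformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

_VALID_ALLELES = frozenset("ACGT")

ANNOTATION_COLUMNS = ["rsid", "gene", "risk_allele", "other_allele", "ref_freq", "ref_n"]


@dataclass(frozen=True)
class SnvAnnotation:
    """One panel SNV: identity, risk allele and reference-panel frequency.

    The risk allele is the allele previously associated with higher obesity
    risk; ``ref_freq`` is its frequency in a reference panel of ``ref_n``
    chromosomes.
    """

    rsid: str
    gene: str
    risk_allele: str
    other_allele: str
    ref_freq: float
    ref_n: int

    def __post_init__(self) -> None:
        if self.risk_allele not in _VALID_ALLELES:
            raise ValidationError(f"{self.rsid}: risk_allele {self.risk_allele!r} is not one of A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            raise ValidationError(f"{self.rsid}: other_allele {self.other_allele!r} is not one of A/C/G/T")
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: risk and other allele are both {self.risk_allele!r}")
        if not 0.0 <= self.ref_freq <= 1.0:
            raise ValidationError(f"{self.rsid}: ref_freq {self.ref_freq} outside [0, 1]")
        if self.ref_n < 0:
            raise ValidationError(f"{self.rsid}: ref_n {self.ref_n} is negative")


@dataclass
class GenotypeMatrix:
    """Subjects x SNVs risk-allele counts; NaN marks a missing genotype."""

    subject_ids: list[str]
    snvs: list[SnvAnnotation]
    g: np.ndarray  # float array, shape (n_subjects, n_snvs), entries in {0,1,2,NaN}

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.shape != (len(self.subject_ids), len(self.snvs)):
            raise ValidationError(
                f"genotype array shape {self.g.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snvs)} SNVs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject_id in genotype matrix")
        ok = np.isnan(self.g) | np.isin(self.g, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"genotype value {self.g[i, j]!r} for subject {self.subject_ids[i]} "
                f"at {self.snvs[j].rsid} is not in {{0, 1, 2, NA}}"
            )

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snvs]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, rsid: str) -> np.ndarray:
        """Risk-allele counts for one SNV, in subject order."""
        try:
            j = self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"rsid {rsid!r} not in panel") from None
        return self.g[:, j]

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, m in zip(self.subject_ids, mask) if m]
        return GenotypeMatrix(ids, list(self.snvs), self.g[mask])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.g, columns=self.rsids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class PhenotypeTable:
    """Per-subject covariates plus longitudinal visit weights.

    ``data`` has one row per subject (subject_id, group, sex, age, height,
    baseline_weight, followup_years and optional glucose/smoking/comorbidity
    columns); ``visits`` is long-format (subject_id, years, weight_kg),
    sorted by time within subject.  Cases must have at least one
    post-baseline visit and followup of a year or more.
    """

    data: pd.DataFrame
    visits: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["subject_id", "years", "weight_kg"]))

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "sex", "age", "height", "baseline_weight"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        if self.data["subject_id"].duplicated().any():
            dup = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r} in phenotype table")
        bad_group = ~self.data["group"].isin(["case", "control"])
        if bad_group.any():
            raise ValidationError(
                f"subject {self.data.loc[bad_group, 'subject_id'].iloc[0]!r}: "
                "group must be 'case' or 'control'"
            )
        if (self.data["baseline_weight"] <= 0).any():
            sid = self.data.loc[self.data["baseline_weight"] <= 0, "subject_id"].iloc[0]
            raise ValidationError(f"subject {sid!r}: non-positive baseline weight")
        if (self.data["height"] <= 0).any():
            sid = self.data.loc[self.data["height"] <= 0, "subject_id"].iloc[0]
            raise ValidationError(f"subject {sid!r}: non-positive height")
        self.visits = self.visits.sort_values(["subject_id", "years"], kind="stable").reset_index(drop=True)
        if (self.visits["weight_kg"] <= 0).any():
            sid = self.visits.loc[self.visits["weight_kg"] <= 0, "subject_id"].iloc[0]
            raise ValidationError(f"subject {sid!r}: non-positive visit weight")
        cases = self.data.loc[self.data["group"] == "case", "subject_id"]
        with_visit = set(self.visits.loc[self.visits["years"] > 0, "subject_id"])
        orphans = [s for s in cases if s not in with_visit]
        if orphans:
            raise ValidationError(f"case {orphans[0]!r} has no post-baseline weight")
        if "followup_years" in self.data.columns:
            case_rows = self.data["group"] == "case"
            fy = pd.to_numeric(self.data.loc[case_rows, "followup_years"], errors="coerce")
            short = fy < 1.0
            if short.any():
                sid = self.data.loc[case_rows].loc[short.values, "subject_id"].iloc[0]
                raise ValidationError(f"case {sid!r}: followup_years < 1")

    @property
    def cases(self) -> pd.DataFrame:
        return self.data[self.data["group"] == "case"].reset_index(drop=True)

    @property
    def controls(self) -> pd.DataFrame:
        return self.data[self.data["group"] == "control"].reset_index(drop=True)

    def visits_for(self, subject_id: str) -> pd.DataFrame:
        return self.visits[self.visits["subject_id"] == subject_id]

    def bmi_baseline(self) -> pd.Series:
        return self.data["baseline_weight"] / self.data["height"] ** 2

    def check_bmi_ranges(self) -> list[str]:
        """Warn about subjects outside the design BMI windows.

        Cases are recruited at BMI 25-40, controls at 18.5-25; out-of-range
        subjects are reported (warning), not rejected, since measured BMI can
        drift around the recruitment threshold.
        """
        bmi = self.bmi_baseline()
        flagged = []
        for _, row in self.data.assign(bmi=bmi).iterrows():
            lo, hi = (25.0, 40.0) if row["group"] == "case" else (18.5, 25.0)
            if not lo <= row["bmi"] <= hi:
                flagged.append(str(row["subject_id"]))
        if flagged:
            warnings.warn(
                f"{len(flagged)} subject(s) outside the BMI window for their group: "
                + ", ".join(flagged[:10]),
                stacklevel=2,
            )
        return flagged


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if (df == ".").any().any():
        col = [c for c in df.columns if (df[c] == ".").any()][0]
        raise ValidationError(f"{path}: bare '.' in column {col!r}; use NA for missing")
    return df


def read_annotations(path: str | Path) -> list[SnvAnnotation]:
    """Read and validate an SNV annotation TSV, preserving file order."""
    df = _read_tsv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: annotation file missing columns {sorted(missing)}")
    annotations: list[SnvAnnotation] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rsid = row["rsid"]
        if rsid in seen:
            raise ValidationError(f"{path} row {i + 2}: duplicate rsid {rsid!r}")
        seen.add(rsid)
        try:
            ann = SnvAnnotation(
                rsid=rsid,
                gene=row["gene"],
                risk_allele=str(row["risk_allele"]),
                other_allele=str(row["other_allele"]),
                ref_freq=float(row["ref_freq"]),
                ref_n=int(row["ref_n"]),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from None
        annotations.append(ann)
    return annotations


def load_panel() -> list[SnvAnnotation]:
    """The packaged 25-locus obesity panel.

    Eight rsIDs are the published ones (rs13078807 in CADM2, rs29941 in
    KCTD15, rs1294421 in LY86, rs2112347 in FLJ35779, rs10150332 in NRXN3,
    rs4929949 in RPL27A, rs7359397 in SH2B1, rs9491696 in RSPO3); the
    remaining 17 loci carry synthetic placeholder IDs in the rs9000000xx
    range because their identifiers were never published, and their
    reference frequencies are synthetic (drawn once and frozen).
    """
    with resources.as_file(resources.files("wlscore.data") / "panel_annotations.tsv") as p:
        return read_annotations(p)


def write_annotations(annotations: Sequence[SnvAnnotation], path: str | Path) -> None:
    pd.DataFrame([vars(a) for a in annotations])[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, annotations: Sequence[SnvAnnotation]) -> GenotypeMatrix:
    """Read a genotype TSV of risk-allele counts, aligned to annotation order.

    Columns not in the panel are dropped with a warning; panel SNVs absent
    from the file come back all-missing with a warning.
    """
    df = _read_tsv(path)
    if "subject_id" not in df.columns:
        raise ValidationError(f"{path}: missing subject_id column")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate subject {dup!r}")
    panel = [a.rsid for a in annotations]
    extra = [c for c in df.columns if c not in panel and c != "subject_id"]
    if extra:
        warnings.warn(f"{path}: dropping {len(extra)} column(s) not in the panel: {extra}", stacklevel=2)
    absent = [r for r in panel if r not in df.columns]
    if absent:
        warnings.warn(f"{path}: {len(absent)} panel SNV(s) absent from file, set to missing: {absent}", stacklevel=2)
    n = len(df)
    g = np.full((n, len(panel)), np.nan)
    for j, rsid in enumerate(panel):
        if rsid not in df.columns:
            continue
        for i, raw in enumerate(df[rsid]):
            if pd.isna(raw):
                continue
            if raw not in ("0", "1", "2"):
                raise ValidationError(
                    f"{path}: value {raw!r} for subject {df['subject_id'].iloc[i]!r} "
                    f"at {rsid} is not 0/1/2/NA"
                )
            g[i, j] = float(raw)
    return GenotypeMatrix(list(df["subject_id"]), list(annotations), g)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.to_frame()
    for c in gm.rsids:
        df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def orient_vcf(vcf_path: str | Path, annotations: Sequence[SnvAnnotation]) -> GenotypeMatrix:
    """Load genotypes from a VCF and orient them to risk-allele counts.

    Sites are matched by ID against the panel.  When ALT is the risk allele
    the ALT-allele count is used directly; when REF is the risk allele the
    count is complemented (2 - ALT count); when neither allele matches the
    annotation the genotype is set missing with a warning.  Multi-allelic
    sites overlapping the panel are rejected (the panel is biallelic).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    panel = {a.rsid: (j, a) for j, a in enumerate(annotations)}
    g = np.full((len(samples), len(annotations)), np.nan)
    seen: set[str] = set()
    for variant in vcf:
        rsid = variant.ID
        if rsid not in panel:
            continue
        if rsid in seen:
            raise ValidationError(f"{vcf_path}: rsid {rsid!r} appears more than once")
        seen.add(rsid)
        j, ann = panel[rsid]
        if len(variant.ALT) != 1:
            raise ValidationError(f"{vcf_path}: {rsid} is multi-allelic; panel SNVs are biallelic")
        ref, alt = variant.REF, variant.ALT[0]
        alt_counts = np.array([
            sum(1 for a in gt[:2] if a == 1) if -1 not in gt[:2] else np.nan
            for gt in variant.genotypes
        ], dtype=float)
        if alt == ann.risk_allele:
            g[:, j] = alt_counts
        elif ref == ann.risk_allele:
            g[:, j] = 2.0 - alt_counts
        else:
            warnings.warn(
                f"{vcf_path}: {rsid} alleles {ref}/{alt} do not include risk allele "
                f"{ann.risk_allele}; genotypes set to missing",
                stacklevel=2,
            )
    absent = [r for r in panel if r not in seen]
    if absent:
        warnings.warn(f"{vcf_path}: {len(absent)} panel SNV(s) absent from VCF: {absent}", stacklevel=2)
    return GenotypeMatrix(samples, list(annotations), g)


def _parse_visit_columns(columns: Iterable[str]) -> dict[str, float]:
    """Map wide visit columns ``weight_y<t>`` to their time in years."""
    out: dict[str, float] = {}
    for c in columns:
        if c.startswith("weight_y"):
            try:
                out[c] = float(c[len("weight_y"):])
            except ValueError:
                raise ValidationError(f"cannot parse visit time from column {c!r}") from None
    return out


_OPTIONAL_NUMERIC = ["followup_years", "glucose_baseline", "glucose_final"]
_OPTIONAL_BOOL = ["smoking", "diabetes", "hypertension"]


def read_phenotypes(path: str | Path, strict_bmi: bool = False) -> PhenotypeTable:
    """Read the phenotype TSV; wide weight_y* columns become long visits."""
    df = _read_tsv(path)
    visit_cols = _parse_visit_columns(df.columns)
    post_cols = [c for c, t in visit_cols.items() if t > 0]
    if post_cols:
        long = df.melt(
            id_vars=["subject_id"], value_vars=post_cols, var_name="col", value_name="weight_kg"
        ).dropna(subset=["weight_kg"])
        visits = pd.DataFrame(
            {
                "subject_id": long["subject_id"],
                "years": long["col"].map(visit_cols),
                "weight_kg": pd.to_numeric(long["weight_kg"], errors="raise"),
            }
        )
    else:
        visits = pd.DataFrame(columns=["subject_id", "years", "weight_kg"])
    data = df.drop(columns=post_cols)
    for col in ["age", "height", "baseline_weight"] + _OPTIONAL_NUMERIC:
        if col in data.columns:
            data[col] = pd.to_numeric(data[col], errors="raise")
    for col in _OPTIONAL_BOOL:
        if col in data.columns:
            data[col] = data[col].map({"1": True, "0": False, "True": True, "False": False})
    if "weight_y0" in data.columns:
        data = data.drop(columns=["weight_y0"])
    table = PhenotypeTable(data.reset_index(drop=True), visits)
    if strict_bmi:
        table.check_bmi_ranges()
    return table


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    """Write the phenotype table back to wide TSV form."""
    wide = table.data.copy()
    if not table.visits.empty:
        pivot = table.visits.pivot_table(
            index="subject_id", columns="years", values="weight_kg", aggfunc="first"
        )
        pivot.columns = [f"weight_y{t:g}" for t in pivot.columns]
        wide = wide.join(pivot, on="subject_id")
    for col in _OPTIONAL_BOOL:
        if col in wide.columns:
            wide[col] = wide[col].map(lambda v: "" if pd.isna(v) else str(int(bool(v))))
    wide.to_csv(path, sep="\t", index=False, na_rep="NA")
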