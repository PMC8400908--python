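"""Reading, validation and encoding of genotype and phenotype tables.

Genotypes are unphased diploid calls at biallelic SNPs.  The canonical
in-memory form is a minor-allele dosage matrix (0, 1, 2 copies; -1 for a
missing call), which together with each SNP's declared allele pair is a
lossless representation of the unordered allele-pair calls found in the
text formats.

The genotype TSV dialect is one row per subject: first column
``subject_id``, one column per SNP, calls written ``X/Y`` (allele order not
semantic) and ``./.`` for missing.  A thin VCF adapter maps unphased or
phased GT fields onto the same matrix (phase is discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpDef",
    "GenotypeMatrix",
    "PhenotypeTable",
    "AnalysisTable",
    "GenotypeParseError",
    "GenotypeValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "read_genotype_vcf",
    "read_phenotype_table",
    "carrier_encode",
    "recessive_complement_encode",
    "complete_case_subset",
]

MISSING_CALL = "./."

#: Allowed genotype-grouping models.  ``carrier_dominant`` pools subjects
#: carrying at least one minor allele as exposed; ``variant_recessive``
#: pools everyone except minor-allele homozygotes as exposed (the contrast
#: is "minor homozygote vs the rest"); ``het_vs_ref`` contrasts
#: heterozygotes against homozygotes.
GROUPINGS = ("carrier_dominant", "variant_recessive", "het_vs_ref")


class GenotypeParseError(ValueError):
    """Malformed genotype file (bad row length or call syntax)."""


class GenotypeValidationError(ValueError):
    """Genotype content inconsistent with the declared SNP definitions."""


@dataclass(frozen=True)
class SnpDef:
    """Definition of one biallelic SNP.

    Parameters
    ----------
    snp_id : str
        rs identifier, e.g. ``"rs5050"``.
    gene : str
        Gene symbol the SNP is annotated to.
    major_allele, minor_allele : str
        Single-base alleles; the minor allele is the one whose population
        frequency is declared in ``maf``.
    maf : float
        Declared minor-allele frequency in [0, 0.5].
    grouping : str
        One of :data:`GROUPINGS`; names which genotypes are pooled as the
        "exposed" group in association analyses.
    """

    snp_id: str
    gene: str
    major_allele: str
    minor_allele: str
    maf: float
    grouping: str = "carrier_dominant"

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: major and minor allele identical")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.grouping not in GROUPINGS:
            raise ValueError(
                f"{self.snp_id}: unknown grouping {self.grouping!r}; "
                f"expected one of {GROUPINGS}"
            )

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.major_allele, self.minor_allele))

    def call_to_dosage(self, call: str, *, subject: str = "?") -> int:
        """Parse an ``X/Y`` call into a minor-allele dosage (-1 = missing)."""
        if call == MISSING_CALL:
            return -1
        parts = call.replace("|", "/").split("/")
        if len(parts) != 2:
            raise GenotypeParseError(
                f"call {call!r} for {self.snp_id} (subject {subject}) is not 'X/Y'"
            )
        dosage = 0
        for allele in parts:
            if allele == self.minor_allele:
                dosage += 1
            elif allele != self.major_allele:
                raise GenotypeValidationError(
                    f"allele {allele!r} for SNP {self.snp_id} (subject {subject}) "
                    f"is not in the declared set {sorted(self.alleles)}"
                )
        return dosage

    def dosage_to_call(self, dosage: int) -> str:
        if dosage < 0:
            return MISSING_CALL
        alleles = ([self.major_allele] * (2 - dosage)) + [self.minor_allele] * dosage
        return "/".join(sorted(alleles))


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs unphased diploid calls.

    ``dosage[i, j]`` is the number of copies of ``snps[j].minor_allele``
    carried by ``subjects[i]`` (int8), or -1 for a missing call.  Allele
    pairs are unordered; the dosage plus the SNP's two declared alleles
    reconstructs each call exactly.
    """

    subjects: list
    snps: list
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.subjects) or m != len(self.snps):
            raise ValueError("dosage shape inconsistent with subjects/snps")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject identifiers are not unique")
        if self.dosage.min(initial=0) < -1 or self.dosage.max(initial=0) > 2:
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def snp_ids(self) -> list:
        return [s.snp_id for s in self.snps]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage < 0

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not present") from None

    def snp_def(self, snp_id: str) -> SnpDef:
        return self.snps[self.snp_index(snp_id)]

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        """Minor-allele dosage as float with NaN for missing calls."""
        col = self.dosage[:, self.snp_index(snp_id)].astype(float)
        col[col < 0] = np.nan
        return col

    def missing_counts(self) -> pd.Series:
        return pd.Series(self.missing_mask.sum(axis=0), index=self.snp_ids)

    def calls_frame(self) -> pd.DataFrame:
        """Calls as ``X/Y`` strings (``./.`` missing), subjects as index."""
        data = {
            snp.snp_id: [snp.dosage_to_call(d) for d in self.dosage[:, j]]
            for j, snp in enumerate(self.snps)
        }
        return pd.DataFrame(data, index=pd.Index(self.subjects, name="subject_id"))

    def subset_subjects(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            subjects=[self.subjects[i] for i in idx],
            snps=list(self.snps),
            dosage=self.dosage[idx],
        )


@dataclass
class PhenotypeTable:
    """Per-subject outcome and covariates, indexed by subject identifier.

    The frame must carry a binary ``bleeding`` column (1 = bleeding event
    while at therapeutic INR).  Conventional covariate columns are binary
    indicators (``sex_male``, ``age_ge_65``, comorbidity and comedication
    flags) plus reporting-only continuous columns (``age_years``,
    ``inr_mean``, ``followup_years``) and categorical valve descriptors.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "bleeding" not in self.df.columns:
            raise ValueError("phenotype table lacks a 'bleeding' column")
        vals = self.df["bleeding"].dropna().unique()
        if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            raise ValueError("'bleeding' must be binary 0/1")
        if not self.df.index.is_unique:
            raise ValueError("duplicate subject identifiers in phenotype table")
        if {"age_years", "age_ge_65"} <= set(self.df.columns):
            both = self.df[["age_years", "age_ge_65"]].dropna()
            implied = (both["age_years"] >= 65).astype(int)
            if not (implied == both["age_ge_65"].astype(int)).all():
                raise ValueError("age_ge_65 inconsistent with age_years")

    @property
    def subjects(self) -> list:
        return list(self.df.index)

    @property
    def bleeding(self) -> np.ndarray:
        return self.df["bleeding"].to_numpy(dtype=float)


@dataclass
class AnalysisTable:
    """Complete-case design for one analysis: outcome plus named binary
    exposure columns, with the number of subjects dropped for missingness."""

    frame: pd.DataFrame
    outcome_col: str = "bleeding"
    n_dropped: int = 0
    dropped_subjects: list = field(default_factory=list)

    @property
    def outcome(self) -> np.ndarray:
        return self.frame[self.outcome_col].to_numpy(dtype=float)

    @property
    def exposure_cols(self) -> list:
        return [c for c in self.frame.columns if c != self.outcome_col]

    def design(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        return self.frame[list(columns) if columns is not None else self.exposure_cols]

    @property
    def n(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers


def read_genotype_table(path, snp_defs: Sequence[SnpDef]) -> GenotypeMatrix:
    """Read the genotype TSV dialect into a validated :class:`GenotypeMatrix`.

    The header must name every SNP in ``snp_defs`` (extra columns are an
    error); calls with alleles outside a SNP's declared pair raise
    :class:`GenotypeValidationError` naming the SNP and subject.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "subject_id":
        raise GenotypeParseError(
            f"first column must be 'subject_id', got {raw.columns[0]!r}"
        )
    by_id = {s.snp_id: s for s in snp_defs}
    file_snps = list(raw.columns[1:])
    unknown = sorted(set(file_snps) - set(by_id))
    if unknown:
        raise GenotypeValidationError(f"SNP columns without definitions: {unknown}")
    absent = sorted(set(by_id) - set(file_snps))
    if absent:
        raise GenotypeValidationError(f"declared SNPs missing from file: {absent}")
    if raw.isna().any().any():
        row = int(raw.isna().any(axis=1).idxmax()) + 2  # 1-based + header
        raise GenotypeParseError(f"malformed row (wrong field count) at line {row}")

    snps = [by_id[sid] for sid in file_snps]
    subjects = raw["subject_id"].tolist()
    n, m = len(subjects), len(snps)
    dosage = np.empty((n, m), dtype=np.int8)
    for j, snp in enumerate(snps):
        col = raw[snp.snp_id].tolist()
        for i, call in enumerate(col):
            dosage[i, j] = snp.call_to_dosage(call, subject=subjects[i])
    return GenotypeMatrix(subjects=subjects, snps=snps, dosage=dosage)


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    """Write the TSV dialect; exact round-trip with :func:`read_genotype_table`."""
    gm.calls_frame().to_csv(path, sep="\t")


def read_genotype_vcf(path, snp_defs: Sequence[SnpDef]) -> GenotypeMatrix:
    """Read genotypes from a VCF (4.x) via cyvcf2, matching records by ID.

    GT fields may be unphased (``0/1``) or phased (``0|1``); phase is
    discarded.  Records whose {REF, ALT} does not equal the declared allele
    pair are rejected.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    by_id = {s.snp_id: s for s in snp_defs}
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols: dict = {}
    for variant in vcf:
        snp = by_id.get(variant.ID)
        if snp is None:
            continue
        alts = list(variant.ALT)
        if len(alts) != 1 or {variant.REF, alts[0]} != set(snp.alleles):
            raise GenotypeValidationError(
                f"{variant.ID}: VCF alleles {variant.REF}>{alts} do not match "
                f"declared {sorted(snp.alleles)}"
            )
        minor_idx = 1 if alts[0] == snp.minor_allele else 0
        col = np.empty(len(subjects), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col[i] = -1
            else:
                col[i] = int(a == minor_idx) + int(b == minor_idx)
        cols[variant.ID] = col
    absent = sorted(set(by_id) - set(cols))
    if absent:
        raise GenotypeValidationError(f"declared SNPs missing from VCF: {absent}")
    snps = [by_id[sid] for sid in cols]
    dosage = np.column_stack([cols[s.snp_id] for s in snps])
    return GenotypeMatrix(subjects=subjects, snps=snps, dosage=dosage)


def read_phenotype_table(path, column_map: Mapping[str, str] | None = None,
                         sep: str | None = None) -> PhenotypeTable:
    """Read a phenotype CSV/TSV; ``column_map`` renames file columns onto the
    canonical names (``{"file_col": "canonical"}``)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# encodings


def carrier_encode(gm: GenotypeMatrix, snp_id: str) -> np.ndarray:
    """Binary exposure vector under the SNP's declared grouping model.

    Returns a float vector with 1 for exposed, 0 for unexposed and NaN for
    missing calls.  Exposure semantics per grouping:

    - ``carrier_dominant``: exposed = at least one minor allele;
    - ``variant_recessive``: exposed = anything but the minor-allele
      homozygote (the unexposed pole is the variant homozygote);
    - ``het_vs_ref``: exposed = heterozygote.
    """
    snp = gm.snp_def(snp_id)
    dos = gm.dosage_vector(snp_id)
    out = np.full_like(dos, np.nan)
    ok = ~np.isnan(dos)
    if snp.grouping == "carrier_dominant":
        out[ok] = (dos[ok] >= 1).astype(float)
    elif snp.grouping == "variant_recessive":
        out[ok] = (dos[ok] < 2).astype(float)
    else:  # het_vs_ref
        out[ok] = (dos[ok] == 1).astype(float)
    return out


def recessive_complement_encode(gm: GenotypeMatrix, snp_id: str) -> np.ndarray:
    """Complement of :func:`carrier_encode`; together they partition every
    non-missing subject exactly once."""
    enc = carrier_encode(gm, snp_id)
    return 1.0 - enc


def _resolve_column(gm: GenotypeMatrix, pt: PhenotypeTable, name: str) -> np.ndarray:
    if name in pt.df.columns:
        return pt.df[name].to_numpy(dtype=float)
    snp_id = name[:-8] if name.endswith("_carrier") else name
    if snp_id in gm.snp_ids:
        return carrier_encode(gm, snp_id)
    raise KeyError(f"column {name!r} is neither a phenotype column nor a SNP id")


def complete_case_subset(gm: GenotypeMatrix, pt: PhenotypeTable,
                         columns: Sequence[str]) -> AnalysisTable:
    """Assemble outcome plus the requested exposure columns, dropping
    subjects with a missing value in any requested column (complete-case
    for *this* analysis only).

    A column name may be a phenotype column, a SNP id (encoded under its
    declared grouping) or ``<snp>_carrier``.
    """
    if gm.subjects != pt.subjects:
        raise ValueError("genotype and phenotype tables list different subjects")
    data = {"bleeding": pt.bleeding}
    for name in columns:
        data[name] = _resolve_column(gm, pt, name)
    frame = pd.DataFrame(data, index=pd.Index(gm.subjects, name="subject_id"))
    complete = frame.dropna()
    dropped = sorted(set(frame.index) - set(complete.index))
    if complete.empty:
        raise ValueError(
            "no complete cases remain; inspect per-column missingness "
            f"(requested columns: {list(columns)})"
        )
    return AnalysisTable(frame=complete, n_dropped=len(dropped),
                         dropped_subjects=dropped)
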