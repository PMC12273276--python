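"""Readers, writers and container types for the formats the pipeline touches.

Internal coordinate convention is 0-based half-open everywhere.  Bismark
coverage files use a 1-based inclusive dialect and are converted on read.
Missing methylation values are encoded as NaN, never 0 (a β of 0 is a
meaningful, fully unmethylated measurement).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

MISSING = float("nan")


class ValidationError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMethylation:
    """A single CpG measurement.

    ``beta`` is recomputed from the methylated/unmethylated counts and is NaN
    when total coverage is zero or below the caller's coverage floor.
    """

    chrom: str
    pos: int  # 0-based
    strand: str = "."
    n_meth: int = 0
    n_unmeth: int = 0
    beta: float = MISSING

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class BetaMatrix:
    """CpG sites x samples matrix of methylation fractions in [0, 1].

    ``beta`` is a DataFrame indexed by site id ("chrom:pos") with sample ids
    as columns.  ``coverage`` is an optional parallel integer matrix.
    """

    beta: pd.DataFrame
    coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValidationError("duplicate site ids in beta matrix")
        if self.beta.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in beta matrix")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=1.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValidationError("beta values outside [0, 1]")
        if self.coverage is not None and self.coverage.shape != self.beta.shape:
            raise ValidationError("coverage matrix shape differs from beta matrix")

    @property
    def site_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape


@dataclass
class ExpressionMatrix:
    """Genes x samples expression. ``is_counts`` records whether values are
    raw integer counts or already-normalized real values."""

    values: pd.DataFrame
    is_counts: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.is_counts:
            arr = self.values.to_numpy()
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise ValidationError("count matrix must hold non-negative integers")


@dataclass
class Region:
    region_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )


class RegionMap:
    """Named genomic intervals (promoters or genes) with CpG membership.

    Membership is resolved lazily against a set of site ids of the form
    "chrom:pos"; a site belongs to a region when its position lies in the
    half-open interval [start, end).
    """

    def __init__(self, regions: Iterable[Region]):
        self.regions: dict[str, Region] = {}
        for r in regions:
            if r.region_id in self.regions:
                raise ValidationError(f"duplicate region id {r.region_id}")
            self.regions[r.region_id] = r
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions.values())

    def _build_trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self.regions.values():
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.region_id)
            self._trees = trees
        return self._trees

    def assign_sites(self, site_ids: Iterable[str]) -> "RegionMap":
        """Populate each region's member list from a collection of site ids."""
        trees = self._build_trees()
        for r in self.regions.values():
            r.site_ids = []
        for sid in site_ids:
            chrom, pos = parse_site_id(sid)
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.at(pos):
                self.regions[iv.data].site_ids.append(sid)
        return self


class GeneSetCollection(dict):
    """Mapping set name -> list of unique gene symbols (order preserved)."""

    def add(self, name: str, genes: Sequence[str]) -> None:
        if name in self:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        seen: dict[str, None] = {}
        dupes = []
        for g in genes:
            if g in seen:
                dupes.append(g)
            seen[g] = None
        if dupes:
            logger.warning("gene set %s: dropped duplicate members %s", name, dupes)
        if not seen:
            raise ValidationError(f"gene set {name!r} is empty")
        self[name] = list(seen)


@dataclass
class SignedGeneSet:
    """A regulator's target genes with expected response direction (+1/-1)."""

    name: str
    directions: dict[str, int]

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in (-1, 1)}
        if bad:
            raise ValidationError(f"regulon {self.name}: directions must be +1/-1, got {bad}")


# ---------------------------------------------------------------------------
# Site-id and stage helpers
# ---------------------------------------------------------------------------


def parse_site_id(site_id: str) -> tuple[str, int]:
    chrom, _, pos = site_id.rpartition(":")
    return chrom, int(pos)


def site_sort_key(site_id: str) -> tuple[str, int]:
    return parse_site_id(site_id)


_STAGE_RE = re.compile(r"^(IV|III|II|I)([A-Z0-9]*)$")
_SUFFIX_RANK = {"": 0, "A": 1, "B": 2, "C": 3, "D": 4,
                "M1A": 5, "M1B": 6, "M1C": 7, "M1D": 8}


def stage_rank(stage: str) -> int:
    """Orderable rank for an AJCC stage string such as III, IIIB, IV, IVM1D."""
    m = _STAGE_RE.match(str(stage).strip().upper())
    if not m:
        raise ValidationError(f"unparseable AJCC stage {stage!r}")
    base = {"I": 1, "II": 2, "III": 3, "IV": 4}[m.group(1)]
    return base * 100 + _SUFFIX_RANK.get(m.group(2), 0)


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------


def read_bismark_coverage(path: str | Path, min_coverage: int = 5) -> list[SiteMethylation]:
    """Parse a Bismark ``.cov`` file (chrom, start, end, %meth, n_meth, n_unmeth).

    β is recomputed from the two count columns; the percentage column is
    ignored because counts are exact.  Sites with total coverage below
    ``min_coverage`` (or zero) are retained with β = NaN so that downstream
    completeness filters stay explicit.  Coordinates are converted from the
    1-based inclusive dialect to 0-based positions.
    """
    sites: list[SiteMethylation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"{path}: line {lineno}: negative counts")
            cov = n_meth + n_unmeth
            beta = n_meth / cov if cov >= max(min_coverage, 1) and cov > 0 else MISSING
            sites.append(
                SiteMethylation(chrom=chrom, pos=start - 1, strand=".",
                                n_meth=n_meth, n_unmeth=n_unmeth, beta=beta)
            )
    return sites


def assemble_beta_matrix(per_sample_sites: Mapping[str, Sequence[SiteMethylation]]) -> BetaMatrix:
    """Union per-sample site lists into a BetaMatrix.

    Rows are the union of site ids, ordered by (chrom, pos); absent
    site/sample pairs are missing.  Output is independent of input order.
    """
    if not per_sample_sites:
        raise ValidationError("need at least one sample")
    samples = list(per_sample_sites)
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample id")
    all_ids = sorted(
        {s.site_id for sites in per_sample_sites.values() for s in sites},
        key=site_sort_key,
    )
    idx = {sid: i for i, sid in enumerate(all_ids)}
    beta = np.full((len(all_ids), len(samples)), np.nan)
    cov = np.zeros((len(all_ids), len(samples)), dtype=int)
    for j, sample in enumerate(sorted(samples)):
        for s in per_sample_sites[sample]:
            i = idx[s.site_id]
            beta[i, j] = s.beta
            cov[i, j] = s.coverage
    cols = sorted(samples)
    return BetaMatrix(
        beta=pd.DataFrame(beta, index=all_ids, columns=cols),
        coverage=pd.DataFrame(cov, index=all_ids, columns=cols),
    )


# ---------------------------------------------------------------------------
# Matrix / table round trips
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_beta_matrix(bm: BetaMatrix | pd.DataFrame, path: str | Path) -> None:
    df = bm.beta if isinstance(bm, BetaMatrix) else bm
    df.to_csv(path, sep="\t", index_label="site_id", float_format=_FLOAT_FMT)


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return BetaMatrix(beta=df)


def write_expression_matrix(em: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = em.values if isinstance(em, ExpressionMatrix) else em
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_expression_matrix(path: str | Path, is_counts: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(values=df, is_counts=is_counts)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named table as a headered TSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=True, float_format=_FLOAT_FMT)
        written.append(p)
    return written


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# GMT / regulons
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member1 <tab> member2..."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            coll.add(fields[0], [g for g in fields[2:] if g])
    return coll


def write_gmt(coll: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_regulons(path: str | Path) -> dict[str, SignedGeneSet]:
    """TSV with columns regulator, target, expected_sign (+1/-1)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"regulator", "target", "expected_sign"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"regulon table must have columns {sorted(needed)}")
    out: dict[str, SignedGeneSet] = {}
    for reg, grp in df.groupby("regulator", sort=False):
        out[str(reg)] = SignedGeneSet(
            name=str(reg),
            directions={str(t): int(s) for t, s in zip(grp["target"], grp["expected_sign"])},
        )
    return out


# ---------------------------------------------------------------------------
# BED and sample sheets
# ---------------------------------------------------------------------------


def read_region_bed(path: str | Path) -> RegionMap:
    """BED4 (chrom, start, end, name), 0-based half-open."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValidationError(f"{path}: line {lineno}: BED4 needs 4 columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            regions.append(Region(region_id=fields[3], chrom=fields[0], start=start, end=end))
    return RegionMap(regions)


def write_region_bed(regions: RegionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


MANDATORY_SHEET_COLUMNS = ["sample_id", "patient_id"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Headered CSV of per-sample clinical data.

    Validates: non-negative times, purity in [0, 1], and consistency of the
    progression flag with initial/final AJCC stage when all three are present.
    Unknown columns are preserved untouched.
    """
    sheet = pd.read_csv(path)
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    for col in MANDATORY_SHEET_COLUMNS:
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing mandatory column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("sample sheet has duplicate sample ids")
    for col in ("survival_months", "relapse_months"):
        if col in sheet.columns and (sheet[col].dropna() < 0).any():
            raise ValidationError(f"negative times in column {col!r}")
    if "purity" in sheet.columns:
        pur = sheet["purity"].dropna()
        if ((pur < 0) | (pur > 1)).any():
            raise ValidationError("purity values outside [0, 1]")
    if {"initial_stage", "final_stage", "progression"}.issubset(sheet.columns):
        for _, row in sheet.iterrows():
            if pd.isna(row["initial_stage"]) or pd.isna(row["final_stage"]):
                continue
            delta = stage_rank(row["final_stage"]) - stage_rank(row["initial_stage"])
            prog = bool(row["progression"])
            if delta > 0 and not prog:
                raise ValidationError(
                    f"sample {row['sample_id']}: final stage beyond initial stage "
                    "but progression flag is FALSE"
                )
            if delta < 0:
                raise ValidationError(
                    f"sample {row['sample_id']}: final stage precedes initial stage"
                )
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False, float_format=_FLOAT_FMT)
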