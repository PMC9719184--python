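"""Shared domain types and readers/writers for every file the pipeline touches.

All tabular files are tab-separated UTF-8 with a mandatory header; lines
starting with ``#`` are comments. Gene sets use the MSigDB GMT convention.
Protein coordinates are 1-based and inclusive on both ends, so a domain
spanning ``start..end`` has length ``end - start + 1``.

Readers validate; they never silently coerce. Every dropped row increments a
counter that is emitted through the module logger, and structural problems
raise :class:`ValidationError` naming the offending row.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical sub-class labels for the shipped TRIM annotation (C-I..C-XI plus
#: "unclassified"). Annotations may declare their own label set instead.
DEFAULT_SUBCLASS_LABELS: tuple[str, ...] = (
    "C-I", "C-II", "C-III", "C-IV", "C-V", "C-VI",
    "C-VII", "C-VIII", "C-IX", "C-X", "C-XI", "UC",
)

MAF_REQUIRED_COLUMNS = ("sample", "cancer", "gene", "protein_pos", "ref_aa", "alt_aa")

_AA_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainRecord:
    """A named protein domain, 1-based inclusive amino-acid coordinates."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, protein_pos: int) -> bool:
        return self.start <= protein_pos <= self.end


@dataclass(frozen=True)
class FamilyGene:
    """One family member: sub-class label, protein length and its domains."""

    gene: str
    subclass: str
    protein_length: int
    domains: tuple[DomainRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValidationError(
                f"{self.gene}: protein_length must be >= 1, got {self.protein_length}"
            )
        for d in self.domains:
            if not (1 <= d.start <= d.end <= self.protein_length):
                raise ValidationError(
                    f"{self.gene}/{d.name}: domain coordinates {d.start}-{d.end} "
                    f"violate 1 <= start <= end <= protein_length={self.protein_length}"
                )


class FamilyAnnotation:
    """Collection of :class:`FamilyGene` records keyed by gene identifier.

    Gene identifiers are matched case-sensitively after whitespace stripping;
    no alias resolution is attempted. Overlapping domains within a gene are
    allowed (a mutation inside two overlapping domains counts for each) but
    reported through the logger.
    """

    def __init__(self, genes: Iterable[FamilyGene],
                 subclass_labels: Sequence[str] | None = None):
        self._genes: dict[str, FamilyGene] = {}
        labels = tuple(subclass_labels) if subclass_labels is not None else None
        for g in genes:
            if g.gene in self._genes:
                raise ValidationError(f"duplicate gene identifier {g.gene!r}")
            if labels is not None and g.subclass not in labels:
                raise ValidationError(
                    f"{g.gene}: subclass {g.subclass!r} not in declared label set"
                )
            self._genes[g.gene] = g
        for g in self._genes.values():
            for i, a in enumerate(g.domains):
                for b in g.domains[i + 1:]:
                    if a.start <= b.end and b.start <= a.end:
                        logger.info(
                            "overlapping domains in %s: %s(%d-%d) and %s(%d-%d)",
                            g.gene, a.name, a.start, a.end, b.name, b.start, b.end,
                        )

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[FamilyGene]:
        return iter(self._genes.values())

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def __getitem__(self, gene: str) -> FamilyGene:
        return self._genes[gene]

    def get(self, gene: str) -> FamilyGene | None:
        return self._genes.get(gene)

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    @property
    def subclasses(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self._genes.values():
            seen.setdefault(g.subclass, None)
        return list(seen)

    def members_of(self, subclass: str) -> list[str]:
        return [g.gene for g in self._genes.values() if g.subclass == subclass]

    def domain_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self._genes.values():
            for d in g.domains:
                seen.setdefault(d.name, None)
        return list(seen)


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers (houses the set size N_G)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene with one column per sample;
    ``sample_meta`` is indexed by sample with columns ``patient``, ``cancer``
    and ``status`` (``tumor`` or ``normal``). ``log_scale`` records whether
    values are log2(FPKM + 1) (True) or raw FPKM (False).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    log_scale: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicated gene row keys: {list(dupes)[:5]}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
        if not self.log_scale and (self.values.to_numpy() < 0).any():
            raise ValidationError("FPKM-scale matrix contains negative values")
        bad = set(self.sample_meta["status"]) - {"tumor", "normal"}
        if bad:
            raise ValidationError(f"unknown sample status values: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.values.columns]
        return replace(
            self,
            values=self.values[samples],
            sample_meta=self.sample_meta.loc[samples],
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_family_annotation(
    path: str | Path, subclass_labels: Sequence[str] | None = None
) -> FamilyAnnotation:
    """Read a family annotation TSV (one row per domain).

    Expected columns: ``gene``, ``subclass``, ``protein_length``,
    ``domain_name``, ``domain_start``, ``domain_end``; the domain columns may
    be blank for domain-less genes. Malformed coordinates raise
    :class:`ValidationError` naming the row.
    """
    df = _read_tsv(path, dtype={"gene": str, "subclass": str})
    required = {"gene", "subclass", "protein_length",
                "domain_name", "domain_start", "domain_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    genes: list[FamilyGene] = []
    for (gene, subclass, plen), grp in df.groupby(
        ["gene", "subclass", "protein_length"], sort=False
    ):
        gene = str(gene).strip()
        domains = []
        for row in grp.itertuples():
            if pd.isna(row.domain_name) or str(row.domain_name).strip() == "":
                continue
            try:
                start, end = int(row.domain_start), int(row.domain_end)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: non-integer domain coordinates for "
                    f"{gene}/{row.domain_name}"
                ) from exc
            domains.append(DomainRecord(str(row.domain_name).strip(), start, end))
        try:
            genes.append(
                FamilyGene(gene, str(subclass).strip(), int(plen), tuple(domains))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    annotation = FamilyAnnotation(genes, subclass_labels=subclass_labels)
    logger.info("read %d family genes from %s", len(annotation), path)
    return annotation


def read_maf_like(path: str | Path) -> pd.DataFrame:
    """Read a reduced MAF-like mutation table.

    Required columns: ``sample``, ``cancer``, ``gene``, ``protein_pos``,
    ``ref_aa``, ``alt_aa`` — except that an ``aa_change`` column in
    ``p.R456C`` style may stand in for the last three. Additional numeric
    columns are kept as impact scores. Rows whose protein position cannot be
    parsed as a positive integer are dropped with a logged count.
    """
    df = _read_tsv(path, dtype={"sample": str, "cancer": str, "gene": str})
    if "aa_change" in df.columns and not {"protein_pos", "ref_aa", "alt_aa"} <= set(
        df.columns
    ):
        parsed = df["aa_change"].astype(str).str.strip().map(_parse_aa_change)
        df = df.assign(
            ref_aa=[p[0] for p in parsed],
            protein_pos=[p[1] for p in parsed],
            alt_aa=[p[2] for p in parsed],
        )
    missing = set(MAF_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")

    pos = pd.to_numeric(df["protein_pos"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (pos != pos.round())
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with unparseable protein_pos", path, n_dropped)
    df = df.loc[~bad].copy()
    df["protein_pos"] = pos[~bad].astype(int)
    for col in ("sample", "cancer", "gene", "ref_aa", "alt_aa"):
        df[col] = df[col].astype(str).str.strip()
    if df.empty:
        logger.warning("%s: mutation table is empty", path)
    df.attrs["n_dropped"] = n_dropped
    return df.reset_index(drop=True)


def _parse_aa_change(text: str) -> tuple[str | None, float, str | None]:
    m = _AA_CHANGE_RE.match(text)
    if m is None:
        return None, np.nan, None
    ref, pos, alt = m.groups()
    return ref.upper(), float(pos), alt.upper()


def impact_score_columns(mutations: pd.DataFrame) -> list[str]:
    """Columns of a mutation table that carry per-mutation impact scores."""
    reserved = set(MAF_REQUIRED_COLUMNS) | {"aa_change"}
    return [
        c for c in mutations.columns
        if c not in reserved and pd.api.types.is_numeric_dtype(mutations[c])
    ]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in MSigDB GMT format (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name = fields[0].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(name, genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_expression(
    values_path: str | Path, meta_path: str | Path, log_scale: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples matrix and its per-sample metadata table."""
    values = _read_tsv(values_path, index_col=0)
    values.index = values.index.astype(str)
    meta = read_sample_meta(meta_path)
    return ExpressionMatrix(values=values, sample_meta=meta, log_scale=log_scale)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = _read_tsv(path, dtype=str).set_index("sample")
    missing = {"patient", "cancer", "status"} - set(meta.columns)
    if missing:
        raise ValidationError(f"{path}: sample metadata missing {sorted(missing)}")
    return meta


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a per-sample clinical table: time (days), event (0/1), response."""
    df = _read_tsv(path, dtype={"sample": str}).set_index("sample")
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: clinical table missing {sorted(missing)}")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    if (df["time"] < 0).any():
        raise ValidationError(f"{path}: negative survival times")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValidationError(f"{path}: event must be 0 or 1")
    if "response" in df.columns:
        bad = set(df["response"].dropna()) - {"PD", "SD", "PR", "CR", "NA"}
        if bad:
            raise ValidationError(f"{path}: unknown response labels {sorted(bad)}")
    else:
        df["response"] = "NA"
    df["response"] = df["response"].fillna("NA")
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read an immune feature table: samples in rows, features in columns."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_category_map(path: str | Path) -> pd.Series:
    """Read a feature -> category map (columns ``feature``, ``category``)."""
    df = _read_tsv(path, dtype=str)
    missing = {"feature", "category"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: category map missing {sorted(missing)}")
    return df.set_index("feature")["category"]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_result_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write any result collection as a TSV with stable column order.

    ``records`` may be a DataFrame, a list of dataclasses or a list of dicts.
    Floats are rendered with full (repr) precision so write-then-read is an
    identity on finite values.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [r.__dict__ if hasattr(r, "__dataclass_fields__") else dict(r) for r in records]
        df = pd.DataFrame(rows, columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_expression(matrix: ExpressionMatrix, values_path: str | Path,
                     meta_path: str | Path) -> None:
    Path(values_path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(values_path, sep="\t", index_label="gene",
                         float_format="%.17g")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def write_family_annotation(annotation: FamilyAnnotation, path: str | Path) -> None:
    rows = []
    for g in annotation:
        if g.domains:
            for d in g.domains:
                rows.append((g.gene, g.subclass, g.protein_length, d.name, d.start, d.end))
        else:
            rows.append((g.gene, g.subclass, g.protein_length, "", "", ""))
    df = pd.DataFrame(rows, columns=["gene", "subclass", "protein_length",
                                     "domain_name", "domain_start", "domain_end"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def bundled_data_path(name: str) -> Path:
    """Path to a data file shipped with the package (fixtures are editable
    reconstructions; users may substitute their own)."""
    return Path(__file__).parent / "data" / name


def load_bundled_family_annotation() -> FamilyAnnotation:
    """The shipped TRIM-family annotation (77 genes, 12 sub-classes)."""
    return read_family_annotation(bundled_data_path("trim_family.tsv"))


def load_bundled_immune_regulators() -> pd.Series:
    """The shipped 78-gene immune-regulator -> category map (7 categories)."""
    return read_category_map(bundled_data_path("immune_regulators.tsv"))
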