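"""Readers and writers for the formats the scoring pipeline touches.

Five inputs are understood:

* multi-sample VCF (plain or bgzipped) — per-individual genotypes,
* a variant annotation TSV (``chrom, pos, ref, alt, gene, consequence, sift``),
* a drug–gene TSV (``drug_id, gene[, role]``) mapping drugs to their
  pharmacokinetic/pharmacodynamic (PK/PD) genes,
* a drug status TSV (``drug_id`` plus five boolean withdrawal/precaution flags),
* a binned count table (row label plus per-bin event counts, one totals row).

All TSVs are UTF-8 with a mandatory header; lines starting with ``#`` are
comments.  Coordinates are 1-based as in VCF; variant identity is exact on
``(chrom, pos, ref, alt)`` after multi-allelic splitting, which makes the
variant key an unambiguous join between the VCF and the annotation table.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

STATUS_FLAGS = (
    "withdrawn_UN",
    "withdrawn_EMA",
    "withdrawn_DrugBank",
    "precaution_Beers",
    "precaution_FDA",
)

ROLES = frozenset({"target", "enzyme", "carrier", "transporter"})


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable layout."""


class RowError(ValueError):
    """A single row violates the format contract; the message names the line."""


class EmptyIntersectionError(ValueError):
    """The VCF and the annotation table share no variant."""


class ConsistencyError(ValueError):
    """Counts in a binned table contradict each other (event > total)."""


class VariantKey(NamedTuple):
    """Exact identity of one alternate allele at one site (1-based, split)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class VariantAnnotation:
    """One nonsynonymous variant with its gene and SIFT score in [0, 1]."""

    key: VariantKey
    gene: str
    consequence: str
    sift: float


class AnnotationSet(Sequence):
    """Retained annotations plus bookkeeping about dropped input rows.

    Behaves as a sequence of :class:`VariantAnnotation`; ``n_input`` minus
    ``n_dropped`` always equals ``len(self)``.
    """

    def __init__(self, records: list[VariantAnnotation], n_input: int, n_dropped: int):
        self.records = records
        self.n_input = n_input
        self.n_dropped = n_dropped

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __repr__(self) -> str:
        return (
            f"AnnotationSet({len(self.records)} retained, "
            f"{self.n_dropped} dropped of {self.n_input})"
        )


@dataclass
class GenotypeCarriage:
    """Individual × variant boolean carriage matrix.

    ``carriage[i, j]`` is true iff individual ``i`` carries at least one copy
    of the alternate allele of variant ``j``.  Zygosity and phasing are
    deliberately ignored: the gene score is defined over the variants an
    individual carries, with no dose term.  Missing genotypes count as
    non-carriage (``n_missing`` records how many calls that affected).
    """

    individuals: list[str]
    variants: list[VariantKey]
    carriage: np.ndarray  # bool, shape (n_individuals, n_variants)
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.carriage = np.asarray(self.carriage, dtype=bool)
        if self.carriage.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"carriage shape {self.carriage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")


@dataclass
class DrugGeneMap:
    """Drug → PK/PD gene set, after the minimum-gene-count inclusion filter.

    Drugs with fewer than ``min_genes`` distinct genes are excluded
    (``n_excluded`` reports how many).  ``roles``, when present, uses the
    controlled vocabulary target/enzyme/carrier/transporter.
    """

    entries: dict[str, frozenset[str]]
    min_genes: int = 5
    roles: dict[tuple[str, str], str] = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for drug, genes in self.entries.items():
            if len(genes) < max(self.min_genes, 1):
                raise ValueError(
                    f"drug {drug!r} has {len(genes)} genes, below min_genes={self.min_genes}"
                )

    @property
    def drugs(self) -> list[str]:
        return sorted(self.entries)

    def with_min_genes(self, min_genes: int) -> "DrugGeneMap":
        """Re-apply the inclusion filter at a different threshold.

        Only thresholds at or above the one this map was built with can be
        fully faithful (already-excluded drugs cannot come back); the
        sensitivity sweep therefore starts from a map built with min_genes=1.
        """
        if min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        kept = {d: g for d, g in self.entries.items() if len(g) >= min_genes}
        roles = {k: v for k, v in self.roles.items() if k[0] in kept}
        return DrugGeneMap(
            entries=kept,
            min_genes=min_genes,
            roles=roles,
            n_excluded=self.n_excluded + (len(self.entries) - len(kept)),
        )


@dataclass
class DrugStatus:
    """Per-drug withdrawal/precaution flags.

    A drug is "withdrawn" iff any withdrawn_* flag is set; "other" iff all
    five flags are false.  Flags are not exclusive — a withdrawn drug may
    simultaneously sit on the Beers or FDA pharmacogenomics lists.
    """

    frame: pd.DataFrame  # index: drug_id; columns: STATUS_FLAGS (bool)

    def __post_init__(self) -> None:
        missing = [c for c in STATUS_FLAGS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"status table missing flag columns: {missing}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate drug ids in status table")
        self.frame = self.frame[list(STATUS_FLAGS)].astype(bool)

    @property
    def withdrawn(self) -> pd.Series:
        cols = [c for c in STATUS_FLAGS if c.startswith("withdrawn")]
        return self.frame[cols].any(axis=1)

    @property
    def other(self) -> pd.Series:
        return ~self.frame.any(axis=1)

    def categories(self) -> dict[str, list[str]]:
        """Overlapping drug categories: withdrawn / beers / fda / other."""
        return {
            "withdrawn": list(self.frame.index[self.withdrawn]),
            "beers": list(self.frame.index[self.frame["precaution_Beers"]]),
            "fda": list(self.frame.index[self.frame["precaution_FDA"]]),
            "other": list(self.frame.index[self.other]),
        }


@dataclass
class BinnedCountTable:
    """Per-bin event counts for one or more labelled rows, plus bin totals."""

    bin_labels: list[str]
    rows: dict[str, np.ndarray]
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=np.int64)
        if self.totals.shape != (len(self.bin_labels),):
            raise ValueError("totals length does not match bin labels")
        if (self.totals < 0).any():
            raise ConsistencyError("negative totals")
        clean = {}
        for label, counts in self.rows.items():
            counts = np.asarray(counts, dtype=np.int64)
            if counts.shape != self.totals.shape:
                raise ValueError(f"row {label!r} has wrong number of bins")
            if (counts < 0).any():
                raise ConsistencyError(f"negative count in row {label!r}")
            over = np.nonzero(counts > self.totals)[0]
            if over.size:
                raise ConsistencyError(
                    f"row {label!r}: events exceed totals in bin "
                    f"{self.bin_labels[over[0]]!r}"
                )
            clean[label] = counts
        self.rows = clean


# ---------------------------------------------------------------------------
# TSV helpers


def _read_tsv(path: str | Path, required: Sequence[str]) -> tuple[pd.DataFrame, list[int]]:
    """Read a commented TSV; return the frame and a data-row → file-line map."""
    path = Path(path)
    lines: list[int] = []
    header_seen = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            lines.append(lineno)
    if not header_seen:
        raise SchemaError(f"{path}: empty file (no header row)")
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return frame, lines


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read the variant annotation table.

    Rows whose consequence is not ``nonsynonymous`` or whose SIFT value is
    missing are dropped (counted, logged).  A SIFT value outside [0, 1] or a
    non-numeric one is an error naming the offending file line.
    """
    frame, lines = _read_tsv(
        path, ["chrom", "pos", "ref", "alt", "gene", "consequence", "sift"]
    )
    records: list[VariantAnnotation] = []
    n_dropped = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        lineno = lines[i] if i < len(lines) else -1
        consequence = str(row.consequence).strip()
        sift_raw = row.sift
        if consequence != "nonsynonymous" or sift_raw is None or (
            isinstance(sift_raw, float) and np.isnan(sift_raw)
        ) or str(sift_raw).strip() == "":
            n_dropped += 1
            continue
        try:
            sift = float(sift_raw)
        except (TypeError, ValueError):
            raise RowError(f"{path} line {lineno}: sift {sift_raw!r} is not numeric")
        if not 0.0 <= sift <= 1.0:
            raise RowError(f"{path} line {lineno}: sift {sift} outside [0, 1]")
        gene = str(row.gene).strip()
        if not gene:
            raise RowError(f"{path} line {lineno}: empty gene symbol")
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise RowError(f"{path} line {lineno}: pos {row.pos!r} is not an integer")
        if pos < 1:
            raise RowError(f"{path} line {lineno}: pos {pos} < 1")
        key = VariantKey(str(row.chrom).strip(), pos, str(row.ref).strip(), str(row.alt).strip())
        if key.ref == key.alt:
            raise RowError(f"{path} line {lineno}: ref equals alt ({key.ref!r})")
        records.append(VariantAnnotation(key, gene, "nonsynonymous", sift))
    if n_dropped:
        logger.info("read_annotations: dropped %d of %d rows", n_dropped, len(frame))
    return AnnotationSet(records, n_input=len(frame), n_dropped=n_dropped)


def read_drug_gene_map(path: str | Path, min_genes: int = 5) -> DrugGeneMap:
    """Read the drug → PK/PD gene table and apply the inclusion filter.

    Drugs with fewer than ``min_genes`` distinct genes are excluded; duplicate
    (drug, gene) pairs are deduplicated with a warning.  Gene symbols are
    matched case-sensitively after whitespace trimming.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    frame, lines = _read_tsv(path, ["drug_id", "gene"])
    if frame.empty:
        raise SchemaError(f"{path}: drug-gene table has no data rows")
    has_role = "role" in frame.columns
    sets: dict[str, set[str]] = {}
    roles: dict[tuple[str, str], str] = {}
    n_dup = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        lineno = lines[i] if i < len(lines) else -1
        drug = str(row.drug_id).strip()
        gene = str(row.gene).strip()
        if not drug or not gene:
            raise RowError(f"{path} line {lineno}: empty drug_id or gene")
        genes = sets.setdefault(drug, set())
        if gene in genes:
            n_dup += 1
            continue
        genes.add(gene)
        if has_role and isinstance(row.role, str) and row.role.strip():
            role = row.role.strip()
            if role not in ROLES:
                raise RowError(
                    f"{path} line {lineno}: role {role!r} not in {sorted(ROLES)}"
                )
            roles[(drug, gene)] = role
    if n_dup:
        logger.warning("read_drug_gene_map: deduplicated %d (drug, gene) pairs", n_dup)
    kept = {d: frozenset(g) for d, g in sets.items() if len(g) >= min_genes}
    n_excluded = len(sets) - len(kept)
    if n_excluded:
        logger.info(
            "read_drug_gene_map: excluded %d of %d drugs below min_genes=%d",
            n_excluded, len(sets), min_genes,
        )
    return DrugGeneMap(
        entries=kept,
        min_genes=min_genes,
        roles={k: v for k, v in roles.items() if k[0] in kept},
        n_excluded=n_excluded,
    )


def read_status(path: str | Path) -> DrugStatus:
    """Read per-drug withdrawal/precaution flags (0/1 or true/false)."""
    frame, _ = _read_tsv(path, ["drug_id", *STATUS_FLAGS])
    truthy = {"1", "true", "yes"}
    falsy = {"0", "false", "no", ""}
    out = {}
    for flag in STATUS_FLAGS:
        vals = frame[flag].fillna("0").astype(str).str.strip().str.lower()
        bad = ~vals.isin(truthy | falsy)
        if bad.any():
            raise RowError(
                f"{path}: column {flag!r} has non-boolean value {vals[bad].iloc[0]!r}"
            )
        out[flag] = vals.isin(truthy)
    df = pd.DataFrame(out)
    df.index = frame["drug_id"].astype(str).str.strip()
    df.index.name = "drug_id"
    return DrugStatus(df)


def read_binned_counts(
    path: str | Path, totals_label: str = "total_study_drugs"
) -> BinnedCountTable:
    """Read a binned count table; the row labelled ``totals_label`` is the totals."""
    frame, lines = _read_tsv(path, [])
    if frame.shape[1] < 3:
        raise SchemaError(f"{path}: need a label column and at least two bins")
    label_col = frame.columns[0]
    bin_labels = list(frame.columns[1:])
    rows: dict[str, np.ndarray] = {}
    totals = None
    for i, row in enumerate(frame.itertuples(index=False)):
        lineno = lines[i] if i < len(lines) else -1
        label = str(row[0]).strip()
        try:
            counts = np.array([int(v) for v in row[1:]], dtype=np.int64)
        except (TypeError, ValueError):
            raise RowError(f"{path} line {lineno}: non-integer count in row {label!r}")
        if (counts < 0).any():
            raise RowError(f"{path} line {lineno}: negative count in row {label!r}")
        if label == totals_label:
            totals = counts
        else:
            rows[label] = counts
    if totals is None:
        raise SchemaError(f"{path}: no totals row labelled {totals_label!r}")
    return BinnedCountTable(bin_labels=bin_labels, rows=rows, totals=totals)


def write_binned_counts(
    table: BinnedCountTable,
    path: str | Path,
    totals_label: str = "total_study_drugs",
    header_comment: str | None = None,
) -> None:
    """Write a binned count table in the layout :func:`read_binned_counts` reads."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("label\t" + "\t".join(table.bin_labels) + "\n")
        for label, counts in table.rows.items():
            fh.write(label + "\t" + "\t".join(str(int(c)) for c in counts) + "\n")
        fh.write(
            totals_label + "\t" + "\t".join(str(int(c)) for c in table.totals) + "\n"
        )


def reference_trend_counts() -> BinnedCountTable:
    """The packaged reference withdrawal/precaution count table (10 AUC bins)."""
    return read_binned_counts(Path(__file__).parent / "data" / "withdrawal_trend_counts.tsv")


# ---------------------------------------------------------------------------
# VCF


def read_vcf_carriage(
    path: str | Path, annotations: Sequence[VariantAnnotation]
) -> GenotypeCarriage:
    """Build the individual × variant carriage matrix from a multi-sample VCF.

    Only sites present in ``annotations`` are kept.  Multi-allelic records are
    split into one variant per alternate allele; an individual carries the
    split variant iff any of its called alleles is that specific alternate.
    Missing genotype calls count as non-carriage and are tallied in
    ``n_missing``.

    Raises :class:`EmptyIntersectionError` if no VCF site matches any
    annotation — an empty result would silently score every drug as ideal.
    """
    if not annotations:
        raise ValueError("annotations must be nonempty")
    wanted = {a.key for a in annotations}
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise RowError(f"{path}: cannot parse VCF header: {exc}") from exc
    individuals = list(vcf.header.samples)
    columns: list[np.ndarray] = []
    variants: list[VariantKey] = []
    n_missing = 0
    n_records = 0
    try:
        for rec in vcf:
            n_records += 1
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                key = VariantKey(str(rec.chrom), int(rec.pos), str(rec.ref), str(alt))
                if key not in wanted:
                    continue
                col = np.zeros(len(individuals), dtype=bool)
                for i, sample in enumerate(individuals):
                    alleles = rec.samples[sample].get("GT")
                    if alleles is None or all(a is None for a in alleles):
                        n_missing += 1
                        continue
                    col[i] = any(a == alt_index for a in alleles if a is not None)
                variants.append(key)
                columns.append(col)
    except (OSError, ValueError) as exc:
        raise RowError(
            f"{path}: malformed VCF near record {n_records + 1}: {exc}"
        ) from exc
    finally:
        vcf.close()
    if not variants:
        raise EmptyIntersectionError(
            f"{path}: no VCF site matches any of the {len(wanted)} annotated variants"
        )
    if n_missing:
        logger.info(
            "read_vcf_carriage: %d missing genotype calls treated as non-carriage",
            n_missing,
        )
    carriage = np.column_stack(columns)
    return GenotypeCarriage(
        individuals=[str(s) for s in individuals],
        variants=variants,
        carriage=carriage,
        n_missing=n_missing,
    )
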