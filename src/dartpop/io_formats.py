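"""Reading and writing DArTseq-style genotype tables and companion sheets.

DArTseq genotyping yields two marker systems: co-dominant SNPs scored as
alternate-allele dosages (0/1/2) and dominant SilicoDArT markers scored as
fragment presence/absence (0/1).  Exports from the platform come in a
"one-row" layout (one line per marker, dosage codes per sample) or a
"two-row" layout (one line per allele, presence codes per sample).  Both
dialects are conventions documented here, not a published standard: real
exports vary, which is why every reader validates tokens strictly and every
parse failure names the file, line and column involved.

Genotype calls live in a dense integer matrix (samples x markers) with a
single reserved sentinel for missing data; both ``-`` and the empty string
map to it on input.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dartpop")

#: Reserved sentinel for a missing call, distinct from every valid code.
MISSING = -9

#: The fourteen chromosomes of the Napier grass (Cenchrus purpureus) genome.
CHROMOSOMES: tuple[str, ...] = tuple(
    f"Cp{sub}{i:02d}" for sub in ("A", "B") for i in range(1, 8)
)

SNP = "SNP"
SILICODART = "SilicoDArT"

_MISSING_TOKENS = {"-", "", "NA", "na", "nan"}


class FormatError(ValueError):
    """A file does not have the expected column layout."""


class ParseError(ValueError):
    """A cell holds a token outside the marker-type alphabet."""

    def __init__(self, path, line: int, column: str, token: str):
        self.path, self.line, self.column, self.token = path, line, column, token
        super().__init__(
            f"{path}: line {line}, column {column!r}: unknown genotype token {token!r}"
        )


@dataclass(frozen=True)
class MarkerRecord:
    """Identity and map position of one DArT marker."""

    marker_id: str
    marker_type: str = SNP
    chrom: str = "unplaced"
    pos: int | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self):
        if self.marker_type not in (SNP, SILICODART):
            raise ValueError(f"unknown marker type {self.marker_type!r}")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"{self.marker_id}: position must be 1-based (got {self.pos})")

    @property
    def mapped(self) -> bool:
        """True when the marker sits on one of the 14 chromosomes or a contig."""
        return self.chrom in CHROMOSOMES or self.chrom.startswith("contig:")


@dataclass
class GenotypeMatrix:
    """Samples x markers integer call matrix, the substrate of every statistic.

    SNP calls count copies of the marker's alternate allele (0, 1, 2);
    SilicoDArT calls are fragment presence (0, 1).  ``MISSING`` marks no-calls.
    """

    sample_ids: list[str]
    markers: list[MarkerRecord]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.markers)} markers)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        snp = self.snp_mask
        valid = (self.calls == MISSING) | (self.calls >= 0)
        ceil = np.where(snp, 2, 1)
        valid &= (self.calls == MISSING) | (self.calls <= ceil)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"call {self.calls[i, j]} at sample {self.sample_ids[i]!r}, "
                f"marker {self.markers[j].marker_id!r} outside the "
                f"{self.markers[j].marker_type} alphabet"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def snp_mask(self) -> np.ndarray:
        return np.array([m.marker_type == SNP for m in self.markers], dtype=bool)

    def select_markers(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Subset to the given marker ids (order preserved) or boolean mask."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = [j for j, m in enumerate(self.markers) if m.marker_id in wanted]
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.markers[j] for j in idx],
            self.calls[:, idx],
        )

    def select_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [order[s] for s in keep]
        return GenotypeMatrix(list(keep), list(self.markers), self.calls[idx, :])

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def concat_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if [m.marker_id for m in other.markers] != self.marker_ids:
            raise ValueError("marker sets differ")
        return GenotypeMatrix(
            self.sample_ids + other.sample_ids,
            list(self.markers),
            np.vstack([self.calls, other.calls]),
        )


@dataclass
class SampleSheet:
    """Per-sample passport data: collection of origin and recorded seed parent."""

    data: pd.DataFrame  # columns: sample_id, collection, recorded_seed_parent

    def __post_init__(self):
        required = {"sample_id", "collection"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"sample sheet lacks column(s) {sorted(missing)}")
        if "recorded_seed_parent" not in self.data.columns:
            self.data["recorded_seed_parent"] = None
        if self.data["sample_id"].duplicated().any():
            dupes = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id(s): {sorted(set(dupes))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def collection_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["collection"]))

    def recorded_parents(self) -> dict[str, str]:
        out = {}
        for _, row in self.data.iterrows():
            p = row["recorded_seed_parent"]
            if p is not None and not (isinstance(p, float) and np.isnan(p)) and p != "":
                out[row["sample_id"]] = p
        return out


@dataclass
class PhenotypeTable:
    """Trait observations, possibly several replicates/harvests per genotype."""

    data: pd.DataFrame  # columns: sample_id, trait, value [, replicate]

    def __post_init__(self):
        required = {"sample_id", "trait", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"phenotype table lacks column(s) {sorted(missing)}")
        if (self.data["value"] < 0).any():
            raise ValueError("phenotype values must be non-negative")

    def aggregate(self, trait: str | None = None) -> pd.Series:
        """Mean value per genotype (one number per sample after aggregation)."""
        d = self.data if trait is None else self.data[self.data["trait"] == trait]
        return d.groupby("sample_id")["value"].mean()


# ---------------------------------------------------------------------------
# Genotype table readers
# ---------------------------------------------------------------------------

_SNP_META = ["marker_id", "chrom", "pos", "ref", "alt"]
_SILICO_META = ["marker_id", "chrom", "pos"]
_TWOROW_META = ["marker_id", "chrom", "pos", "allele"]


def _parse_pos(token: str) -> int | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    return int(token)


def _parse_call(token: str, allowed: tuple[int, ...], path, line: int, column: str) -> int:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return MISSING
    if token.isdigit() and int(token) in allowed:
        return int(token)
    raise ParseError(path, line, column, token)


def _read_table(path, expected_meta: list[str]):
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    for i, name in enumerate(expected_meta):
        if i >= len(header) or header[i].lower() != name:
            got = header[i] if i < len(header) else "<absent>"
            raise FormatError(
                f"{path}: expected metadata column {i + 1} to be {name!r}, got {got!r}"
            )
    sample_ids = header[len(expected_meta):]
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns after the metadata columns")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicated sample columns")
    return rows[1:], sample_ids


def read_dartseq_snp(path, dialect: str = "one-row") -> GenotypeMatrix:
    """Read a DArTseq SNP table in the one-row or two-row dialect.

    One-row: columns ``marker_id, chrom, pos, ref, alt`` then one dosage
    column (0/1/2, ``-`` missing) per sample.

    Two-row: columns ``marker_id, chrom, pos, allele`` then one
    presence column (0/1) per sample; consecutive row pairs sharing the
    clone-id prefix of ``marker_id`` (the part before ``|``) carry the
    reference and alternate allele respectively.  Presence pairs
    (1,0)/(0,1)/(1,1) map to dosages 0/2/1.
    """
    if dialect == "one-row":
        return _read_snp_one_row(path)
    if dialect == "two-row":
        return _read_snp_two_row(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'one-row' or 'two-row')")


def _read_snp_one_row(path) -> GenotypeMatrix:
    rows, sample_ids = _read_table(path, _SNP_META)
    markers, calls = [], []
    for lineno, row in enumerate(rows, start=2):
        mid, chrom, pos, ref, alt = (c.strip() for c in row[:5])
        markers.append(
            MarkerRecord(mid, SNP, chrom or "unplaced", _parse_pos(pos), ref or None, alt or None)
        )
        calls.append(
            [
                _parse_call(tok, (0, 1, 2), path, lineno, sample_ids[j])
                for j, tok in enumerate(row[5:])
            ]
        )
    gm = GenotypeMatrix(sample_ids, markers, np.array(calls, dtype=np.int16).T)
    logger.info("read %d SNP markers x %d samples from %s", gm.n_markers, gm.n_samples, path)
    return gm


def _clone_prefix(marker_id: str) -> str:
    return marker_id.split("|")[0].strip()


def _read_snp_two_row(path) -> GenotypeMatrix:
    rows, sample_ids = _read_table(path, _TWOROW_META)
    if len(rows) % 2:
        raise FormatError(f"{path}: two-row dialect requires an even number of data rows")
    markers, calls = [], []
    for r in range(0, len(rows), 2):
        ref_row, alt_row = rows[r], rows[r + 1]
        if _clone_prefix(ref_row[0]) != _clone_prefix(alt_row[0]):
            raise FormatError(
                f"{path}: rows {r + 2} and {r + 3} do not share a clone id prefix "
                f"({ref_row[0]!r} vs {alt_row[0]!r})"
            )
        mid, chrom, pos, ref = (c.strip() for c in ref_row[:4])
        alt = alt_row[3].strip()
        markers.append(
            MarkerRecord(
                _clone_prefix(mid), SNP, chrom or "unplaced", _parse_pos(pos), ref or None, alt or None
            )
        )
        row_calls = []
        for j in range(len(sample_ids)):
            a = _parse_call(ref_row[4 + j], (0, 1), path, r + 2, sample_ids[j])
            b = _parse_call(alt_row[4 + j], (0, 1), path, r + 3, sample_ids[j])
            if a == MISSING or b == MISSING or (a, b) == (0, 0):
                row_calls.append(MISSING)
            elif (a, b) == (1, 0):
                row_calls.append(0)
            elif (a, b) == (0, 1):
                row_calls.append(2)
            else:  # (1, 1) -> heterozygote
                row_calls.append(1)
        calls.append(row_calls)
    gm = GenotypeMatrix(sample_ids, markers, np.array(calls, dtype=np.int16).T)
    logger.info("read %d SNP markers x %d samples from %s", gm.n_markers, gm.n_samples, path)
    return gm


def read_dartseq_silico(path) -> GenotypeMatrix:
    """Read a SilicoDArT presence/absence table (codes 0/1, ``-`` missing)."""
    rows, sample_ids = _read_table(path, _SILICO_META)
    markers, calls = [], []
    for lineno, row in enumerate(rows, start=2):
        mid, chrom, pos = (c.strip() for c in row[:3])
        markers.append(MarkerRecord(mid, SILICODART, chrom or "unplaced", _parse_pos(pos)))
        calls.append(
            [
                _parse_call(tok, (0, 1), path, lineno, sample_ids[j])
                for j, tok in enumerate(row[3:])
            ]
        )
    gm = GenotypeMatrix(sample_ids, markers, np.array(calls, dtype=np.int16).T)
    logger.info(
        "read %d SilicoDArT markers x %d samples from %s", gm.n_markers, gm.n_samples, path
    )
    return gm


def write_dartseq_snp(gm: GenotypeMatrix, path) -> None:
    """Write the one-row SNP dialect (inverse of ``read_dartseq_snp``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SNP_META + gm.sample_ids)
        for j, m in enumerate(gm.markers):
            col = gm.calls[:, j]
            w.writerow(
                [m.marker_id, m.chrom, m.pos if m.pos is not None else "-",
                 m.ref_allele or "-", m.alt_allele or "-"]
                + ["-" if c == MISSING else str(c) for c in col]
            )


def write_dartseq_silico(gm: GenotypeMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SILICO_META + gm.sample_ids)
        for j, m in enumerate(gm.markers):
            col = gm.calls[:, j]
            w.writerow(
                [m.marker_id, m.chrom, m.pos if m.pos is not None else "-"]
                + ["-" if c == MISSING else str(c) for c in col]
            )


# ---------------------------------------------------------------------------
# Sample sheet and phenotypes
# ---------------------------------------------------------------------------


def read_sample_sheet(path, genotype_samples: Iterable[str] | None = None) -> SampleSheet:
    """Read a sample sheet CSV/TSV and check referential integrity.

    Unknown collection labels pass through verbatim.  When
    ``genotype_samples`` is given, mismatches between the sheet and the
    genotype matrix raise warnings (never a silent drop), as does a
    ``recorded_seed_parent`` that names no known sample.
    """
    df = _read_csv_or_tsv(path)
    sheet = SampleSheet(df)
    known = set(sheet.sample_ids)
    if genotype_samples is not None:
        geno = set(genotype_samples)
        only_sheet = sorted(known - geno)
        only_geno = sorted(geno - known)
        if only_sheet:
            warnings.warn(f"sample sheet rows absent from genotypes: {only_sheet}")
        if only_geno:
            warnings.warn(f"genotyped samples absent from sample sheet: {only_geno}")
        known |= geno
    orphans = sorted(p for p in sheet.recorded_parents().values() if p not in known)
    if orphans:
        warnings.warn(f"recorded_seed_parent not among samples: {orphans}")
    return sheet


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(_read_csv_or_tsv(path))


def _read_csv_or_tsv(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Summaries and exports
# ---------------------------------------------------------------------------


def chromosome_marker_counts(gm: GenotypeMatrix) -> pd.DataFrame:
    """Markers per chromosome/contig/unplaced; fractions sum to one."""
    buckets: dict[str, int] = {}
    for m in gm.markers:
        key = m.chrom if (m.chrom in CHROMOSOMES or m.chrom.startswith("contig:")) else "unplaced"
        buckets[key] = buckets.get(key, 0) + 1
    order = [c for c in CHROMOSOMES if c in buckets]
    order += sorted(k for k in buckets if k.startswith("contig:"))
    if "unplaced" in buckets:
        order.append("unplaced")
    n = np.array([buckets[k] for k in order], dtype=float)
    return pd.DataFrame(
        {"chrom": order, "n_markers": n.astype(int), "fraction": n / n.sum()}
    )


def export_vcf(gm: GenotypeMatrix, path) -> int:
    """Write SNP calls as VCF 4.2 (unphased GT); returns the SNP count written.

    SilicoDArT markers carry no allele pair and are excluded (count logged).
    """
    snp = gm.snp_mask
    n_excluded = int((~snp).sum())
    if n_excluded:
        logger.info("export_vcf: excluding %d SilicoDArT markers", n_excluded)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    order = sorted(
        np.flatnonzero(snp),
        key=lambda j: (
            _chrom_rank(gm.markers[j].chrom),
            gm.markers[j].pos or 0,
            gm.markers[j].marker_id,
        ),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dartpop\n")
        for c in CHROMOSOMES:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j in order:
            m = gm.markers[j]
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.pos or 0),
                        m.marker_id,
                        m.ref_allele or "N",
                        m.alt_allele or "N",
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + [gt_map[int(c)] for c in gm.calls[:, j]]
                )
                + "\n"
            )
    return int(snp.sum())


def _chrom_rank(chrom: str):
    try:
        return (0, CHROMOSOMES.index(chrom))
    except ValueError:
        return (1, chrom)


def export_newick(tree, path) -> None:
    """Write a clustering tree (see ``clustering.upgma``) as newick."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def export_tsv(table: pd.DataFrame, path) -> None:
    """Write any result table as TSV with a stable column order."""
    table.to_csv(path, sep="\t", index=False)
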