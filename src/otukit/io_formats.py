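"""Readers and writers for the QIIME-era file dialects the toolkit consumes.

Covers BIOM 1.0 JSON OTU tables (sparse and dense), QIIME mapping files,
``pick_otus``-style OTU maps, Greengenes taxonomy tables, tab-delimited
distance matrices, Newick trees and FASTA. Every reader/writer pair
round-trips: ``write(read(path))`` reproduces the data and vice versa.

Domain containers
-----------------
OtuTable
    OTU x sample count (or proportion) matrix backed by a pandas DataFrame,
    with optional per-OTU taxonomy strings.
OtuMap
    Ordered mapping OTU ID -> member sequence IDs (a plain dict; helpers
    here validate its invariants).
TaxonomyString
    Greengenes-style 7-rank lineage with truncation semantics.
SampleMetadata
    QIIME mapping-file rows keyed by sample ID.

Distance matrices are represented by :class:`skbio.DistanceMatrix` and trees
by :class:`dendropy.Tree`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix

log = logging.getLogger("otukit")

__all__ = [
    "TaxonomyString",
    "OtuTable",
    "SampleMetadata",
    "read_biom",
    "write_biom",
    "read_mapping",
    "write_mapping",
    "read_otu_map",
    "write_otu_map",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "RANK_PREFIXES",
    "RANK_DEPTH",
]

#: Canonical Greengenes rank prefixes, kingdom through species.
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Rank name -> truncation depth (number of leading ranks kept).
RANK_DEPTH = {
    "kingdom": 1,
    "phylum": 2,
    "class": 3,
    "order": 4,
    "family": 5,
    "genus": 6,
    "species": 7,
}


@dataclass(frozen=True)
class TaxonomyString:
    """A Greengenes-style lineage: ordered (rank prefix, name) pairs.

    Rank prefixes are the canonical ``k__ p__ c__ o__ f__ g__ s__``; a token
    that carries no recognizable prefix is kept verbatim as a name with an
    empty prefix. Names may be empty (unresolved ranks).
    """

    ranks: tuple[tuple[str, str], ...] = ()

    @classmethod
    def parse(cls, lineage: str) -> "TaxonomyString":
        lineage = lineage.strip()
        if not lineage:
            return cls(())
        ranks = []
        for token in lineage.split(";"):
            token = token.strip()
            if len(token) >= 3 and token[:3] in RANK_PREFIXES:
                ranks.append((token[:3], token[3:].strip()))
            else:
                if token:
                    log.debug("unparseable rank token kept verbatim: %r", token)
                ranks.append(("", token))
        return cls(tuple(ranks))

    def __str__(self) -> str:
        return "; ".join(prefix + name for prefix, name in self.ranks)

    def truncate(self, depth: int) -> "TaxonomyString":
        """Keep the first ``depth`` ranks (e.g. 6 for genus level)."""
        return TaxonomyString(self.ranks[:depth])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.ranks)

    def name_at(self, prefix: str) -> str:
        for p, name in self.ranks:
            if p == prefix:
                return name
        return ""

    def deepest_named(self) -> tuple[str, str] | None:
        """The last (prefix, name) pair with a nonempty name, or None."""
        for prefix, name in reversed(self.ranks):
            if name:
                return prefix, name
        return None


class OtuTable:
    """OTU x sample abundance matrix with optional per-OTU taxonomy.

    ``counts`` is a DataFrame indexed by OTU ID with sample-ID columns;
    values are nonnegative. ``taxonomy`` maps OTU ID -> lineage string.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: dict[str, str] | None = None):
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if (counts.values < 0).any():
            raise ValueError("negative counts in OTU table")
        self.counts = counts
        self.taxonomy = taxonomy

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def grand_total(self) -> float:
        return float(self.counts.values.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.counts.values, other.counts.values)
            and (self.taxonomy or {}) == (other.taxonomy or {})
        )

    def __repr__(self) -> str:
        return f"OtuTable({self.shape[0]} OTUs x {self.shape[1]} samples)"


#: Columns every QIIME mapping file must provide besides #SampleID.
REQUIRED_MAPPING_COLUMNS = ("BarcodeSequence", "LinkerPrimerSequence", "Description")


@dataclass
class SampleMetadata:
    """QIIME mapping-file contents: one row of fields per sample."""

    frame: pd.DataFrame  # indexed by sample ID, columns in file order

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in mapping: {dupes}")
        missing = [c for c in REQUIRED_MAPPING_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"mapping file missing required column(s): {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"mapping file has no column {name!r}")
        return self.frame[name]

    def groups(self, category: str) -> dict[str, list[str]]:
        """Sample IDs per category value, in order of first appearance."""
        col = self.column(category)
        out: dict[str, list[str]] = {}
        for sid, val in col.items():
            out.setdefault(str(val), []).append(sid)
        return out


# ---------------------------------------------------------------------------
# BIOM 1.0 JSON
# ---------------------------------------------------------------------------

def _taxonomy_from_row_metadata(meta) -> str | None:
    if not isinstance(meta, dict):
        return None
    tax = meta.get("taxonomy")
    if tax is None:
        return None
    if isinstance(tax, str):
        return str(TaxonomyString.parse(tax))
    return str(TaxonomyString(tuple(
        (t.strip()[:3], t.strip()[3:].strip()) if t.strip()[:3] in RANK_PREFIXES
        else ("", t.strip())
        for t in tax
    )))


def read_biom(path) -> OtuTable:
    """Read a BIOM 1.0 JSON table (sparse or dense ``matrix_type``)."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed BIOM JSON in {path}: {exc}") from None
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in doc:
            raise ValueError(f"malformed BIOM file {path}: missing element {key!r}")
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    if len(otu_ids) != n_rows or len(sample_ids) != n_cols:
        raise ValueError(f"malformed BIOM file {path}: shape does not match rows/columns")
    mat = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    elif doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        raise ValueError(
            f"malformed BIOM file {path}: unknown matrix_type {doc['matrix_type']!r}"
        )
    taxonomy = {}
    for r in doc["rows"]:
        tax = _taxonomy_from_row_metadata(r.get("metadata"))
        if tax is not None:
            taxonomy[str(r["id"])] = tax
    counts = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    return OtuTable(counts, taxonomy=taxonomy or None)


def write_biom(table: OtuTable, path, matrix_type: str = "sparse") -> None:
    """Write an :class:`OtuTable` as BIOM 1.0 JSON."""
    mat = table.counts.values
    rows = []
    for otu in table.otu_ids:
        meta = None
        if table.taxonomy and otu in table.taxonomy:
            meta = {"taxonomy": [t.strip() for t in table.taxonomy[otu].split(";")]}
        rows.append({"id": otu, "metadata": meta})
    cols = [{"id": s, "metadata": None} for s in table.sample_ids]
    if matrix_type == "sparse":
        nz = np.argwhere(mat != 0)
        data = [[int(i), int(j), float(mat[i, j])] for i, j in nz]
    elif matrix_type == "dense":
        data = [[float(v) for v in row] for row in mat]
    else:
        raise ValueError(f"matrix_type must be 'sparse' or 'dense', got {matrix_type!r}")
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "otukit",
        "date": "",
        "matrix_type": matrix_type,
        "matrix_element_type": "float",
        "shape": [len(rows), len(cols)],
        "rows": rows,
        "columns": cols,
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# QIIME mapping file
# ---------------------------------------------------------------------------

def read_mapping(path) -> SampleMetadata:
    """Read a QIIME mapping file (tab-delimited, header starts '#SampleID')."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#SampleID"):
        raise ValueError(f"mapping file {path} must start with a '#SampleID' header")
    header = lines[0].lstrip("#").split("\t")
    records = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue  # comments after the header are skipped
        records.append(line.split("\t"))
    frame = pd.DataFrame(records, columns=header)
    frame = frame.set_index(header[0])
    return SampleMetadata(frame)


def write_mapping(metadata: SampleMetadata, path) -> None:
    with open(path, "w") as fh:
        fh.write("#SampleID\t" + "\t".join(metadata.frame.columns) + "\n")
        for sid, row in metadata.frame.iterrows():
            fh.write(sid + "\t" + "\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# OTU map (pick_otus output)
# ---------------------------------------------------------------------------

def validate_otu_map(otu_map: Mapping[str, list[str]]) -> None:
    """Check OTU-map invariants: globally unique seq IDs, no empty entries."""
    seen: set[str] = set()
    for otu, seqs in otu_map.items():
        if not seqs:
            raise ValueError(f"OTU {otu!r} has no member sequences")
        for s in seqs:
            if s in seen:
                raise ValueError(f"sequence id {s!r} appears more than once in OTU map")
            seen.add(s)


def read_otu_map(path) -> dict[str, list[str]]:
    """Read a pick_otus-style OTU map: OTU ID then member seq IDs, tab-split."""
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.rstrip("\n").split("\t")
        otu, seqs = tokens[0], [t for t in tokens[1:] if t]
        if otu in out:
            raise ValueError(f"duplicate OTU id {otu!r} at line {lineno} of {path}")
        if not seqs:
            raise ValueError(f"OTU {otu!r} at line {lineno} has no sequence ids")
        out[otu] = seqs
    validate_otu_map(out)
    return out


def write_otu_map(otu_map: Mapping[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for otu, seqs in otu_map.items():
            fh.write("\t".join([otu, *seqs]) + "\n")


# ---------------------------------------------------------------------------
# Greengenes taxonomy table
# ---------------------------------------------------------------------------

def read_taxonomy_table(path) -> dict[str, TaxonomyString]:
    """Read a two-column (reference ID, semicolon lineage) taxonomy table."""
    out: dict[str, TaxonomyString] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise ValueError(f"taxonomy table {path}: no tab separator at line {lineno}")
        ref_id, lineage = line.split("\t", 1)
        ref_id = ref_id.strip()
        if ref_id in out:
            log.warning("duplicate reference id %r at line %d: last entry wins", ref_id, lineno)
        tax = TaxonomyString.parse(lineage)
        if not tax.ranks:
            log.warning("empty lineage for reference id %r at line %d", ref_id, lineno)
        out[ref_id] = tax
    return out


def write_taxonomy_table(taxonomy: Mapping[str, TaxonomyString], path) -> None:
    with open(path, "w") as fh:
        for ref_id, tax in taxonomy.items():
            fh.write(f"{ref_id}\t{tax}\n")


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

#: Asymmetry beyond this is an error; below it, symmetrize by averaging.
ASYMMETRY_TOLERANCE = 1e-9


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a QIIME tab-delimited distance matrix.

    Tiny asymmetries (floating-point artifacts from upstream UniFrac runs)
    are averaged away; anything beyond ``ASYMMETRY_TOLERANCE`` is an error.
    The diagonal is forced to zero.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(
            f"distance matrix {path} is not square: {frame.shape[0]}x{frame.shape[1]}"
        )
    row_labels = [str(x) for x in frame.index]
    col_labels = [str(x) for x in frame.columns]
    if row_labels != col_labels:
        raise ValueError(f"distance matrix {path}: row and column labels differ")
    vals = frame.values.astype(float)
    asym = np.abs(vals - vals.T).max() if vals.size else 0.0
    if asym > ASYMMETRY_TOLERANCE:
        raise ValueError(
            f"distance matrix {path} asymmetric beyond tolerance: max |d_ij - d_ji| = {asym:g}"
        )
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(vals, ids=row_labels)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    frame = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick / FASTA
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,  # bare OTU-ID labels stay bare
        preserve_spaces=True,       # display names with spaces stay quoted
        suppress_rooting=True,
    )


def read_fasta(path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def make_seq_record(seq_id: str, sequence: str, description: str = "") -> SeqRecord:
    """Convenience constructor for a FASTA record."""
    return SeqRecord(Seq(sequence), id=seq_id, description=description)
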