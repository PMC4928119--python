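"""Post-OTU-picking pipeline operations.

The pipeline this module implements sits downstream of reference-based
(BLAST) OTU picking against a Greengenes-style database and upstream of
diversity analysis:

* ``split_sequences`` / ``merge_otu_results`` — bookkeeping that lets
  picking be distributed over chunks of the input and re-joined losslessly.
* ``primer_average`` — reconciles the two OTU maps produced when the same
  samples are sequenced with two different 16S hypervariable-region primer
  sets: an OTU captured by both primers is counted roughly twice, so its
  member list is scaled down to the average of the two observations.
* ``assign_taxonomy`` — because picking is reference-based, OTU IDs *are*
  database IDs and taxonomy assignment is a lookup.
* ``condense_otus`` — reference databases carry many entries per species;
  condensing bins OTUs sharing a full taxonomy string into one.
* ``filter_transient`` — removes genus-level aggregates that are too rare
  (prevalence) or too scarce (abundance) to be part of the core community.
* ``build_otu_table`` — tabulates member sequence IDs into an OTU x sample
  count table, decoding the originating sample from each sequence ID.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .io_formats import (
    OtuTable,
    RANK_DEPTH,
    SampleMetadata,
    TaxonomyString,
    validate_otu_map,
)

log = logging.getLogger("otukit")

#: Sentinel lineage for OTUs with no reference-database entry.
UNASSIGNED = TaxonomyString((("", "Unassigned"),))


@dataclass
class TaxonomyAssignment:
    """OTU ID -> (lineage, reference ID), plus the IDs that had no entry."""

    entries: dict[str, tuple[TaxonomyString, str]]
    missing: set[str] = field(default_factory=set)

    def lineage(self, otu_id: str) -> TaxonomyString:
        return self.entries[otu_id][0]

    def lineage_str(self, otu_id: str) -> str:
        return str(self.entries[otu_id][0])

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RemovalRecord:
    """One aggregate removed by ``filter_transient``."""

    aggregate_id: str        # truncated taxonomy string of the aggregate
    pass_label: str          # "prevalence" or "abundance"
    percent_abundance: float  # % of the original table's grand total
    otu_ids: list[str]
    seq_ids: list[str] = field(default_factory=list)


@dataclass
class RemovalReport:
    removed: list[RemovalRecord] = field(default_factory=list)

    @property
    def removed_otu_ids(self) -> set[str]:
        return {o for rec in self.removed for o in rec.otu_ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "aggregate_id": r.aggregate_id,
                    "pass": r.pass_label,
                    "percent_abundance": r.percent_abundance,
                    "otu_ids": ";".join(r.otu_ids),
                    "seq_ids": ";".join(r.seq_ids),
                }
                for r in self.removed
            ],
            columns=["aggregate_id", "pass", "percent_abundance", "otu_ids", "seq_ids"],
        )


@dataclass
class CondensedResult:
    """Output of ``condense_otus``: one OTU per distinct full lineage."""

    otu_map: dict[str, list[str]]
    representatives: dict[str, str]  # taxonomy string -> representative OTU ID
    assignments: TaxonomyAssignment


# ---------------------------------------------------------------------------
# chunk / merge bookkeeping
# ---------------------------------------------------------------------------

def split_sequences(records: Iterable, chunk_size: int = 20000) -> list[list]:
    """Split a record stream into consecutive chunks of ``chunk_size``.

    Records are never split or reordered; only the last chunk may be short.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    chunks: list[list] = []
    current: list = []
    for rec in records:
        current.append(rec)
        if len(current) == chunk_size:
            chunks.append(current)
            current = []
    if current:
        chunks.append(current)
    return chunks


def merge_otu_results(maps: Sequence[Mapping[str, list[str]]]) -> dict[str, list[str]]:
    """Concatenate per-chunk OTU maps into one, preserving input order.

    Sequence IDs must be globally unique across the inputs (each read was
    picked exactly once).
    """
    merged: dict[str, list[str]] = {}
    seen: set[str] = set()
    for m in maps:
        for otu, seqs in m.items():
            for s in seqs:
                if s in seen:
                    raise ValueError(
                        f"sequence id {s!r} appears in more than one input map"
                    )
                seen.add(s)
            merged.setdefault(otu, []).extend(seqs)
    return merged


# ---------------------------------------------------------------------------
# two-primer averaging
# ---------------------------------------------------------------------------

def primer_average(
    map_a: Mapping[str, list[str]], map_b: Mapping[str, list[str]]
) -> dict[str, list[str]]:
    """Average OTU abundances observed from two primer sets.

    An OTU found by only one primer passes through unchanged. An OTU found
    by both was effectively observed twice, so its output member list is cut
    to ``ceil((n_a + n_b) / 2)`` sequence IDs, drawn by alternating between
    the two input lists (map_a first) and truncating — deterministic, and
    the ceiling guarantees an OTU shared as a singleton by both primers
    survives.
    """
    validate_otu_map(map_a)
    validate_otu_map(map_b)
    out: dict[str, list[str]] = {}
    for otu, seqs_a in map_a.items():
        if otu not in map_b:
            out[otu] = list(seqs_a)
            continue
        seqs_b = map_b[otu]
        keep = math.ceil((len(seqs_a) + len(seqs_b)) / 2)
        interleaved: list[str] = []
        for i in range(max(len(seqs_a), len(seqs_b))):
            if i < len(seqs_a):
                interleaved.append(seqs_a[i])
            if i < len(seqs_b):
                interleaved.append(seqs_b[i])
        out[otu] = interleaved[:keep]
    for otu, seqs_b in map_b.items():
        if otu not in map_a:
            out[otu] = list(seqs_b)
    return out


# ---------------------------------------------------------------------------
# taxonomy lookup and condensing
# ---------------------------------------------------------------------------

def assign_taxonomy(
    otu_map: Mapping[str, list[str]],
    reference: Mapping[str, TaxonomyString],
) -> TaxonomyAssignment:
    """Look up each OTU's lineage in the reference taxonomy table.

    OTU IDs are reference-database IDs (the picker matched reads against the
    database), so assignment is a dictionary lookup. IDs without an entry
    get the ``Unassigned`` sentinel and are collected in ``missing``.
    """
    entries: dict[str, tuple[TaxonomyString, str]] = {}
    missing: set[str] = set()
    for otu in otu_map:
        if otu in reference:
            entries[otu] = (reference[otu], otu)
        else:
            entries[otu] = (UNASSIGNED, otu)
            missing.add(otu)
    if missing:
        log.warning("%d OTU id(s) absent from the reference taxonomy", len(missing))
    return TaxonomyAssignment(entries=entries, missing=missing)


def condense_otus(
    assignments: TaxonomyAssignment, otu_map: Mapping[str, list[str]]
) -> CondensedResult:
    """Bin OTUs sharing a full taxonomy string into a single OTU.

    Reference databases hold many 16S entries per species; without
    condensing each contributes its own OTU, cluttering every downstream
    view. Per distinct lineage the lexicographically smallest member OTU ID
    becomes the representative; member sequence lists are concatenated in
    ascending OTU-ID order (representative first), conserving the
    sequence-ID multiset.
    """
    missing = [otu for otu in otu_map if otu not in assignments]
    if missing:
        raise ValueError(f"OTU id(s) without taxonomy assignment: {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for otu in otu_map:
        groups.setdefault(assignments.lineage_str(otu), []).append(otu)
    condensed: dict[str, list[str]] = {}
    representatives: dict[str, str] = {}
    entries: dict[str, tuple[TaxonomyString, str]] = {}
    for tax_str, members in groups.items():
        members = sorted(members)
        rep = members[0]
        merged: list[str] = []
        for m in members:
            merged.extend(otu_map[m])
        condensed[rep] = merged
        representatives[tax_str] = rep
        entries[rep] = (assignments.lineage(rep), rep)
    return CondensedResult(
        otu_map=condensed,
        representatives=representatives,
        assignments=TaxonomyAssignment(entries=entries),
    )


def pick_representatives(
    otu_ids: Sequence[str], reference_sequences: Mapping[str, SeqRecord]
) -> list[SeqRecord]:
    """Fetch each OTU's full-length reference 16S sequence.

    Instead of electing a representative read, the (longer) database
    sequence stands in for the OTU — better input for alignment and tree
    building.
    """
    absent = [o for o in otu_ids if o not in reference_sequences]
    if absent:
        raise ValueError(f"OTU id(s) absent from reference sequences: {absent}")
    return [reference_sequences[o] for o in otu_ids]


# ---------------------------------------------------------------------------
# transient-OTU filtering
# ---------------------------------------------------------------------------

def filter_transient(
    table: OtuTable,
    assignments: TaxonomyAssignment,
    prevalence_frac: float = 0.05,
    abundance_frac: float = 0.0001,
    rank: str | int = "genus",
    otu_map: Mapping[str, list[str]] | None = None,
    abundance_denominator: str = "original",
) -> tuple[OtuTable, RemovalReport]:
    """Remove transient organisms from an OTU table, in two passes.

    OTUs are aggregated by taxonomy truncated at ``rank`` (genus by
    default). Pass 1 removes aggregates present (count > 0) in strictly
    fewer than ``prevalence_frac`` of samples. Pass 2 removes surviving
    aggregates whose total count is strictly below ``abundance_frac`` of the
    table's grand total (the original total by default;
    ``abundance_denominator="survivors"`` uses the post-pass-1 total).
    Removed aggregates are reported with their percent abundance and member
    IDs (sequence IDs when an ``otu_map`` is supplied).
    """
    if not 0 <= prevalence_frac <= 1 or not 0 <= abundance_frac <= 1:
        raise ValueError("prevalence_frac and abundance_frac must be in [0, 1]")
    depth = RANK_DEPTH[rank] if isinstance(rank, str) else int(rank)
    missing = [o for o in table.otu_ids if o not in assignments]
    if missing:
        raise ValueError(f"OTU id(s) without taxonomy assignment: {sorted(missing)}")

    agg_key = {
        otu: str(assignments.lineage(otu).truncate(depth)) for otu in table.otu_ids
    }
    members: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        members.setdefault(agg_key[otu], []).append(otu)

    n_samples = len(table.sample_ids)
    grand_total = table.grand_total()
    report = RemovalReport()

    def record(key: str, pass_label: str) -> None:
        otus = members[key]
        total = float(table.counts.loc[otus].values.sum())
        seqs: list[str] = []
        if otu_map is not None:
            for o in otus:
                seqs.extend(otu_map.get(o, []))
        report.removed.append(
            RemovalRecord(
                aggregate_id=key,
                pass_label=pass_label,
                percent_abundance=100.0 * total / grand_total if grand_total else 0.0,
                otu_ids=list(otus),
                seq_ids=seqs,
            )
        )

    # pass 1: prevalence ("occur in less than prevalence_frac of samples")
    survivors: list[str] = []
    for key, otus in members.items():
        agg_counts = table.counts.loc[otus].values.sum(axis=0)
        present_in = int((agg_counts > 0).sum())
        if present_in < prevalence_frac * n_samples:
            record(key, "prevalence")
        else:
            survivors.append(key)

    # pass 2: abundance on survivors
    if abundance_denominator == "original":
        denom = grand_total
    elif abundance_denominator == "survivors":
        denom = float(
            sum(table.counts.loc[members[k]].values.sum() for k in survivors)
        )
    else:
        raise ValueError("abundance_denominator must be 'original' or 'survivors'")
    retained_keys: list[str] = []
    for key in survivors:
        total = float(table.counts.loc[members[key]].values.sum())
        if total < abundance_frac * denom:
            record(key, "abundance")
        else:
            retained_keys.append(key)

    retained_otus = [o for o in table.otu_ids if agg_key[o] in set(retained_keys)]
    filtered = OtuTable(
        table.counts.loc[retained_otus].copy(),
        taxonomy={o: table.taxonomy[o] for o in retained_otus if o in table.taxonomy}
        if table.taxonomy
        else None,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# OTU table construction
# ---------------------------------------------------------------------------

def decode_sample(seq_id: str) -> str:
    """Sample ID encoded as the prefix before the final underscore."""
    if "_" not in seq_id:
        raise ValueError(f"sequence id {seq_id!r} does not encode a sample id")
    return seq_id.rsplit("_", 1)[0]


def build_otu_table(
    otu_map: Mapping[str, list[str]],
    assignments: TaxonomyAssignment,
    metadata: SampleMetadata,
) -> OtuTable:
    """Tabulate member sequence IDs into an OTU x sample count table.

    Each sequence ID encodes its originating sample as the prefix before the
    final underscore (``S1_000123`` -> ``S1``); every decoded sample must
    appear in the mapping file.
    """
    samples = metadata.sample_ids
    sample_pos = {s: j for j, s in enumerate(samples)}
    otus = list(otu_map)
    mat = np.zeros((len(otus), len(samples)))
    offenders: list[str] = []
    for i, otu in enumerate(otus):
        for seq_id in otu_map[otu]:
            try:
                sample = decode_sample(seq_id)
            except ValueError:
                offenders.append(seq_id)
                continue
            if sample not in sample_pos:
                offenders.append(seq_id)
                continue
            mat[i, sample_pos[sample]] += 1
    if offenders:
        raise ValueError(
            "sequence id(s) with undecodable or unknown sample: "
            f"{offenders[:10]}{'...' if len(offenders) > 10 else ''}"
        )
    taxonomy = {
        otu: assignments.lineage_str(otu) for otu in otus if otu in assignments
    }
    counts = pd.DataFrame(mat, index=otus, columns=samples)
    return OtuTable(counts, taxonomy=taxonomy or None)
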