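"""Quantitative tree annotation for the Interactive Tree of Life (iTol).

Relabels OTU-ID tree leaves with genus/species display names and computes
per-OTU abundance tracks — log10 raw abundance, mean relative abundance
(MRA), and group-normalized MRA (NMRA) — written in iTol's text dataset
format (simple-bar for single tracks, multi-value bar for NMRA).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .diversity import relative_abundance
from .io_formats import OtuTable, SampleMetadata, TaxonomyString
from .otu_workflow import TaxonomyAssignment

log = logging.getLogger("otukit")

_SANITIZE = re.compile(r"[^A-Za-z0-9_.-]")

MODES = ("log10_raw", "mra", "nmra")


@dataclass
class ItolDataset:
    """Numeric annotation tracks keyed by tree-leaf label."""

    mode: str
    columns: list[str]
    rows: dict[str, list[float]]
    stabilized: bool = False
    zero_total: set[str] = field(default_factory=set)
    label: str = "abundance"


def species_label(t: TaxonomyString) -> str:
    """Human-readable display name for a lineage.

    "Genus species" when both are named, else the deepest named rank kept
    with its rank prefix; characters iTol cannot digest become underscores.
    An all-empty lineage is "Unassigned".
    """
    genus = t.name_at("g__")
    species = t.name_at("s__")
    if genus and species:
        label = f"{genus} {species}"
    else:
        deepest = t.deepest_named()
        if deepest is None:
            return "Unassigned"
        prefix, name = deepest
        label = f"{prefix}{name}" if prefix else name
    return _SANITIZE.sub("_", label)


def unique_labels(labels: Sequence[str]) -> list[str]:
    """Disambiguate duplicates by appending _2, _3, ... in input order."""
    counts: dict[str, int] = {}
    out = []
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
        out.append(lab if counts[lab] == 1 else f"{lab}_{counts[lab]}")
    return out


def relabel_tree(
    tree: dendropy.Tree, assignments: TaxonomyAssignment
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Replace OTU-ID leaf labels with species display names.

    Topology and branch lengths are untouched. Returns the relabeled clone
    and the old -> new mapping so data tracks can follow the rename.
    """
    # round-trip through newick: a fully independent copy with fresh taxa
    out = dendropy.Tree.get(
        data=tree.as_string(
            schema="newick", unquoted_underscores=True, preserve_spaces=True,
            suppress_rooting=True,
        ),
        schema="newick",
        preserve_underscores=True,
    )
    leaves = [lf for lf in out.leaf_node_iter()]
    old = [lf.taxon.label if lf.taxon else str(lf.label) for lf in leaves]
    missing = [o for o in old if o not in assignments]
    if missing:
        raise ValueError(f"leaf label(s) without taxonomy assignment: {sorted(missing)}")
    new = unique_labels([species_label(assignments.lineage(o)) for o in old])
    mapping = dict(zip(old, new))
    for lf, name in zip(leaves, new):
        if lf.taxon is not None:
            lf.taxon.label = name
        else:
            lf.label = name
    return out, mapping


# ---------------------------------------------------------------------------
# abundance metrics
# ---------------------------------------------------------------------------

def arcsine_sqrt(p) -> np.ndarray:
    """Variance-stabilizing transform asin(sqrt(p)), [0,1] -> [0, pi/2]."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("arcsine-sqrt transform requires proportions in [0, 1]")
    return np.arcsin(np.sqrt(p))


def _mra(rel: OtuTable, samples: Sequence[str], stabilize: bool) -> np.ndarray:
    """Mean over ``samples`` of per-sample relative abundance, per OTU.

    The arcsine-sqrt transform, when requested, is applied to each
    per-sample proportion *before* averaging (the mean of transforms, not
    the transform of the mean).
    """
    r = rel.counts[list(samples)].values.astype(float)
    if stabilize:
        r = arcsine_sqrt(r)
    return r.mean(axis=1)


def itol_metrics(
    table: OtuTable,
    metadata: SampleMetadata | None = None,
    category: str | None = None,
    mode: str = "mra",
    stabilize: bool = False,
    label_map: Mapping[str, str] | None = None,
) -> ItolDataset:
    """Compute an abundance data track per OTU for tree annotation.

    * ``log10_raw`` — log10(1 + total count over all samples).
    * ``mra`` — mean over samples of the OTU's per-sample relative
      abundance; optional arcsine-sqrt stabilization of each proportion
      before averaging.
    * ``nmra`` — MRA computed per metadata group, then normalized across
      groups per OTU so each row sums to 1 (groups in mapping-file order);
      OTUs absent from every group get a zero row, flagged.

    ``label_map`` renames rows (e.g. with ``relabel_tree``'s mapping) so
    they match the annotated tree's leaves.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "log10_raw" and stabilize:
        raise ValueError("arcsine-sqrt stabilization applies to proportions, not log counts")
    otus = table.otu_ids
    if mode == "log10_raw":
        totals = table.counts.values.sum(axis=1)
        values = np.log10(1.0 + totals)[:, None]
        columns = ["log10_abundance"]
        zero_total: set[str] = set()
    elif mode == "mra":
        rel = relative_abundance(table)
        values = _mra(rel, table.sample_ids, stabilize)[:, None]
        columns = ["MRA_stabilized" if stabilize else "MRA"]
        zero_total = set()
    else:  # nmra
        if metadata is None or category is None:
            raise ValueError("nmra requires a mapping file and a category column")
        groups = metadata.groups(category)
        known = set(table.sample_ids)
        groups = {g: [s for s in sids if s in known] for g, sids in groups.items()}
        groups = {g: sids for g, sids in groups.items() if sids}
        if not groups:
            raise ValueError(f"category {category!r} matches no samples in the table")
        rel = relative_abundance(table)
        per_group = np.column_stack(
            [_mra(rel, sids, stabilize) for sids in groups.values()]
        )
        denom = per_group.sum(axis=1)
        zero_total = {o for o, d in zip(otus, denom) if d == 0}
        if zero_total:
            log.warning("%d OTU(s) with zero abundance in every group", len(zero_total))
        values = per_group / np.where(denom == 0, 1.0, denom)[:, None]
        columns = list(groups)
    rows = {}
    for otu, vals in zip(otus, values):
        key = label_map.get(otu, otu) if label_map else otu
        rows[key] = [float(v) for v in vals]
    return ItolDataset(
        mode=mode, columns=columns, rows=rows, stabilized=stabilize,
        zero_total=zero_total,
    )


# ---------------------------------------------------------------------------
# iTol dataset text format
# ---------------------------------------------------------------------------

_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def write_itol_dataset(ds: ItolDataset, path) -> None:
    """Serialize a dataset in iTol's template text format.

    Single-column tracks become a DATASET_SIMPLEBAR, multi-column (NMRA)
    tracks a DATASET_MULTIBAR.
    """
    multi = len(ds.columns) > 1
    lines = [
        "DATASET_MULTIBAR" if multi else "DATASET_SIMPLEBAR",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{ds.label}_{ds.mode}",
        f"COLOR,{_PALETTE[0]}",
        "FIELD_LABELS," + ",".join(ds.columns),
    ]
    if multi:
        colors = [_PALETTE[i % len(_PALETTE)] for i in range(len(ds.columns))]
        lines.append("FIELD_COLORS," + ",".join(colors))
    lines.append("DATA")
    for leaf, vals in ds.rows.items():
        lines.append(",".join([leaf, *(repr(v) for v in vals)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_itol_dataset(path) -> ItolDataset:
    """Parse a dataset written by :func:`write_itol_dataset` (round-trip)."""
    lines = Path(path).read_text().splitlines()
    columns: list[str] = []
    mode = ""
    rows: dict[str, list[float]] = {}
    in_data = False
    for line in lines:
        if not line.strip():
            continue
        if in_data:
            parts = line.split(",")
            rows[parts[0]] = [float(v) for v in parts[1:]]
        elif line == "DATA":
            in_data = True
        elif line.startswith("FIELD_LABELS,"):
            columns = line.split(",")[1:]
        elif line.startswith("DATASET_LABEL,"):
            label = line.split(",", 1)[1]
            by_len = sorted(MODES, key=len, reverse=True)
            mode = next((m for m in by_len if label.endswith(m)), label)
    if not in_data:
        raise ValueError(f"no DATA section in {path}")
    return ItolDataset(mode=mode, columns=columns, rows=rows)
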