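"""Deterministic synthetic 16S community generator.

Emits every artifact the pipeline consumes — OTU map with sample-encoded
sequence IDs, Greengenes-style reference taxonomy (with deliberate
redundancy: several reference IDs per species, to exercise condensing),
QIIME mapping file, placeholder reference FASTA, and a random coalescent
tree over the reference IDs — all reproducible from a single seed.

Counts follow the standard overdispersed model for amplicon data: each
sample's composition is Dirichlet-distributed around the community base
(scaled per group by multiplicative effects on selected species) and reads
are a multinomial draw at fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .io_formats import SampleMetadata, TaxonomyString, make_seq_record


@dataclass
class CommunitySpec:
    """Parameters of a synthetic two-group (or k-group) 16S study.

    Defaults sketch a modest oral-plaque-like survey: 50 species under a
    long-tailed (concentration 0.5) Dirichlet base, 20 samples per group at
    5000 reads each, and 3 redundant reference entries per species.
    ``effects`` maps a group label to {species index: fold-change} applied
    multiplicatively to the Dirichlet concentration.
    """

    n_species: int = 50
    n_samples: int = 20            # per group
    groups: tuple[str, ...] = ("Control", "Treatment")
    base_concentration: float | Sequence[float] = 0.5
    effects: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    depth: int = 5000
    redundancy: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_samples < 1 or self.depth < 1:
            raise ValueError("n_species, n_samples and depth must be positive")
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        for g, eff in self.effects.items():
            if any(f <= 0 for f in eff.values()):
                raise ValueError(f"fold-changes must be > 0 (group {g!r})")


@dataclass
class CommunityData:
    otu_map: dict[str, list[str]]
    taxonomy: dict[str, TaxonomyString]
    metadata: SampleMetadata
    reference_seqs: list[SeqRecord]
    tree: dendropy.Tree
    lineages: list[str]                 # distinct lineage per species
    species_refs: dict[int, list[str]]  # species index -> reference IDs


_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
          "Fusobacteria", "Spirochaetes")


def _lineage(i: int) -> TaxonomyString:
    phylum = _PHYLA[i % len(_PHYLA)]
    return TaxonomyString((
        ("k__", "Bacteria"),
        ("p__", phylum),
        ("c__", f"Class{i % 9}"),
        ("o__", f"Order{i % 17}"),
        ("f__", f"Family{i % 23}"),
        ("g__", f"Genus{i}"),
        ("s__", f"species{i}"),
    ))


def _random_sequence(rng: np.random.Generator, length: int = 250) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def coalescent_newick(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Random sequential coalescence with exponential waiting times.

    Only topology and leaf-label consistency matter downstream; branch
    lengths are exponential(1) increments of the coalescence clock.
    """
    if len(labels) == 1:
        return f"({labels[0]}:1.0);"
    nodes = list(labels)
    heights = [0.0] * len(nodes)
    t = 0.0
    while len(nodes) > 1:
        t += rng.exponential(1.0)
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        ha, hb = heights[i], heights[j]
        merged = f"({a}:{t - ha:.6f},{b}:{t - hb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        heights = [h for k, h in enumerate(heights) if k not in (i, j)] + [t]
    return nodes[0] + ";"


def _sample_ids(spec: CommunitySpec) -> list[tuple[str, str]]:
    """(sample_id, group) pairs; IDs avoid underscores so they decode cleanly."""
    out = []
    for g in spec.groups:
        prefix = "".join(ch for ch in g if ch.isalnum()) or "G"
        for i in range(1, spec.n_samples + 1):
            out.append((f"{prefix}{i:03d}", g))
    return out


def _concentration(spec: CommunitySpec, group: str) -> np.ndarray:
    base = np.asarray(spec.base_concentration, dtype=float)
    if base.ndim == 0:
        base = np.full(spec.n_species, float(base))
    if base.size != spec.n_species:
        raise ValueError("base_concentration length must equal n_species")
    alpha = base.copy()
    for idx, fold in spec.effects.get(group, {}).items():
        alpha[idx] *= fold
    return alpha


def make_community(spec: CommunitySpec) -> CommunityData:
    """Generate a complete, internally consistent synthetic dataset.

    Each species is emitted under ``spec.redundancy`` distinct reference IDs
    sharing one taxonomy string; a species' reads in a sample are spread
    uniformly over its reference IDs. Reference IDs that capture no read
    are absent from the OTU map (as with real picking) but present in the
    taxonomy, FASTA and tree.
    """
    rng = np.random.default_rng(spec.seed)
    lineages = [_lineage(i) for i in range(spec.n_species)]
    species_refs = {
        i: [str(1000 + i * spec.redundancy + r) for r in range(spec.redundancy)]
        for i in range(spec.n_species)
    }
    all_refs = [r for refs in species_refs.values() for r in refs]
    taxonomy = {
        ref: lineages[i] for i, refs in species_refs.items() for ref in refs
    }

    otu_map: dict[str, list[str]] = {ref: [] for ref in all_refs}
    samples = _sample_ids(spec)
    for sid, group in samples:
        alpha = _concentration(spec, group)
        comp = rng.dirichlet(alpha)
        counts = rng.multinomial(spec.depth, comp)
        read_no = 0
        for i, c in enumerate(counts):
            if c == 0:
                continue
            refs = species_refs[i]
            split = rng.multinomial(c, np.full(len(refs), 1.0 / len(refs)))
            for ref, k in zip(refs, split):
                for _ in range(k):
                    read_no += 1
                    otu_map[ref].append(f"{sid}_{read_no:06d}")
    otu_map = {ref: seqs for ref, seqs in otu_map.items() if seqs}

    rows = []
    for sid, group in samples:
        rows.append({
            "SampleID": sid,
            "BarcodeSequence": _random_sequence(rng, 8),
            "LinkerPrimerSequence": "CATGCTGCCTCCCGTAGGAGT",
            "Group": group,
            "Description": f"synthetic sample {sid}",
        })
    frame = pd.DataFrame(rows).set_index("SampleID")
    metadata = SampleMetadata(frame)

    reference_seqs = [
        make_seq_record(ref, _random_sequence(rng), description="synthetic 16S")
        for ref in all_refs
    ]
    tree = dendropy.Tree.get(
        data=coalescent_newick(all_refs, rng), schema="newick",
        preserve_underscores=True,
    )
    return CommunityData(
        otu_map=otu_map,
        taxonomy=taxonomy,
        metadata=metadata,
        reference_seqs=reference_seqs,
        tree=tree,
        lineages=[str(t) for t in lineages],
        species_refs=species_refs,
    )


def lda_benchmark_spec(seed: int = 0) -> CommunitySpec:
    """The two-group community used to benchmark LDA group recovery.

    Eight core species (fewer taxa than the 40 samples, as after transient
    filtering of a core community — a training-set separation statistic is
    only meaningful when the within-class scatter has full rank), 20 samples
    per group, Dirichlet concentration 3.0, 5000 reads per sample, and an
    8-fold enrichment of five species in the Treatment group.
    """
    return CommunitySpec(
        n_species=8,
        n_samples=20,
        base_concentration=3.0,
        depth=5000,
        redundancy=1,
        seed=seed,
        effects={"Treatment": {i: 8.0 for i in range(5)}},
    )


def make_two_primer_maps(
    spec: CommunitySpec, overlap_frac: float
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Two primer-specific OTU maps over one community.

    A fraction ``overlap_frac`` of species (the lowest indices) is captured
    by both primers — independent multinomial draws each — and the rest is
    split alternately between the two. Sequence IDs carry an ``a``/``b``
    read tag so the union of both maps is collision-free.
    """
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must be in [0, 1]")
    rng = np.random.default_rng(spec.seed + 1)
    n_shared = round(overlap_frac * spec.n_species)
    shared = set(range(n_shared))
    only_a = set(range(n_shared, spec.n_species, 2))
    only_b = set(range(spec.n_species)) - shared - only_a

    def draw(tag: str, keep: set[int]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, group in _sample_ids(spec):
            alpha = _concentration(spec, group)
            comp = rng.dirichlet(alpha)
            counts = rng.multinomial(spec.depth, comp)
            read_no = 0
            for i, c in enumerate(counts):
                if c == 0 or i not in keep:
                    continue
                ref = str(1000 + i * spec.redundancy)  # first reference per species
                for _ in range(c):
                    read_no += 1
                    out.setdefault(ref, []).append(f"{sid}_{tag}{read_no:06d}")
        return out

    return draw("a", shared | only_a), draw("b", shared | only_b)
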