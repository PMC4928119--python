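import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from otukit import otu_workflow as wf
from otukit.fixtures import CommunitySpec, make_community
from otukit.io_formats import OtuTable, SampleMetadata, TaxonomyString


@pytest.fixture(scope="session")
def small_community():
    """10 species x 3 redundant reference IDs, 5 samples/group, 1000 reads."""
    spec = CommunitySpec(
        n_species=10,
        n_samples=5,
        depth=1000,
        redundancy=3,
        seed=42,
        effects={"Treatment": {0: 8.0, 1: 8.0}},
    )
    return make_community(spec)


@pytest.fixture(scope="session")
def small_assignments(small_community):
    return wf.assign_taxonomy(small_community.otu_map, small_community.taxonomy)


@pytest.fixture(scope="session")
def small_table(small_community, small_assignments):
    return wf.build_otu_table(
        small_community.otu_map, small_assignments, small_community.metadata
    )


def metadata_for(sample_ids, group=None):
    """Minimal valid mapping-file metadata over the given sample IDs."""
    frame = pd.DataFrame(
        {
            "BarcodeSequence": ["ACGTACGT"] * len(sample_ids),
            "LinkerPrimerSequence": ["CATG"] * len(sample_ids),
            "Group": group if group is not None else ["G1"] * len(sample_ids),
            "Description": ["test"] * len(sample_ids),
        },
        index=pd.Index(sample_ids, name="SampleID"),
    )
    return SampleMetadata(frame)


def table_from_counts(counts: dict[str, list[float]], sample_ids):
    """OtuTable from {otu_id: per-sample counts}."""
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=sample_ids)
    return OtuTable(frame.astype(float))


def distinct_assignments(otu_ids):
    """One distinct genus-level lineage per OTU."""
    entries = {}
    for i, otu in enumerate(otu_ids):
        tax = TaxonomyString((
            ("k__", "Bacteria"), ("p__", "P"), ("c__", "C"), ("o__", "O"),
            ("f__", "F"), ("g__", f"Genus{i}"), ("s__", f"sp{i}"),
        ))
        entries[otu] = (tax, otu)
    return wf.TaxonomyAssignment(entries=entries)
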