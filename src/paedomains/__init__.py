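"""paedomains: domain architectures from AlphaFold2 confidence and PAE outputs.

The pipeline turns a predicted model (per-residue pLDDT) and its predicted
aligned error matrix into a machine-readable domain architecture:
structured/disordered segmentation, rigid-unit clustering, split-domain
detection, interdomain-contact calls, reference-based homology labelling
via core C-alpha superposition, and diagram rendering.  A synthetic-data
generator with planted ground truth makes every stage testable offline.
"""

from importlib import resources
import json

from .model_io import (
    PAEMatrix,
    ResidueRange,
    StructureModel,
    read_architecture,
    read_intensity_table,
    read_pae,
    read_structure_model,
    write_architecture,
    write_intensity_table,
    write_pae,
    write_structure_model,
)
from .segmentation import Segment, refine_segments_with_pae, segment_disorder, smooth_plddt
from .rigidity import (
    ContactCall,
    RigidUnit,
    cluster_segments,
    contact_matrix,
    rigid_assemblies,
    symmetrize_pae,
)
from .domains import (
    Architecture,
    DomainCall,
    call_domains,
    compare_architecture,
    detect_split_domains,
    label_by_reference,
)
from .superposition import (
    SuperpositionResult,
    core_superpose,
    kabsch,
    pair_by_sequence,
)
from .mobility import MobilityProfile, domain_mobility, mobility_report
from .report import AnnotateConfig, annotate, render_diagram, render_matrix
from .synthetic import (
    Element,
    GroundTruth,
    Noise,
    SyntheticSpec,
    default_spec,
    generate_intensity_profiles,
    generate_model,
    generate_pae,
    parp1_like_spec,
)

__version__ = "0.1.0"


def load_parp_reference() -> dict:
    """Published PARP-family domain annotations packaged with the library."""
    with resources.files("paedomains.data").joinpath("parp_reference.json").open() as fh:
        return json.load(fh)


__all__ = [
    "AnnotateConfig",
    "Architecture",
    "ContactCall",
    "DomainCall",
    "Element",
    "GroundTruth",
    "MobilityProfile",
    "Noise",
    "PAEMatrix",
    "ResidueRange",
    "RigidUnit",
    "Segment",
    "StructureModel",
    "SuperpositionResult",
    "SyntheticSpec",
    "annotate",
    "call_domains",
    "cluster_segments",
    "compare_architecture",
    "contact_matrix",
    "core_superpose",
    "default_spec",
    "detect_split_domains",
    "domain_mobility",
    "generate_intensity_profiles",
    "generate_model",
    "generate_pae",
    "kabsch",
    "label_by_reference",
    "load_parp_reference",
    "mobility_report",
    "pair_by_sequence",
    "parp1_like_spec",
    "read_architecture",
    "read_intensity_table",
    "read_pae",
    "read_structure_model",
    "refine_segments_with_pae",
    "render_diagram",
    "render_matrix",
    "rigid_assemblies",
    "segment_disorder",
    "smooth_plddt",
    "symmetrize_pae",
    "write_architecture",
    "write_intensity_table",
    "write_pae",
    "write_structure_model",
]
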