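"""Architecture diagrams, annotated PAE heat maps, and the end-to-end
``annotate`` pipeline that strings every stage together.

Diagrams follow the conventions of domain-architecture figures: a grey
baseline scaled to chain length, labelled boxes for domains (split parts
linked by a bracket), boundary residue numbers beneath.  PAE heat maps get
domain-boundary grid lines and dashed boxes over called contact blocks,
drawn below the diagonal only (the upper triangle carries the
quasi-symmetric equivalent and is left clean).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import segmentation as seg
from . import rigidity as rig
from .domains import (
    Architecture,
    DEFAULT_MIN_INSERTION,
    call_domains,
    detect_split_domains,
)
from .model_io import PAEMatrix, ResidueRange, StructureModel

logger = logging.getLogger(__name__)


@dataclass
class AnnotateConfig:
    """Every tunable of the annotation pipeline, in one place.

    All values are recorded into the output architecture JSON so a result
    can always be traced back to the parameters that produced it.
    """

    plddt_cutoff: float = seg.DEFAULT_PLDDT_CUTOFF
    window: int = seg.DEFAULT_WINDOW
    min_struct: int = seg.DEFAULT_MIN_STRUCT
    min_gap: int = seg.DEFAULT_MIN_GAP
    split_gain: float = seg.DEFAULT_SPLIT_GAIN
    min_subsegment: int = seg.DEFAULT_MIN_SUBSEGMENT
    tau_domain: float = rig.DEFAULT_TAU_DOMAIN
    tau_assembly: float = rig.DEFAULT_TAU_ASSEMBLY
    tau_contact: float = rig.DEFAULT_TAU_CONTACT
    symmetrize: str = rig.DEFAULT_SYMMETRIZE
    min_insertion: int = DEFAULT_MIN_INSERTION


def annotate(
    model: StructureModel, pae: PAEMatrix, config: AnnotateConfig | None = None
) -> Architecture:
    """Model + PAE -> Architecture: the full inference pipeline.

    Stages: confidence segmentation -> PAE change-point refinement ->
    average-linkage rigid-unit clustering -> domain calls -> split-domain
    detection -> contact scoring.  Reference labelling is a separate,
    optional step (`domains.label_by_reference`).
    """
    config = config or AnnotateConfig()
    if len(model) != pae.n:
        raise ValueError(
            f"model has {len(model)} residues but PAE is {pae.n} x {pae.n}"
        )
    segments = seg.segment_disorder(
        model,
        plddt_cutoff=config.plddt_cutoff,
        window=config.window,
        min_struct=config.min_struct,
        min_gap=config.min_gap,
    )
    segments = seg.refine_segments_with_pae(
        segments,
        pae,
        min_sub=config.min_subsegment,
        gain=config.split_gain,
        plddt=model.plddt,
    )
    structured = [s for s in segments if s.structured]
    disordered = [s.range for s in segments if not s.structured]
    if not structured:
        return Architecture(
            entry_id=model.entry_id,
            length=int(model.residue_numbers[-1]),
            domains=[],
            disordered=disordered,
            params=asdict(config),
        )
    domain_units, _assemblies = rig.rigid_assemblies(
        segments,
        pae,
        tau_domain=config.tau_domain,
        tau_assembly=config.tau_assembly,
        mode=config.symmetrize,
    )
    calls = call_domains(domain_units)
    calls = detect_split_domains(calls, min_insertion=config.min_insertion)
    # split detection may merge ranges across short gaps; any disordered
    # range swallowed by a merge must not be double-counted in the tiling
    claimed = set()
    for call in calls:
        for r in call.ranges:
            claimed.update(r.residues())
    disordered = _subtract(disordered, claimed)
    contacts = (
        rig.contact_matrix(
            domain_units,
            pae,
            tau_contact=config.tau_contact,
            mode=config.symmetrize,
            names=[c.domain_id for c in calls],
        )
        if len(domain_units) >= 2
        else []
    )
    return Architecture(
        entry_id=model.entry_id,
        length=int(model.residue_numbers[-1]),
        domains=calls,
        disordered=disordered,
        contacts=contacts,
        params=asdict(config),
    )


def _subtract(ranges: list[ResidueRange], claimed: set[int]) -> list[ResidueRange]:
    out = []
    for r in ranges:
        start = None
        for i in range(r.start, r.end + 2):
            if i <= r.end and i not in claimed:
                if start is None:
                    start = i
            elif start is not None:
                out.append(ResidueRange(start, i - 1))
                start = None
    return out


# ---------------------------------------------------------------------------
# rendering


_BOX_COLORS = [
    "#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
    "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd",
]


def render_diagram(arch: Architecture, path: str | Path, width: int = 900) -> None:
    """Write a deterministic SVG architecture diagram.

    Grey baseline scaled to chain length; coloured labelled boxes for
    domains, with the parts of a split domain linked by a bracket; domain
    boundary numbers beneath the baseline.
    """
    height = 150
    margin = 40
    scale = (width - 2 * margin) / max(arch.length, 1)
    y_mid = 70
    box_h = 34

    def x(residue: float) -> float:
        return margin + (residue - 0.5) * scale

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<text x="{margin}" y="20" font-family="sans-serif" font-size="14">'
        f"{_esc(arch.entry_id)} ({arch.length} aa)</text>",
        f'<line x1="{x(1):.1f}" y1="{y_mid}" x2="{x(arch.length):.1f}" y2="{y_mid}" '
        'stroke="#555555" stroke-width="4"/>',
    ]
    for k, call in enumerate(arch.domains):
        color = _BOX_COLORS[k % len(_BOX_COLORS)]
        labels = call.part_labels()
        for r, label in zip(call.ranges, labels):
            x0, x1 = x(r.start), x(r.end)
            parts.append(
                f'<rect x="{x0:.1f}" y="{y_mid - box_h / 2}" width="{x1 - x0:.1f}" '
                f'height="{box_h}" rx="4" fill="{color}" stroke="#222222"/>'
            )
            parts.append(
                f'<text x="{(x0 + x1) / 2:.1f}" y="{y_mid + 5}" text-anchor="middle" '
                f'font-family="sans-serif" font-size="12" fill="#ffffff">{_esc(label)}</text>'
            )
            for boundary in (r.start, r.end):
                parts.append(
                    f'<text x="{x(boundary):.1f}" y="{y_mid + box_h / 2 + 16}" '
                    'text-anchor="middle" font-family="sans-serif" font-size="9" '
                    f'fill="#333333">{boundary}</text>'
                )
        if call.split:
            # bracket linking the parts of a split domain
            xa = x((call.ranges[0].start + call.ranges[0].end) / 2)
            xb = x((call.ranges[-1].start + call.ranges[-1].end) / 2)
            y_top = y_mid - box_h / 2 - 8
            parts.append(
                f'<path d="M {xa:.1f} {y_mid - box_h / 2} L {xa:.1f} {y_top} '
                f'L {xb:.1f} {y_top} L {xb:.1f} {y_mid - box_h / 2}" '
                'fill="none" stroke="#222222" stroke-width="1.2"/>'
            )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def render_matrix(pae: PAEMatrix, arch: Architecture, path: str | Path) -> None:
    """Heat map of the PAE matrix annotated with the inferred architecture.

    Domain-boundary grid lines span the matrix; called contact blocks are
    outlined with dashed orange boxes below the diagonal only.
    """
    if arch.length != pae.n:
        raise ValueError(
            f"architecture length {arch.length} != PAE size {pae.n}"
        )
    fig, ax = plt.subplots(figsize=(6, 5.5))
    im = ax.imshow(
        pae.values,
        cmap="Greens_r",
        vmin=0.0,
        vmax=pae.max_value,
        origin="upper",
        extent=(0.5, pae.n + 0.5, pae.n + 0.5, 0.5),
    )
    fig.colorbar(im, ax=ax, label="expected position error (Å)")
    boundaries = sorted(
        {r.start - 0.5 for c in arch.domains for r in c.ranges}
        | {r.end + 0.5 for c in arch.domains for r in c.ranges}
    )
    for b in boundaries:
        ax.axhline(b, color="#00000055", lw=0.5)
        ax.axvline(b, color="#00000055", lw=0.5)
    spans = {c.domain_id: c.ranges for c in arch.domains}
    for contact in arch.contacts:
        if not contact.is_contact:
            continue
        for ra in spans.get(contact.domain_a, []):
            for rb in spans.get(contact.domain_b, []):
                # below the diagonal: rows = later segment, cols = earlier
                row, col = (ra, rb) if ra.start > rb.start else (rb, ra)
                ax.add_patch(
                    plt.Rectangle(
                        (col.start - 0.5, row.start - 0.5),
                        len(col),
                        len(row),
                        fill=False,
                        edgecolor="#ff7f0e",
                        linestyle="--",
                        linewidth=1.5,
                    )
                )
    ax.set_xlabel("scored residue")
    ax.set_ylabel("aligned residue")
    ax.set_title(arch.entry_id)
    fig.savefig(path, dpi=150)
    plt.close(fig)
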