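"""Mapping the recombinationally suppressed region per heterokaryon pair.

Under near-obligate selfing, recombination keeps the two mat-linked alleles
of a gene (nearly) identical; alleles diverge only where crossing over is
suppressed. Each (pair, gene) is therefore classified from its raw
difference count, and the suppressed region of a pair is the span between
the outermost diverged genes. Homoallelic genes strictly inside that span
stay inside the region — they are gene-conversion candidates, not gaps in
suppression.

Classification uses the raw difference count (coding + intron SNPs), not
dS, because the recombining flanks occasionally show a single outcrossing
SNP that should not be mistaken for suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .divergence import DivergenceRecord
from .errors import ValidationError
from .io import ChromosomeLayout, Manifest

CLASS_HOMOALLELIC = "homoallelic"
CLASS_FLAGGED = "homoallelic_flagged"
CLASS_DIVERGED = "diverged"
CLASS_MISSING = "missing"

CLASSES = (CLASS_HOMOALLELIC, CLASS_FLAGGED, CLASS_DIVERGED, CLASS_MISSING)


def classify_allele_pair(
    record: Optional[DivergenceRecord], min_diffs: int = 2
) -> str:
    """Classify one (pair, gene) from its raw difference count.

    ``diverged`` at >= ``min_diffs`` differences, ``homoallelic_flagged``
    at exactly one (the single-SNP outcrossing signature), ``homoallelic``
    at zero, ``missing`` when undefined.
    """
    if record is None or record.raw_diffs is None:
        return CLASS_MISSING
    if record.raw_diffs >= min_diffs:
        return CLASS_DIVERGED
    if record.raw_diffs == 1:
        return CLASS_FLAGGED
    return CLASS_HOMOALLELIC


@dataclass
class SuppressionMap:
    """Per-pair demarcation of the suppressed region along the layout."""

    pair_id: str
    classes: dict[str, str]
    region_start_gene: Optional[str]
    region_end_gene: Optional[str]
    internal_homoallelic_genes: list[str] = field(default_factory=list)

    @property
    def has_region(self) -> bool:
        return self.region_start_gene is not None

    def contains(self, layout: ChromosomeLayout, gene: str) -> bool:
        """Whether a gene falls inside the pair's suppressed span."""
        if not self.has_region:
            return False
        i = layout.index(gene)
        return (
            layout.index(self.region_start_gene)
            <= i
            <= layout.index(self.region_end_gene)
        )


def demarcate_region(
    classes: Sequence[str], layout: ChromosomeLayout, pair_id: str = ""
) -> SuppressionMap:
    """Span between the outermost diverged genes of one pair.

    Flagged (single-SNP) genes never set a boundary. Homoallelic or
    flagged genes strictly inside the span are listed as conversion
    candidates.
    """
    if len(classes) != len(layout.genes):
        raise ValidationError(
            f"got {len(classes)} classes for {len(layout.genes)} layout genes"
        )
    for c in classes:
        if c not in CLASSES:
            raise ValidationError(f"unknown class {c!r}")
    diverged_idx = [i for i, c in enumerate(classes) if c == CLASS_DIVERGED]
    class_map = dict(zip(layout.genes, classes))
    if not diverged_idx:
        return SuppressionMap(pair_id, class_map, None, None, [])
    start, end = diverged_idx[0], diverged_idx[-1]
    internal = [
        layout.genes[i]
        for i in range(start + 1, end)
        if classes[i] in (CLASS_HOMOALLELIC, CLASS_FLAGGED)
    ]
    return SuppressionMap(
        pair_id=pair_id,
        classes=class_map,
        region_start_gene=layout.genes[start],
        region_end_gene=layout.genes[end],
        internal_homoallelic_genes=internal,
    )


def build_suppression_maps(
    records: Sequence[DivergenceRecord],
    layout: ChromosomeLayout,
    manifest: Manifest,
    min_diffs: int = 2,
) -> dict[str, SuppressionMap]:
    by_key = {(r.pair_id, r.gene): r for r in records}
    maps = {}
    for pair_id in manifest.pair_ids:
        classes = [
            classify_allele_pair(by_key.get((pair_id, g)), min_diffs)
            for g in layout.genes
        ]
        maps[pair_id] = demarcate_region(classes, layout, pair_id)
    return maps


def compare_boundaries(
    maps: Mapping[str, SuppressionMap], layout: ChromosomeLayout
) -> pd.DataFrame:
    """Per-pair suppressed-region boundaries, flagged where they deviate.

    A pair is flagged on a side when its boundary gene differs from the
    majority boundary over all pairs (ties flag every non-modal pair) —
    the signature of lineage-specific expansion or contraction.
    """
    if len(maps) < 2:
        raise ValidationError("boundary comparison needs >= 2 suppression maps")

    def majority(values: list) -> object:
        counts: dict = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts.values())
        modal = [v for v, c in counts.items() if c == best]
        return modal[0] if len(modal) == 1 else None

    lefts = [m.region_start_gene for m in maps.values()]
    rights = [m.region_end_gene for m in maps.values()]
    modal_left, modal_right = majority(lefts), majority(rights)
    rows = []
    for pair_id, m in maps.items():
        rows.append(
            {
                "pair_id": pair_id,
                "left_boundary": m.region_start_gene,
                "right_boundary": m.region_end_gene,
                "left_differs": m.region_start_gene != modal_left,
                "right_differs": m.region_end_gene != modal_right,
            }
        )
    return pd.DataFrame(rows)


def write_suppression_tsv(
    maps: Mapping[str, SuppressionMap], layout: ChromosomeLayout, path
) -> None:
    lines = ["pair_id\t" + "\t".join(layout.genes)]
    for pair_id, m in maps.items():
        lines.append(
            pair_id + "\t" + "\t".join(m.classes[g] for g in layout.genes)
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
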