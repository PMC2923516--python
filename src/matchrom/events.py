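"""Gene conversion and crossover detection from ordered gene genealogies.

A gene conversion between the two mat chromosomes of one heterokaryon pair
homogenizes the alleles of the converted gene while leaving the neighbours
diverged. The detector slides a window of three genealogies along the
chromosome and emits an event when the focal gene shows the pair's alleles
*together* while both flanking genealogies show them *separated*, at least
one flanking separation carried by a significantly supported branch.

The template (donor) chromosome of a conversion is read off the focal
genealogy: if the converted allele pair nests inside the smallest supported
clade whose other members are mat a-linked alleles of other pairs, the mat
a chromosome served as template (and symmetrically for mat A).

Events at one gene whose converted alleles are (near-)identical across
several lineages are merged into a single ancestral event that predates the
split of those lineages.

Crossovers are reciprocal: both alleles of a pair swap their clade
affiliation (which mating-type clade of the other lineages each allele
nests within) at some point along the gene order, and the swap persists.

The per-site homogenization rate of a gene is r = K/(2T), where K is its
number of conversion events divided by the number of lineages and T the
time since the lineages diverged from their common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .divergence import raw_diff_count
from .errors import ValidationError
from .genealogy import (
    PHASE_SEPARATED,
    PHASE_TOGETHER,
    PHASE_UNRESOLVED,
    PairPhaseCall,
    PhaseMatrix,
    SupportThresholds,
    edge_is_supported,
)
from .io import ChromosomeLayout, GeneAlignmentSet, Manifest, SupportedTree
from .suppression import SuppressionMap

TEMPLATE_A = "mat_A"
TEMPLATE_a = "mat_a"
TEMPLATE_UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# event types
# ---------------------------------------------------------------------------


@dataclass
class WindowEvidence:
    """The three-genealogy window supporting one conversion call."""

    left_gene: str
    focal_gene: str
    right_gene: str
    left_call: PairPhaseCall
    focal_call: PairPhaseCall
    right_call: PairPhaseCall

    def to_dict(self) -> dict:
        def call_info(c: PairPhaseCall) -> dict:
            return {
                "phase": c.phase,
                "supported": c.separation_supported,
                "max_support": c.max_support_on_path,
            }

        return {
            "window": [self.left_gene, self.focal_gene, self.right_gene],
            "left": call_info(self.left_call),
            "focal": call_info(self.focal_call),
            "right": call_info(self.right_call),
        }


@dataclass
class ConversionEvent:
    gene: str
    affected_pairs: frozenset[str]
    template: str = TEMPLATE_UNKNOWN
    ancestral: bool = False
    lineages: frozenset[str] = frozenset()
    in_region: Optional[bool] = None
    evidence: dict[str, WindowEvidence] = field(default_factory=dict)

    def __post_init__(self):
        for ev in self.evidence.values():
            if ev.focal_call.phase != PHASE_TOGETHER:
                raise ValidationError("conversion evidence: focal phase not together")
            if (
                ev.left_call.phase != PHASE_SEPARATED
                or ev.right_call.phase != PHASE_SEPARATED
            ):
                raise ValidationError("conversion evidence: flank not separated")
            if not (
                ev.left_call.separation_supported
                or ev.right_call.separation_supported
            ):
                raise ValidationError("conversion evidence: no supported flank")

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "affected_pairs": sorted(self.affected_pairs),
            "template": self.template,
            "ancestral": self.ancestral,
            "lineages": sorted(self.lineages),
            "in_region": self.in_region,
            "evidence": {p: ev.to_dict() for p, ev in sorted(self.evidence.items())},
        }


@dataclass
class CrossoverEvent:
    pair_id: str
    interval: tuple[str, str]
    evidence: dict[str, str] = field(default_factory=dict)  # gene -> state

    def to_dict(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "interval": list(self.interval),
            "evidence": dict(self.evidence),
        }


@dataclass
class RateEstimate:
    """Per-site homogenization rate r = K/(2T), K = events/lineages."""

    gene: Optional[str]
    event_count: float
    n_lineages: int
    T: float

    def __post_init__(self):
        if self.n_lineages < 1:
            raise ValidationError("n_lineages must be >= 1")
        if self.T <= 0:
            raise ValidationError("divergence time T must be positive")
        if self.event_count < 0:
            raise ValidationError("event_count must be >= 0")

    @property
    def K(self) -> float:
        return self.event_count / self.n_lineages

    @property
    def r(self) -> float:
        return self.K / (2.0 * self.T)

    @property
    def r_rounded(self) -> float:
        return round(self.r, 3)


def homogenization_rate(
    event_count: float, n_lineages: int, T: float, gene: Optional[str] = None
) -> RateEstimate:
    """Rate of per-site homogenization by gene conversion, r = K/(2T)."""
    return RateEstimate(gene=gene, event_count=event_count, n_lineages=n_lineages, T=T)


# ---------------------------------------------------------------------------
# conversion detection
# ---------------------------------------------------------------------------


def detect_conversions(
    phases: PhaseMatrix,
    maps: Mapping[str, SuppressionMap],
    layout: ChromosomeLayout,
    strict_adjacency: bool = False,
) -> list[ConversionEvent]:
    """Three-genealogy window scan; one (unmerged) event per (gene, pair).

    By default an unresolved neighbour extends the window to the next
    informative gene; with ``strict_adjacency`` only the immediate layout
    neighbours are considered. Genes without two informative neighbours
    (in particular the layout ends) never produce an event. Each event is
    annotated with membership of the pair's suppressed span.
    """
    if list(phases.genes) != list(layout.genes):
        raise ValidationError("phase matrix genes do not match layout order")
    events: list[ConversionEvent] = []
    for pair_id in phases.pair_ids:
        calls = {g: phases.call(g, pair_id) for g in layout.genes}
        informative = [
            g for g in layout.genes if calls[g].phase != PHASE_UNRESOLVED
        ]
        for k in range(1, len(informative) - 1):
            left, focal, right = informative[k - 1], informative[k], informative[k + 1]
            if strict_adjacency:
                i = layout.index(focal)
                if layout.index(left) != i - 1 or layout.index(right) != i + 1:
                    continue
            lc, fc, rc = calls[left], calls[focal], calls[right]
            if fc.phase != PHASE_TOGETHER:
                continue
            if lc.phase != PHASE_SEPARATED or rc.phase != PHASE_SEPARATED:
                continue
            if not (lc.separation_supported or rc.separation_supported):
                continue
            pair_map = maps.get(pair_id)
            in_region = (
                pair_map.contains(layout, focal) if pair_map is not None else None
            )
            events.append(
                ConversionEvent(
                    gene=focal,
                    affected_pairs=frozenset([pair_id]),
                    lineages=frozenset(),
                    in_region=in_region,
                    evidence={
                        pair_id: WindowEvidence(left, focal, right, lc, fc, rc)
                    },
                )
            )
    return events


# ---------------------------------------------------------------------------
# template direction
# ---------------------------------------------------------------------------


def _supported_sides(
    tree: SupportedTree, thresholds: SupportThresholds
) -> list[frozenset[str]]:
    """Both sides of every significantly supported internal bipartition."""
    all_labels = tree.leaf_labels
    sides: list[frozenset[str]] = []
    for edge, below in tree.bipartition_sides().items():
        if not edge_is_supported(edge, thresholds):
            continue
        if 1 < len(below) < len(all_labels) - 1:
            sides.append(below)
            sides.append(all_labels - below)
    return sides


def _majority_type(types: Sequence[str], majority: float) -> Optional[str]:
    if not types:
        return None
    for mt in ("A", "a"):
        if sum(t == mt for t in types) / len(types) >= majority:
            return mt
    return None


def _clade_votes(
    side: frozenset[str],
    focal: set[str],
    manifest: Manifest,
) -> list[tuple[str, str]]:
    """(strain_id, mating_type) voters for the identity of a clade.

    Only pairs contributing exactly one of their two alleles to the clade
    vote (with that allele's mating type): a pair whose both alleles sit
    inside is itself homogenized by conversion and carries no information
    about the clade's chromosome of origin.
    """
    votes = []
    for pair_id, (strain_A, strain_a) in manifest.pairs.items():
        ids = {strain_A.strain_id, strain_a.strain_id}
        if ids & focal:
            continue
        inside = ids & side
        if len(inside) == 1:
            (sid,) = inside
            votes.append((sid, manifest.by_id[sid].mating_type))
    return votes


def _best_candidate(tree: SupportedTree, focal_leaves, candidates):
    """Pick the host clade whose voters are patristically nearest.

    ``candidates`` is a list of ``(side, votes)``. Two supported sides can
    tie on size (a genuine host clade versus the complement of some small
    clade elsewhere); the informative context is the one whose voting
    alleles sit closest to the focal alleles on the tree.
    """
    present = [f for f in focal_leaves if tree.find_leaf(f) is not None]

    def key(cand):
        side, votes = cand
        dmin = min(
            tree.patristic_distance(f, sid)
            for f in present
            for sid, _ in votes
        )
        return (round(dmin, 9), len(side), tuple(sorted(side)))

    return min(candidates, key=key)


def infer_template_direction(
    tree: SupportedTree,
    pair_ids: str | Sequence[str],
    manifest: Manifest,
    thresholds: SupportThresholds,
    direction_majority: float = 1.0,
) -> str:
    """Donor chromosome of a conversion, from the focal genealogy.

    Looks for the smallest supported clade containing both alleles of
    every affected pair together with at least one allele of an
    unaffected pair; if those other alleles are (at fraction >=
    ``direction_majority``) all mat a-linked, the template was the mat a
    chromosome, and symmetrically. For a merged ancestral event pass all
    affected pairs: their alleles are copies of the donor and must not
    take part in the vote.
    """
    if isinstance(pair_ids, str):
        pair_ids = [pair_ids]
    focal: set[str] = set()
    for pair_id in pair_ids:
        for strain in manifest.pairs[pair_id]:
            focal.add(strain.strain_id)
    n_leaves = len(tree.leaf_labels)
    # a host clade spanning most of the tree carries no nesting signal;
    # cap its size at half the leaves beyond the focal alleles themselves
    max_side = n_leaves / 2 + len(focal)
    candidates = []
    for side in _supported_sides(tree, thresholds):
        if not focal <= side or len(side) > max_side:
            continue
        votes = _clade_votes(side, focal, manifest)
        if not votes:
            continue
        candidates.append((side, votes))
    if not candidates:
        return TEMPLATE_UNKNOWN
    _, votes = _best_candidate(tree, focal, candidates)
    mt = _majority_type([v for _, v in votes], direction_majority)
    if mt == "A":
        return TEMPLATE_A
    if mt == "a":
        return TEMPLATE_a
    return TEMPLATE_UNKNOWN


# ---------------------------------------------------------------------------
# ancestral merging
# ---------------------------------------------------------------------------


def merge_ancestral_events(
    events: Sequence[ConversionEvent],
    alignments: Mapping[str, GeneAlignmentSet],
    manifest: Manifest,
    merge_max_diffs: int = 4,
) -> list[ConversionEvent]:
    """Merge same-gene events whose converted alleles match across pairs.

    Two events at one gene merge when every cross-pair allele comparison
    shows at most ``merge_max_diffs`` differences — the converted tract
    then predates the split of the lineages involved. The default
    tolerance of 4 allows for the one-or-two residual substitutions each
    allele of an incompletely homogenized conversion may carry (two
    alleles compared, hence up to four). A merged event
    spanning several lineages is marked ancestral with their union as its
    lineage set.
    """
    by_gene: dict[str, list[ConversionEvent]] = {}
    for ev in events:
        by_gene.setdefault(ev.gene, []).append(ev)

    def pair_seqs(gene: str, pair_id: str) -> list[str]:
        aln = alignments.get(gene)
        if aln is None:
            return []
        out = []
        for strain in manifest.pairs[pair_id]:
            if strain.strain_id in aln.sequences:
                out.append(aln.sequences[strain.strain_id])
        return out

    merged: list[ConversionEvent] = []
    for gene, group in by_gene.items():
        n = len(group)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: int, y: int) -> None:
            parent[find(x)] = find(y)

        seqs = [
            [s for p in ev.affected_pairs for s in pair_seqs(gene, p)]
            for ev in group
        ]
        for i in range(n):
            for j in range(i + 1, n):
                if not seqs[i] or not seqs[j]:
                    continue
                worst = max(
                    raw_diff_count(a, b) for a in seqs[i] for b in seqs[j]
                )
                if worst <= merge_max_diffs:
                    union(i, j)

        clusters: dict[int, list[ConversionEvent]] = {}
        for i, ev in enumerate(group):
            clusters.setdefault(find(i), []).append(ev)
        for members in clusters.values():
            pairs = frozenset().union(*(m.affected_pairs for m in members))
            lineages = frozenset(manifest.pair_lineage(p) for p in pairs)
            templates = {m.template for m in members} - {TEMPLATE_UNKNOWN}
            evidence: dict[str, WindowEvidence] = {}
            for m in members:
                evidence.update(m.evidence)
            in_region_vals = {m.in_region for m in members if m.in_region is not None}
            merged.append(
                ConversionEvent(
                    gene=gene,
                    affected_pairs=pairs,
                    template=templates.pop() if len(templates) == 1 else TEMPLATE_UNKNOWN,
                    ancestral=len(lineages) > 1,
                    lineages=lineages,
                    in_region=(
                        any(in_region_vals) if in_region_vals else None
                    ),
                    evidence=evidence,
                )
            )
    merged.sort(key=lambda e: (e.gene, tuple(sorted(e.affected_pairs))))
    return merged


# ---------------------------------------------------------------------------
# crossover detection
# ---------------------------------------------------------------------------


def allele_affiliation(
    tree: SupportedTree,
    leaf_label: str,
    focal_pair_strains: frozenset[str],
    manifest: Manifest,
    thresholds: SupportThresholds,
    direction_majority: float = 1.0,
) -> Optional[str]:
    """Mating type of the supported other-lineage clade an allele nests in."""
    if tree.find_leaf(leaf_label) is None:
        return None
    n_leaves = len(tree.leaf_labels)
    max_side = n_leaves / 2 + len(focal_pair_strains)
    candidates = []
    for side in _supported_sides(tree, thresholds):
        if leaf_label not in side or len(side) > max_side:
            continue
        votes = _clade_votes(side, set(focal_pair_strains), manifest)
        if not votes:
            continue
        candidates.append((side, votes))
    if not candidates:
        return None
    _, votes = _best_candidate(tree, [leaf_label], candidates)
    return _majority_type([v for _, v in votes], direction_majority)


def detect_crossovers(
    trees: Mapping[str, Optional[SupportedTree]],
    manifest: Manifest,
    layout: ChromosomeLayout,
    thresholds: SupportThresholds,
    persistence: int = 2,
    direction_majority: float = 1.0,
) -> list[CrossoverEvent]:
    """Persistent reciprocal swaps of clade affiliation along the layout.

    A gene is informative for a pair when its two alleles carry opposite
    affiliations; a crossover is placed between the last informative gene
    of the old state and the first of the new state, provided the new
    state holds for at least ``persistence`` consecutive informative genes
    or to the chromosome end.
    """
    if persistence < 1:
        raise ValidationError("persistence must be >= 1")
    events: list[CrossoverEvent] = []
    for pair_id, (strain_A, strain_a) in manifest.pairs.items():
        focal = frozenset([strain_A.strain_id, strain_a.strain_id])
        states: list[tuple[str, str]] = []  # (gene, 'normal'|'swapped')
        for gene in layout.genes:
            tree = trees.get(gene)
            if tree is None:
                continue
            aff_A = allele_affiliation(
                tree, strain_A.strain_id, focal, manifest, thresholds,
                direction_majority,
            )
            aff_a = allele_affiliation(
                tree, strain_a.strain_id, focal, manifest, thresholds,
                direction_majority,
            )
            if aff_A is None or aff_a is None or aff_A == aff_a:
                continue
            states.append((gene, "normal" if aff_A == "A" else "swapped"))
        if len(states) < 2:
            continue
        # compress into runs of equal state
        runs: list[tuple[str, list[str]]] = []
        for gene, state in states:
            if runs and runs[-1][0] == state:
                runs[-1][1].append(gene)
            else:
                runs.append((state, [gene]))
        accepted = runs[0][0]
        for i in range(1, len(runs)):
            state, genes = runs[i]
            if state == accepted:
                continue  # return from a non-persistent blip
            persists = len(genes) >= persistence or i == len(runs) - 1
            if not persists:
                continue
            prev_genes = runs[i - 1][1]
            events.append(
                CrossoverEvent(
                    pair_id=pair_id,
                    interval=(prev_genes[-1], genes[0]),
                    evidence=dict(states),
                )
            )
            accepted = state
    return events


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


def count_events_per_gene(
    events: Iterable[ConversionEvent],
    counting: str = "per_event",
    inside_region_only: bool = True,
) -> dict[str, int]:
    """Conversion-event counts per gene.

    ``per_event`` counts each (merged) event once; ``per_pair`` counts it
    once per affected chromosome pair.
    """
    if counting not in ("per_event", "per_pair"):
        raise ValidationError(f"unknown counting convention {counting!r}")
    counts: dict[str, int] = {}
    for ev in events:
        if inside_region_only and ev.in_region is False:
            continue
        inc = 1 if counting == "per_event" else len(ev.affected_pairs)
        counts[ev.gene] = counts.get(ev.gene, 0) + inc
    return counts


def rates_table(
    events: Iterable[ConversionEvent],
    n_lineages: int,
    T: float,
    counting: str = "per_event",
    inside_region_only: bool = True,
) -> pd.DataFrame:
    """Per-gene homogenization rates under both counting conventions.

    The ``r`` column follows the ``counting`` argument; both conventions
    are always reported alongside.
    """
    events = list(events)
    per_event = count_events_per_gene(events, "per_event", inside_region_only)
    per_pair = count_events_per_gene(events, "per_pair", inside_region_only)
    rows = []
    for gene in sorted(set(per_event) | set(per_pair)):
        r_event = homogenization_rate(per_event.get(gene, 0), n_lineages, T, gene)
        r_pair = homogenization_rate(per_pair.get(gene, 0), n_lineages, T, gene)
        chosen = r_event if counting == "per_event" else r_pair
        rows.append(
            {
                "gene": gene,
                "events": per_event.get(gene, 0),
                "events_per_pair": per_pair.get(gene, 0),
                "n_lineages": n_lineages,
                "T": T,
                "r_per_event": r_event.r,
                "r_per_pair": r_pair.r,
                "r": chosen.r,
                "r_rounded": chosen.r_rounded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "events", "events_per_pair", "n_lineages", "T",
            "r_per_event", "r_per_pair", "r", "r_rounded",
        ],
    )
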