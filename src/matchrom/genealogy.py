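"""Per-gene genealogies and allele phase calls.

Trees are built by neighbor joining on Jukes-Cantor distances, with branch
support from a nonparametric bootstrap over alignment columns. Externally
supplied trees (e.g. ML or Bayesian genealogies read with
:func:`matchrom.io.read_newick_supported`) can be used interchangeably
wherever a :class:`~matchrom.io.SupportedTree` is consumed.

The phase of a heterokaryon pair on a gene tree is:

* ``together`` — no supported branch lies on the path between the pair's
  two allele leaves and their patristic distance is at most
  ``together_max_dist`` (the tolerance absorbs one or two residual
  substitutions after an incomplete homogenization);
* ``separated`` — at least one branch on that path meets the bootstrap or
  posterior support threshold;
* ``unresolved`` — a leaf is missing, or the tree neither supports the
  separation nor shows near-identical alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import AlignmentError, CorrectionUndefinedError, ValidationError
from .io import ChromosomeLayout, GeneAlignmentSet, Manifest, SupportedTree

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SupportThresholds:
    """Branch-support significance thresholds and bootstrap settings."""

    bootstrap_min: float = 70.0
    posterior_min: float = 0.95
    bootstrap_reps: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.bootstrap_min <= 100.0:
            raise ValidationError("bootstrap_min must be in [0, 100]")
        if not 0.0 <= self.posterior_min <= 1.0:
            raise ValidationError("posterior_min must be in [0, 1]")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")


def edge_is_supported(edge, thresholds: SupportThresholds) -> bool:
    """A branch is significant if EITHER support criterion is met."""
    boot = getattr(edge, "bootstrap", None)
    post = getattr(edge, "posterior", None)
    if boot is not None and boot >= thresholds.bootstrap_min:
        return True
    if post is not None and post >= thresholds.posterior_min:
        return True
    return False


def _edge_support_percent(edge) -> Optional[float]:
    """Support on a common percent scale (posterior mapped to [0, 100])."""
    boot = getattr(edge, "bootstrap", None)
    post = getattr(edge, "posterior", None)
    vals = []
    if boot is not None:
        vals.append(float(boot))
    if post is not None:
        vals.append(100.0 * float(post))
    return max(vals) if vals else None


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def encode_sequences(
    sequences: Mapping[str, str], labels: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Encode sequences as a (n, L) uint8 matrix (A,C,G,T -> 0..3, other -> 4)."""
    if labels is None:
        labels = sorted(sequences)
    rows = [
        np.frombuffer(sequences[lab].upper().encode(), dtype=np.uint8)
        for lab in labels
    ]
    return list(labels), _CODE[np.vstack(rows)]


def jc_distance_matrix(
    alignment: GeneAlignmentSet | Mapping[str, str],
) -> tuple[list[str], np.ndarray]:
    """Symmetric JC-corrected distance matrix over all sequences.

    Columns with a gap or ambiguous base in either member of a pair are
    deleted pairwise. Requires >= 3 sequences (the input of neighbor
    joining).
    """
    sequences = (
        alignment.sequences
        if isinstance(alignment, GeneAlignmentSet)
        else alignment
    )
    if len(sequences) < 3:
        raise ValidationError(
            f"need >= 3 sequences for a distance matrix, got {len(sequences)}"
        )
    labels, X = encode_sequences(sequences)
    n = len(labels)
    valid = X < 4
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise AlignmentError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float(((X[i] != X[j]) & both).sum()) / sites
            if p >= 0.75:
                raise CorrectionUndefinedError(
                    p, context=f"pair {labels[i]!r}-{labels[j]!r}"
                )
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return labels, D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _validate_distances(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    return D


def _nj_joins(D: np.ndarray):
    """Run the NJ agglomeration.

    Returns ``(joins, star)``: ``joins`` is a list of
    ``(id_i, id_j, len_i, len_j, new_id)`` with leaf ids ``0..n-1``;
    ``star`` is ``(ids, lengths)`` for the final trifurcation. Ties in the
    Q matrix break to the lowest (row, col) index pair, making the result
    deterministic. Negative branch lengths are kept as computed so that
    additive matrices are reproduced exactly.
    """
    n0 = D.shape[0]
    D = D.copy()
    active = list(range(n0))
    next_id = n0
    joins = []
    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = map(int, np.argwhere(Q == Q.min())[0])
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        joins.append((active[i], active[j], li, lj, next_id))
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k != i and k != j]
        newD = np.empty((m - 1, m - 1))
        newD[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        newD[-1, : m - 2] = dnew[keep]
        newD[: m - 2, -1] = dnew[keep]
        newD[-1, -1] = 0.0
        D = newD
        active = [active[k] for k in keep] + [next_id]
        next_id += 1
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    return joins, (list(active), [la, lb, lc])


def nj_tree(
    D: np.ndarray, labels: Sequence[str], gene: str | None = None
) -> SupportedTree:
    """Neighbor-joining tree (unrooted, trifurcating root) from distances."""
    D = _validate_distances(D)
    if len(labels) != D.shape[0]:
        raise ValidationError("labels do not match distance matrix size")
    joins, (star_ids, star_lengths) = _nj_joins(D)

    # mat A / mat a strain ids differ only by case: the namespace must not
    # fold case, or the two alleles of a pair collapse into one taxon
    taxon_ns = dendropy.TaxonNamespace(is_case_sensitive=True)
    nodes: dict[int, dendropy.Node] = {}
    for idx, lab in enumerate(labels):
        taxon = dendropy.Taxon(label=str(lab))
        taxon_ns.add_taxon(taxon)
        node = dendropy.Node()
        node.taxon = taxon
        nodes[idx] = node
    for id_i, id_j, len_i, len_j, new_id in joins:
        parent = dendropy.Node()
        parent.add_child(nodes[id_i])
        nodes[id_i].edge.length = len_i
        parent.add_child(nodes[id_j])
        nodes[id_j].edge.length = len_j
        nodes[new_id] = parent
    root = dendropy.Node()
    for nid, length in zip(star_ids, star_lengths):
        root.add_child(nodes[nid])
        nodes[nid].edge.length = length
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return SupportedTree(tree=tree, gene=gene)


def canonical_bipartition(
    side: frozenset[str], all_labels: frozenset[str]
) -> frozenset[str]:
    """Rotation/rooting-independent key for an unrooted bipartition."""
    comp = all_labels - side
    if len(side) < len(comp):
        return side
    if len(comp) < len(side):
        return comp
    return side if tuple(sorted(side)) < tuple(sorted(comp)) else comp


def _nj_bipartitions(D: np.ndarray, labels: Sequence[str]) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the NJ tree, without building node objects."""
    joins, _ = _nj_joins(D)
    all_labels = frozenset(labels)
    leafsets: dict[int, frozenset[str]] = {
        i: frozenset([labels[i]]) for i in range(len(labels))
    }
    bips: set[frozenset[str]] = set()
    for id_i, id_j, _li, _lj, new_id in joins:
        s = leafsets[id_i] | leafsets[id_j]
        leafsets[new_id] = s
        if 1 < len(s) < len(all_labels) - 1:
            bips.add(canonical_bipartition(s, all_labels))
    return bips


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_supports(
    alignment: GeneAlignmentSet | Mapping[str, str],
    reps: int,
    seed: int,
    gene: str | None = None,
) -> SupportedTree:
    """NJ tree with bootstrap percentages on internal branches.

    Alignment columns are resampled with replacement; each internal branch
    of the full-data tree is annotated with the percentage of replicate
    trees containing the same (label-set) bipartition. Replicates on which
    the JC correction is undefined are dropped from the denominator.
    Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValidationError("bootstrap reps must be >= 1")
    sequences = (
        alignment.sequences
        if isinstance(alignment, GeneAlignmentSet)
        else alignment
    )
    if isinstance(alignment, GeneAlignmentSet) and gene is None:
        gene = alignment.gene
    labels, X = encode_sequences(sequences)
    n, L = X.shape
    valid = X < 4

    pair_index = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff_prof = np.empty((len(pair_index), L))
    valid_prof = np.empty((len(pair_index), L))
    for p, (i, j) in enumerate(pair_index):
        both = valid[i] & valid[j]
        valid_prof[p] = both
        diff_prof[p] = (X[i] != X[j]) & both

    def distances(weights: np.ndarray) -> Optional[np.ndarray]:
        diffs = diff_prof @ weights
        sites = valid_prof @ weights
        if (sites <= 0).any():
            return None
        p = diffs / sites
        if (p >= 0.75).any():
            return None
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        D = np.zeros((n, n))
        for idx, (i, j) in enumerate(pair_index):
            D[i, j] = D[j, i] = d[idx]
        return D

    D0 = distances(np.ones(L))
    if D0 is None:
        raise CorrectionUndefinedError(0.75, context="full alignment")
    tree = nj_tree(D0, labels, gene=gene)

    all_labels = frozenset(labels)
    edge_bips = {
        edge: canonical_bipartition(side, all_labels)
        for edge, side in tree.bipartition_sides().items()
        if 1 < len(side) < len(all_labels) - 1
    }
    counts = {bip: 0 for bip in edge_bips.values()}

    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(reps):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        D = distances(w)
        if D is None:
            continue
        successes += 1
        # permute taxon order per replicate: NJ breaks Q-matrix ties by
        # index, and identical sequences tie in every replicate — without
        # the permutation an arbitrary resolution of a clump of identical
        # leaves would collect 100% support
        perm = rng.permutation(n)
        Dp = D[np.ix_(perm, perm)]
        labels_p = [labels[k] for k in perm]
        for bip in _nj_bipartitions(Dp, labels_p):
            if bip in counts:
                counts[bip] += 1
    for edge, bip in edge_bips.items():
        edge.bootstrap = (
            100.0 * counts[bip] / successes if successes else 0.0
        )
    return tree


# ---------------------------------------------------------------------------
# phase calls
# ---------------------------------------------------------------------------

PHASE_TOGETHER = "together"
PHASE_SEPARATED = "separated"
PHASE_UNRESOLVED = "unresolved"


@dataclass
class PairPhaseCall:
    """Whether a pair's mat A and mat a alleles co-cluster on one gene tree."""

    pair_id: str
    gene: Optional[str]
    phase: str
    separation_supported: bool = False
    max_support_on_path: Optional[float] = None
    patristic: Optional[float] = None
    reason: Optional[str] = None


def pair_phase(
    tree: SupportedTree,
    pair_id: str,
    strain_a_id: str,
    strain_b_id: str,
    thresholds: SupportThresholds,
    together_max_dist: float = 0.005,
) -> PairPhaseCall:
    gene = tree.gene
    if tree.find_leaf(strain_a_id) is None or tree.find_leaf(strain_b_id) is None:
        return PairPhaseCall(
            pair_id, gene, PHASE_UNRESOLVED, reason="strain missing from tree"
        )
    edges = tree.path_edges(strain_a_id, strain_b_id)
    internal = [e for e in edges if not e.head_node.is_leaf()]
    patristic = sum((e.length or 0.0) for e in edges)
    supports = [
        s for s in (_edge_support_percent(e) for e in internal) if s is not None
    ]
    max_support = max(supports) if supports else None
    # near-identity takes precedence: a supported branch between alleles
    # that differ by a couple of substitutions is resampling noise
    if patristic <= together_max_dist:
        return PairPhaseCall(
            pair_id,
            gene,
            PHASE_TOGETHER,
            max_support_on_path=max_support,
            patristic=patristic,
        )
    if any(edge_is_supported(e, thresholds) for e in internal):
        return PairPhaseCall(
            pair_id,
            gene,
            PHASE_SEPARATED,
            separation_supported=True,
            max_support_on_path=max_support,
            patristic=patristic,
        )
    return PairPhaseCall(
        pair_id,
        gene,
        PHASE_UNRESOLVED,
        max_support_on_path=max_support,
        patristic=patristic,
        reason="alleles apart but separation not supported",
    )


@dataclass
class PhaseMatrix:
    """gene x pair matrix of phase calls, in layout order."""

    genes: list[str]
    pair_ids: list[str]
    calls: dict[tuple[str, str], PairPhaseCall] = field(default_factory=dict)

    def call(self, gene: str, pair_id: str) -> PairPhaseCall:
        return self.calls[(gene, pair_id)]

    def to_frame(self) -> pd.DataFrame:
        def render(call: PairPhaseCall) -> str:
            if call.phase == PHASE_SEPARATED and call.separation_supported:
                return "separated†"
            return call.phase

        data = {
            pair: [render(self.calls[(g, pair)]) for g in self.genes]
            for pair in self.pair_ids
        }
        return pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def phase_matrix(
    trees: Mapping[str, Optional[SupportedTree]],
    manifest: Manifest,
    layout: ChromosomeLayout,
    thresholds: SupportThresholds,
    together_max_dist: float = 0.005,
) -> PhaseMatrix:
    """Phase calls for every (gene, pair); missing trees yield unresolved."""
    matrix = PhaseMatrix(genes=list(layout.genes), pair_ids=manifest.pair_ids)
    for gene in layout.genes:
        tree = trees.get(gene)
        for pair_id, (strain_A, strain_a) in manifest.pairs.items():
            if tree is None:
                call = PairPhaseCall(
                    pair_id, gene, PHASE_UNRESOLVED, reason="no tree for gene"
                )
            else:
                call = pair_phase(
                    tree,
                    pair_id,
                    strain_A.strain_id,
                    strain_a.strain_id,
                    thresholds,
                    together_max_dist,
                )
                if call.gene is None:
                    call.gene = gene
            matrix.calls[(gene, pair_id)] = call
    return matrix
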