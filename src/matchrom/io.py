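"""Dataset model and readers/writers for all on-disk formats.

The dataset of a mating-type (mat) chromosome study consists of

* a strain manifest (TSV): one row per sequenced haploid component strain,
  carrying its mating type (``A`` or ``a``), phylogenetic lineage and the
  heterokaryon pair it was isolated from;
* a chromosome layout (TSV): the genes in chromosomal order, with the
  positions of the mat locus and the centromere marked;
* one pre-aligned FASTA file per gene, with a coding mask (BED-like TSV,
  half-open 0-based column intervals) describing which alignment columns
  are protein coding and in which codon phase the coding part starts;
* optionally, per-gene genealogies as Newick with branch supports.

All coordinates are 0-based with half-open intervals.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, NewickParseError, ValidationError

MATING_TYPES = ("A", "a")

UNAMBIGUOUS = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainInfo:
    """One haploid single-mating-type component strain."""

    strain_id: str
    mating_type: str
    lineage: str
    pair_id: str

    def __post_init__(self):
        if self.mating_type not in MATING_TYPES:
            raise ValidationError(
                f"strain {self.strain_id!r}: mating_type must be one of "
                f"{MATING_TYPES}, got {self.mating_type!r}"
            )


@dataclass
class Manifest:
    """Validated collection of strains forming complete A/a pairs."""

    strains: list[StrainInfo]

    def __post_init__(self):
        seen = set()
        for s in self.strains:
            if s.strain_id in seen:
                raise ValidationError(f"duplicate strain id {s.strain_id!r}")
            seen.add(s.strain_id)
        for pair_id, (a_type, b_type) in self._pair_types().items():
            if a_type is None or b_type is None:
                raise ValidationError(
                    f"pair {pair_id!r} must have exactly one mat A and one "
                    f"mat a strain"
                )

    def _pair_types(self) -> dict[str, list]:
        by_pair: dict[str, list] = {}
        for s in self.strains:
            slot = by_pair.setdefault(s.pair_id, [None, None])
            idx = 0 if s.mating_type == "A" else 1
            if slot[idx] is not None:
                raise ValidationError(
                    f"pair {s.pair_id!r} has more than one mat "
                    f"{s.mating_type} strain"
                )
            slot[idx] = s
        return by_pair

    @property
    def by_id(self) -> dict[str, StrainInfo]:
        return {s.strain_id: s for s in self.strains}

    @property
    def pairs(self) -> dict[str, tuple[StrainInfo, StrainInfo]]:
        """pair_id -> (mat A strain, mat a strain)."""
        return {p: (a, b) for p, (a, b) in self._pair_types().items()}

    @property
    def pair_ids(self) -> list[str]:
        out = []
        for s in self.strains:
            if s.pair_id not in out:
                out.append(s.pair_id)
        return out

    def pair_lineage(self, pair_id: str) -> str:
        return self.pairs[pair_id][0].lineage

    @property
    def lineages(self) -> list[str]:
        out = []
        for s in self.strains:
            if s.lineage not in out:
                out.append(s.lineage)
        return out


@dataclass
class ChromosomeLayout:
    """Ordered gene list with mat-locus and centromere landmarks.

    ``mat_locus_after`` / ``centromere_after`` name the gene immediately to
    the left of the respective landmark.
    """

    genes: list[str]
    mat_locus_after: str
    centromere_after: str
    region_hint: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("layout gene names must be unique")
        for landmark in (self.mat_locus_after, self.centromere_after):
            if landmark not in self.genes:
                raise ValidationError(
                    f"landmark anchor {landmark!r} is not a layout gene"
                )
        self._index = {g: i for i, g in enumerate(self.genes)}

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise ValidationError(f"gene {gene!r} not in layout") from None

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


@dataclass
class GeneAlignmentSet:
    """Pre-aligned alleles of one gene, keyed by strain id.

    ``coding_mask`` flags protein-coding alignment columns; ``frame_offset``
    is the codon phase of the first coding column (0 means it starts a
    codon).
    """

    gene: str
    sequences: dict[str, str]
    coding_mask: np.ndarray
    frame_offset: int = 0

    def __post_init__(self):
        if not self.sequences:
            raise ValidationError(f"gene {self.gene!r}: no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"gene {self.gene!r}: unequal sequence lengths {sorted(lengths)}"
            )
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        self.coding_mask = np.asarray(self.coding_mask, dtype=bool)
        (length,) = lengths
        if self.coding_mask.shape != (length,):
            raise ValidationError(
                f"gene {self.gene!r}: coding mask length "
                f"{self.coding_mask.shape} != alignment length {length}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError("frame_offset must be 0, 1 or 2")
        n_coding = int(self.coding_mask.sum())
        lead = (3 - self.frame_offset) % 3
        if n_coding and (n_coding - lead) % 3 != 0:
            raise ValidationError(
                f"gene {self.gene!r}: {n_coding} coding columns with frame "
                f"offset {self.frame_offset} is not a whole number of codons"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strain_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def coding_columns(self) -> np.ndarray:
        return np.flatnonzero(self.coding_mask)

    @property
    def noncoding_columns(self) -> np.ndarray:
        return np.flatnonzero(~self.coding_mask)

    @property
    def has_introns(self) -> bool:
        return bool((~self.coding_mask).any())

    def coding_sequence(self, strain_id: str) -> str:
        """In-frame coding sequence (partial leading codon trimmed)."""
        cols = self.coding_columns
        lead = (3 - self.frame_offset) % 3
        cols = cols[lead:]
        cols = cols[: len(cols) - len(cols) % 3]
        seq = self.sequences[strain_id]
        return "".join(seq[c] for c in cols)


@dataclass
class SupportedTree:
    """Unrooted gene genealogy with per-branch support values.

    Supports live on dendropy ``Edge`` objects as ``bootstrap`` (percent in
    [0, 100]) and ``posterior`` (probability in [0, 1]) attributes; either
    may be absent.
    """

    tree: dendropy.Tree
    gene: str | None = None

    # -- basic queries ----------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(
            lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon
        )

    def find_leaf(self, label: str):
        for lf in self.tree.leaf_node_iter():
            if lf.taxon is not None and lf.taxon.label == label:
                return lf
        return None

    def path_edges(self, label_a: str, label_b: str) -> list[dendropy.Edge]:
        """Edges on the unique path between two leaves."""
        na, nb = self.find_leaf(label_a), self.find_leaf(label_b)
        if na is None or nb is None:
            missing = label_a if na is None else label_b
            raise ValidationError(f"leaf {missing!r} not in tree")
        anc_a = []
        node = na
        while node is not None:
            anc_a.append(node)
            node = node.parent_node
        anc_set = {id(n): i for i, n in enumerate(anc_a)}
        path_b = []
        node = nb
        while id(node) not in anc_set:
            path_b.append(node.edge)
            node = node.parent_node
        mrca_idx = anc_set[id(node)]
        path_a = [n.edge for n in anc_a[:mrca_idx]]
        return path_a + list(reversed(path_b))

    def patristic_distance(self, label_a: str, label_b: str) -> float:
        return sum(
            (e.length or 0.0) for e in self.path_edges(label_a, label_b)
        )

    def internal_edges(self) -> list[dendropy.Edge]:
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if not node.is_leaf():
                out.append(node.edge)
        return out

    def bipartition_sides(self) -> dict:
        """Map internal edge -> frozenset of leaf labels below it."""
        sides = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._leafset = frozenset([node.taxon.label])
            else:
                node._leafset = frozenset().union(
                    *(c._leafset for c in node.child_nodes())
                )
                if node.parent_node is not None:
                    sides[node.edge] = node._leafset
        return sides

    # -- serialization ----------------------------------------------------

    def as_newick(self) -> str:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            node.label = format_support_label(
                getattr(node.edge, "bootstrap", None),
                getattr(node.edge, "posterior", None),
            )
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        )
        return s.strip() + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.as_newick())


def format_support_label(bootstrap, posterior) -> str | None:
    def fmt(x):
        return f"{x:g}"

    if bootstrap is not None and posterior is not None:
        return f"{fmt(bootstrap)}/{fmt(posterior)}"
    if bootstrap is not None:
        return fmt(bootstrap)
    if posterior is not None:
        return fmt(posterior)
    return None


def _parse_support_label(label: str) -> tuple[float | None, float | None]:
    """``"85"`` -> bootstrap 85; ``"0.99"`` -> posterior; ``"85/0.99"`` -> both.

    A lone numeric label <= 1 is read as a posterior probability, > 1 as a
    bootstrap percentage (the common Newick export dialects).
    """
    label = label.strip()
    if not label:
        return None, None
    parts = label.split("/")
    try:
        values = [float(p) for p in parts]
    except ValueError:
        return None, None
    if len(values) == 1:
        v = values[0]
        return (None, v) if v <= 1.0 else (v, None)
    if len(values) == 2:
        return values[0], values[1]
    return None, None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv_rows(path) -> tuple[list[str], list[dict[str, str]]]:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    rows = []
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        rows.append(dict(zip(header, fields)))
    return header, rows


def read_manifest(path) -> Manifest:
    """Read the strain manifest TSV (strain_id, mating_type, lineage, pair_id)."""
    header, rows = _read_tsv_rows(path)
    required = {"strain_id", "mating_type", "lineage", "pair_id"}
    missing = required - set(header)
    if missing:
        raise FormatError(f"{path}: missing manifest columns {sorted(missing)}")
    strains = [
        StrainInfo(
            strain_id=r["strain_id"],
            mating_type=r["mating_type"],
            lineage=r["lineage"],
            pair_id=r["pair_id"],
        )
        for r in rows
    ]
    if not strains:
        raise FormatError(f"{path}: manifest has no strain rows")
    return Manifest(strains)


def read_layout(path) -> ChromosomeLayout:
    """Read the chromosome layout TSV.

    Columns: ``gene`` (required, rows in chromosomal order), optional
    ``region_hint`` and ``landmark_after`` (``mat`` or ``centromere`` on the
    gene that immediately precedes the landmark).
    """
    header, rows = _read_tsv_rows(path)
    if "gene" not in header:
        raise FormatError(f"{path}: layout must have a 'gene' column")
    genes, hints = [], {}
    mat_after = cen_after = None
    for r in rows:
        g = r["gene"]
        genes.append(g)
        if r.get("region_hint"):
            hints[g] = r["region_hint"]
        lm = r.get("landmark_after", "")
        if lm == "mat":
            mat_after = g
        elif lm == "centromere":
            cen_after = g
    if mat_after is None or cen_after is None:
        raise FormatError(
            f"{path}: layout must mark 'mat' and 'centromere' in a "
            f"'landmark_after' column"
        )
    return ChromosomeLayout(genes, mat_after, cen_after, hints)


@dataclass
class MaskSpec:
    """Coding-column intervals (half-open, 0-based) and codon phase."""

    intervals: list[tuple[int, int]]
    frame_offset: int = 0

    def to_mask(self, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        for start, end in self.intervals:
            if not (0 <= start <= end <= length):
                raise ValidationError(
                    f"coding interval [{start}, {end}) outside alignment "
                    f"of length {length}"
                )
            mask[start:end] = True
        return mask


def read_coding_mask(path) -> dict[str, MaskSpec]:
    """Read the BED-like coding mask TSV (gene, start, end, label[, frame])."""
    header, rows = _read_tsv_rows(path)
    required = {"gene", "start", "end", "label"}
    missing = required - set(header)
    if missing:
        raise FormatError(f"{path}: missing mask columns {sorted(missing)}")
    specs: dict[str, MaskSpec] = {}
    for r in rows:
        if r["label"] != "coding":
            continue
        spec = specs.setdefault(r["gene"], MaskSpec(intervals=[]))
        spec.intervals.append((int(r["start"]), int(r["end"])))
        if r.get("frame"):
            spec.frame_offset = int(r["frame"])
    return specs


def read_gene_alignment(
    path,
    mask: MaskSpec | None = None,
    gene: str | None = None,
    manifest: Manifest | None = None,
) -> GeneAlignmentSet:
    """Read one per-gene FASTA alignment and apply its coding mask.

    With no mask every column is treated as coding (frame 0). Headers must
    resolve to manifest strain ids when a manifest is given.
    """
    path = Path(path)
    if gene is None:
        gene = path.stem
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    sequences: dict[str, str] = {}
    for rec in records:
        sid = rec.id
        if manifest is not None and sid not in manifest.by_id:
            raise ValidationError(f"{path}: unknown strain id {sid!r}")
        if sid in sequences:
            raise ValidationError(f"{path}: duplicate record for {sid!r}")
        sequences[sid] = str(rec.seq).upper()
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise AlignmentError(
            f"{path}: records are not aligned (lengths {sorted(lengths)})"
        )
    (length,) = lengths
    if mask is None:
        coding = np.ones(length, dtype=bool)
        frame = 0
    else:
        coding = mask.to_mask(length)
        frame = mask.frame_offset
    return GeneAlignmentSet(
        gene=gene, sequences=sequences, coding_mask=coding, frame_offset=frame
    )


def read_newick_supported(source, gene: str | None = None) -> SupportedTree:
    """Read a Newick tree whose internal node labels carry branch supports."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            # strain ids may differ only by mating-type case (L1A vs L1a)
            case_sensitive_taxon_labels=True,
            taxon_namespace=dendropy.TaxonNamespace(is_case_sensitive=True),
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label:
            boot, post = _parse_support_label(node.label)
            if boot is not None:
                node.edge.bootstrap = boot
            if post is not None:
                node.edge.posterior = post
    return SupportedTree(tree=tree, gene=gene)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_manifest(manifest: Manifest, path) -> None:
    buf = _io.StringIO()
    buf.write("strain_id\tmating_type\tlineage\tpair_id\n")
    for s in manifest.strains:
        buf.write(f"{s.strain_id}\t{s.mating_type}\t{s.lineage}\t{s.pair_id}\n")
    Path(path).write_text(buf.getvalue())


def write_layout(layout: ChromosomeLayout, path) -> None:
    buf = _io.StringIO()
    buf.write("gene\tregion_hint\tlandmark_after\n")
    for g in layout.genes:
        lm = ""
        if g == layout.mat_locus_after:
            lm = "mat"
        elif g == layout.centromere_after:
            lm = "centromere"
        buf.write(f"{g}\t{layout.region_hint.get(g, '')}\t{lm}\n")
    Path(path).write_text(buf.getvalue())


def write_gene_alignment(aln: GeneAlignmentSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in aln.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_coding_mask(specs: Mapping[str, MaskSpec], path) -> None:
    buf = _io.StringIO()
    buf.write("gene\tstart\tend\tlabel\tframe\n")
    for gene, spec in specs.items():
        for i, (start, end) in enumerate(spec.intervals):
            frame = str(spec.frame_offset) if i == 0 else ""
            buf.write(f"{gene}\t{start}\t{end}\tcoding\t{frame}\n")
    Path(path).write_text(buf.getvalue())


def mask_from_alignment(aln: GeneAlignmentSet) -> MaskSpec:
    """Recover the interval form of an alignment's coding mask."""
    mask = aln.coding_mask
    intervals = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(mask)))
    return MaskSpec(intervals=intervals, frame_offset=aln.frame_offset)
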