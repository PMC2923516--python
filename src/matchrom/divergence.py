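"""Pairwise allelic divergence: Nei-Gojobori (1986) dN/dS and intron counts.

For each heterokaryon pair and each gene, the two alleles (one from the mat
A component strain, one from the mat a component) are compared:

* coding columns are scored with the unweighted Nei-Gojobori method —
  synonymous/nonsynonymous site counts per codon, minimal mutational
  pathways averaged with equal weights for multi-hit codons, and a
  Jukes-Cantor correction applied separately to pN and pS;
* intron (noncoding) columns contribute a simple SNP count, excluding
  indel and ambiguous columns.

Conventions (they differ between published NG86 implementations):
codons containing a gap or ambiguous base in either allele are dropped
pairwise; single-base changes into a stop codon count as nonsynonymous in
the site counts; mutational pathways passing through a stop codon are
excluded unless every pathway does; codon pairs where either codon *is* a
stop are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import AlignmentError, CorrectionUndefinedError, ValidationError
from .io import ChromosomeLayout, GeneAlignmentSet, Manifest

log = logging.getLogger(__name__)

BASES = "ACGT"


def _standard_code() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


GENETIC_CODE = _standard_code()


# ---------------------------------------------------------------------------
# codon-level primitives
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes (#synonymous single-base neighbours)/3
    synonymous sites; the two counts always sum to 3. Changes to stop
    codons are nonsynonymous. Raises on stop codons or ambiguous bases.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValidationError(f"codon must be 3 unambiguous bases, got {codon!r}")
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValidationError(f"stop codon {codon!r} has no NG86 site counts")
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[neighbour] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all minimal mutational pathways (orderings of the
    differing positions) with equal weights; pathways whose intermediate
    codons are stops are excluded unless every pathway passes through a
    stop.
    """
    diff_positions = tuple(i for i in range(3) if codon_a[i] != codon_b[i])
    if not diff_positions:
        return 0.0, 0.0

    paths: list[tuple[float, float, bool]] = []  # (syn, nonsyn, via_stop)

    def explore(current: str, remaining: tuple[int, ...], syn: float,
                nonsyn: float, via_stop: bool) -> None:
        if not remaining:
            paths.append((syn, nonsyn, via_stop))
            return
        for k, pos in enumerate(remaining):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = GENETIC_CODE[current], GENETIC_CODE[nxt]
            step_syn = aa_from == aa_to and aa_from != "*"
            intermediate_stop = aa_to == "*" and len(remaining) > 1
            explore(
                nxt,
                remaining[:k] + remaining[k + 1 :],
                syn + (1.0 if step_syn else 0.0),
                nonsyn + (0.0 if step_syn else 1.0),
                via_stop or intermediate_stop,
            )

    explore(codon_a, diff_positions, 0.0, 0.0, False)
    usable = [p for p in paths if not p[2]] or paths
    syn = sum(p[0] for p in usable) / len(usable)
    nonsyn = sum(p[1] for p in usable) / len(usable)
    return syn, nonsyn


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if not 0.0 <= p < 0.75:
        raise CorrectionUndefinedError(p)
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------


@dataclass
class NG86Result:
    d_n: Optional[float]
    d_s: Optional[float]
    nonsyn_sites: float
    syn_sites: float
    nonsyn_diffs: float
    syn_diffs: float
    codons_used: int

    @property
    def sites(self) -> int:
        """Coding sites retained after pairwise codon deletion."""
        return 3 * self.codons_used


def _is_scoreable(codon: str) -> bool:
    return all(b in BASES for b in codon) and GENETIC_CODE[codon] != "*"


def ng86_pairwise(seq_a: str, seq_b: str) -> NG86Result:
    """NG86 dN and dS between two in-frame coding sequences."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"coding sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    if len(seq_a) % 3 != 0:
        raise AlignmentError("coding sequence length is not a multiple of 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    syn_sites = nonsyn_sites = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    codons_used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_is_scoreable(ca) and _is_scoreable(cb)):
            continue  # pairwise deletion at codon granularity
        sa = ng86_site_counts(ca)
        sb = ng86_site_counts(cb)
        syn_sites += (sa[0] + sb[0]) / 2.0
        nonsyn_sites += (sa[1] + sb[1]) / 2.0
        sd, nd = _pathway_diff_counts(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd
        codons_used += 1

    def corrected(diffs: float, sites: float, label: str) -> Optional[float]:
        if sites <= 0:
            return None
        p = diffs / sites
        if p >= 0.75:
            raise CorrectionUndefinedError(p, context=f"p{label}")
        return jc_correct(p)

    return NG86Result(
        d_n=corrected(nonsyn_diffs, nonsyn_sites, "N"),
        d_s=corrected(syn_diffs, syn_sites, "S"),
        nonsyn_sites=nonsyn_sites,
        syn_sites=syn_sites,
        nonsyn_diffs=nonsyn_diffs,
        syn_diffs=syn_diffs,
        codons_used=codons_used,
    )


def intron_diff_count(seq_a: str, seq_b: str, noncoding_columns: Iterable[int]) -> int:
    """SNP count over noncoding columns; indel/ambiguous columns excluded."""
    count = 0
    for c in noncoding_columns:
        a, b = seq_a[c].upper(), seq_b[c].upper()
        if a in BASES and b in BASES and a != b:
            count += 1
    return count


def raw_diff_count(seq_a: str, seq_b: str) -> int:
    """Total differing columns where both bases are unambiguous non-gap."""
    count = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in BASES and b in BASES and a != b:
            count += 1
    return count


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


@dataclass
class DivergenceRecord:
    """One (pair, gene) cell of the allelic divergence table."""

    pair_id: str
    gene: str
    d_n: Optional[float]
    d_s: Optional[float]
    intron_diffs: Optional[int]
    raw_diffs: Optional[int]
    sites_used: Optional[int]

    @property
    def defined(self) -> bool:
        return self.raw_diffs is not None


def divergence_table(
    alignments: Mapping[str, GeneAlignmentSet],
    layout: ChromosomeLayout,
    manifest: Manifest,
) -> list[DivergenceRecord]:
    """Compute one DivergenceRecord per (pair, gene) in layout order.

    Pairs missing a strain at a gene yield a record with undefined values
    and a logged warning.
    """
    records: list[DivergenceRecord] = []
    for gene in layout.genes:
        aln = alignments.get(gene)
        for pair_id, (strain_A, strain_a) in manifest.pairs.items():
            if (
                aln is None
                or strain_A.strain_id not in aln.sequences
                or strain_a.strain_id not in aln.sequences
            ):
                log.warning(
                    "pair %s has no complete allele pair at gene %s", pair_id, gene
                )
                records.append(
                    DivergenceRecord(pair_id, gene, None, None, None, None, None)
                )
                continue
            seq_A = aln.sequences[strain_A.strain_id]
            seq_a = aln.sequences[strain_a.strain_id]
            try:
                ng = ng86_pairwise(
                    aln.coding_sequence(strain_A.strain_id),
                    aln.coding_sequence(strain_a.strain_id),
                )
                d_n, d_s, sites = ng.d_n, ng.d_s, ng.sites
            except CorrectionUndefinedError as exc:
                log.warning(
                    "pair %s gene %s: %s; divergence left undefined",
                    pair_id, gene, exc,
                )
                d_n = d_s = sites = None
            intron = (
                intron_diff_count(seq_A, seq_a, aln.noncoding_columns)
                if aln.has_introns
                else None
            )
            records.append(
                DivergenceRecord(
                    pair_id=pair_id,
                    gene=gene,
                    d_n=d_n,
                    d_s=d_s,
                    intron_diffs=intron,
                    raw_diffs=raw_diff_count(seq_A, seq_a),
                    sites_used=sites,
                )
            )
    return records


def records_by_key(
    records: Iterable[DivergenceRecord],
) -> dict[tuple[str, str], DivergenceRecord]:
    return {(r.pair_id, r.gene): r for r in records}


def divergence_frame(records: Iterable[DivergenceRecord]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": r.pair_id,
            "gene": r.gene,
            "dN": r.d_n,
            "dS": r.d_s,
            "i": r.intron_diffs,
            "raw_diffs": r.raw_diffs,
            "sites": r.sites_used,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_divergence_tsv(records: Iterable[DivergenceRecord], path) -> None:
    """TSV mirror of the divergence table; 3 decimals, '-' for absent values."""

    def num(x, decimals=3):
        if x is None:
            return "-"
        return f"{x:.{decimals}f}"

    def integer(x):
        return "-" if x is None else str(x)

    lines = ["pair_id\tgene\tdN\tdS\ti\traw_diffs\tsites"]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.pair_id,
                    r.gene,
                    num(r.d_n),
                    num(r.d_s),
                    integer(r.intron_diffs),
                    integer(r.raw_diffs),
                    integer(r.sites_used),
                ]
            )
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
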