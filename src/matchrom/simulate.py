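"""Forward-time simulator for mating-type chromosome datasets.

The generator emulates the statistical structure the analysis assumes:

* ten heterokaryon pairs from nine lineages (one lineage sampled twice)
  radiating from a common ancestor 4.6 million years ago, optionally with
  shallow cherries so that ancestral (pre-split) conversions can be
  planted;
* per gene, a recombination-cessation time: zero on the recombining
  flanks (selfing keeps the pair's two alleles identical copies), positive
  inside the suppressed span, where the mat A- and mat a-linked alleles
  evolve independently since cessation. Cessation times older than the
  lineage radiation produce the trans-specific pattern in which alleles
  cluster by mating type rather than by lineage;
* planted gene conversions (whole-gene or partial tract, pair-level or
  ancestral) that copy the template chromosome's allele over the other at
  the event time, planted crossovers that swap the mating-type linkage of
  all genes distal to a breakpoint, and rare single-SNP flank
  polymorphisms mimicking occasional outcrossing.

Sequences evolve under Jukes-Cantor (per-site Poisson(mu*t) substitutions,
equal exchange) with purifying selection approximated by accepting
proposed nonsynonymous coding changes with probability ``omega`` and
rejecting changes that create stop codons.

Every run is a pure function of the configuration and its seed; the truth
tables (planted events, spans, realized substitution counts) are returned
alongside the dataset for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .divergence import GENETIC_CODE
from .errors import ConfigError
from .io import (
    ChromosomeLayout,
    GeneAlignmentSet,
    Manifest,
    MaskSpec,
    StrainInfo,
    write_coding_mask,
    write_gene_alignment,
    write_layout,
    write_manifest,
)

_BASES = "ACGT"
_AA_BY_INDEX = np.array(
    [GENETIC_CODE[a + b + c] for a in _BASES for b in _BASES for c in _BASES]
)
_NONSTOP_CODON_CODES = np.array(
    [i for i, aa in enumerate(_AA_BY_INDEX) if aa != "*"], dtype=np.int64
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    name: str
    coding_len: int
    intron_len: int = 0

    def __post_init__(self):
        if self.coding_len % 3 != 0 or self.coding_len <= 0:
            raise ConfigError(
                f"gene {self.name!r}: coding_len must be a positive multiple of 3"
            )
        if self.intron_len < 0:
            raise ConfigError(f"gene {self.name!r}: intron_len must be >= 0")

    @property
    def length(self) -> int:
        return self.coding_len + self.intron_len


@dataclass(frozen=True)
class ConversionPlan:
    """A planted gene conversion.

    Target either one pair (``pair_id``) or the ancestral line of one or
    two lineages (``lineages``; two lineages must form a configured
    cherry). ``template`` is the mating-type linkage of the donor allele
    at the event time. Partial tracts copy a contiguous prefix or suffix
    fraction of the gene.
    """

    gene: str
    time: float
    template: str  # 'A' or 'a'
    pair_id: Optional[str] = None
    lineages: Optional[tuple[str, ...]] = None
    tract_fraction: float = 1.0
    tract_anchor: str = "prefix"

    def __post_init__(self):
        if (self.pair_id is None) == (self.lineages is None):
            raise ConfigError(
                "conversion plan must target exactly one of pair_id / lineages"
            )
        if self.template not in ("A", "a"):
            raise ConfigError("conversion template must be 'A' or 'a'")
        if not 0.0 < self.tract_fraction <= 1.0:
            raise ConfigError("tract_fraction must be in (0, 1]")
        if self.tract_anchor not in ("prefix", "suffix"):
            raise ConfigError("tract_anchor must be 'prefix' or 'suffix'")
        if self.time < 0:
            raise ConfigError("event times must be non-negative")


@dataclass(frozen=True)
class CrossoverPlan:
    """A planted crossover for one pair between two adjacent genes."""

    pair_id: str
    interval: tuple[str, str]
    time: float

    def __post_init__(self):
        if self.time < 0:
            raise ConfigError("event times must be non-negative")


@dataclass
class SimConfig:
    gene_specs: list[GeneSpec]
    mat_locus_after: str
    centromere_after: str
    pairs: list[tuple[str, str]]  # (pair_id, lineage)
    split_time: float = 4.6
    cherries: dict[tuple[str, str], float] = field(default_factory=dict)
    pair_split_times: dict[str, float] = field(default_factory=dict)
    spans: dict[str, Optional[tuple[str, str]]] = field(default_factory=dict)
    cessation: dict[str, float] = field(default_factory=dict)
    mu: float = 0.0065  # substitutions / site / MY
    omega: float = 0.1  # nonsynonymous acceptance probability
    conversions: list[ConversionPlan] = field(default_factory=list)
    crossovers: list[CrossoverPlan] = field(default_factory=list)
    outcross_snp_rate: float = 0.03  # per (pair, recombining gene)
    rng_seed: int = 0

    # -- derived --------------------------------------------------------

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.gene_specs]

    @property
    def lineage_order(self) -> list[str]:
        out = []
        for _, lin in self.pairs:
            if lin not in out:
                out.append(lin)
        return out

    def layout(self) -> ChromosomeLayout:
        names = self.gene_names
        central = [g for g in names if self.cessation.get(g, 0.0) > 0]
        hints = {}
        if central:
            lo = names.index(central[0])
            hi = names.index(central[-1])
            for i, g in enumerate(names):
                hints[g] = (
                    "left_flank" if i < lo else "central" if i <= hi else "right_flank"
                )
        return ChromosomeLayout(
            genes=list(names),
            mat_locus_after=self.mat_locus_after,
            centromere_after=self.centromere_after,
            region_hint=hints,
        )

    def manifest(self) -> Manifest:
        strains = []
        for pair_id, lineage in self.pairs:
            for mt in ("A", "a"):
                strains.append(
                    StrainInfo(
                        strain_id=f"{pair_id}{mt}",
                        mating_type=mt,
                        lineage=lineage,
                        pair_id=pair_id,
                    )
                )
        return Manifest(strains)

    def cessation_of(self, gene: str, lineage: str) -> float:
        """Recombination-cessation time of a gene in one lineage (0 = recombining)."""
        span = self.spans.get(lineage)
        if span is None:
            return 0.0
        names = self.gene_names
        lo, hi = names.index(span[0]), names.index(span[1])
        i = names.index(gene)
        if lo <= i <= hi:
            return self.cessation.get(gene, 0.0)
        return 0.0

    def validate(self) -> None:
        names = self.gene_names
        if len(set(names)) != len(names):
            raise ConfigError("duplicate gene names")
        pair_ids = [p for p, _ in self.pairs]
        if len(set(pair_ids)) != len(pair_ids):
            raise ConfigError("duplicate pair ids")
        lineages = set(self.lineage_order)
        seen = set()
        for members, t in self.cherries.items():
            if len(members) != 2 or not set(members) <= lineages:
                raise ConfigError(f"cherry {members!r} must name two known lineages")
            if set(members) & seen:
                raise ConfigError("a lineage may belong to at most one cherry")
            seen |= set(members)
            if not 0 <= t <= self.split_time:
                raise ConfigError("cherry split time must be within [0, split_time]")
        for lineage, span in self.spans.items():
            if span is not None:
                for g in span:
                    if g not in names:
                        raise ConfigError(f"span gene {g!r} not in layout")
        for plan in self.conversions:
            if plan.gene not in names:
                raise ConfigError(f"conversion gene {plan.gene!r} not in layout")
            key, (t_bottom, t_top) = self._resolve_target(plan)
            if not t_bottom <= plan.time < t_top:
                raise ConfigError(
                    f"conversion at {plan.gene} (t={plan.time}) outside the "
                    f"lifetime [{t_bottom}, {t_top}) of its target line {key}"
                )
        for plan in self.crossovers:
            if plan.pair_id not in pair_ids:
                raise ConfigError(f"unknown crossover pair {plan.pair_id!r}")
            left, right = plan.interval
            if left not in names or right not in names:
                raise ConfigError("crossover interval genes must be in layout")
            if names.index(right) != names.index(left) + 1:
                raise ConfigError(
                    "crossover interval genes must be adjacent in layout order"
                )
            _, (t_bottom, t_top) = self._resolve_target_pair(plan.pair_id)
            if not t_bottom <= plan.time < t_top:
                raise ConfigError(
                    f"crossover for {plan.pair_id} (t={plan.time}) outside the "
                    f"pair line's lifetime"
                )

    # line keys: ('stem',), ('cherry', frozenset), ('lineage', lin), ('pair', pid)

    def _lineage_origin(self, lineage: str) -> float:
        for members, t in self.cherries.items():
            if lineage in members:
                return t
        return self.split_time

    def _pairs_of(self, lineage: str) -> list[str]:
        return [p for p, lin in self.pairs if lin == lineage]

    def _resolve_target_pair(self, pair_id: str):
        lineage = dict(self.pairs)[pair_id]
        pairs = self._pairs_of(lineage)
        if len(pairs) > 1:
            top = self.pair_split_times.get(lineage, 0.0)
        else:
            top = self._lineage_origin(lineage)
        return ("pair", pair_id), (0.0, top)

    def _resolve_target(self, plan: ConversionPlan):
        if plan.pair_id is not None:
            if plan.pair_id not in dict(self.pairs):
                raise ConfigError(f"unknown pair {plan.pair_id!r}")
            return self._resolve_target_pair(plan.pair_id)
        lins = tuple(plan.lineages)
        if len(lins) == 1:
            lineage = lins[0]
            pairs = self._pairs_of(lineage)
            if not pairs:
                raise ConfigError(f"unknown lineage {lineage!r}")
            if len(pairs) == 1:
                return self._resolve_target_pair(pairs[0])
            bottom = self.pair_split_times.get(lineage, 0.0)
            return ("lineage", lineage), (bottom, self._lineage_origin(lineage))
        if len(lins) == 2:
            key = frozenset(lins)
            for members, t in self.cherries.items():
                if frozenset(members) == key:
                    return ("cherry", key), (t, self.split_time)
            raise ConfigError(
                f"ancestral conversion lineages {lins} do not form a cherry"
            )
        raise ConfigError("conversion may target at most two lineages")


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------


@dataclass
class TrueConversion:
    gene: str
    pairs: tuple[str, ...]
    lineages: tuple[str, ...]
    time: float
    template_link: str  # mating-type linkage of the donor at event time
    template_clade: Optional[str]  # allele-line identity of the donor
    tract_fraction: float
    ancestral: bool


@dataclass
class TrueCrossover:
    pair_id: str
    interval: tuple[str, str]
    time: float


@dataclass
class SimTruth:
    conversions: list[TrueConversion] = field(default_factory=list)
    crossovers: list[TrueCrossover] = field(default_factory=list)
    spans: dict[str, Optional[tuple[str, str]]] = field(default_factory=dict)
    snp_injections: list[dict] = field(default_factory=list)
    realized_substitutions: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


class _GeneEvolver:
    """Mutation machinery for one gene's column layout (frame 0 coding)."""

    def __init__(self, coding_mask: np.ndarray):
        self.mask = np.asarray(coding_mask, dtype=bool)
        self.L = len(self.mask)
        coding_cols = np.flatnonzero(self.mask)
        if len(coding_cols) % 3 != 0:
            raise ConfigError("coding columns must form whole codons")
        self.codon_cols = coding_cols.reshape(-1, 3)
        self.codon_of = np.full(self.L, -1, dtype=np.int64)
        self.pos_in_codon = np.zeros(self.L, dtype=np.int64)
        for ci, cols in enumerate(self.codon_cols):
            for off, col in enumerate(cols):
                self.codon_of[col] = ci
                self.pos_in_codon[col] = off

    def random_root(self, rng: np.random.Generator) -> np.ndarray:
        seq = rng.integers(0, 4, size=self.L, dtype=np.int64)
        codons = rng.choice(_NONSTOP_CODON_CODES, size=len(self.codon_cols))
        for ci, cols in enumerate(self.codon_cols):
            code = int(codons[ci])
            seq[cols[0]] = code // 16
            seq[cols[1]] = (code // 4) % 4
            seq[cols[2]] = code % 4
        return seq

    def _codon_aa(self, seq: np.ndarray, ci: int) -> str:
        c0, c1, c2 = (int(seq[c]) for c in self.codon_cols[ci])
        return _AA_BY_INDEX[c0 * 16 + c1 * 4 + c2]

    def evolve(
        self,
        seq: np.ndarray,
        t: float,
        mu: float,
        omega: float,
        rng: np.random.Generator,
    ) -> int:
        """Mutate ``seq`` in place over time ``t``; returns accepted changes."""
        if t < 0:
            raise ConfigError("cannot evolve for negative time")
        n_events = rng.poisson(mu * t * self.L)
        accepted = 0
        for _ in range(n_events):
            pos = int(rng.integers(0, self.L))
            old = int(seq[pos])
            new = (old + 1 + int(rng.integers(0, 3))) % 4
            ci = self.codon_of[pos]
            if ci >= 0:
                aa_old = self._codon_aa(seq, ci)
                seq[pos] = new
                aa_new = self._codon_aa(seq, ci)
                if aa_new == "*":
                    seq[pos] = old  # lethal
                    continue
                if aa_new != aa_old and rng.random() >= omega:
                    seq[pos] = old  # purifying rejection
                    continue
                accepted += 1
            else:
                seq[pos] = new
                accepted += 1
        return accepted

    def inject_snp(self, seq: np.ndarray, rng: np.random.Generator) -> Optional[int]:
        """Force a single random (non-stop-creating) SNP; returns the column."""
        for _ in range(100):
            pos = int(rng.integers(0, self.L))
            old = int(seq[pos])
            new = (old + 1 + int(rng.integers(0, 3))) % 4
            ci = self.codon_of[pos]
            if ci >= 0:
                seq[pos] = new
                if self._codon_aa(seq, ci) == "*":
                    seq[pos] = old
                    continue
            else:
                seq[pos] = new
            return pos
        return None


def decode(seq: np.ndarray) -> str:
    return "".join(_BASES[int(b)] for b in seq)


def encode(seq: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate(_BASES)}
    return np.array([lut[c] for c in seq.upper()], dtype=np.int64)


def evolve_gene(
    ancestor: str,
    time: float,
    mu: float,
    omega: float,
    coding_mask: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Evolve one sequence forward in time under the simulator's model."""
    evolver = _GeneEvolver(coding_mask)
    seq = encode(ancestor)
    evolver.evolve(seq, time, mu, omega, rng)
    return decode(seq)


# ---------------------------------------------------------------------------
# per-gene genealogy execution
# ---------------------------------------------------------------------------


@dataclass
class _Allele:
    seq: np.ndarray
    clade: Optional[str]  # allele-line identity, set when divergence begins

    def copy(self) -> "_Allele":
        return _Allele(self.seq.copy(), self.clade)


class _LineState:
    def __init__(self, shared: _Allele):
        self.diverged = False
        self.onset: Optional[float] = None
        self.shared: Optional[_Allele] = shared
        self.alleles: dict[str, _Allele] = {}

    def copy(self) -> "_LineState":
        new = _LineState(self.shared.copy() if self.shared is not None else None)
        new.diverged = self.diverged
        new.onset = self.onset
        new.alleles = {k: v.copy() for k, v in self.alleles.items()}
        return new

    def diverge(self, time: float) -> None:
        self.diverged = True
        self.onset = time
        self.alleles = {
            "A": _Allele(self.shared.seq.copy(), "A"),
            "a": _Allele(self.shared.seq, "a"),
        }
        self.shared = None

    def homogenize(self) -> None:
        """Recombination resumed: the mat a-linked copy survives on both."""
        self.shared = _Allele(self.alleles["a"].seq, None)
        self.alleles = {}
        self.diverged = False
        self.onset = None


class _GeneSimulation:
    def __init__(self, config: SimConfig, gene: GeneSpec, layout_names: list[str],
                 truth: SimTruth, rng: np.random.Generator):
        self.config = config
        self.gene = gene
        self.names = layout_names
        self.truth = truth
        self.rng = rng
        k = (gene.coding_len // 2 // 3) * 3
        mask = np.ones(gene.length, dtype=bool)
        if gene.intron_len:
            mask[k : k + gene.intron_len] = False
        self.mask = mask
        self.evolver = _GeneEvolver(mask)
        self.substitutions = 0
        self.tips: dict[str, dict[str, np.ndarray]] = {}  # pair -> {mt: seq}

        gi = self.names.index(gene.name)
        self.conversion_actions: dict[tuple, list[ConversionPlan]] = {}
        for plan in config.conversions:
            if plan.gene != gene.name:
                continue
            key, _ = config._resolve_target(plan)
            self.conversion_actions.setdefault(key, []).append(plan)
        self.crossover_actions: dict[tuple, list[CrossoverPlan]] = {}
        for plan in config.crossovers:
            left, right = plan.interval
            if gi >= self.names.index(right):
                key = ("pair", plan.pair_id)
                self.crossover_actions.setdefault(key, []).append(plan)

    # -- helpers --------------------------------------------------------

    def _descendant_pairs(self, key: tuple) -> list[str]:
        kind = key[0]
        if kind == "pair":
            return [key[1]]
        if kind == "lineage":
            return self.config._pairs_of(key[1])
        if kind == "cherry":
            return [
                p
                for lin in sorted(key[1])
                for p in self.config._pairs_of(lin)
            ]
        return [p for p, _ in self.config.pairs]

    def _evolve_state(self, state: _LineState, dt: float) -> None:
        if dt <= 0:
            return
        mu, om = self.config.mu, self.config.omega
        if state.diverged:
            for mt in ("A", "a"):
                self.substitutions += self.evolver.evolve(
                    state.alleles[mt].seq, dt, mu, om, self.rng
                )
        else:
            self.substitutions += self.evolver.evolve(
                state.shared.seq, dt, mu, om, self.rng
            )

    def _apply_conversion(self, state: _LineState, plan: ConversionPlan,
                          key: tuple) -> None:
        lineages = tuple(
            sorted({dict(self.config.pairs)[p] for p in self._descendant_pairs(key)})
        )
        if not state.diverged:
            donor_clade = None
        else:
            donor = state.alleles[plan.template]
            recipient_key = "a" if plan.template == "A" else "A"
            recipient = state.alleles[recipient_key]
            if plan.tract_fraction >= 1.0:
                state.alleles[recipient_key] = _Allele(donor.seq.copy(), donor.clade)
            else:
                k = int(round(plan.tract_fraction * self.evolver.L))
                if plan.tract_anchor == "prefix":
                    recipient.seq[:k] = donor.seq[:k]
                else:
                    recipient.seq[self.evolver.L - k :] = donor.seq[self.evolver.L - k :]
                if plan.tract_fraction >= 0.5:
                    recipient.clade = donor.clade
            donor_clade = donor.clade
        self.truth.conversions.append(
            TrueConversion(
                gene=self.gene.name,
                pairs=tuple(self._descendant_pairs(key)),
                lineages=lineages,
                time=plan.time,
                template_link=plan.template,
                template_clade=donor_clade,
                tract_fraction=plan.tract_fraction,
                ancestral=len(lineages) > 1,
            )
        )

    def _apply_crossover(self, state: _LineState) -> None:
        if state.diverged:
            state.alleles["A"], state.alleles["a"] = (
                state.alleles["a"],
                state.alleles["A"],
            )

    def _run_line(self, state: _LineState, key: tuple, t_top: float,
                  t_bottom: float, onset_param: float) -> None:
        actions: list[tuple[float, int, object]] = []
        if not state.diverged and onset_param > 0:
            onset_time = min(onset_param, t_top)
            if onset_time >= t_bottom:
                # priority 0: divergence happens before same-time events
                actions.append((onset_time, 0, "diverge"))
        for plan in self.crossover_actions.get(key, []):
            actions.append((plan.time, 1, plan))
        for plan in self.conversion_actions.get(key, []):
            actions.append((plan.time, 2, plan))
        actions.sort(key=lambda a: (-a[0], a[1]))
        t = t_top
        for time, _prio, action in actions:
            self._evolve_state(state, t - time)
            if action == "diverge":
                state.diverge(time)
            elif isinstance(action, CrossoverPlan):
                self._apply_crossover(state)
            else:
                self._apply_conversion(state, action, key)
            t = time
        self._evolve_state(state, t - t_bottom)

    def _enter_child(self, state: _LineState, child_onset: float) -> _LineState:
        child = state.copy()
        if child.diverged and child.onset is not None and child.onset > child_onset + 1e-12:
            child.homogenize()
        return child

    # -- main -----------------------------------------------------------

    def run(self) -> None:
        cfg = self.config
        s_of = {lin: cfg.cessation_of(self.gene.name, lin) for lin in cfg.lineage_order}
        global_onset = max(s_of.values(), default=0.0)
        root_age = max(cfg.split_time, global_onset)

        root = _LineState(_Allele(self.evolver.random_root(self.rng), None))
        self._run_line(root, ("stem",), root_age, cfg.split_time, global_onset)

        handled: set[str] = set()
        for lineage in cfg.lineage_order:
            if lineage in handled:
                continue
            cherry = None
            for members, t_ch in cfg.cherries.items():
                if lineage in members:
                    cherry = (tuple(members), t_ch)
                    break
            if cherry is None:
                handled.add(lineage)
                onset = s_of[lineage]
                state = self._enter_child(root, onset)
                self._run_lineage(state, lineage, cfg.split_time, onset)
            else:
                members, t_ch = cherry
                handled |= set(members)
                node_onset = max(s_of[lin] for lin in members)
                key = ("cherry", frozenset(members))
                state = self._enter_child(root, node_onset)
                self._run_line(state, key, cfg.split_time, t_ch, node_onset)
                for lin in members:
                    child = self._enter_child(state, s_of[lin])
                    self._run_lineage(child, lin, t_ch, s_of[lin])

    def _run_lineage(self, state: _LineState, lineage: str, t_top: float,
                     onset: float) -> None:
        cfg = self.config
        pairs = cfg._pairs_of(lineage)
        if len(pairs) == 1:
            key = ("pair", pairs[0])
            self._run_line(state, key, t_top, 0.0, onset)
            self._finalize_pair(state, pairs[0], lineage)
            return
        t_split = cfg.pair_split_times.get(lineage, 0.0)
        self._run_line(state, ("lineage", lineage), t_top, t_split, onset)
        for pair_id in pairs:
            child = self._enter_child(state, onset)
            self._run_line(child, ("pair", pair_id), t_split, 0.0, onset)
            self._finalize_pair(child, pair_id, lineage)

    def _finalize_pair(self, state: _LineState, pair_id: str, lineage: str) -> None:
        cfg = self.config
        if state.diverged:
            seqs = {mt: state.alleles[mt].seq.copy() for mt in ("A", "a")}
        else:
            seqs = {"A": state.shared.seq.copy(), "a": state.shared.seq.copy()}
            if (
                cfg.cessation_of(self.gene.name, lineage) == 0.0
                and cfg.outcross_snp_rate > 0
                and self.rng.random() < cfg.outcross_snp_rate
            ):
                mt = ("A", "a")[int(self.rng.integers(0, 2))]
                col = self.evolver.inject_snp(seqs[mt], self.rng)
                if col is not None:
                    self.truth.snp_injections.append(
                        {"pair_id": pair_id, "gene": self.gene.name,
                         "mating_type": mt, "column": int(col)}
                    )
        self.tips[pair_id] = seqs


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SimDataset:
    alignments: dict[str, GeneAlignmentSet]
    manifest: Manifest
    layout: ChromosomeLayout
    masks: dict[str, MaskSpec]
    truth: SimTruth
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "genes").mkdir(parents=True, exist_ok=True)
        for gene, aln in self.alignments.items():
            write_gene_alignment(aln, outdir / "genes" / f"{gene}.fasta")
        write_manifest(self.manifest, outdir / "manifest.tsv")
        write_layout(self.layout, outdir / "layout.tsv")
        write_coding_mask(self.masks, outdir / "mask.tsv")
        self.truth.write(outdir / "truth.json")


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate a full dataset plus truth tables; deterministic per seed."""
    config.validate()
    truth = SimTruth(
        spans={lin: config.spans.get(lin) for lin in config.lineage_order}
    )
    names = config.gene_names
    alignments: dict[str, GeneAlignmentSet] = {}
    masks: dict[str, MaskSpec] = {}
    for gi, gene in enumerate(config.gene_specs):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.rng_seed) % (2**31), gi])
        )
        sim = _GeneSimulation(config, gene, names, truth, rng)
        sim.run()
        sequences = {}
        for pair_id, _lin in config.pairs:
            for mt in ("A", "a"):
                sequences[f"{pair_id}{mt}"] = decode(sim.tips[pair_id][mt])
        aln = GeneAlignmentSet(
            gene=gene.name,
            sequences=sequences,
            coding_mask=sim.mask,
            frame_offset=0,
        )
        alignments[gene.name] = aln
        k = (gene.coding_len // 2 // 3) * 3
        intervals = (
            [(0, k), (k + gene.intron_len, gene.length)]
            if gene.intron_len
            else [(0, gene.length)]
        )
        masks[gene.name] = MaskSpec(intervals=intervals, frame_offset=0)
        truth.realized_substitutions[gene.name] = sim.substitutions
    for plan in config.crossovers:
        truth.crossovers.append(
            TrueCrossover(pair_id=plan.pair_id, interval=plan.interval,
                          time=plan.time)
        )
    truth.conversions.sort(key=lambda c: (c.gene, c.pairs, c.time))
    return SimDataset(
        alignments=alignments,
        manifest=config.manifest(),
        layout=config.layout(),
        masks=masks,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# the default (study-like) configuration
# ---------------------------------------------------------------------------

# 24 genes of the mat chromosome in N. crassa order. Coding lengths follow
# the sequenced exon lengths of the study system, rounded down to whole
# codons; genes sequenced with introns get a 300 bp intron block.
_GENE_TABLE: list[tuple[str, int, int]] = [
    ("ro-10", 588, 300),
    ("nit-2", 3291, 300),
    ("krev-1", 519, 300),
    ("sod-1", 465, 300),
    ("mus-42", 1680, 0),
    ("rid", 2559, 0),
    ("leu-4", 1863, 300),
    ("cys-5", 882, 0),
    ("ser-3", 921, 0),
    ("tef-1", 474, 300),
    ("un-3", 1923, 0),
    ("upr-1", 2886, 0),
    ("erg-8", 1428, 300),
    ("arg-1", 1119, 300),
    ("eth-1", 864, 300),
    ("lys-4", 1053, 300),
    ("cys-9", 906, 300),
    ("ad-9", 609, 300),
    ("al-1", 1635, 300),
    ("lys-3", 3324, 300),
    ("os-1", 1749, 300),
    ("prd-4", 1473, 300),
    ("arg-13", 999, 300),
    ("phr", 1767, 300),
]

# Recombination-cessation strata (MY ago). The oldest stratum predates the
# 4.6 MY radiation, giving the trans-specific mat A / mat a clustering of
# the chromosome centre; the younger edge stratum diverged within lineages.
_OLD_STRATUM = 5.5
_EDGE_STRATUM = 2.5
_CESSATION: dict[str, float] = {
    "mus-42": _EDGE_STRATUM,
    "rid": _EDGE_STRATUM,
    "leu-4": _OLD_STRATUM,
    "cys-5": _OLD_STRATUM,
    "ser-3": _OLD_STRATUM,
    "tef-1": _OLD_STRATUM,
    "un-3": _OLD_STRATUM,
    "upr-1": _OLD_STRATUM,
    "erg-8": _OLD_STRATUM,
    "arg-1": _OLD_STRATUM,
    "eth-1": _OLD_STRATUM,
    "lys-4": _OLD_STRATUM,
    "cys-9": _OLD_STRATUM,
    "ad-9": _OLD_STRATUM,
    "al-1": _OLD_STRATUM,
    "lys-3": _EDGE_STRATUM,
}

_SPANS: dict[str, tuple[str, str]] = {
    "1": ("leu-4", "al-1"),
    "2": ("mus-42", "lys-3"),
    "3": ("leu-4", "al-1"),
    "4": ("rid", "al-1"),
    "5": ("mus-42", "lys-3"),
    "6": ("mus-42", "lys-3"),
    "7": ("leu-4", "al-1"),
    "8": ("leu-4", "al-1"),
    "9": ("mus-42", "lys-3"),
}


def study_like_config(seed: int = 0) -> SimConfig:
    """Default study-like configuration.

    24 genes, ten pairs from nine lineages (lineage 8 twice), a suppressed
    central span with lineage-specific borders, eight planted conversions
    (two ancestral, one affecting both pairs of a lineage) and one planted
    crossover between upr-1 and erg-8 in lineage 4.
    """
    pairs = [(f"L{i}", str(i)) for i in range(1, 8)]
    pairs += [("L8(1)", "8"), ("L8(2)", "8"), ("L9", "9")]
    conversions = [
        ConversionPlan("lys-4", 0.04, "A", pair_id="L4"),
        ConversionPlan("cys-5", 0.12, "a", lineages=("5", "6")),
        ConversionPlan("ad-9", 0.035, "a", lineages=("8",)),
        ConversionPlan("arg-1", 0.04, "A", pair_id="L3"),
        ConversionPlan("ser-3", 0.04, "A", pair_id="L2"),
        ConversionPlan("ser-3", 0.04, "a", pair_id="L4"),
        ConversionPlan("ser-3", 0.04, "a", pair_id="L7"),
        ConversionPlan("ser-3", 0.12, "a", lineages=("3", "8")),
    ]
    return SimConfig(
        gene_specs=[GeneSpec(n, c, i) for n, c, i in _GENE_TABLE],
        mat_locus_after="un-3",
        centromere_after="eth-1",
        pairs=pairs,
        split_time=4.6,
        cherries={("3", "8"): 0.05, ("5", "6"): 0.05},
        pair_split_times={"8": 0.02},
        spans=dict(_SPANS),
        cessation=dict(_CESSATION),
        mu=0.0065,
        omega=0.1,
        conversions=conversions,
        crossovers=[CrossoverPlan("L4", ("upr-1", "erg-8"), 0.4)],
        outcross_snp_rate=0.03,
        rng_seed=seed,
    )
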