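"""Forward simulator for intron gain/loss histories and the data they leave behind.

The generator evolves intron presence/absence along a rooted tree under a
two-state regime: on a branch of length *t* a present intron is lost with
probability ``1 - exp(-loss_rate * t)`` and an unoccupied site slot acquires
an intron with probability ``1 - exp(-gain_rate * t)``.  Losses are
irreversible and a slot is gained at most once, so every simulated history is
Dollo-compatible and can serve as ground truth for parsimony and for the
posterior event filters.

From a history the emitters materialize everything the downstream analyses
read: per-species gene structures, genome FASTA + GFF3, the true (gap
consistent) codon alignments, and an FPKM table with an optional planted
expression shift in intron-lost genes.  Losses may be precise (the exon
junction is restored exactly) or imprecise (a small insertion or deletion is
left at the junction); introns may carry a planted boundary repeat
(microhomology) of a configurable size.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .phylo import TreeIndex
from .structures import GeneStructure, IntronRecord, OrthologGroupAlignment

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
NT = np.array(list("ACGT"))
MIN_INTRON_LENGTH = 30
_FLANK_MARGIN = 50  # nt kept free of sites at each CDS end
_SITE_SPACING = 45  # minimum nt between site junctions


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation run."""

    tree: str                       # newick string or path
    root_site_count: int = 300
    loss_rate: float = 0.5
    gain_rate: float = 0.05
    n_groups: int = 50
    intron_length_model: tuple[float, float] = (4.0, 0.6)  # log-mean, log-sd
    imprecise_fraction: float = 0.0
    indel_size_range: tuple[int, int] = (1, 5)
    microhomology_fraction: float = 0.0
    repeat_size: int = 5
    expression_effect: float = 1.0
    substitution_rate: float = 0.01   # per nt per unit branch length
    codons_per_gene: int | None = None
    expression_log_mean: float = 1.6  # baseline FPKM ~ lognormal, median ≈ 5
    expression_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_site_count < 0:
            raise ValueError("root_site_count must be >= 0")
        if self.loss_rate < 0 or self.gain_rate < 0 or self.substitution_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0 <= self.imprecise_fraction <= 1:
            raise ValueError("imprecise_fraction must be in [0, 1]")
        if not 0 <= self.microhomology_fraction <= 1:
            raise ValueError("microhomology_fraction must be in [0, 1]")
        lo, hi = self.indel_size_range
        if lo < 1 or hi < lo:
            raise ValueError("indel_size_range must be an increasing pair >= 1")
        if not 3 <= self.repeat_size <= 8:
            raise ValueError("repeat_size must be in [3, 8]")
        if self.expression_effect < 0:
            raise ValueError("expression_effect must be >= 0")
        if self.intron_length_model[1] < 0:
            raise ValueError("intron length log-sd must be >= 0")

    def tree_index(self) -> TreeIndex:
        return TreeIndex.from_newick(self.tree)


@dataclass
class LossEvent:
    branch: str                      # label of the child node of the branch
    precise: bool = True
    indel_size: int = 0
    indel_kind: Literal["ins", "del", "none"] = "none"


@dataclass
class SiteHistory:
    """Ground truth for one intron site of one ortholog group."""

    site_uid: str
    group_id: str
    cds_offset: int                  # offset in the ancestral spliced CDS
    phase: int
    origin: str                      # node label: root or the gaining branch's child
    losses: list[LossEvent] = field(default_factory=list)
    leaf_presence: dict[str, int] = field(default_factory=dict)
    leaf_lengths: dict[str, int] = field(default_factory=dict)
    base_length: int = MIN_INTRON_LENGTH
    planted_repeat: bool = False

    @property
    def gained(self) -> bool:
        return self.origin != "root"


@dataclass
class GroupHistory:
    group_id: str
    n_codons: int
    sites: list[SiteHistory] = field(default_factory=list)


@dataclass
class TrueHistory:
    """Event log plus leaf matrices for a whole simulation."""

    tree: TreeIndex
    groups: list[GroupHistory]

    def all_sites(self) -> list[SiteHistory]:
        return [s for g in self.groups for s in g.sites]

    def leaf_matrix(self, observable_only: bool = True) -> pd.DataFrame:
        """sites x species 0/1 table of the simulated truth."""
        rows = {}
        for s in self.all_sites():
            if observable_only and not any(s.leaf_presence.values()):
                continue
            rows[s.site_uid] = s.leaf_presence
        return pd.DataFrame.from_dict(rows, orient="index", dtype=int).reindex(
            columns=self.tree.leaf_labels
        )

    def lost_gene_flags(self) -> dict[tuple[str, str], bool]:
        """(group, species) -> True if that species' gene lost >= 1 intron."""
        tree = self.tree
        flags = {(g.group_id, sp): False for g in self.groups for sp in tree.leaf_labels}
        for g in self.groups:
            for s in g.sites:
                for ev in s.losses:
                    b = tree.index_of[ev.branch]
                    for leaf in tree.subtree_leaves(b):
                        flags[(g.group_id, tree.labels[leaf])] = True
        return flags

    def validate(self) -> None:
        """Replay every site's events and check the leaf vectors match."""
        tree = self.tree
        for s in self.all_sites():
            origin = tree.index_of[s.origin]
            loss_nodes = {tree.index_of[ev.branch] for ev in s.losses}
            for leaf in tree.leaf_indices:
                path = set(tree.path_to_root(int(leaf)))
                present = origin in path and not (loss_nodes & path)
                if int(present) != s.leaf_presence[tree.labels[leaf]]:
                    raise AssertionError(f"replay mismatch at {s.site_uid}")
            for node in loss_nodes:
                if origin not in tree.path_to_root(int(node)):
                    raise AssertionError(f"{s.site_uid}: loss outside origin clade")

    def to_json(self) -> str:
        payload = []
        for g in self.groups:
            payload.append(
                {
                    "group_id": g.group_id,
                    "n_codons": g.n_codons,
                    "sites": [
                        {
                            **{
                                k: v
                                for k, v in dataclasses.asdict(s).items()
                                if k != "losses"
                            },
                            "losses": [dataclasses.asdict(ev) for ev in s.losses],
                        }
                        for s in g.sites
                    ],
                }
            )
        return json.dumps(payload, sort_keys=True)


def _site_positions(rng: np.random.Generator, n_codons: int, k: int) -> list[int]:
    """k junction offsets with a minimum spacing, away from the CDS ends."""
    L = 3 * n_codons
    lo, hi = _FLANK_MARGIN, L - _FLANK_MARGIN
    if k == 0:
        return []
    if hi - lo < k * _SITE_SPACING:
        raise ValueError(f"gene of {n_codons} codons cannot host {k} spaced sites")
    # sample gaps then rescale (stick breaking keeps spacing exact)
    slack = (hi - lo) - (k - 1) * _SITE_SPACING
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    return [int(lo + cuts[i] + i * _SITE_SPACING) for i in range(k)]


def _free_positions(n_codons: int, occupied: list[int]) -> list[int]:
    L = 3 * n_codons
    out = []
    for pos in range(_FLANK_MARGIN, L - _FLANK_MARGIN):
        if all(abs(pos - o) >= _SITE_SPACING for o in occupied):
            out.append(pos)
    return out


def simulate_history(config: SimConfig) -> TrueHistory:
    """Evolve intron sites down the tree; return the full event log.

    Losses hit present sites per branch with probability ``1-exp(-loss*t)``;
    gains hit free, spacing-compatible junction offsets with probability
    ``1-exp(-gain*t)`` per slot, at most once per slot across the whole tree.
    """
    tree = config.tree_index()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    log_mu, log_sd = config.intron_length_model

    per_group = config.root_site_count // config.n_groups
    extras = config.root_site_count % config.n_groups
    groups: list[GroupHistory] = []
    site_serial = 0
    for gi in range(config.n_groups):
        k_root = per_group + (1 if gi < extras else 0)
        n_codons = config.codons_per_gene or max(80, 20 * (k_root + 2))
        gid = f"og{gi:04d}"
        group = GroupHistory(group_id=gid, n_codons=n_codons)
        positions = _site_positions(rng, n_codons, k_root)
        sites: list[SiteHistory] = []
        for pos in positions:
            sites.append(
                SiteHistory(
                    site_uid=f"s{site_serial:06d}",
                    group_id=gid,
                    cds_offset=pos,
                    phase=pos % 3,
                    origin="root",
                )
            )
            site_serial += 1

        # walk the tree in preorder: losses on present sites, gains on free slots
        state: dict[int, dict[str, bool]] = {tree.root: {s.site_uid: True for s in sites}}
        occupied = list(positions)
        for node in tree.preorder():
            if node == tree.root:
                continue
            parent_state = state[tree.parent[node]]
            t = tree.blen[node]
            p_loss = 1.0 - np.exp(-config.loss_rate * t)
            my_state = {}
            for s in sites:
                present = parent_state.get(s.site_uid, False)
                if present and rng.random() < p_loss:
                    present = False
                    s.losses.append(LossEvent(branch=tree.labels[node]))
                my_state[s.site_uid] = present
            if config.gain_rate > 0:
                p_gain = 1.0 - np.exp(-config.gain_rate * t)
                free = _free_positions(n_codons, occupied)
                n_gain = rng.binomial(len(free), p_gain) if free else 0
                for pos in rng.choice(len(free), size=n_gain, replace=False) if n_gain else []:
                    offset = free[int(pos)]
                    occupied.append(offset)
                    s = SiteHistory(
                        site_uid=f"s{site_serial:06d}",
                        group_id=gid,
                        cds_offset=offset,
                        phase=offset % 3,
                        origin=tree.labels[node],
                    )
                    site_serial += 1
                    sites.append(s)
                    my_state[s.site_uid] = True
            state[node] = my_state

        # leaf vectors, lengths, loss precision, planted repeats
        for s in sites:
            for leaf in tree.leaf_indices:
                lab = tree.labels[leaf]
                s.leaf_presence[lab] = int(state[int(leaf)].get(s.site_uid, False))
            s.base_length = max(
                MIN_INTRON_LENGTH, int(round(rng.lognormal(log_mu, log_sd)))
            )
            for lab, pres in s.leaf_presence.items():
                if pres:
                    jitter = rng.normal(0.0, 0.1)
                    s.leaf_lengths[lab] = max(
                        MIN_INTRON_LENGTH, int(round(s.base_length * np.exp(jitter)))
                    )
            for ev in s.losses:
                if rng.random() < config.imprecise_fraction:
                    ev.precise = False
                    lo, hi = config.indel_size_range
                    ev.indel_size = int(rng.integers(lo, hi + 1))
                    ev.indel_kind = "ins" if rng.random() < 0.5 else "del"
            s.planted_repeat = rng.random() < config.microhomology_fraction
        group.sites = sorted(sites, key=lambda s: s.cds_offset)
        groups.append(group)

    history = TrueHistory(tree=tree, groups=groups)
    history.validate()
    return history


def simulate_matrix(
    tree: TreeIndex | str,
    loss_rate: float,
    gain_rate: float,
    n_sites: int,
    seed: int = 0,
) -> pd.DataFrame:
    """iid presence/absence columns under the reversible two-state chain.

    Root states draw from the stationary distribution, every branch applies
    the exact exponential transition matrix (re-gain after loss allowed), and
    unobservable (all-absent) columns are discarded and redrawn, mirroring the
    ascertainment handled by the conditioned likelihood.  This is the matched
    generator for rate-recovery checks of the ML machinery.
    """
    tr = tree if isinstance(tree, TreeIndex) else TreeIndex.from_newick(tree)
    if loss_rate <= 0 and gain_rate <= 0:
        raise ValueError("at least one rate must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pi1 = gain_rate / (gain_rate + loss_rate)
    cols = []
    batch = max(64, n_sites)
    while len(cols) < n_sites:
        states = np.zeros((batch, tr.n_nodes), dtype=np.int8)
        states[:, tr.root] = rng.random(batch) < pi1
        for node in tr.preorder():
            if node == tr.root:
                continue
            t = tr.blen[node]
            p01 = 1.0 - np.exp(-gain_rate * t)
            p10 = 1.0 - np.exp(-loss_rate * t)
            par = states[:, tr.parent[node]]
            u = rng.random(batch)
            states[:, node] = np.where(par == 1, u >= p10, u < p01)
        leaf_states = states[:, tr.leaf_indices]
        keep = leaf_states.sum(axis=1) > 0
        cols.extend(leaf_states[keep].tolist())
    data = np.array(cols[:n_sites], dtype=int)
    return pd.DataFrame(
        data, columns=tr.leaf_labels, index=[f"s{i:06d}" for i in range(n_sites)]
    )


# ---------------------------------------------------------------------------
# sequence-level emission


@dataclass
class SimulatedData:
    """Everything emitted for one simulated history."""

    history: TrueHistory
    structures: dict[str, dict[str, GeneStructure]]   # species -> gene_id -> structure
    alignments: dict[str, OrthologGroupAlignment]     # group_id -> alignment
    genomes: dict[str, str]                           # species -> chromosome sequence
    gff: dict[str, str]                               # species -> GFF3 text

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "alignments").mkdir(parents=True, exist_ok=True)
        (outdir / "genomes").mkdir(exist_ok=True)
        (outdir / "gff").mkdir(exist_ok=True)
        for gid, aln in self.alignments.items():
            with open(outdir / "alignments" / f"{gid}.fasta", "w") as fh:
                for sp, seq in aln.aligned.items():
                    fh.write(f">{sp}\n{seq}\n")
        for sp, seq in self.genomes.items():
            with open(outdir / "genomes" / f"{sp}.fasta", "w") as fh:
                fh.write(f">{sp}_chr1\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        for sp, text in self.gff.items():
            (outdir / "gff" / f"{sp}.gff3").write_text(text)
        (outdir / "true_history.json").write_text(self.history.to_json())


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=n)])


def _plant_kmer(rng: np.random.Generator, k: int) -> str:
    """Repeat k-mer compatible with GT..AG when it spans a boundary (k > 5)."""
    kmer = list(_random_nt(rng, k))
    if k >= 6:
        kmer[5] = "G"
    if k >= 7:
        kmer[6] = "T"
    m = k - 5
    if m == 1:
        kmer[0] = "G"
    elif m >= 2:
        kmer[m - 2] = "A"
        kmer[m - 1] = "G"
    return "".join(kmer)


def _intron_sequence(
    rng: np.random.Generator, length: int, plant: str | None
) -> str:
    """GT ... polypyrimidine tract ... AG, optionally with boundary repeat parts."""
    if length < MIN_INTRON_LENGTH:
        raise ValueError("intron shorter than the minimum")
    body = list(_random_nt(rng, length))
    body[0:2] = "GT"
    body[-2:] = "AG"
    # polypyrimidine tract: 10 nt ending 3 nt before the terminal AG
    ppt = "".join(rng.choice(list("CT"), size=10))
    body[-15:-5] = ppt
    if plant is not None:
        k = len(plant)
        if k > 5:
            m = k - 5
            body[0:m] = plant[5 : 5 + m]      # intron head after the exon part
            body[-m:] = plant[0:m]            # intron tail before the exon part
            body[0:2] = "GT"                  # boundary dinucleotides win
            body[-2:] = "AG"
    return "".join(body)


def emit_genes(history: TrueHistory, config: SimConfig) -> SimulatedData:
    """Materialize gene structures, genomes, GFF3 and true alignments."""
    tree = history.tree
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    structures: dict[str, dict[str, GeneStructure]] = {
        sp: {} for sp in tree.leaf_labels
    }
    alignments: dict[str, OrthologGroupAlignment] = {}
    genome_parts: dict[str, list[str]] = {sp: [] for sp in tree.leaf_labels}
    gff_lines: dict[str, list[str]] = {
        sp: ["##gff-version 3"] for sp in tree.leaf_labels
    }
    genome_cursor: dict[str, int] = {sp: 0 for sp in tree.leaf_labels}

    for group in history.groups:
        L = 3 * group.n_codons
        anc = list(_random_codons(rng, group.n_codons))

        # plant boundary repeats by editing the ancestral exon context
        plants: dict[str, str] = {}
        for s in group.sites:
            if s.planted_repeat:
                k = config.repeat_size
                kmer = _plant_kmer(rng, k)
                plants[s.site_uid] = kmer
                ex = min(k, 5)
                o = s.cds_offset
                anc[o - ex : o] = kmer[:ex]
                anc[o : o + ex] = kmer[:ex] if k <= 5 else kmer[k - 5 :]

        # per-node sequences with substitutions (no indels at this stage)
        seqs: dict[int, np.ndarray] = {tree.root: np.array(anc)}
        for node in tree.preorder():
            if node == tree.root:
                continue
            seq = seqs[tree.parent[node]].copy()
            p_sub = 1.0 - np.exp(-config.substitution_rate * tree.blen[node])
            hits = np.flatnonzero(rng.random(L) < p_sub)
            if hits.size:
                seq[hits] = NT[rng.integers(0, 4, size=hits.size)]
            seqs[node] = seq

        # junction indels from imprecise losses, keyed by event, shared by
        # every leaf below the losing branch
        ins_events: list[tuple[int, str, str, set[str]]] = []  # (offset, id, seq, leaves)
        deleted: dict[str, set[int]] = {sp: set() for sp in tree.leaf_labels}
        ev_serial = 0
        for s in group.sites:
            for ev in s.losses:
                if ev.precise:
                    continue
                below = {
                    tree.labels[lf]
                    for lf in tree.subtree_leaves(tree.index_of[ev.branch])
                }
                if ev.indel_kind == "ins":
                    ins_events.append(
                        (s.cds_offset, f"e{ev_serial}", _random_nt(rng, ev.indel_size), below)
                    )
                else:
                    for sp in below:
                        deleted[sp].update(
                            range(s.cds_offset, s.cds_offset + ev.indel_size)
                        )
                ev_serial += 1
        ins_by_offset: dict[int, list[tuple[str, str, set[str]]]] = {}
        for off, eid, seq, leaves in sorted(ins_events):
            ins_by_offset.setdefault(off, []).append((eid, seq, leaves))

        # build the true multiple alignment column by column
        aligned: dict[str, list[str]] = {sp: [] for sp in tree.leaf_labels}
        aln_pos: dict[str, int] = {sp: 0 for sp in tree.leaf_labels}  # ungapped count
        leaf_arr = {
            tree.labels[lf]: seqs[int(lf)] for lf in tree.leaf_indices
        }
        # per-species junction offsets in own CDS coordinates
        own_offset: dict[str, dict[str, int]] = {sp: {} for sp in tree.leaf_labels}
        site_at_offset = {s.cds_offset: s for s in group.sites}
        for pos in range(L + 1):
            for eid, iseq, leaves in ins_by_offset.get(pos, []):
                for ch in iseq:
                    for sp in tree.leaf_labels:
                        if sp in leaves:
                            aligned[sp].append(ch)
                            aln_pos[sp] += 1
                        else:
                            aligned[sp].append("-")
            if pos in site_at_offset:
                s = site_at_offset[pos]
                for sp in tree.leaf_labels:
                    if s.leaf_presence.get(sp):
                        own_offset[sp][s.site_uid] = aln_pos[sp]
            if pos < L:
                for sp in tree.leaf_labels:
                    if pos in deleted[sp]:
                        aligned[sp].append("-")
                    else:
                        aligned[sp].append(leaf_arr[sp][pos])
                        aln_pos[sp] += 1

        aln_strings = {sp: "".join(chars) for sp, chars in aligned.items()}

        # gene structures + genomes + GFF3
        group_structs: dict[str, GeneStructure] = {}
        for sp in tree.leaf_labels:
            cds = aln_strings[sp].replace("-", "")
            introns: list[IntronRecord] = []
            for s in group.sites:
                if not s.leaf_presence.get(sp):
                    continue
                off = own_offset[sp][s.site_uid]
                iseq = _intron_sequence(
                    rng, s.leaf_lengths[sp], plants.get(s.site_uid)
                )
                introns.append(
                    IntronRecord(
                        cds_offset=off,
                        phase=off % 3,
                        length=len(iseq),
                        sequence=iseq,
                    )
                )
            gene_id = f"{group.group_id}_{sp}"
            gs = GeneStructure(
                gene_id=gene_id,
                species=sp,
                cds_length=len(cds),
                introns=tuple(sorted(introns, key=lambda r: r.cds_offset)),
            )
            group_structs[sp] = gs
            structures[sp][gene_id] = gs

            # genomic layout: spacer, then exon/intron segments on + strand
            spacer = _random_nt(rng, 100)
            genome_parts[sp].append(spacer)
            genome_cursor[sp] += 100
            gene_start = genome_cursor[sp] + 1  # 1-based
            segs: list[tuple[int, int]] = []     # genomic 1-based CDS segments
            prev = 0
            gpos = gene_start
            pieces: list[str] = []
            for rec in gs.introns:
                exon = cds[prev : rec.cds_offset]
                segs.append((gpos, gpos + len(exon) - 1))
                pieces.append(exon)
                gpos += len(exon)
                pieces.append(rec.sequence)
                gpos += rec.length
                prev = rec.cds_offset
            exon = cds[prev:]
            segs.append((gpos, gpos + len(exon) - 1))
            pieces.append(exon)
            gpos += len(exon)
            gene_seq = "".join(pieces)
            genome_parts[sp].append(gene_seq)
            genome_cursor[sp] += len(gene_seq)
            gene_end = gpos - 1
            chrom = f"{sp}_chr1"
            gl = gff_lines[sp]
            gl.append(
                f"{chrom}\tintronevo\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\tID={gene_id}"
            )
            gl.append(
                f"{chrom}\tintronevo\tmRNA\t{gene_start}\t{gene_end}\t.\t+\t.\t"
                f"ID={gene_id}.t1;Parent={gene_id}"
            )
            phase_acc = 0
            for i, (a, b) in enumerate(segs):
                gl.append(
                    f"{chrom}\tintronevo\texon\t{a}\t{b}\t.\t+\t.\t"
                    f"ID={gene_id}.e{i};Parent={gene_id}.t1"
                )
                frame = (3 - phase_acc % 3) % 3
                gl.append(
                    f"{chrom}\tintronevo\tCDS\t{a}\t{b}\t.\t+\t{frame}\t"
                    f"ID={gene_id}.c{i};Parent={gene_id}.t1"
                )
                phase_acc += b - a + 1

        alignments[group.group_id] = OrthologGroupAlignment(
            group.group_id, aln_strings, group_structs
        )

    return SimulatedData(
        history=history,
        structures=structures,
        alignments=alignments,
        genomes={sp: "".join(parts) for sp, parts in genome_parts.items()},
        gff={sp: "\n".join(lines) + "\n" for sp, lines in gff_lines.items()},
    )


def emit_expression(history: TrueHistory, config: SimConfig) -> pd.DataFrame:
    """FPKM table with the configured multiplicative shift in intron-lost genes.

    Baselines are log-normal (heavy right tail, like RNA-seq FPKM); a gene is
    flagged intron-lost when its lineage lost at least one site.
    """
    if config.expression_effect < 0:
        raise ValueError("expression_effect must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    flags = history.lost_gene_flags()
    rows = []
    for (gid, sp), lost in sorted(flags.items()):
        fpkm = float(rng.lognormal(config.expression_log_mean, config.expression_log_sd))
        if lost:
            fpkm *= config.expression_effect
        rows.append(
            {
                "group_id": gid,
                "gene_id": f"{gid}_{sp}",
                "species": sp,
                "fpkm": fpkm,
                "intron_lost": lost,
            }
        )
    return pd.DataFrame(rows)
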