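"""Project intron positions onto ortholog alignments and build the site matrix.

Two introns from different species belong to the same site iff they fall on
the same alignment column (the column of the first aligned base 3' of the
junction) with the same phase.  Absence calls are screened with the flanking
alignment-quality filters: within 45 columns on each side of the junction the
pairwise comparison against every intron-bearing species must show fewer than
10 gap characters and an identity above 0.5, each side independently;
otherwise the cell is ambiguous ('?').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .structures import GAP, OrthologGroupAlignment

logger = logging.getLogger(__name__)

PresenceState = Literal["present", "absent", "ambiguous"]
SiteState = Literal["conserved", "discordant", "ambiguous"]

DEFAULT_WINDOW = 45
DEFAULT_MAX_GAPS = 10
DEFAULT_MIN_IDENTITY = 0.5
MIN_USABLE_COLUMNS = 20
DEFAULT_MAX_AMBIGUOUS = 11
PRECISION_WINDOW = 15


@dataclass
class AlignedIntronSite:
    """One intron site projected onto a group alignment."""

    group_id: str
    site_id: str
    alignment_column: int
    phase: int
    presence: dict[str, PresenceState]
    flank_metrics: dict[tuple[str, str], tuple[int, float, int, float]] = field(
        default_factory=dict
    )  # (species_a, species_b) -> (up_gaps, up_identity, down_gaps, down_identity)
    state: SiteState = "ambiguous"

    def __post_init__(self) -> None:
        if not any(v == "present" for v in self.presence.values()):
            raise ValueError(f"{self.site_id}: site with no presence")


def _window_metrics(
    seq_a: str, seq_b: str, lo: int, hi: int
) -> tuple[int, float, int]:
    """(gap characters, identity over ungapped columns, usable columns)."""
    gaps = 0
    usable = 0
    matches = 0
    for col in range(max(lo, 0), min(hi, len(seq_a))):
        ca, cb = seq_a[col], seq_b[col]
        if ca == GAP:
            gaps += 1
        if cb == GAP:
            gaps += 1
        if ca != GAP and cb != GAP:
            usable += 1
            if ca == cb:
                matches += 1
    identity = matches / usable if usable else 0.0
    return gaps, identity, usable


def _flanks_pass(
    seq_a: str,
    seq_b: str,
    column: int,
    window: int,
    max_gaps: int,
    min_identity: float,
) -> tuple[bool, tuple[int, float, int, float]]:
    up = _window_metrics(seq_a, seq_b, column - window, column)
    down = _window_metrics(seq_a, seq_b, column, column + window)
    metrics = (up[0], up[1], down[0], down[1])
    for gaps, ident, usable in (up, down):
        if usable < MIN_USABLE_COLUMNS:
            return False, metrics
        if gaps >= max_gaps:
            return False, metrics
        if ident <= min_identity:
            return False, metrics
    return True, metrics


def _offset_to_column(seq: str) -> list[int]:
    """For each ungapped offset, the alignment column of that base."""
    cols = [c for c, ch in enumerate(seq) if ch != GAP]
    cols.append(len(seq))  # junction at the very end of the CDS
    return cols

def map_introns(group: OrthologGroupAlignment) -> list[AlignedIntronSite]:
    """Collect the group's intron sites keyed by (alignment column, phase)."""
    species = list(group.aligned)
    off2col = {sp: _offset_to_column(group.aligned[sp]) for sp in species}
    sites: dict[tuple[int, int], set[str]] = {}
    for sp, struct in group.structures.items():
        for rec in struct.introns:
            col = off2col[sp][rec.cds_offset]
            sites.setdefault((col, rec.phase), set()).add(sp)
    out: list[AlignedIntronSite] = []
    for idx, (col, phase) in enumerate(sorted(sites)):
        carriers = sites[(col, phase)]
        presence: dict[str, PresenceState] = {
            sp: "present" if sp in carriers else "absent" for sp in species
        }
        out.append(
            AlignedIntronSite(
                group_id=group.group_id,
                site_id=f"{group.group_id}:{idx:03d}",
                alignment_column=col,
                phase=phase,
                presence=presence,
            )
        )
    return out


def classify_site(
    site: AlignedIntronSite,
    group: OrthologGroupAlignment,
    window: int = DEFAULT_WINDOW,
    max_gaps: int = DEFAULT_MAX_GAPS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> SiteState:
    """Classify a site and refine its per-species presence states in place.

    Every species lacking the intron is compared against every species
    carrying it; an absence call stands only if all its comparisons pass the
    flank filters, otherwise the cell becomes ambiguous.
    """
    present = [sp for sp, st in site.presence.items() if st == "present"]
    absent = [sp for sp, st in site.presence.items() if st != "present"]
    col = site.alignment_column
    for sp in absent:
        ok_all = True
        for ref in present:
            ok, metrics = _flanks_pass(
                group.aligned[sp], group.aligned[ref], col, window, max_gaps, min_identity
            )
            site.flank_metrics[(sp, ref)] = metrics
            if not ok:
                ok_all = False
        site.presence[sp] = "absent" if ok_all else "ambiguous"
    if not absent:
        usable = all(
            _window_metrics(group.aligned[sp], group.aligned[sp], col - window, col)[2]
            >= MIN_USABLE_COLUMNS
            and _window_metrics(group.aligned[sp], group.aligned[sp], col, col + window)[2]
            >= MIN_USABLE_COLUMNS
            for sp in present
        )
        site.state = "conserved" if usable else "ambiguous"
    elif any(site.presence[sp] == "absent" for sp in absent):
        site.state = "discordant"
    else:
        site.state = "ambiguous"
    return site.state


@dataclass
class IntronSiteMatrix:
    """Sites x species presence/absence table with '?' for ambiguous cells."""

    table: pd.DataFrame            # values in {"0", "1", "?"}
    metadata: pd.DataFrame         # per-site: group_id, aln_column, phase, state

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def presence_counts(self) -> pd.Series:
        return (self.table == "1").sum(axis=0)

    def to_tsv(self, path) -> None:
        merged = self.metadata.join(self.table)
        merged.to_csv(path, sep="\t", index_label="site_id")

    @classmethod
    def from_tsv(cls, path) -> "IntronSiteMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_id", dtype=str)
        meta_cols = ["group_id", "aln_column", "phase", "state"]
        meta = df[meta_cols].copy()
        meta["aln_column"] = meta["aln_column"].astype(int)
        meta["phase"] = meta["phase"].astype(int)
        return cls(table=df.drop(columns=meta_cols), metadata=meta)


def build_matrix(
    sites: Iterable[tuple[AlignedIntronSite, None] | AlignedIntronSite],
    max_ambiguous: int = DEFAULT_MAX_AMBIGUOUS,
    species: list[str] | None = None,
) -> IntronSiteMatrix:
    """Assemble the matrix, dropping rows with too many ambiguous cells."""
    rows = {}
    meta = {}
    dropped = 0
    seen: set[str] = set()
    site_list = [s for s in sites]
    if species is None:
        species = sorted({sp for s in site_list for sp in s.presence})
    for site in site_list:
        if site.site_id in seen:
            raise ValueError(f"duplicate site_id {site.site_id}")
        seen.add(site.site_id)
        cells = {}
        n_amb = 0
        for sp in species:
            st = site.presence.get(sp, "ambiguous")
            if st == "present":
                cells[sp] = "1"
            elif st == "absent":
                cells[sp] = "0"
            else:
                cells[sp] = "?"
                n_amb += 1
        if n_amb > max_ambiguous:
            dropped += 1
            continue
        rows[site.site_id] = cells
        meta[site.site_id] = {
            "group_id": site.group_id,
            "aln_column": site.alignment_column,
            "phase": site.phase,
            "state": site.state,
        }
    logger.info(
        "matrix: %d sites retained, %d dropped (> %d ambiguous), %d species",
        len(rows), dropped, max_ambiguous, len(species),
    )
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=species)
    if table.empty:
        table = pd.DataFrame(columns=species, dtype=str)
    metadata = pd.DataFrame.from_dict(meta, orient="index").reindex(index=table.index)
    return IntronSiteMatrix(table=table, metadata=metadata)


@dataclass(frozen=True)
class PrecisionCall:
    call: Literal["precise", "imprecise", "ambiguous"]
    indel_nt: int = 0


def classify_precision(
    site: AlignedIntronSite,
    group: OrthologGroupAlignment,
    losing_species: str,
    reference_species: str,
    window: int = PRECISION_WINDOW,
) -> PrecisionCall:
    """Precise iff the junction-proximal alignment windows are gap free.

    Inspects ``window`` columns on each side of the junction column in the
    pair (losing species, intron-retaining reference); any gap column makes
    the loss imprecise, with the gap-column count reported as the indel size.
    """
    if site.presence.get(losing_species) == "present":
        raise ValueError(f"{losing_species} is not a losing species at {site.site_id}")
    if site.presence.get(reference_species) != "present":
        raise ValueError(f"{reference_species} does not retain {site.site_id}")
    a = group.aligned[losing_species]
    b = group.aligned[reference_species]
    col = site.alignment_column
    lo, hi = max(col - window, 0), min(col + window, len(a))
    if hi - lo == 0:
        return PrecisionCall("ambiguous")
    # columns gapped in both sequences are padding for third species, not an
    # indel between this pair
    gap_cols = sum(1 for c in range(lo, hi) if (a[c] == GAP) != (b[c] == GAP))
    if gap_cols == 0:
        return PrecisionCall("precise")
    return PrecisionCall("imprecise", indel_nt=gap_cols)
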