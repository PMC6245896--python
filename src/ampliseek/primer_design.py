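"""Degenerate forward-primer design from aligned signal-peptide (or
propeptide) coding regions, and amplicon-size compatibility prediction.

The design recipe: cluster ungapped input sequences at a global-identity
threshold, scan each cluster alignment for gap-free windows with at most a
budgeted number of polymorphic columns, collapse each window to a minimal
degenerate consensus, and bolt on the fixed 5' tail used for multiplexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .seqcore import (
    NucSeq,
    degeneracy as _degeneracy,
    iupac_code_for,
    iupac_match,
)

__all__ = [
    "RegionAlignment",
    "SeqCluster",
    "ConservedWindow",
    "DegeneratePrimer",
    "AmpliconPrediction",
    "DesignError",
    "cluster_by_identity",
    "scan_windows",
    "make_degenerate",
    "attach_tail",
    "pick_primer_position",
    "predict_amplicons",
    "global_identity",
]

logger = logging.getLogger(__name__)

#: 5' tail attached to every forward primer for the outer barcoding PCR.
DEFAULT_FORWARD_TAIL = "CAGGACCAGGGTACGGTG"
#: 5' tail of the poly-dT reverse primer.
DEFAULT_REVERSE_TAIL = "CCTCTCTATGGGCAGTCGGTGAT"


class DesignError(RuntimeError):
    """Raised when primer design cannot proceed (e.g. no usable window)."""


@dataclass(frozen=True)
class RegionAlignment:
    """A gapped alignment of one conserved coding region."""

    members: tuple
    region_kind: str = "signal"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("alignment needs at least 2 members")
        lengths = {len(m.bases) for m in self.members}
        if len(lengths) != 1:
            raise ValueError("aligned members must have uniform length")
        if self.region_kind not in ("signal", "propeptide"):
            raise ValueError(f"unknown region kind {self.region_kind!r}")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def length(self) -> int:
        return len(self.members[0].bases)


@dataclass(frozen=True)
class GappedSeq:
    """An aligned sequence: like NucSeq but admits '-' gap characters."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        up = self.bases.upper()
        from .seqcore import NUC_ALPHABET

        bad = set(up) - NUC_ALPHABET - {"-"}
        if bad:
            raise ValueError(f"invalid aligned character(s) {sorted(bad)} in {self.id!r}")
        object.__setattr__(self, "bases", up)

    def ungapped(self) -> NucSeq:
        return NucSeq(self.id, self.bases.replace("-", ""))


@dataclass
class SeqCluster:
    representative: NucSeq
    members: list[NucSeq]
    identity_threshold: float


@dataclass(frozen=True)
class ConservedWindow:
    start: int
    length: int
    polymorphic_columns: tuple[int, ...]
    consensus: NucSeq


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    specific_part: NucSeq
    tail: NucSeq
    degeneracy: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "degeneracy", _degeneracy(self.specific_part))

    @property
    def full_sequence(self) -> str:
        return self.tail.bases + self.specific_part.bases


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    forward_site: int
    product_length: int
    exceeds_platform_limit: bool
    mismatches: int = 0
    primer_name: str = ""


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment: matches / alignment columns."""
    aln = _aligner().align(a, b)[0]
    cols = 0
    matches = 0
    sa, sb = aln[0], aln[1]
    for x, y in zip(sa, sb):
        cols += 1
        if x == y and x != "-":
            matches += 1
    return matches / cols if cols else 0.0


def cluster_by_identity(seqs: list[NucSeq], threshold: float = 0.8) -> list[SeqCluster]:
    """Greedy longest-first clustering at a global-identity threshold.

    Sequences are sorted by length descending (stable); each joins the first
    existing cluster whose representative it matches at >= threshold, else
    founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    clusters: list[SeqCluster] = []
    for seq in sorted(seqs, key=lambda s: -len(s.bases)):
        for cl in clusters:
            if global_identity(seq.bases, cl.representative.bases) >= threshold:
                cl.members.append(seq)
                break
        else:
            clusters.append(SeqCluster(seq, [seq], threshold))
    return clusters


def column_base_sets(aln: RegionAlignment, minor_freq_floor: float = 0.0) -> list[set[str]]:
    """Observed base set per column, applying the minor-frequency floor.

    Gaps are kept as '-' entries so callers can exclude gapped columns.
    """
    n = len(aln.members)
    sets: list[set[str]] = []
    for col in range(aln.length):
        counts: dict[str, int] = {}
        for m in aln.members:
            b = m.bases[col]
            counts[b] = counts.get(b, 0) + 1
        kept = {b for b, c in counts.items() if c / n > minor_freq_floor}
        if not kept:  # floor removed everything; keep the majority base
            kept = {max(counts, key=counts.get)}
        sets.append(kept)
    return sets


def scan_windows(
    aln: RegionAlignment,
    window_len: int = 20,
    max_polymorphic: int = 3,
    minor_freq_floor: float = 0.0,
) -> list[ConservedWindow]:
    """All gap-free windows with at most ``max_polymorphic`` polymorphic columns.

    A column is polymorphic iff at least two distinct bases each exceed the
    minor-frequency floor (default 0: any second observed base counts).
    """
    if aln.length < window_len:
        return []
    sets = column_base_sets(aln, minor_freq_floor)
    gapped = ["-" in s for s in sets]
    poly = [len(s - {"-"}) >= 2 for s in sets]
    windows = []
    for start in range(aln.length - window_len + 1):
        cols = range(start, start + window_len)
        if any(gapped[c] for c in cols):
            continue
        poly_cols = tuple(c for c in cols if poly[c])
        if len(poly_cols) > max_polymorphic:
            continue
        consensus = make_degenerate([sets[c] for c in cols], id=f"win{start}")
        windows.append(ConservedWindow(start, window_len, poly_cols, consensus))
    return windows


def make_degenerate(columns: list[set[str]], id: str = "consensus") -> NucSeq:
    """Collapse per-column base sets to the minimal covering IUPAC codes.

    Columns containing N (or all four bases) emit N with a warning.
    """
    out = []
    for i, col in enumerate(columns):
        if "-" in col:
            raise ValueError(f"gap in column {i}")
        if "N" in col or len(col - {"N"}) == 4:
            logger.warning("column %d fully ambiguous; emitting N", i)
            out.append("N")
        else:
            out.append(iupac_code_for(col))
    return NucSeq(id, "".join(out))


def attach_tail(specific: NucSeq, tail: NucSeq, name: str = "primer") -> DegeneratePrimer:
    """Assemble a full primer: fixed 5' tail followed by the specific part."""
    return DegeneratePrimer(name=name, specific_part=specific, tail=tail)


def pick_primer_position(
    windows: list[ConservedWindow],
    mode: str = "signal_any",
    max_degeneracy: int | None = None,
) -> ConservedWindow:
    """Select the design window.

    ``signal_any``: fewest polymorphic columns, ties to leftmost.
    ``propeptide_3prime``: largest start coordinate among windows within the
    degeneracy budget (all windows when no budget given).
    """
    if not windows:
        raise DesignError("no conserved window available for primer design")
    if mode == "signal_any":
        return min(windows, key=lambda w: (len(w.polymorphic_columns), w.start))
    if mode == "propeptide_3prime":
        pool = windows
        if max_degeneracy is not None:
            pool = [w for w in windows if _degeneracy(w.consensus) <= max_degeneracy]
            if not pool:
                raise DesignError("no window within the degeneracy budget")
        return max(pool, key=lambda w: w.start)
    raise ValueError(f"unknown mode {mode!r}")


def find_binding_site(template: str, specific: str, max_mismatches: int) -> tuple[int, int] | None:
    """Best IUPAC-aware match of the primer specific part on the template.

    Returns (start, mismatches) of the lowest-mismatch (then leftmost) site
    with mismatches <= max_mismatches, or None.
    """
    k = len(specific)
    best: tuple[int, int] | None = None
    for start in range(len(template) - k + 1):
        mm = 0
        for i in range(k):
            if not iupac_match(specific[i], template[start + i]):
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            if best is None or mm < best[1]:
                best = (start, mm)
    return best


def predict_amplicons(
    templates: list[NucSeq],
    panel: list[DegeneratePrimer],
    max_mismatches: int = 2,
    platform_max: int = 450,
    reverse_tail_len: int = len(DEFAULT_REVERSE_TAIL),
) -> list[AmpliconPrediction]:
    """Predict product sizes of the primer panel on poly-A-terminated templates.

    Product length = (template end - forward binding-site start) + forward
    tail length + reverse tail length. Templates with no binding site for any
    primer are omitted with a logged reason.
    """
    out = []
    for tpl in templates:
        best: tuple[int, int, DegeneratePrimer] | None = None
        for primer in panel:
            site = find_binding_site(tpl.bases, primer.specific_part.bases, max_mismatches)
            if site and (best is None or site[1] < best[1]):
                best = (site[0], site[1], primer)
        if best is None:
            logger.info("template %s: no primer binding site within %d mismatches",
                        tpl.id, max_mismatches)
            continue
        start, mm, primer = best
        length = (len(tpl.bases) - start) + len(primer.tail.bases) + reverse_tail_len
        out.append(
            AmpliconPrediction(
                template_id=tpl.id,
                forward_site=start,
                product_length=length,
                exceeds_platform_limit=length > platform_max,
                mismatches=mm,
                primer_name=primer.name,
            )
        )
    return out
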