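"""Raw amplicon reads to high-confidence contigs.

Stages: modified-Mott quality trimming with adapter clipping and a length
floor, barcode demultiplexing, greedy overlap-layout-consensus assembly,
read-support filtering, and re-mapping with stringent re-assembly of
polymorphic contigs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .seqcore import NucSeq, QualRead, reverse_complement

__all__ = [
    "TrimConfig",
    "Contig",
    "RemapResult",
    "trim_read",
    "demultiplex",
    "assemble_olc",
    "filter_support",
    "remap_and_flag",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrimConfig:
    error_prob_limit: float = 0.05
    min_length: int = 100
    adapters: tuple[str, ...] = ()
    barcode_length: int = 10
    barcode_max_mismatch: int = 1
    adapter_mismatch_frac: float = 0.10
    adapter_min_suffix: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.error_prob_limit < 1:
            raise ValueError("error_prob_limit must be in (0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        object.__setattr__(
            self, "adapters", tuple(a.upper() for a in self.adapters)
        )


@dataclass
class Contig:
    """Assembled consensus with read support and (optional) polymorphism rate."""

    consensus: NucSeq
    supporting_reads: int
    coverage: list[int] = field(default_factory=list)
    polymorphism_rate: float = 0.0
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.supporting_reads < 1:
            raise ValueError("a contig needs at least one supporting read")
        if "-" in self.consensus.bases:
            raise ValueError("contig consensus must be gap-free")

    def __len__(self) -> int:
        return len(self.consensus.bases)


# ---------------------------------------------------------------------------
# Trimming


def mott_segment(quals: list[int] | tuple[int, ...], limit: float) -> tuple[int, int]:
    """Modified-Mott segment: maximize the running sum of (limit - P_err).

    Returns the 0-based half-open (start, end) of the best segment; among
    equal sums the leftmost start wins, then the longest extent. (0, 0) when
    every prefix weight is unprofitable.
    """
    eps = 1e-9
    best_sum = 0.0
    best = (0, 0)
    cur = 0.0
    cur_start = 0
    for i, q in enumerate(quals):
        w = limit - 10.0 ** (-q / 10.0)
        if cur < 0:
            cur = 0.0
            cur_start = i
        cur += w
        if cur > best_sum + eps:
            best_sum = cur
            best = (cur_start, i + 1)
        elif cur > eps and abs(cur - best_sum) <= eps:
            if cur_start < best[0] or (cur_start == best[0] and i + 1 > best[1]):
                best = (cur_start, i + 1)
    return best


def _clip_adapters(bases: str, cfg: TrimConfig) -> str:
    """Clip the read at the leftmost adapter occurrence (read-through model).

    Full occurrences tolerate ``adapter_mismatch_frac`` mismatches; adapter
    prefixes overhanging the 3' end are clipped from ``adapter_min_suffix``
    bases of overlap.
    """
    cut = len(bases)
    for adapter in cfg.adapters:
        k = len(adapter)
        allowed = int(cfg.adapter_mismatch_frac * k)
        for start in range(len(bases) - k + 1):
            mm = 0
            for i in range(k):
                if bases[start + i] != adapter[i]:
                    mm += 1
                    if mm > allowed:
                        break
            else:
                cut = min(cut, start)
                break
        # partial adapter hanging off the 3' end
        for ovl in range(min(k - 1, len(bases)), cfg.adapter_min_suffix - 1, -1):
            start = len(bases) - ovl
            if start >= cut:
                continue
            allowed_p = int(cfg.adapter_mismatch_frac * ovl)
            mm = sum(1 for i in range(ovl) if bases[start + i] != adapter[i])
            if mm <= allowed_p:
                cut = min(cut, start)
                break
    return bases[:cut]


def trim_read(read: QualRead, cfg: TrimConfig) -> QualRead | None:
    """Quality-trim, adapter-clip and length-filter one read.

    Returns the trimmed read, or None when it falls below ``min_length``
    (discard is a normal, logged outcome).
    """
    start, end = mott_segment(read.quals, cfg.error_prob_limit)
    bases = read.bases[start:end]
    quals = read.quals[start:end]
    if cfg.adapters:
        clipped = _clip_adapters(bases, cfg)
        quals = quals[: len(clipped)]
        bases = clipped
    # strip leading/trailing ambiguous calls
    left = 0
    while left < len(bases) and bases[left] == "N":
        left += 1
    right = len(bases)
    while right > left and bases[right - 1] == "N":
        right -= 1
    bases, quals = bases[left:right], quals[left:right]
    if len(bases) < cfg.min_length:
        logger.debug("read %s discarded: trimmed length %d < %d",
                     read.id, len(bases), cfg.min_length)
        return None
    return QualRead(read.id, bases, quals)


# ---------------------------------------------------------------------------
# Demultiplexing


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def demultiplex(
    reads: list[QualRead],
    barcodes: dict[str, str],
    max_mismatch: int = 1,
) -> dict[str, list[QualRead]]:
    """Assign reads to samples by barcode prefix within ``max_mismatch``.

    The barcode table must be unambiguous: equal lengths and pairwise Hamming
    distance > 2 * max_mismatch. Assigned reads lose their barcode prefix;
    the rest land in the "undetermined" bin.
    """
    samples = list(barcodes)
    seqs = {s: barcodes[s].upper() for s in samples}
    lengths = {len(v) for v in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("barcodes must share one length")
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1 :]:
            if _hamming(seqs[s1], seqs[s2]) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {s1!r} and {s2!r} too close for {max_mismatch} mismatches"
                )
    blen = lengths.pop() if lengths else 0
    bins: dict[str, list[QualRead]] = {s: [] for s in samples}
    bins["undetermined"] = []
    for read in reads:
        prefix = read.bases[:blen]
        assigned = None
        if len(prefix) == blen:
            for s in samples:
                if _hamming(prefix, seqs[s]) <= max_mismatch:
                    assigned = s
                    break
        if assigned is None:
            bins["undetermined"].append(read)
        else:
            bins[assigned].append(
                QualRead(read.id, read.bases[blen:], read.quals[blen:])
            )
    return bins


# ---------------------------------------------------------------------------
# Greedy OLC assembly


class _Draft:
    """Mutable assembly intermediate: consensus + per-column base counts."""

    __slots__ = ("seq", "counts", "support", "read_ids")

    def __init__(self, seq: str, read_id: str):
        self.seq = seq
        self.counts: list[Counter] = [Counter({b: 1}) for b in seq]
        self.support = 1
        self.read_ids = [read_id]

    def revcomp(self) -> "_Draft":
        d = _Draft.__new__(_Draft)
        d.seq = reverse_complement(self.seq)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        d.counts = [
            Counter({comp[b]: c for b, c in col.items()}) for col in reversed(self.counts)
        ]
        d.support = self.support
        d.read_ids = list(self.read_ids)
        return d


def _merge(a: _Draft, b: _Draft, p: int) -> _Draft:
    """Merge b onto a at offset p (b's prefix aligned to a[p:])."""
    ovl = min(len(b.seq), len(a.seq) - p)
    merged = _Draft.__new__(_Draft)
    counts = a.counts[:p]
    seq = [a.seq[:p]]
    for i in range(ovl):
        col = a.counts[p + i] + b.counts[i]
        top = max(col.values())
        winners = [x for x, c in col.items() if c == top]
        prefer = a.seq[p + i]  # ties go to the earlier-merged base
        base = prefer if prefer in winners else winners[0]
        counts.append(col)
        seq.append(base)
    if len(b.seq) > ovl:
        counts.extend(b.counts[ovl:])
        seq.append(b.seq[ovl:])
    else:
        counts.extend(a.counts[p + ovl :])
        seq.append(a.seq[p + ovl :])
    merged.seq = "".join(seq)
    merged.counts = counts
    merged.support = a.support + b.support
    merged.read_ids = a.read_ids + b.read_ids
    return merged


def _overlap_identity(a: str, b: str, p: int, ovl: int) -> float:
    mm = 0
    for i in range(ovl):
        if a[p + i] != b[i]:
            mm += 1
    return 1.0 - mm / ovl if ovl else 0.0


def assemble_olc(
    reads: list[NucSeq],
    min_overlap: int = 50,
    min_overlap_identity: float = 0.95,
    both_orientations: bool = True,
    seed_len: int = 14,
) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly.

    Repeatedly merges the best suffix-prefix (or containment) overlap of at
    least ``min_overlap`` bases at identity >= ``min_overlap_identity``;
    candidate overlaps are seeded by an exact ``seed_len``-mer anchored at
    the incoming sequence's start. Consensus is per-column majority with ties
    to the earlier-merged base.
    """
    drafts = [_Draft(r.bases, r.id) for r in reads if len(r.bases) >= min_overlap]
    short = [r for r in reads if len(r.bases) < min_overlap]
    for r in short:
        logger.debug("read %s shorter than min_overlap; kept as singleton", r.id)
    singletons = [_Draft(r.bases, r.id) for r in short]

    while True:
        merged_any = False
        # index: seed -> indices whose prefix (or revcomp prefix) starts with it
        fwd_index: dict[str, list[int]] = {}
        rc_index: dict[str, list[int]] = {}
        for i, d in enumerate(drafts):
            fwd_index.setdefault(d.seq[:seed_len], []).append(i)
            if both_orientations:
                rc_index.setdefault(reverse_complement(d.seq)[:seed_len], []).append(i)
        candidates: list[tuple[int, float, int, int, int, bool]] = []
        for ia, a in enumerate(drafts):
            la = len(a.seq)
            for p in range(0, la - min_overlap + 1):
                seed = a.seq[p : p + seed_len]
                for index, is_rc in ((fwd_index, False), (rc_index, True)):
                    for ib in index.get(seed, ()):
                        if ib == ia:
                            continue
                        b = drafts[ib]
                        bseq = reverse_complement(b.seq) if is_rc else b.seq
                        ovl = min(len(bseq), la - p)
                        if ovl < min_overlap:
                            continue
                        ident = _overlap_identity(a.seq, bseq, p, ovl)
                        if ident >= min_overlap_identity:
                            candidates.append((ovl, ident, ia, ib, p, is_rc))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
        consumed: set[int] = set()
        result: dict[int, _Draft] = {}
        for ovl, ident, ia, ib, p, is_rc in candidates:
            if ia in consumed or ib in consumed:
                continue
            a, b = drafts[ia], drafts[ib]
            if is_rc:
                b = b.revcomp()
            result[ia] = _merge(a, b, p)
            consumed.add(ia)
            consumed.add(ib)
            merged_any = True
        drafts = [result.get(i, d) for i, d in enumerate(drafts) if i not in consumed or i in result]
        if not merged_any:
            break

    contigs = []
    for i, d in enumerate(drafts + singletons):
        contigs.append(
            Contig(
                consensus=NucSeq(f"contig_{i + 1}", d.seq),
                supporting_reads=d.support,
                coverage=[sum(c.values()) for c in d.counts],
                read_ids=d.read_ids,
            )
        )
    return contigs


def filter_support(contigs: list[Contig], min_reads: int = 3) -> list[Contig]:
    """Retain contigs supported by at least ``min_reads`` reads."""
    kept = [c for c in contigs if c.supporting_reads >= min_reads]
    for c in contigs:
        if c.supporting_reads < min_reads:
            logger.debug("contig %s discarded: support %d < %d",
                         c.consensus.id, c.supporting_reads, min_reads)
    return kept


# ---------------------------------------------------------------------------
# Re-mapping and stringent re-assembly


@dataclass
class RemapResult:
    contigs: list[Contig]
    flagged: list[Contig]
    unmapped: int
    allele_counts: dict[str, list[Counter]]


def _map_read(bases: str, contig: str, seed_len: int = 14) -> tuple[int, int, int] | None:
    """Best ungapped placement of a read on a contig via exact-seed anchors.

    Returns (offset, mismatches, overlap) or None. Negative offsets (read
    overhanging the contig start) are allowed.
    """
    anchors = []
    for qpos in (0, len(bases) // 2, max(0, len(bases) - seed_len)):
        seed = bases[qpos : qpos + seed_len]
        if len(seed) < seed_len:
            continue
        start = contig.find(seed)
        while start != -1:
            anchors.append(start - qpos)
            start = contig.find(seed, start + 1)
    best = None
    for off in set(anchors):
        lo = max(0, off)
        hi = min(len(contig), off + len(bases))
        ovl = hi - lo
        if ovl <= 0:
            continue
        mm = sum(1 for i in range(lo, hi) if contig[i] != bases[i - off])
        if best is None or (mm / ovl, -ovl) < (best[1] / best[2], -best[2]):
            best = (off, mm, ovl)
    return best


def remap_and_flag(
    contigs: list[Contig],
    reads: list[NucSeq],
    polymorphism_floor: float = 0.2,
    flag_threshold: float = 0.02,
    stringent_identity: float = 0.99,
    min_overlap: int = 50,
    min_identity: float = 0.8,
    both_orientations: bool = True,
) -> RemapResult:
    """Re-map reads onto contigs, score per-column polymorphism, and
    stringently re-assemble flagged contigs into their sequence variants.

    polymorphism_rate = fraction of consensus columns whose minor-allele
    frequency is >= ``polymorphism_floor``. Contigs at or above
    ``flag_threshold`` are re-assembled from their mapped reads with
    ``min_overlap_identity`` raised to ``stringent_identity``.
    """
    allele: dict[str, list[Counter]] = {
        c.consensus.id: [Counter() for _ in range(len(c))] for c in contigs
    }
    assigned: dict[str, list[NucSeq]] = {c.consensus.id: [] for c in contigs}
    unmapped = 0
    for read in reads:
        best = None
        for contig in contigs:
            for bases, flipped in ((read.bases, False),) + (
                ((reverse_complement(read.bases), True),) if both_orientations else ()
            ):
                hit = _map_read(bases, contig.consensus.bases)
                if hit is None:
                    continue
                off, mm, ovl = hit
                ident = 1.0 - mm / ovl
                if ident < min_identity:
                    continue
                key = (-ovl * ident, mm)
                if best is None or key < best[0]:
                    best = (key, contig, off, bases)
        if best is None:
            unmapped += 1
            continue
        _, contig, off, bases = best
        cid = contig.consensus.id
        assigned[cid].append(NucSeq(read.id, bases))
        cols = allele[cid]
        for i, b in enumerate(bases):
            pos = off + i
            if 0 <= pos < len(cols):
                cols[pos][b] += 1
    if unmapped:
        logger.info("%d read(s) mapped to no contig", unmapped)

    updated: list[Contig] = []
    flagged: list[Contig] = []
    for contig in contigs:
        cols = allele[contig.consensus.id]
        poly = 0
        for col in cols:
            total = sum(col.values())
            if total < 2 or len(col) < 2:
                continue
            minor = sorted(col.values(), reverse=True)[1]
            if minor / total >= polymorphism_floor:
                poly += 1
        rate = poly / len(cols) if cols else 0.0
        contig.polymorphism_rate = rate
        if rate >= flag_threshold:
            flagged.append(contig)
            variants = assemble_olc(
                assigned[contig.consensus.id],
                min_overlap=min_overlap,
                min_overlap_identity=stringent_identity,
                both_orientations=both_orientations,
            )
            for j, v in enumerate(variants):
                v.consensus = NucSeq(f"{contig.consensus.id}.v{j + 1}", v.consensus.bases)
                v.polymorphism_rate = 0.0
                updated.append(v)
        else:
            updated.append(contig)
    return RemapResult(contigs=updated, flagged=flagged, unmapped=unmapped,
                       allele_counts=allele)
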