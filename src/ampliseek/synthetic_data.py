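"""Seeded generation of ground-truthed AMP precursor gene families and
Ion-Torrent-like amplicon reads, so every pipeline stage is testable offline.

Generated loci follow the canonical precursor architecture: start codon,
conserved signal-peptide region, acidic propeptide ending at a Lys-Arg
processing site, hypervariable cationic mature peptide (optionally with a
rana-box Cys loop and/or a trailing amidation signal), stop codon, a short
3' UTR and a poly-A tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .physchem import net_charge
from .precursor_annotation import resolve_amidation
from .primer_design import DegeneratePrimer, find_binding_site
from .seqcore import CODON_TABLE, NucSeq, PepSeq, QualRead, translate

__all__ = [
    "FamilySpec",
    "ReadSimSpec",
    "TruthRecord",
    "GenerationError",
    "generate_family",
    "simulate_reads",
]

logger = logging.getLogger(__name__)

#: One codon per residue; fixed so generated coding regions are deterministic
#: functions of the peptide and the seed only controls peptide composition.
PREFERRED_CODON = {}
for _codon, _aa in CODON_TABLE.items():
    if _aa != "*" and _aa not in PREFERRED_CODON:
        PREFERRED_CODON[_aa] = _codon

_HYDROPHOBIC_POOL = "GLAIVFSTWPNQ"
_ACIDIC_POOL = "DEASLQ"


class GenerationError(RuntimeError):
    """Raised for infeasible generator specs."""


@dataclass(frozen=True)
class FamilySpec:
    n_loci: int = 10
    signal_consensus: str = (
        "TTCACCTTGAAGAAATCTCTGTTGCTCCTGTTCTTCCTGGGGACCATCAACTTATCTCTC"
    )
    signal_mutation_rate: float = 0.02
    propeptide_length: int = 18
    mature_length_range: tuple[int, int] = (14, 24)
    mature_charge_target: int = 3
    ranabox_probability: float = 0.3
    amidation_probability: float = 0.3
    utr3_length_range: tuple[int, int] = (60, 180)
    polya_length: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.utr3_length_range[1] > 200:
            raise ValueError("3' UTR must stay below 200 nt")
        for p in (self.signal_mutation_rate, self.ranabox_probability,
                  self.amidation_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.signal_consensus) % 3 != 0:
            raise ValueError("signal consensus must be whole codons")


@dataclass(frozen=True)
class ReadSimSpec:
    coverage: int = 50
    read_length_mean: int = 330
    read_length_sd: int = 60
    max_read_length: int = 450
    min_read_length: int = 60
    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.005
    barcode: str = "CTAAGGTAAC"
    forward_tail: str = "CAGGACCAGGGTACGGTG"
    reverse_tail: str = "CCTCTCTATGGGCAGTCGGTGAT"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.max_read_length > 450:
            raise ValueError("read length cap exceeds the 450 nt platform limit")


@dataclass(frozen=True)
class TruthRecord:
    locus_id: str
    transcript: NucSeq
    precursor_protein: PepSeq
    mature: PepSeq          # processed form (amidation resolved)
    mature_raw: str         # as encoded, before amidation stripping
    amidated: bool
    ranabox: bool
    signal_protein: str
    propeptide: str


def _encode(peptide: str) -> str:
    return "".join(PREFERRED_CODON[a] for a in peptide)


def _mutate_signal(consensus: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate the signal coding region, synonymously where possible so the
    conserved protein stays recognizable."""
    bases = list(consensus)
    for i in range(len(bases)):
        if rng.random() < rate:
            # prefer third codon positions (more often synonymous)
            pos = (i // 3) * 3 + 2
            choices = [b for b in "ACGT" if b != bases[pos]]
            bases[pos] = choices[rng.integers(len(choices))]
    return "".join(bases)


def _make_mature(
    length: int,
    charge_target: int,
    ranabox: bool,
    amidate: bool,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """(mature processed form, raw encoded form). Charge target is met by K/R
    placement; the rana-box reserves the C-terminal 7 residues."""
    n_basic = charge_target - 1
    reserved = 7 if ranabox else 0
    if n_basic < 0 or length < n_basic + reserved + 2:
        raise GenerationError(
            f"mature length {length} cannot carry charge {charge_target:+d}"
            + (" with a rana-box" if ranabox else "")
        )
    for _ in range(200):
        body_len = length - reserved
        body = [str(_HYDROPHOBIC_POOL[rng.integers(len(_HYDROPHOBIC_POOL))])
                for _ in range(body_len)]
        free = body_len - (1 if ranabox else 0)
        n_body_basic = n_basic - (1 if ranabox else 0)
        if n_body_basic < 0:
            n_body_basic = 0
        positions = rng.choice(free, size=min(n_body_basic, free), replace=False)
        for p in positions:
            body[int(p)] = "K" if rng.random() < 0.5 else "R"
        pep = "".join(body)
        if ranabox:
            # C . . K . . C with hydrophobic filler
            fill = [str(_HYDROPHOBIC_POOL[rng.integers(len(_HYDROPHOBIC_POOL))])
                    for _ in range(4)]
            pep = pep + "C" + fill[0] + fill[1] + "K" + fill[2] + fill[3] + "C"
        pep = pep[:length]
        raw = pep + ("G" + ("K" if rng.random() < 0.5 else "R") if amidate else "")
        if "KR" in raw:
            continue  # would confuse the cleavage-site caller
        if net_charge(pep) != charge_target:
            continue
        return pep, raw
    raise GenerationError("could not satisfy mature-peptide constraints")


def _make_propeptide(length: int, rng: np.random.Generator) -> str:
    """Acidic spacer: guaranteed net charge < 0, no K/R."""
    if length < 3:
        raise GenerationError("propeptide too short")
    for _ in range(100):
        pep = "".join(
            str(_ACIDIC_POOL[rng.integers(len(_ACIDIC_POOL))]) for _ in range(length - 1)
        )
        # anchor enough D/E to force negativity
        n_acidic = pep.count("D") + pep.count("E")
        if n_acidic < 2:
            continue
        return pep + "E"
    raise GenerationError("could not build an acidic propeptide")


def generate_family(spec: FamilySpec) -> tuple[list[NucSeq], list[TruthRecord]]:
    """Generate ``n_loci`` precursor transcripts plus their truth manifest.

    Deterministic for a fixed spec (byte-identical FASTA across runs).
    """
    rng = np.random.default_rng(spec.seed)
    transcripts: list[NucSeq] = []
    manifest: list[TruthRecord] = []
    for locus in range(spec.n_loci):
        locus_id = f"locus_{locus + 1:03d}"
        signal_nt = _mutate_signal(spec.signal_consensus, spec.signal_mutation_rate, rng)
        signal_prot = translate(signal_nt)
        if "*" in signal_prot:
            signal_nt = spec.signal_consensus  # mutation hit a stop; fall back
            signal_prot = translate(signal_nt)
        pro = _make_propeptide(spec.propeptide_length, rng)
        lo, hi = spec.mature_length_range
        mlen = int(rng.integers(lo, hi + 1))
        ranabox = bool(rng.random() < spec.ranabox_probability)
        amidate = bool(rng.random() < spec.amidation_probability)
        mature, mature_raw = _make_mature(
            mlen, spec.mature_charge_target, ranabox, amidate, rng
        )
        coding = (
            "ATG" + signal_nt + _encode(pro) + "AAACGT" + _encode(mature_raw) + "TAA"
        )
        utr_len = int(rng.integers(spec.utr3_length_range[0], spec.utr3_length_range[1] + 1))
        utr = "".join("ACGT"[rng.integers(4)] for _ in range(utr_len))
        transcript = NucSeq(locus_id, coding + utr + "A" * spec.polya_length)
        protein = PepSeq(locus_id + "|precursor",
                         "M" + signal_prot + pro + "KR" + mature_raw)
        processed = resolve_amidation(PepSeq(locus_id + "|mature", mature_raw))
        transcripts.append(transcript)
        manifest.append(
            TruthRecord(
                locus_id=locus_id,
                transcript=transcript,
                precursor_protein=protein,
                mature=processed,
                mature_raw=mature_raw,
                amidated=processed.amidated,
                ranabox=ranabox,
                signal_protein="M" + signal_prot,
                propeptide=pro,
            )
        )
    return transcripts, manifest


_HOMOPOLYMER_MIN = 2


def _apply_errors(bases: str, spec: ReadSimSpec, rng: np.random.Generator) -> str:
    out = []
    i = 0
    n = len(bases)
    while i < n:
        b = bases[i]
        # homopolymer length +/- 1 errors at runs of >= _HOMOPOLYMER_MIN
        j = i
        while j < n and bases[j] == b:
            j += 1
        run = j - i
        emitted = run
        if run >= _HOMOPOLYMER_MIN and rng.random() < spec.homopolymer_indel_rate * run:
            emitted = run + (1 if rng.random() < 0.5 else -1)
        for _ in range(emitted):
            if rng.random() < spec.substitution_rate:
                choices = [c for c in "ACGT" if c != b]
                out.append(choices[rng.integers(3)])
            else:
                out.append(b)
        i = j
    return "".join(out)


def _quality_profile(length: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Simple decreasing-quality model: high 5' quality decaying 3'-ward."""
    pos = np.arange(length)
    mean = 36.0 - 12.0 * pos / max(length, 1)
    quals = np.clip(np.rint(mean + rng.normal(0, 2, size=length)), 2, 40)
    return tuple(int(q) for q in quals)


def simulate_reads(
    transcripts: list[NucSeq],
    panel: list[DegeneratePrimer],
    spec: ReadSimSpec,
    max_mismatches: int = 2,
) -> tuple[list[QualRead], dict[str, str]]:
    """Simulate amplicon reads; returns (reads, amplicon-per-locus map).

    Library layout per read: barcode + forward tail + template from the
    primer binding site through the poly-A + reverse-complemented reverse
    tail. Reads are 5' prefixes of the amplicon with substitution and
    homopolymer-indel errors; templates lacking a binding site are omitted
    with a log entry. Deterministic under the spec seed.
    """
    from .seqcore import reverse_complement

    rng = np.random.default_rng(spec.seed)
    amplicons: dict[str, str] = {}
    for tpl in transcripts:
        best = None
        for primer in panel:
            hit = find_binding_site(tpl.bases, primer.specific_part.bases, max_mismatches)
            if hit and (best is None or hit[1] < best[1]):
                best = hit
        if best is None:
            logger.info("template %s has no primer binding site; omitted", tpl.id)
            continue
        start, _ = best
        amplicons[tpl.id] = (
            spec.barcode
            + spec.forward_tail
            + tpl.bases[start:]
            + reverse_complement(spec.reverse_tail)
        )
    reads: list[QualRead] = []
    counter = 0
    for locus_id, amplicon in amplicons.items():
        for _ in range(spec.coverage):
            counter += 1
            length = int(
                np.clip(
                    rng.normal(spec.read_length_mean, spec.read_length_sd),
                    spec.min_read_length,
                    spec.max_read_length,
                )
            )
            raw = amplicon[:length]
            seq = _apply_errors(raw, spec, rng)
            seq = seq[: spec.max_read_length]
            quals = _quality_profile(len(seq), rng)
            reads.append(QualRead(f"read_{counter:05d}|{locus_id}", seq, quals))
    return reads, amplicons
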