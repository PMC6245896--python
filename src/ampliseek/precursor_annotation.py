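"""AMP precursor annotation.

Splits a precursor protein into signal / acidic propeptide / mature peptide
at the dibasic Lys-Arg processing site, resolves C-terminal amidation,
detects the rana-box loop, assigns feature-based classes and novelty tiers
against the known-AMP database.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

from .homology_screen import SearchHit
from .physchem import CCS_SCALE, HydroScale, mean_hydrophobicity, net_charge
from .seqcore import Orf, PepSeq

__all__ = [
    "PrecursorAnnotation",
    "NoveltyTier",
    "Tier",
    "ClassAssignment",
    "ClassRule",
    "DEFAULT_CLASS_RULES",
    "split_precursor",
    "resolve_amidation",
    "detect_ranabox",
    "assign_novelty",
    "classify",
    "peptide_features",
]

logger = logging.getLogger(__name__)

#: Pace-Scholtz alpha-helix propensities (kcal/mol relative to Ala; lower =
#: stronger helix former). Used only as a crude secondary-structure feature.
HELIX_PROPENSITY = {
    "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
    "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
    "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
    "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.00, "P": 3.16,
}


class Tier(str, Enum):
    KNOWN_IDENTICAL = "known_identical"
    SIMILAR_81_99 = "similar_81_99"
    BELOW_80 = "below_80"
    NOVEL_NO_HIT = "novel_no_hit"
    IDENTICAL_LOW_COVER = "identical_low_cover"


@dataclass(frozen=True)
class NoveltyTier:
    tier: Tier
    supporting_hit: SearchHit | None = None


@dataclass
class PrecursorAnnotation:
    """A precursor ORF split into its three architectural segments.

    ``signal + propeptide + 'KR' + mature_raw`` reconstitutes the ORF protein
    (mature_raw = mature with any stripped amidation suffix restored).
    """

    orf: Orf | None
    protein: PepSeq
    signal: PepSeq
    propeptide: PepSeq
    mature: PepSeq
    cleavage_site: int  # residue index of the K of the processing K-R
    stripped_suffix: str = ""
    no_cleavage_site: bool = False

    @property
    def mature_raw(self) -> str:
        return self.mature.sequence + self.stripped_suffix

    def reconstruct(self) -> str:
        if self.no_cleavage_site:
            return self.protein.sequence
        return (
            self.signal.sequence
            + self.propeptide.sequence
            + "KR"
            + self.mature_raw
        )


def resolve_amidation(mature_raw: PepSeq) -> PepSeq:
    """Strip a C-terminal amidation signal (G followed by zero or more K/R)
    and flag the preceding residue as amidated.

    Already-amidated peptides pass through unchanged (idempotence). Sequences
    reduced to nothing by stripping are returned unchanged.
    """
    if mature_raw.amidated:
        return mature_raw
    seq = mature_raw.sequence
    m = re.search(r"G[KR]*$", seq)
    if m is None or m.start() == 0:
        return PepSeq(mature_raw.id, seq, amidated=False)
    return PepSeq(mature_raw.id, seq[: m.start()], amidated=True)


def split_precursor(
    protein: PepSeq,
    signal_length: int = 22,
    strip_amidation: bool = False,
    site_choice: str = "last",
    accept_dibasic: tuple[str, ...] = ("KR",),
) -> PrecursorAnnotation:
    """Split a precursor at the dibasic cleavage site.

    The site is the last (or first, per ``site_choice``) occurrence of an
    accepted dibasic motif whose downstream segment has non-negative net
    charge; when no occurrence qualifies the last occurrence is used with a
    warning. No motif at all yields a flagged annotation with empty mature.

    Amidation stripping is opt-in: published mature tables list both the
    raw (G/GK-terminal) and the processed (-NH2) forms, so the
    transformation is explicit and flagged, never silent.
    """
    seq = protein.sequence
    sites = []
    for motif in accept_dibasic:
        sites.extend(m.start() for m in re.finditer(f"(?={motif})", seq))
    sites.sort()
    if not sites:
        logger.debug("%s: no dibasic cleavage motif found", protein.id)
        return PrecursorAnnotation(
            orf=None,
            protein=protein,
            signal=PepSeq(protein.id + "|signal", seq[:signal_length] or "X"),
            propeptide=PepSeq(protein.id + "|pro", seq[signal_length:] or "X"),
            mature=PepSeq(protein.id + "|mature", "X"),
            cleavage_site=-1,
            no_cleavage_site=True,
        )
    qualifying = [s for s in sites if net_charge(seq[s + 2 :] or "G") >= 0 and s + 2 < len(seq)]
    if qualifying:
        site = qualifying[-1] if site_choice == "last" else qualifying[0]
    else:
        site = sites[-1] if site_choice == "last" else sites[0]
        logger.debug("%s: no cleavage site with cationic downstream; using fallback",
                     protein.id)
    mature_raw = seq[site + 2 :]
    mature = PepSeq(protein.id + "|mature", mature_raw or "X")
    stripped = ""
    if strip_amidation and mature_raw:
        resolved = resolve_amidation(mature)
        stripped = mature_raw[len(resolved.sequence) :]
        mature = resolved
    sig_len = min(signal_length, site)
    annotation = PrecursorAnnotation(
        orf=None,
        protein=protein,
        signal=PepSeq(protein.id + "|signal", seq[:sig_len] or "X"),
        propeptide=PepSeq(protein.id + "|pro", seq[sig_len:site] or "X"),
        mature=mature,
        cleavage_site=site,
        stripped_suffix=stripped,
        no_cleavage_site=not mature_raw,
    )
    if not annotation.no_cleavage_site:
        pro = annotation.propeptide.sequence
        if pro != "X" and net_charge(pro) > 0:
            logger.warning("%s: propeptide has positive net charge", protein.id)
    return annotation


def detect_ranabox(
    mature: PepSeq, tail_window: int = 10, loop_min: int = 3, loop_max: int = 5
) -> tuple[bool, tuple[int, int] | None]:
    """Detect the rana-box: two Cys 3-5 residues apart within the C-terminal
    window, with at least one K/R inside the loop. Returns (flag, (c1, c2))."""
    seq = mature.sequence
    tail_start = max(0, len(seq) - tail_window)
    cys = [i for i in range(tail_start, len(seq)) if seq[i] == "C"]
    for i, c1 in enumerate(cys):
        for c2 in cys[i + 1 :]:
            gap = c2 - c1 - 1
            if loop_min <= gap <= loop_max:
                loop = seq[c1 + 1 : c2]
                if any(a in "KR" for a in loop):
                    return True, (c1, c2)
    return False, None


def assign_novelty(
    peptide: PepSeq,
    hits: list[SearchHit],
    alpha: float = 0.05,
    cover_novel: float = 70.0,
) -> NoveltyTier:
    """Assign one of the five novelty tiers from pre-filtered hits.

    Identity is banded on the integer rounded half away from zero:
    >=100 identical (split by query coverage at ``cover_novel``), 81-99
    similar, <=80 below-80. No hit below ``alpha`` means entirely novel.
    """
    significant = [h for h in hits if h.evalue < alpha]
    if not significant:
        return NoveltyTier(Tier.NOVEL_NO_HIT, None)
    best = min(significant, key=lambda h: (h.evalue, -h.identity))
    ident = _round_half_away(best.identity)
    if ident >= 100:
        if best.coverage < cover_novel:
            return NoveltyTier(Tier.IDENTICAL_LOW_COVER, best)
        return NoveltyTier(Tier.KNOWN_IDENTICAL, best)
    if ident >= 81:
        return NoveltyTier(Tier.SIMILAR_81_99, best)
    return NoveltyTier(Tier.BELOW_80, best)


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Feature-based classification


@dataclass(frozen=True)
class ClassRule:
    """One configurable classification rule; all set bounds must hold."""

    label: int
    name: str
    min_length: int | None = None
    max_length: int | None = None
    min_charge: int | None = None
    max_charge: int | None = None
    min_hydrophobicity: float | None = None
    max_hydrophobicity: float | None = None
    min_cys: int | None = None
    max_cys: int | None = None
    ranabox: bool | None = None
    amidated: bool | None = None
    max_helix_propensity: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.label <= 8:
            raise ValueError("class label must be 1-8")

    def matches(self, f: dict) -> bool:
        checks = (
            (self.min_length, f["length"] >= (self.min_length or 0)),
            (self.max_length, f["length"] <= (self.max_length or 0)),
            (self.min_charge, f["net_charge"] >= (self.min_charge or 0)),
            (self.max_charge, f["net_charge"] <= (self.max_charge or 0)),
            (self.min_hydrophobicity, f["mean_hydrophobicity"] >= (self.min_hydrophobicity or 0)),
            (self.max_hydrophobicity, f["mean_hydrophobicity"] <= (self.max_hydrophobicity or 0)),
            (self.min_cys, f["cys_count"] >= (self.min_cys or 0)),
            (self.max_cys, f["cys_count"] <= (self.max_cys or 0)),
            (self.ranabox, f["ranabox"] == self.ranabox),
            (self.amidated, f["amidated"] == self.amidated),
            (self.max_helix_propensity, f["helix_propensity"] <= (self.max_helix_propensity or 0)),
        )
        return all(ok for bound, ok in checks if bound is not None)


@dataclass(frozen=True)
class ClassAssignment:
    label: int
    rule_name: str
    features: dict


#: Reconstruction of the eight-group scheme as explicit feature rules; the
#: original grouping was manual, so these defaults are replaceable config.
DEFAULT_CLASS_RULES: tuple[ClassRule, ...] = (
    ClassRule(1, "ranabox", ranabox=True),
    ClassRule(2, "cys_pair_no_box", min_cys=2, ranabox=False),
    ClassRule(3, "short_helical_cationic", max_length=16, min_charge=2,
              min_hydrophobicity=0.0, max_helix_propensity=0.55, max_cys=0),
    ClassRule(4, "long_helical_cationic", min_length=17, min_charge=2,
              min_hydrophobicity=0.0, max_cys=0),
    ClassRule(5, "amidated_short", amidated=True, max_length=20),
    ClassRule(6, "anionic_or_neutral", max_charge=1, max_cys=1),
    ClassRule(7, "hydrophilic_cationic", min_charge=2, max_hydrophobicity=0.0),
)


def peptide_features(mature: PepSeq, scale: HydroScale = CCS_SCALE) -> dict:
    """Feature vector used by the rule-based classifier."""
    seq = mature.sequence
    box, _ = detect_ranabox(mature)
    return {
        "length": len(seq),
        "net_charge": net_charge(seq),
        "mean_hydrophobicity": mean_hydrophobicity(seq, scale),
        "cys_count": seq.count("C"),
        "ranabox": box,
        "amidated": mature.amidated,
        "helix_propensity": sum(HELIX_PROPENSITY.get(a, 0.65) for a in seq) / len(seq),
    }


def classify(
    mature: PepSeq,
    rules: tuple[ClassRule, ...] = DEFAULT_CLASS_RULES,
    scale: HydroScale = CCS_SCALE,
) -> ClassAssignment:
    """First matching rule wins; class 8 is the unconditional fallback."""
    for rule in rules:
        if rule.label == 8:
            raise ValueError("class 8 is reserved for the fallback")
    features = peptide_features(mature, scale)
    for rule in rules:
        if rule.matches(features):
            return ClassAssignment(rule.label, rule.name, features)
    return ClassAssignment(8, "unclassified", features)
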