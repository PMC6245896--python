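"""Physicochemical descriptors of mature peptides: net charge, mean
hydrophobicity and average molecular weight with amidation correction."""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import AA_ALPHABET, AlphabetError, PepSeq

__all__ = [
    "HydroScale",
    "PhyschemProfile",
    "CCS_SCALE",
    "KYTE_DOOLITTLE",
    "net_charge",
    "net_charge_hh",
    "mean_hydrophobicity",
    "molecular_weight",
    "profile_peptide",
]


@dataclass(frozen=True)
class HydroScale:
    """A per-residue hydrophobicity scale covering the 20 standard residues."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = AA_ALPHABET - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise AlphabetError(
                f"residue {residue!r} not covered by scale {self.name!r}"
            ) from None


#: Consensus hydrophobicity scale used for the H descriptor.
CCS_SCALE = HydroScale(
    "CCS",
    {
        "A": -1.1, "C": -2.3, "D": -8.3, "E": -8.3, "F": 10.0,
        "G": -2.4, "H": -3.8, "I": 8.7, "K": -9.9, "L": 9.7,
        "M": 4.6, "N": -7.1, "P": -0.2, "Q": -6.0, "R": -10.0,
        "S": -4.3, "T": -3.8, "V": 4.1, "W": 9.7, "Y": 2.5,
    },
)

#: Kyte-Doolittle scale, shipped as an alternative.
KYTE_DOOLITTLE = HydroScale(
    "Kyte-Doolittle",
    {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
        "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
        "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
        "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
    },
)

#: Average (isotope-weighted) residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.015
#: OH -> NH2 mass shift for C-terminal amidation.
AMIDATION_SHIFT = -0.984

# Henderson-Hasselbalch side-chain / termini pKa values (non-default convention).
_PKA_POS = {"K": 10.5, "R": 12.5, "H": 6.0}
_PKA_NEG = {"D": 3.9, "E": 4.1, "C": 8.3, "Y": 10.1}
_PKA_NTERM = 9.0
_PKA_CTERM = 2.0


@dataclass(frozen=True)
class PhyschemProfile:
    """Bundle of the three descriptors for one mature peptide."""

    net_charge: int
    mean_hydrophobicity: float
    molecular_weight: float
    length: int
    amidated: bool

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.length < 1:
            raise ValueError("length must be >= 1")


def _residues(peptide: PepSeq | str) -> str:
    seq = peptide.sequence if isinstance(peptide, PepSeq) else peptide.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid residue(s) {sorted(bad)}")
    if not seq:
        raise ValueError("empty peptide")
    return seq


def net_charge(peptide: PepSeq | str) -> int:
    """Net formal charge: (#Lys + #Arg) - (#Asp + #Glu) + 1 for the free
    N-terminal amine. His, Cys and the C-terminus contribute nothing."""
    seq = _residues(peptide)
    return seq.count("K") + seq.count("R") - seq.count("D") - seq.count("E") + 1


def net_charge_hh(peptide: PepSeq | str, ph: float = 7.0, amidated: bool = False) -> float:
    """Henderson-Hasselbalch net charge at the given pH (alternative convention)."""
    seq = _residues(peptide)
    pos = sum(1.0 / (1.0 + 10 ** (ph - _PKA_POS[a])) for a in seq if a in _PKA_POS)
    neg = sum(1.0 / (1.0 + 10 ** (_PKA_NEG[a] - ph)) for a in seq if a in _PKA_NEG)
    pos += 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
    if not amidated:
        neg += 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    return pos - neg


def mean_hydrophobicity(peptide: PepSeq | str, scale: HydroScale = CCS_SCALE) -> float:
    """Arithmetic mean of per-residue scale values."""
    seq = _residues(peptide)
    return sum(scale[a] for a in seq) / len(seq)


def molecular_weight(peptide: PepSeq | str, amidated: bool | None = None) -> float:
    """Average molecular weight in Da.

    Amidated peptides get the OH->NH2 correction. When ``amidated`` is None
    the flag is taken from the PepSeq (False for bare strings).
    """
    seq = _residues(peptide)
    if amidated is None:
        amidated = peptide.amidated if isinstance(peptide, PepSeq) else False
    mass = sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS
    if amidated:
        mass += AMIDATION_SHIFT
    return mass


def profile_peptide(peptide: PepSeq | str, scale: HydroScale = CCS_SCALE) -> PhyschemProfile:
    """Compute all three descriptors for a peptide."""
    seq = _residues(peptide)
    amidated = peptide.amidated if isinstance(peptide, PepSeq) else False
    return PhyschemProfile(
        net_charge=net_charge(seq),
        mean_hydrophobicity=mean_hydrophobicity(seq, scale),
        molecular_weight=molecular_weight(seq, amidated=amidated),
        length=len(seq),
        amidated=amidated,
    )
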