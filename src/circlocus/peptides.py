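"""In-silico trypsin digestion and PRM inclusion-mass prediction.

Discriminative tryptic peptides are those unique to the circle-specific
translation product relative to the linear proteome; their monoisotopic
[M+nH]n+ values make up a parallel-reaction-monitoring inclusion list.
Masses use the standard monoisotopic residue table; an inclusion list for
synthetic (unmodified) peptides is computed without fixed modifications —
carbamidomethyl-Cys and Met oxidation are available as named modifications
for database-search-style masses.
"""

from __future__ import annotations

from dataclasses import dataclass

WATER = 18.010565
PROTON = 1.007276

# monoisotopic residue (amino-acid minus water) masses, Da
RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

NAMED_MODS = {
    "carbamidomethyl": 57.021464,
    "oxidation": 15.994915,
}


@dataclass(frozen=True)
class DigestParams:
    max_missed_cleavages: int = 0
    min_length: int = 1
    proline_rule: bool = True

    def __post_init__(self):
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    start: int               # 0-based position in the parent protein
    missed_cleavages: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def _check_residues(protein: str) -> str:
    protein = protein.upper().rstrip("*")
    for i, aa in enumerate(protein):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"non-standard residue {aa!r} at position {i}")
    return protein


def trypsin_digest(protein: str, params: DigestParams | None = None) -> list[TrypticPeptide]:
    """Tryptic peptides: cleavage C-terminal to K/R, suppressed before P.

    Enumerates all peptides with up to ``max_missed_cleavages`` retained
    internal sites, ordered N->C then by missed-cleavage count. The protein
    C terminus is a valid peptide C terminus (a C-terminal peptide need not
    end in K/R).
    """
    p = params or DigestParams()
    protein = _check_residues(protein)
    if not protein:
        raise ValueError("empty protein")
    cuts = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and not (p.proline_rule and protein[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(protein))
    out = []
    for a in range(len(cuts) - 1):
        for missed in range(p.max_missed_cleavages + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            seq = protein[cuts[a]:cuts[b]]
            if len(seq) >= p.min_length:
                out.append(TrypticPeptide(seq, cuts[a], missed))
    out.sort(key=lambda t: (t.start, t.missed_cleavages))
    return out


def discriminative_peptides(circ_peptide: str, linear_proteins: dict[str, str] | list[str],
                            params: DigestParams | None = None) -> list[TrypticPeptide]:
    """Tryptic peptides of the circle-specific product absent from every
    linear protein's digest (same parameters) — the PRM candidates."""
    if not circ_peptide:
        raise ValueError("empty circle-specific peptide")
    p = params or DigestParams()
    proteins = (list(linear_proteins.values())
                if isinstance(linear_proteins, dict) else list(linear_proteins))
    background = set()
    for prot in proteins:
        background.update(t.sequence for t in trypsin_digest(prot, p))
    return [t for t in trypsin_digest(circ_peptide, p) if t.sequence not in background]


Modification = tuple[int | None, "float | str"]


def _mod_delta(mod: Modification, peptide: str) -> float:
    pos, delta = mod
    if pos is not None and not (0 <= pos < len(peptide)):
        raise ValueError(f"modification position {pos} outside peptide")
    if isinstance(delta, str):
        try:
            return NAMED_MODS[delta.lower()]
        except KeyError:
            raise ValueError(f"unknown modification {delta!r}") from None
    return float(delta)


def monoisotopic_mass(peptide: str, modifications: list[Modification] = ()) -> float:
    """Neutral monoisotopic mass: sum of residue masses + water + mod deltas."""
    peptide = _check_residues(peptide)
    mass = sum(RESIDUE_MASS[aa] for aa in peptide) + WATER
    return mass + sum(_mod_delta(m, peptide) for m in modifications)


def mz(peptide: str, charge: int, modifications: list[Modification] = ()) -> float:
    """[M+nH]n+ of a peptide, reported to 5 decimals (PRM inclusion style)."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    m = monoisotopic_mass(peptide, modifications)
    return round((m + charge * PROTON) / charge, 5)


def feasible_charges(peptide: str, scan_range: tuple[float, float] = (350.0, 1500.0),
                     max_charge: int = 6,
                     modifications: list[Modification] = ()) -> list[int]:
    """Charge states 1..max_charge whose m/z falls inside the MS1 scan range."""
    lo, hi = scan_range
    if not lo < hi:
        raise ValueError("scan range low must be below high")
    return [z for z in range(1, max_charge + 1)
            if lo <= mz(peptide, z, modifications) <= hi]


@dataclass(frozen=True)
class PeptideIon:
    sequence: str
    charge: int
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        _check_residues(self.sequence)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.sequence, list(self.modifications))

    @property
    def mz(self) -> float:
        return mz(self.sequence, self.charge, list(self.modifications))


def predict_charge(peptide: str) -> int:
    """Most likely ESI charge: one proton per basic residue (K/R) plus the
    N-terminal amine."""
    peptide = _check_residues(peptide)
    return 1 + sum(peptide.count(aa) for aa in "KR")


def prm_inclusion_list(peptides: list[str],
                       scan_range: tuple[float, float] = (350.0, 1500.0),
                       modifications: list[Modification] = ()) -> list[PeptideIon]:
    """One precursor ion per peptide for a PRM inclusion list.

    The charge is the predicted ESI charge (K/R count + 1); if that ion falls
    outside the MS1 scan range the nearest feasible charge is used instead.
    Peptides with no feasible charge are dropped.
    """
    ions = []
    for pep in peptides:
        charges = feasible_charges(pep, scan_range, modifications=modifications)
        if not charges:
            continue
        z = predict_charge(pep)
        if z not in charges:
            z = min(charges, key=lambda c: abs(c - z))
        ions.append(PeptideIon(pep, z, tuple(modifications)))
    return ions
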