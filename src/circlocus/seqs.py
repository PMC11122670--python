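"""Small nucleotide-sequence helpers shared across the package.

Everything here works on plain upper-case DNA strings; RNA input (U) is
normalised to DNA at the I/O boundary.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Seq import Seq

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware via Biopython)."""
    return str(Seq(seq).reverse_complement())


def normalize_nt(seq: str) -> str:
    """Upper-case and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC nucleotide motif to a lookahead regex.

    The lookahead makes overlapping occurrences visible, which matters for
    restriction sites like CTNAG that can overlap themselves.
    """
    if len(motif) < 2:
        raise ValueError("motif shorter than 2 nt is not a usable recognition site")
    parts = []
    for ch in motif.upper():
        try:
            opts = _IUPAC[ch]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {ch!r} in motif {motif!r}") from None
        parts.append(ch if len(opts) == 1 else "[" + opts + "]")
    return re.compile("(?=" + "".join(parts) + ")")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5,
               forbid: str | None = None) -> str:
    """Random DNA with the requested GC fraction.

    ``forbid`` is an optional substring (e.g. ``"AG"`` or ``"ATG"``) that the
    emitted sequence must not contain; enforced by per-base resampling so the
    stream stays deterministic for a fixed generator state.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if forbid is None:
        idx = rng.choice(4, size=length, p=p)
        return "".join(DNA[i] for i in idx)
    out: list[str] = []
    while len(out) < length:
        base = DNA[rng.choice(4, p=p)]
        out.append(base)
        k = len(forbid)
        if len(out) >= k and "".join(out[-k:]) == forbid:
            out.pop()
    return "".join(out)
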