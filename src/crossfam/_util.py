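"""Small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import reverse_complement as _bio_rc

# IUPAC nucleotide codes -> set of plain bases each code stands for.
# 'N' in a PAM pattern is a true wildcard and also accepts an ambiguous 'N'
# in the amplicon; every other code only accepts its literal expansion, so an
# amplicon 'N' never satisfies e.g. the 'G' of NGG.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N."""
    return _bio_rc(seq)


def matches_iupac(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position."""
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern, seq):
        if s not in IUPAC[p]:
            return False
    return True


def validate_pam_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if len(pattern) != 3 or any(c not in IUPAC for c in pattern):
        raise ValueError(f"PAM pattern must be a 3-letter IUPAC motif, got {pattern!r}")
    return pattern
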