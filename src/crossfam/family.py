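"""Gene-family definitions: amplicon references paired with designed guides.

A *gene family* here is the unit of a cross-reactivity analysis: a small set
of paralogous amplicons (PCR products of ~0.9-1.1 kb spanning each target
site), each with one designed 20-nt SpCas9 guide.  Everything downstream —
off-target candidate enumeration, configuration tables and activity
quantification — operates on the :class:`GeneFamily` loaded here.

Coordinate conventions used throughout the package:

* coordinates are 0-based, half-open, on the forward strand of the amplicon;
* a protospacer site is reported by the leftmost base of its 20-mer window
  on the forward strand, whatever its strand;
* strand ``+`` means the guide matches the forward strand with the PAM
  immediately 3' of it; ``-`` means the match lies on the reverse complement.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import matches_iupac, revcomp, validate_pam_pattern

logger = logging.getLogger(__name__)

GUIDE_LEN = 20
PAM_LEN = 3
GUIDE_ALPHABET = frozenset("ACGT")
AMPLICON_ALPHABET = frozenset("ACGTN")


class FamilyError(ValueError):
    """Invalid family definition (bad guide, missing amplicon, duplicates)."""


@dataclass(frozen=True)
class Guide:
    """A designed 20-nt spacer, written 5'->3' in protospacer orientation."""

    name: str
    sequence: str
    family_member: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != GUIDE_LEN:
            raise FamilyError(
                f"guide {self.name!r}: length {len(seq)}, must be exactly {GUIDE_LEN}"
            )
        bad = set(seq) - GUIDE_ALPHABET
        if bad:
            raise FamilyError(f"guide {self.name!r}: non-ACGT characters {sorted(bad)}")


@dataclass(frozen=True)
class Amplicon:
    """One amplicon reference sequence (uppercase, may contain N)."""

    name: str
    sequence: str
    family: str = ""

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < GUIDE_LEN + PAM_LEN:
            raise FamilyError(
                f"amplicon {self.name!r}: length {len(seq)} cannot host a "
                f"protospacer+PAM (needs >= {GUIDE_LEN + PAM_LEN})"
            )
        bad = set(seq) - AMPLICON_ALPHABET
        if bad:
            raise FamilyError(f"amplicon {self.name!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFamily:
    """Ordered pairing of amplicons with their designed guides (a bijection)."""

    name: str
    members: list[tuple[Amplicon, Guide]] = field(default_factory=list)

    def __post_init__(self):
        amp_names = [a.name for a, _ in self.members]
        guide_names = [g.name for _, g in self.members]
        if len(set(amp_names)) != len(amp_names):
            raise FamilyError(f"family {self.name!r}: duplicate amplicon names")
        if len(set(guide_names)) != len(guide_names):
            raise FamilyError(f"family {self.name!r}: duplicate guide names")
        for amp, g in self.members:
            if g.family_member != amp.name:
                raise FamilyError(
                    f"guide {g.name!r} is paired with amplicon {amp.name!r} but "
                    f"declares family_member {g.family_member!r}"
                )

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def amplicons(self) -> dict[str, Amplicon]:
        return {a.name: a for a, _ in self.members}

    @property
    def guides(self) -> dict[str, Guide]:
        return {g.name: g for _, g in self.members}

    def amplicon_of(self, guide_name: str) -> Amplicon:
        for amp, g in self.members:
            if g.name == guide_name:
                return amp
        raise KeyError(guide_name)


def load_family(
    fasta_path: str | Path,
    guide_table_path: str | Path,
    name: str | None = None,
) -> GeneFamily:
    """Load a gene family from an amplicon FASTA and a guide table CSV.

    The guide table must have a header with columns ``member,guide,amplicon``:
    one row per family member, pairing a named 20-nt guide with the amplicon
    record (by FASTA id) it was designed to cut.

    Raises :class:`FamilyError` on a missing amplicon, malformed guide, or
    duplicate names, naming the offending record.
    """
    fasta_path, guide_table_path = Path(fasta_path), Path(guide_table_path)
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise FamilyError(f"no FASTA records found in {fasta_path}")

    rows = []
    with open(guide_table_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"member", "guide", "amplicon"} - set(reader.fieldnames or [])
        if missing:
            raise FamilyError(f"guide table missing columns: {sorted(missing)}")
        rows = list(reader)
    if not rows:
        raise FamilyError(f"guide table {guide_table_path} has no data rows")

    members: list[tuple[Amplicon, Guide]] = []
    fam_name = name if name is not None else fasta_path.stem
    for row in rows:
        amp_name = row["amplicon"].strip()
        if amp_name not in records:
            raise FamilyError(
                f"amplicon {amp_name!r} named in guide table not present in {fasta_path}"
            )
        amp = Amplicon(name=amp_name, sequence=records[amp_name], family=fam_name)
        guide = Guide(name=row["member"].strip(), sequence=row["guide"].strip(),
                      family_member=amp_name)
        members.append((amp, guide))

    family = GeneFamily(name=fam_name, members=members)
    for amp, _ in family.members:
        logger.info("amplicon %s: %d bp", amp.name, len(amp))
    return family


def write_family(family: GeneFamily, fasta_path: str | Path, guide_table_path: str | Path) -> None:
    """Write a family back to FASTA + guide-table CSV (inverse of load_family)."""
    recs = [
        SeqRecord(Seq(a.sequence), id=a.name, description="")
        for a, _ in family.members
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    with open(guide_table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["member", "guide", "amplicon"])
        for amp, g in family.members:
            w.writerow([g.name, g.sequence, amp.name])


def find_on_target_hits(
    amplicon: Amplicon, guide: Guide, pam_pattern: str = "NGG"
) -> list[tuple[int, str, str]]:
    """Exact occurrences of guide+PAM in an amplicon, both strands.

    Returns ``(position, strand, pam)`` tuples where position is the leftmost
    forward-strand base of the 20-mer protospacer window.
    """
    pam_pattern = validate_pam_pattern(pam_pattern)
    seq = amplicon.sequence
    g = guide.sequence
    g_rc = revcomp(g)
    hits: list[tuple[int, str, str]] = []
    for p in range(len(seq) - GUIDE_LEN + 1):
        window = seq[p : p + GUIDE_LEN]
        # forward: guide then PAM immediately 3'
        if window == g and p + GUIDE_LEN + PAM_LEN <= len(seq):
            pam = seq[p + GUIDE_LEN : p + GUIDE_LEN + PAM_LEN]
            if matches_iupac(pam_pattern, pam):
                hits.append((p, "+", pam))
        # reverse: revcomp(PAM) immediately 5' of revcomp(guide)
        if window == g_rc and p - PAM_LEN >= 0:
            pam = revcomp(seq[p - PAM_LEN : p])
            if matches_iupac(pam_pattern, pam):
                hits.append((p, "-", pam))
    return hits


def validate_on_target(family: GeneFamily, pam_pattern: str = "NGG") -> list[dict]:
    """Locate each member's exact on-target site and flag anomalies.

    Returns one report row per hit (``member, position, strand, pam, n_hits``);
    a member with no exact hit yields a single row with position -1.  Zero or
    multiple hits raise warnings only — reference/allele mismatches should not
    abort an analysis.
    """
    report: list[dict] = []
    for amp, guide in family.members:
        hits = find_on_target_hits(amp, guide, pam_pattern)
        if len(hits) == 0:
            warnings.warn(
                f"guide {guide.name!r}: no exact on-target occurrence in {amp.name!r}",
                stacklevel=2,
            )
            report.append(
                {"member": guide.name, "position": -1, "strand": "", "pam": "",
                 "n_hits": 0}
            )
            continue
        if len(hits) > 1:
            warnings.warn(
                f"guide {guide.name!r}: {len(hits)} on-target occurrences in {amp.name!r}",
                stacklevel=2,
            )
        for pos, strand, pam in hits:
            report.append(
                {"member": guide.name, "position": pos, "strand": strand,
                 "pam": pam, "n_hits": len(hits)}
            )
    return report


def write_validation_report(report: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["member", "position", "strand", "pam", "n_hits"])
        w.writeheader()
        w.writerows(report)
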