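"""Enumeration of putative off-target sites within a gene family.

For a family with amplicons F1..Fn and guides g1..gn, every ordered pair
(i, j), j != i, gets a candidate list L(i, j): all PAM-adjacent 20-mers in
sibling amplicon Fj, kept when their pairwise alignment score against gi is
at least ``min_alignment_score`` and their Levenshtein distance from gi is at
most ``max_edit_distance``.  k(i, j) = |L(i, j)| and k_i = max_j k(i, j)
summarise how much cross-reactivity potential each guide has inside its own
family.

The scan is exhaustive and window-based: overlapping candidates are all kept,
and a sibling's own on-target site is a legitimate candidate (it can be
excluded with ``exclude_sibling_on_target`` when the analysis question calls
for it).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import edlib
from Bio import Align

from ._util import matches_iupac, revcomp, validate_pam_pattern
from .family import GUIDE_LEN, PAM_LEN, Amplicon, GeneFamily, Guide

GREEK = "αβγδεζηθικλμνξοπρστυφχψω"


@dataclass(frozen=True)
class ScoringParams:
    """Pairwise-alignment scoring used for the alignment-score filter.

    Defaults (match=1, mismatch=0, gaps free, global) score an alignment by
    its number of matched bases, so a perfect 20-mer scores 20 and the score
    equals the length of the longest common subsequence.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = 0.0
    gap_extend: float = 0.0
    mode: str = "global"

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mode not in ("global", "local"):
            raise ValueError(f"mode must be 'global' or 'local', got {self.mode!r}")


@lru_cache(maxsize=16)
def _aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = params.mode
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def alignment_score(candidate: str, guide: Guide | str, params: ScoringParams | None = None) -> float:
    """Optimal pairwise alignment score of a candidate 20-mer against a guide."""
    params = params or ScoringParams()
    guide_seq = guide.sequence if isinstance(guide, Guide) else guide
    if not candidate or not guide_seq:
        raise ValueError("cannot align an empty sequence")
    return float(_aligner(params).score(candidate.upper(), guide_seq.upper()))


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions, deletions).

    N is treated as an ordinary fifth symbol: it matches nothing but itself,
    so reference ambiguity counts as mismatch against any guide base.
    """
    if not a or not b:
        raise ValueError("edit_distance requires non-empty sequences")
    return edlib.align(a.upper(), b.upper(), mode="NW", task="distance")["editDistance"]


@dataclass(frozen=True)
class CandidateSite:
    """One PAM-adjacent 20-mer scored against a target guide.

    ``position`` is the leftmost forward-strand base of the 20-mer window;
    ``protospacer`` and ``pam`` are reported in guide orientation (minus-strand
    hits reverse-complemented).
    """

    target_guide: str
    host_amplicon: str
    position: int
    strand: str
    protospacer: str
    pam: str
    alignment_score: float
    edit_distance: int
    is_on_target: bool = False
    label: str = ""


@dataclass
class EnumerationResult:
    """The candidate lists L(i, j) with their counts and thresholds."""

    lists: dict[tuple[str, str], list[CandidateSite]]
    min_alignment_score: float
    max_edit_distance: int
    pam_pattern: str
    scoring: ScoringParams = field(default_factory=ScoringParams)

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        """k(i, j) = |L(i, j)|."""
        return {key: len(sites) for key, sites in self.lists.items()}

    @property
    def k_max(self) -> dict[str, int]:
        """k_i = max_j k(i, j)."""
        out: dict[str, int] = {}
        for (gi, _), sites in self.lists.items():
            out[gi] = max(out.get(gi, 0), len(sites))
        return out

    def sites_for(self, target_guide: str) -> list[CandidateSite]:
        return [
            s
            for (gi, _), sites in sorted(self.lists.items())
            for s in sites
            if gi == target_guide
        ]

    def all_sites(self) -> list[CandidateSite]:
        return [s for _, sites in sorted(self.lists.items()) for s in sites]


def scan_protospacers(
    amplicon: Amplicon | str, pam_pattern: str = "NGG"
) -> list[tuple[int, str, str, str]]:
    """All 20-mer windows with a PAM immediately 3' of them, on both strands.

    Returns ``(position, strand, protospacer, pam)`` sorted by (position,
    strand), protospacer and PAM in guide orientation.  On the forward strand
    the PAM occupies the 3 bases right of the window; a minus-strand hit
    appears on the forward strand as revcomp(PAM) immediately left of the
    window.
    """
    pam_pattern = validate_pam_pattern(pam_pattern)
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon.upper()
    hits: list[tuple[int, str, str, str]] = []
    n = len(seq)
    for p in range(n - GUIDE_LEN + 1):
        window = seq[p : p + GUIDE_LEN]
        if p + GUIDE_LEN + PAM_LEN <= n:
            pam = seq[p + GUIDE_LEN : p + GUIDE_LEN + PAM_LEN]
            if matches_iupac(pam_pattern, pam):
                hits.append((p, "+", window, pam))
        if p >= PAM_LEN:
            pam_rc = revcomp(seq[p - PAM_LEN : p])
            if matches_iupac(pam_pattern, pam_rc):
                hits.append((p, "-", revcomp(window), pam_rc))
    return hits


def _sort_key(site: CandidateSite):
    return (-site.alignment_score, site.edit_distance, site.position,
            0 if site.strand == "+" else 1)


def enumerate_offtargets(
    family: GeneFamily,
    min_alignment_score: float = 10.0,
    max_edit_distance: int = 12,
    pam_pattern: str = "NGG",
    params: ScoringParams | None = None,
    exclude_sibling_on_target: bool = False,
) -> EnumerationResult:
    """Build L(i, j) for every ordered guide/sibling-amplicon pair.

    Each list is sorted by (alignment score desc, edit distance asc, position
    asc, '+' before '-') so downstream selection and labelling are
    deterministic.  Default thresholds (score >= 10, ED <= 12) are permissive
    enough to admit the distant cross-reactive sites seen in real families
    (edit distances of 9-10 between paralog guides are common).
    """
    if family.n < 2:
        raise ValueError("cross-activity needs at least two members")
    params = params or ScoringParams()
    pam_pattern = validate_pam_pattern(pam_pattern)

    scan_cache = {
        amp.name: scan_protospacers(amp, pam_pattern) for amp, _ in family.members
    }
    # exact on-target windows of each amplicon's own guide (for optional exclusion)
    own_site: dict[str, set[tuple[int, str]]] = {}
    for amp, guide in family.members:
        own_site[amp.name] = {
            (pos, strand)
            for pos, strand, proto, _ in scan_cache[amp.name]
            if proto == guide.sequence
        }

    lists: dict[tuple[str, str], list[CandidateSite]] = {}
    for amp_i, guide_i in family.members:
        for amp_j, _guide_j in family.members:
            if amp_j.name == amp_i.name:
                continue
            sites: list[CandidateSite] = []
            for pos, strand, proto, pam in scan_cache[amp_j.name]:
                if exclude_sibling_on_target and (pos, strand) in own_site[amp_j.name]:
                    continue
                ed = edit_distance(proto, guide_i.sequence)
                if ed > max_edit_distance:
                    continue
                score = alignment_score(proto, guide_i, params)
                if score < min_alignment_score:
                    continue
                sites.append(
                    CandidateSite(
                        target_guide=guide_i.name,
                        host_amplicon=amp_j.name,
                        position=pos,
                        strand=strand,
                        protospacer=proto,
                        pam=pam,
                        alignment_score=score,
                        edit_distance=ed,
                        is_on_target=(amp_j.name == guide_i.family_member and ed == 0),
                    )
                )
            sites.sort(key=_sort_key)
            lists[(guide_i.name, amp_j.name)] = sites

    return EnumerationResult(
        lists=lists,
        min_alignment_score=min_alignment_score,
        max_edit_distance=max_edit_distance,
        pam_pattern=pam_pattern,
        scoring=params,
    )


def select_reported_sites(result: EnumerationResult, per_pair_limit: int) -> EnumerationResult:
    """Keep the top ``per_pair_limit`` sites of each L(i, j) and label them.

    Retained sites are labelled α, β, γ... in sort order, mirroring the
    convention used when a handful of candidate sites per sibling are carried
    into quantification.
    """
    if per_pair_limit < 1:
        raise ValueError("per_pair_limit must be >= 1")
    new_lists: dict[tuple[str, str], list[CandidateSite]] = {}
    for key, sites in result.lists.items():
        kept = []
        for rank, site in enumerate(sites[:per_pair_limit]):
            label = GREEK[rank] if rank < len(GREEK) else f"s{rank + 1}"
            kept.append(replace(site, label=label))
        new_lists[key] = kept
    return EnumerationResult(
        lists=new_lists,
        min_alignment_score=result.min_alignment_score,
        max_edit_distance=result.max_edit_distance,
        pam_pattern=result.pam_pattern,
        scoring=result.scoring,
    )


SITES_COLUMNS = [
    "target_guide", "host_amplicon", "position", "strand", "protospacer",
    "pam", "alignment_score", "edit_distance", "is_on_target", "label",
]


def write_sites_csv(result: EnumerationResult, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SITES_COLUMNS)
        for site in result.all_sites():
            w.writerow([
                site.target_guide, site.host_amplicon, site.position, site.strand,
                site.protospacer, site.pam, f"{site.alignment_score:g}",
                site.edit_distance, site.is_on_target, site.label,
            ])


def read_sites_csv(path: str | Path) -> list[CandidateSite]:
    sites: list[CandidateSite] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            sites.append(
                CandidateSite(
                    target_guide=row["target_guide"],
                    host_amplicon=row["host_amplicon"],
                    position=int(row["position"]),
                    strand=row["strand"],
                    protospacer=row["protospacer"],
                    pam=row["pam"],
                    alignment_score=float(row["alignment_score"]),
                    edit_distance=int(row["edit_distance"]),
                    is_on_target=row["is_on_target"] == "True",
                    label=row.get("label", ""),
                )
            )
    return sites
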