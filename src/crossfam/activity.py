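"""Editing-activity quantification from long amplicon reads.

The quantifier is deliberately simple and transparent: reads are assigned to
family amplicons by whole-read edit distance (long reads span the full
amplicon, so paralog assignment is unambiguous at realistic divergence), each
read is aligned to its reference, and a read counts as *edited* at a site
when the alignment shows an insertion or deletion overlapping a window around
the predicted Cas9 cut position.  Substitutions never count: NHEJ signatures
are indel-dominated, while long-read residual errors are not.

Per site and sample the result is an edited-read proportion with a Wilson
0.95 interval and a one-sided Fisher exact comparison against the mock
(no-nuclease) control.  Because any indel sequencing error inside the window
is also counted, the raw proportion carries a background term shared with the
mock; a background-corrected estimate (treatment rate minus mock rate,
rescaled) is therefore computed alongside whenever a mock is available.
"""

from __future__ import annotations

import csv
import gzip
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportion_confint

from ._util import revcomp
from .config import ConfigTable
from .enumeration import _aligner, ScoringParams
from .family import GeneFamily

logger = logging.getLogger(__name__)

#: blunt cut 3 nt 5' of the PAM: between protospacer positions 17 and 18
#: (1-based), i.e. forward-coordinate protospacer_start + 17 on '+'.
CUT_OFFSET = 17

#: affine scheme for the optional "affine" calling path; chosen to prefer one
#: contiguous indel at the cut site over scattered gaps.
AFFINE_CALL_PARAMS = ScoringParams(match=2.0, mismatch=-2.0, gap_open=-4.0, gap_extend=-1.0)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class SiteLocus:
    """A cut position inside an amplicon plus the calling window half-width."""

    amplicon_name: str
    cut_position: int
    window_halfwidth: int = 10

    def __post_init__(self):
        if self.cut_position < 0 or self.window_halfwidth < 0:
            raise QuantError("cut_position and window_halfwidth must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        """Half-open forward-strand interval the call inspects."""
        return (self.cut_position - self.window_halfwidth,
                self.cut_position + self.window_halfwidth)


@dataclass(frozen=True)
class ActivityEstimate:
    site_name: str
    sample: str
    n_reads: int
    n_edited: int
    n_discarded: int
    rate: float
    ci_low: float
    ci_high: float
    mock_rate: float
    significant_vs_mock: bool
    flags: frozenset[str]
    p_value: float = float("nan")
    corrected_rate: float = float("nan")
    corrected_ci_low: float = float("nan")
    corrected_ci_high: float = float("nan")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTQ, transparently handling gzip."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def load_sample_map(path: str | Path) -> tuple[dict[str, Path], str | None]:
    """Parse a ``sample,fastq_path,is_mock`` CSV; returns (paths, mock name)."""
    samples: dict[str, Path] = {}
    mock = None
    base = Path(path).parent
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            p = Path(row["fastq_path"])
            samples[row["sample"]] = p if p.is_absolute() else base / p
            if row.get("is_mock", "").strip().lower() in ("1", "true", "yes"):
                mock = row["sample"]
    return samples, mock


def locate_site(grna: str, amplicon_sequence: str) -> tuple[int, str, int]:
    """Find a recognition sequence in its amplicon and derive the cut position.

    Returns (position, strand, cut_position); the leftmost occurrence wins
    when the 20-mer appears more than once.
    """
    pos = amplicon_sequence.find(grna)
    if pos >= 0:
        return pos, "+", pos + CUT_OFFSET
    pos = amplicon_sequence.find(revcomp(grna))
    if pos >= 0:
        # guide-orientation index i sits at forward coordinate pos + 19 - i;
        # the blunt cut between indices 16|17 is the forward junction pos + 3.
        return pos, "-", pos + (20 - CUT_OFFSET)
    raise QuantError("recognition sequence not found in amplicon on either strand")


def config_loci(config: ConfigTable, window_halfwidth: int = 10) -> dict[str, SiteLocus]:
    """One SiteLocus per config row, keyed by site name."""
    loci: dict[str, SiteLocus] = {}
    for row in config.rows:
        _, _, cut = locate_site(row.grna, row.amplicon_sequence)
        loci[row.site_name] = SiteLocus(row.amplicon_name, cut, window_halfwidth)
    return loci


# ---------------------------------------------------------------------------
# read assignment


def assign_reads(
    reads: list[tuple[str, str]],
    references: GeneFamily | dict[str, str],
    max_assign_distance_frac: float = 0.3,
    min_length_frac: float = 0.5,
) -> tuple[dict[str, list[tuple[str, str]]], list[str]]:
    """Assign each read to the amplicon it most plausibly derives from.

    The read (or its reverse complement, whichever is closer) is compared
    against every reference by global edit distance; the smallest distance
    wins, ties broken by reference order.  Reads whose best distance exceeds
    ``max_assign_distance_frac`` x reference length, or shorter than
    ``min_length_frac`` x the shortest reference (fragments), are returned as
    unassigned.  Assigned reads are reoriented to the reference forward strand.
    """
    if isinstance(references, GeneFamily):
        refs = {a.name: a.sequence for a, _ in references.members}
    else:
        refs = dict(references)
    if not refs:
        raise QuantError("no reference amplicons to assign against")
    if not reads:
        raise QuantError("empty read set")

    min_len = min(len(s) for s in refs.values())
    assigned: dict[str, list[tuple[str, str]]] = {name: [] for name in refs}
    unassigned: list[str] = []
    ref_items = list(refs.items())
    for rid, seq in reads:
        if len(seq) < min_length_frac * min_len:
            unassigned.append(rid)
            continue
        rc = revcomp(seq)
        best = None  # (distance, name, oriented_seq, ref_len)
        for name, ref in ref_items:
            # a candidate only wins by strictly beating the current best, so
            # cap the banded alignment there (first ref wins ties)
            cap = int(max_assign_distance_frac * len(ref))
            if best is not None:
                cap = min(cap, best[0] - 1)
            if cap < 0:
                continue
            for oriented in (seq, rc):
                d = edlib.align(oriented, ref, mode="NW", task="distance", k=cap)["editDistance"]
                if d != -1 and (best is None or d < best[0]):
                    best = (d, name, oriented, len(ref))
                    cap = d - 1
                    if cap < 0:
                        break
        if best is None:
            unassigned.append(rid)
        else:
            _, name, oriented, _ = best
            assigned[name].append((rid, oriented))
    return assigned, unassigned


# ---------------------------------------------------------------------------
# edit calling


#: minimum exact-match run length treated as anchoring the read to the
#: reference; coverage is the ref span between the outermost anchors, so a
#: spurious few-base match at the end of a truncated read does not fake
#: coverage of the window.
ANCHOR_LEN = 15


def _gaps_unit(read: str, ref: str):
    """Gap intervals and anchored coverage from a unit-cost global alignment.

    Returns (insertions, deletions, coverage): insertion junctions as ref
    coordinates, deletions as half-open ref intervals, coverage as the ref
    span between the outermost match runs of >= ANCHOR_LEN bases (end gaps
    from truncated reads fall outside it).
    """
    cigar = edlib.align(read, ref, mode="NW", task="path")["cigar"]
    insertions: list[tuple[int, int]] = []   # (junction, length)
    deletions: list[tuple[int, int]] = []    # [start, end)
    cov_start = cov_end = None
    ref_pos = 0
    for count, op in _CIGAR_RE.findall(cigar):
        count = int(count)
        if op in "=XM":
            if op == "=" and count >= ANCHOR_LEN:
                if cov_start is None:
                    cov_start = ref_pos
                cov_end = ref_pos + count
            ref_pos += count
        elif op == "D":  # read missing bases relative to ref
            deletions.append((ref_pos, ref_pos + count))
            ref_pos += count
        elif op == "I":  # extra bases in read
            insertions.append((ref_pos, count))
    if cov_start is None:
        cov_start = cov_end = 0
    return insertions, deletions, (cov_start, cov_end)


def _gaps_affine(read: str, ref: str):
    """Same as :func:`_gaps_unit` but from an affine-gap optimal alignment."""
    aligner = _aligner(AFFINE_CALL_PARAMS)
    aln = aligner.align(ref, read)[0]
    ref_blocks, read_blocks = aln.aligned
    insertions: list[tuple[int, int]] = []
    deletions: list[tuple[int, int]] = []
    if len(ref_blocks) == 0:
        return insertions, deletions, (0, 0)
    for k in range(len(ref_blocks) - 1):
        t_end, t_next = ref_blocks[k][1], ref_blocks[k + 1][0]
        q_end, q_next = read_blocks[k][1], read_blocks[k + 1][0]
        if t_next > t_end:
            deletions.append((int(t_end), int(t_next)))
        if q_next > q_end:
            insertions.append((int(t_end), int(q_next - q_end)))
    anchors = [b for b in ref_blocks if b[1] - b[0] >= ANCHOR_LEN]
    if not anchors:
        return insertions, deletions, (0, 0)
    return insertions, deletions, (int(anchors[0][0]), int(anchors[-1][1]))


def _classify(insertions, deletions, coverage, locus: SiteLocus) -> str:
    w0, w1 = locus.window
    w0 = max(w0, 0)
    if not (coverage[0] <= w0 and coverage[1] >= w1):
        return "discarded"
    for start, end in deletions:
        if start < w1 and end > w0:
            return "edited"
    for junction, _length in insertions:
        if w0 <= junction <= w1:
            return "edited"
    return "unedited"


def call_edit(read: str, amplicon_sequence: str, locus: SiteLocus, method: str = "unit") -> str:
    """Classify one read at one locus as edited / unedited / discarded.

    ``method='unit'`` extracts gaps from a unit-cost (Levenshtein) global
    alignment; ``method='affine'`` uses an affine-gap optimal alignment that
    favours one contiguous indel.  Both agree on clean NHEJ indels; unit cost
    is orders of magnitude faster on kilobase reads and is the default.
    """
    gapper = {"unit": _gaps_unit, "affine": _gaps_affine}[method]
    return _classify(*gapper(read, amplicon_sequence), locus)


# ---------------------------------------------------------------------------
# estimation


def rate_flags(rate: float) -> frozenset[str]:
    flags = set()
    if rate < 0.01:
        flags.add("lt_1pct")
    if rate < 0.003:
        flags.add("lt_0.3pct")
    if rate < 0.001:
        flags.add("lt_0.1pct")
    if rate < 0.0001:
        flags.add("lt_0.01pct")
    return frozenset(flags)


def wilson_interval(count: int, nobs: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    # the exact bounds are 0 and 1 at the boundaries; clear numerical fuzz
    lo = 0.0 if count == 0 else min(max(float(lo), 0.0), 1.0)
    hi = 1.0 if count == nobs else min(max(float(hi), 0.0), 1.0)
    return lo, hi


def corrected_estimate(
    n_edited: int, n_reads: int, mock_edited: int, mock_reads: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Background-corrected activity: (p_t - p_m) / (1 - p_m), with a CI.

    The mock control measures the no-editing background call rate (indel
    sequencing errors inside the window).  Under independent background and
    editing, E[p_t] = r + p_m - r p_m, so this estimator is unbiased for the
    true edited fraction r.  The interval is a Newcombe hybrid score interval
    for p_t - p_m, rescaled by 1/(1 - p_m).  The point estimate is left
    unclipped (a small negative value is a downward background fluctuation);
    clipping at zero would bias replicate averages upward at the sub-percent
    rates this analysis cares about.
    """
    pt, pm = n_edited / n_reads, mock_edited / mock_reads
    l1, u1 = wilson_interval(n_edited, n_reads, alpha)
    l2, u2 = wilson_interval(mock_edited, mock_reads, alpha)
    d = pt - pm
    lo_d = d - np.sqrt((pt - l1) ** 2 + (u2 - pm) ** 2)
    hi_d = d + np.sqrt((u1 - pt) ** 2 + (pm - l2) ** 2)
    denom = max(1.0 - pm, 1e-12)

    def clamp(x: float) -> float:
        return float(min(max(x, -1.0), 1.0))

    return clamp(d / denom), clamp(lo_d / denom), clamp(hi_d / denom)


def estimate_activity(
    n_edited: int,
    n_reads: int,
    mock_edited: int = 0,
    mock_reads: int = 0,
    alpha: float = 0.05,
    site_name: str = "",
    sample: str = "",
    n_discarded: int = 0,
) -> ActivityEstimate:
    """Point rate, Wilson 0.95 interval and mock comparison for one site.

    The rate is the raw edited-read proportion n_edited / n_reads.  The mock
    comparison is a one-sided Fisher exact test (treatment > mock) at
    ``alpha``; with no mock (mock_reads == 0) it is reported non-significant.
    """
    if n_reads < 1:
        raise QuantError("n_reads must be >= 1")
    if not 0 <= n_edited <= n_reads:
        raise QuantError("need 0 <= n_edited <= n_reads")
    rate = n_edited / n_reads
    ci_low, ci_high = wilson_interval(n_edited, n_reads, alpha)
    mock_rate = mock_edited / mock_reads if mock_reads else float("nan")
    p_value = float("nan")
    significant = False
    corr = (float("nan"),) * 3
    if mock_reads:
        table = [[n_edited, n_reads - n_edited], [mock_edited, mock_reads - mock_edited]]
        _, p_value = fisher_exact(table, alternative="greater")
        significant = bool(p_value < alpha)
        corr = corrected_estimate(n_edited, n_reads, mock_edited, mock_reads, alpha)
    return ActivityEstimate(
        site_name=site_name,
        sample=sample,
        n_reads=n_reads,
        n_edited=n_edited,
        n_discarded=n_discarded,
        rate=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        mock_rate=mock_rate,
        significant_vs_mock=significant,
        flags=rate_flags(rate),
        p_value=float(p_value) if p_value == p_value else p_value,
        corrected_rate=corr[0],
        corrected_ci_low=corr[1],
        corrected_ci_high=corr[2],
    )


def benjamini_hochberg(estimates: list[ActivityEstimate], alpha: float = 0.05) -> list[ActivityEstimate]:
    """Recompute significance flags with BH FDR control across estimates."""
    from dataclasses import replace

    from statsmodels.stats.multitest import multipletests

    testable = [i for i, e in enumerate(estimates) if e.p_value == e.p_value]
    if not testable:
        return list(estimates)
    reject, *_ = multipletests([estimates[i].p_value for i in testable],
                               alpha=alpha, method="fdr_bh")
    out = list(estimates)
    for i, rej in zip(testable, reject):
        out[i] = replace(out[i], significant_vs_mock=bool(rej))
    return out


# ---------------------------------------------------------------------------
# the full per-sample, per-site quantification


def _site_counts(
    assigned: dict[str, list[tuple[str, str]]],
    refs: dict[str, str],
    loci_by_amp: dict[str, list[tuple[str, SiteLocus]]],
    method: str,
) -> dict[str, list[int]]:
    """counts[site] = [n_edited, n_unedited, n_discarded] for one sample."""
    gapper = {"unit": _gaps_unit, "affine": _gaps_affine}[method]
    counts = {
        site: [0, 0, 0] for sites in loci_by_amp.values() for site, _ in sites
    }
    for amp_name, sites in loci_by_amp.items():
        ref = refs[amp_name]
        for _rid, seq in assigned.get(amp_name, []):
            gaps = gapper(seq, ref)
            for site, locus in sites:
                verdict = _classify(*gaps, locus)
                idx = {"edited": 0, "unedited": 1, "discarded": 2}[verdict]
                counts[site][idx] += 1
    return counts


def quantify(
    config: ConfigTable,
    reads_by_sample: dict[str, list[tuple[str, str]]],
    mock_sample: str | None = None,
    window_halfwidth: int = 10,
    max_assign_distance_frac: float = 0.3,
    alpha: float = 0.05,
    method: str = "unit",
    bh_correct: bool = False,
    references: dict[str, str] | None = None,
) -> list[ActivityEstimate]:
    """Quantify activity at every configured site in every sample.

    Emits one :class:`ActivityEstimate` per (site, sample) in config-row-major
    order.  When ``mock_sample`` names a sample in ``reads_by_sample``, each
    treatment estimate is compared against the mock's counts at the same
    locus; a missing mock downgrades to no-mock mode with a warning.
    ``references`` can supply extra amplicons for read assignment (e.g. the
    whole family when the config only covers part of it).
    """
    if not reads_by_sample:
        raise QuantError("no samples given")
    refs = {row.amplicon_name: row.amplicon_sequence for row in config.rows}
    if references:
        refs = {**references, **refs}
    loci = config_loci(config, window_halfwidth)
    loci_by_amp: dict[str, list[tuple[str, SiteLocus]]] = {}
    for row in config.rows:
        loci_by_amp.setdefault(row.amplicon_name, []).append((row.site_name, loci[row.site_name]))

    if mock_sample is not None and mock_sample not in reads_by_sample:
        warnings.warn(f"mock sample {mock_sample!r} not found; proceeding without mock")
        mock_sample = None

    per_sample_counts: dict[str, dict[str, list[int]]] = {}
    for sample, reads in reads_by_sample.items():
        assigned, unassigned = assign_reads(reads, refs, max_assign_distance_frac)
        if unassigned:
            logger.info("sample %s: %d unassigned reads", sample, len(unassigned))
        per_sample_counts[sample] = _site_counts(assigned, refs, loci_by_amp, method)

    mock_counts = per_sample_counts.get(mock_sample) if mock_sample else None
    estimates: list[ActivityEstimate] = []
    for row in config.rows:
        for sample in reads_by_sample:
            e, u, d = per_sample_counts[sample][row.site_name]
            if e + u == 0:
                warnings.warn(f"site {row.site_name!r}, sample {sample!r}: no evaluable reads")
                estimates.append(ActivityEstimate(
                    site_name=row.site_name, sample=sample, n_reads=0, n_edited=0,
                    n_discarded=d, rate=float("nan"), ci_low=float("nan"),
                    ci_high=float("nan"), mock_rate=float("nan"),
                    significant_vs_mock=False, flags=frozenset()))
                continue
            me, mu = (0, 0)
            if mock_counts is not None and sample != mock_sample:
                me, mu = mock_counts[row.site_name][0], mock_counts[row.site_name][1]
            estimates.append(estimate_activity(
                n_edited=e, n_reads=e + u, mock_edited=me, mock_reads=me + mu if (me + mu) else 0,
                alpha=alpha, site_name=row.site_name, sample=sample, n_discarded=d,
            ))
    if bh_correct:
        estimates = benjamini_hochberg(estimates, alpha)
    return estimates


ACTIVITY_COLUMNS = [
    "site_name", "sample", "n_reads", "n_edited", "n_discarded", "rate",
    "ci_low", "ci_high", "mock_rate", "significant_vs_mock", "flags",
    "p_value", "corrected_rate", "corrected_ci_low", "corrected_ci_high",
]


def activity_frame(estimates: list[ActivityEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "site_name": e.site_name, "sample": e.sample, "n_reads": e.n_reads,
            "n_edited": e.n_edited, "n_discarded": e.n_discarded,
            "rate": e.rate, "ci_low": e.ci_low, "ci_high": e.ci_high,
            "mock_rate": e.mock_rate, "significant_vs_mock": e.significant_vs_mock,
            "flags": ";".join(sorted(e.flags)), "p_value": e.p_value,
            "corrected_rate": e.corrected_rate,
            "corrected_ci_low": e.corrected_ci_low,
            "corrected_ci_high": e.corrected_ci_high,
        })
    return pd.DataFrame(rows, columns=ACTIVITY_COLUMNS)


def write_activity_csv(estimates: list[ActivityEstimate], path: str | Path) -> None:
    activity_frame(estimates).to_csv(path, index=False, float_format="%.8g")
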