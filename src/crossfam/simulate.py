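"""Synthetic gene families and long-read datasets with exact ground truth.

The generator emulates the study design the package targets: a small family
of paralogous ~1 kb amplicons derived from one ancestor, one designed guide
with an NGG-adjacent on-target site per member, optional planted off-target
20-mers at a chosen edit distance in sibling members, and CCS-like reads
(low i.i.d. per-base error) in several treated replicates plus one mock
(no-editing) control.  Editing is a cut-site indel applied to a configurable
fraction of reads.

Every planted feature is recorded in a truth table with its exact position,
strand and edit distance, so enumeration and quantification can be tested
against known answers.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import revcomp
from .enumeration import edit_distance
from .family import Amplicon, GeneFamily, Guide, write_family

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPL = dict(zip("ACGTN", "TGCAN"))


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FamilySimSpec:
    """Recipe for one synthetic gene family.

    ``divergence`` is the per-base substitution probability applied
    independently to each member relative to the ancestor (0.05 gives the
    ~90-97% pairwise identity typical of recently duplicated paralogs);
    ``indel_divergence`` adds short indels at that per-base rate.
    ``planted_offtargets`` are (source member, host member, edit distance)
    triples; each plants a PAM-adjacent 20-mer at exactly that Levenshtein
    distance from the source member's guide into the host amplicon.
    """

    n_members: int = 2
    amplicon_length: int = 1000
    divergence: float = 0.05
    indel_divergence: float = 0.002
    planted_offtargets: tuple[tuple[str, str, int], ...] = ()
    seed: int = 0
    name: str = "SIM"
    margin: int = 100  # min distance of planted features from amplicon ends

    def __post_init__(self):
        if not 2 <= self.n_members <= 10:
            raise SimulationError("n_members must be in [2, 10]")
        if not 0 <= self.divergence <= 0.5:
            raise SimulationError("divergence must be in [0, 0.5]")
        for _, _, d in self.planted_offtargets:
            if not 0 <= d <= 20:
                raise SimulationError(f"planted edit distance {d} outside [0, 20]")


@dataclass(frozen=True)
class ReadSimSpec:
    """Recipe for CCS-like reads over a family.

    Error rates are i.i.d. per base (substitution/insertion/deletion
    0.003/0.003/0.004 by default, ~1% total).  ``edit_rates`` maps truth-table
    site ids to the true edited fraction; sites not listed stay at 0.  Edits
    are cut-site indels drawn from a deletion(1-10 nt)/insertion(1-3 nt)
    mixture.  ``n_replicates`` treated samples are generated, plus one mock
    with all edit rates forced to 0 when ``include_mock`` is set.
    """

    n_reads: int = 2000
    error_sub: float = 0.003
    error_ins: float = 0.003
    error_del: float = 0.004
    edit_rates: dict = field(default_factory=dict)
    n_replicates: int = 6
    include_mock: bool = True
    seed: int = 0
    del_lengths: tuple[int, int] = (1, 10)
    ins_lengths: tuple[int, int] = (1, 3)
    deletion_prob: float = 0.7

    def __post_init__(self):
        for p in (self.error_sub, self.error_ins, self.error_del):
            if not 0 <= p <= 1:
                raise SimulationError("error probabilities must be in [0, 1]")
        for r in self.edit_rates.values():
            if not 0 <= r <= 1:
                raise SimulationError("edit rates must be in [0, 1]")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, sub_p: float, indel_p: float) -> str:
    """Apply i.i.d. substitutions and short (1-3 nt) indels to a sequence."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    sub_mask = rng.random(arr.size) < sub_p
    if sub_mask.any():
        shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        cur = np.array([idx[b] for b in arr[sub_mask]])
        arr[sub_mask] = BASES[(cur + shifts) % 4]
    s = list(arr.tobytes().decode())
    if indel_p > 0:
        positions = np.nonzero(rng.random(len(s)) < indel_p)[0]
        for p in positions[::-1]:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                del s[p : p + size]
            else:
                s[p:p] = _random_seq(rng, size)
    return "".join(s)


def _variant_at_distance(rng: np.random.Generator, guide: str, d: int, max_retries: int = 200) -> str:
    """A length-20 variant at exactly Levenshtein distance d from the guide.

    Substitution-only edit scripts are proposed and verified with the same
    edit-distance routine the enumerator uses, so truth labels are exact; the
    fixed length keeps the planted PAM-adjacent window identical to the
    variant itself.
    """
    if d == 0:
        return guide
    if d > len(guide):
        raise SimulationError(f"cannot plant distance {d} for a {len(guide)}-mer")
    arr = np.frombuffer(guide.encode(), dtype=np.uint8)
    idx = {65: 0, 67: 1, 71: 2, 84: 3}
    for _ in range(max_retries):
        pos = rng.choice(len(guide), size=d, replace=False)
        out = arr.copy()
        shifts = rng.integers(1, 4, size=d)
        cur = np.array([idx[b] for b in out[pos]])
        out[pos] = BASES[(cur + shifts) % 4]
        variant = out.tobytes().decode()
        if edit_distance(variant, guide) == d:
            return variant
    raise SimulationError(f"failed to construct a variant at distance {d} after {max_retries} tries")


def _splice(seq: str, start: int, insert: str) -> str:
    return seq[:start] + insert + seq[start + len(insert):]


def _free_position(rng, occupied: list[tuple[int, int]], length: int, block: int, margin: int,
                   max_retries: int = 200) -> int:
    for _ in range(max_retries):
        start = int(rng.integers(margin, length - margin - block))
        if all(start + block + 25 <= a or start >= b + 25 for a, b in occupied):
            occupied.append((start, start + block))
            return start
    raise SimulationError("could not place a site away from existing features")


TRUTH_COLUMNS = ["site_id", "role", "source_guide", "host_amplicon", "position",
                 "strand", "protospacer", "pam", "edit_distance", "cut_position"]


def simulate_family(spec: FamilySimSpec) -> tuple[GeneFamily, pd.DataFrame]:
    """Generate a family plus the truth table of all planted sites.

    Members are named S1..Sn (guide and amplicon share the member name).
    Positions in the truth table follow the package convention: leftmost
    forward-strand base of the 20-mer window; the cut position is the blunt
    cut 3 nt 5' of the PAM.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = _random_seq(rng, spec.amplicon_length)
    member_names = [f"S{i + 1}" for i in range(spec.n_members)]
    seqs: dict[str, str] = {
        m: _mutate(rng, ancestor, spec.divergence, spec.indel_divergence)
        for m in member_names
    }
    occupied: dict[str, list[tuple[int, int]]] = {m: [] for m in member_names}
    truth_rows: list[dict] = []
    guides: dict[str, str] = {}

    for m in member_names:
        guide = _random_seq(rng, 20)
        guides[m] = guide
        pam = _random_seq(rng, 1) + "GG"
        strand = "+" if rng.random() < 0.5 else "-"
        start = _free_position(rng, occupied[m], len(seqs[m]), 23, spec.margin)
        if strand == "+":
            seqs[m] = _splice(seqs[m], start, guide + pam)
            position = start
        else:
            seqs[m] = _splice(seqs[m], start, revcomp(guide + pam))
            position = start + 3
        cut = position + 17 if strand == "+" else position + 3
        truth_rows.append({
            "site_id": f"{m}_on", "role": "on", "source_guide": m,
            "host_amplicon": m, "position": position, "strand": strand,
            "protospacer": guide, "pam": pam, "edit_distance": 0,
            "cut_position": cut,
        })

    for k, (src, host, d) in enumerate(spec.planted_offtargets):
        if src not in guides or host not in seqs:
            raise SimulationError(f"planted off-target references unknown member: {src}->{host}")
        variant = _variant_at_distance(rng, guides[src], d)
        pam = _random_seq(rng, 1) + "GG"
        strand = "+" if rng.random() < 0.5 else "-"
        start = _free_position(rng, occupied[host], len(seqs[host]), 23, spec.margin)
        if strand == "+":
            seqs[host] = _splice(seqs[host], start, variant + pam)
            position = start
        else:
            seqs[host] = _splice(seqs[host], start, revcomp(variant + pam))
            position = start + 3
        cut = position + 17 if strand == "+" else position + 3
        truth_rows.append({
            "site_id": f"{host}_off{k + 1}_{src}", "role": "off", "source_guide": src,
            "host_amplicon": host, "position": position, "strand": strand,
            "protospacer": variant, "pam": pam, "edit_distance": d,
            "cut_position": cut,
        })

    members = [
        (Amplicon(name=m, sequence=seqs[m], family=spec.name),
         Guide(name=m, sequence=guides[m], family_member=m))
        for m in member_names
    ]
    family = GeneFamily(name=spec.name, members=members)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return family, truth


# ---------------------------------------------------------------------------
# reads


def _apply_cut_indel(rng: np.random.Generator, seq: str, cut: int, spec: ReadSimSpec) -> str:
    """Plant one NHEJ-like indel at a cut junction (left-aligned as applied)."""
    if rng.random() < spec.deletion_prob:
        size = int(rng.integers(spec.del_lengths[0], spec.del_lengths[1] + 1))
        start = max(cut - (size + 1) // 2, 0)
        return seq[:start] + seq[start + size:]
    size = int(rng.integers(spec.ins_lengths[0], spec.ins_lengths[1] + 1))
    return seq[:cut] + _random_seq(rng, size) + seq[cut:]


def _apply_errors(rng: np.random.Generator, seq: str, spec: ReadSimSpec) -> str:
    out = _mutate(rng, seq, spec.error_sub, 0.0) if spec.error_sub else seq
    if spec.error_ins == 0 and spec.error_del == 0:
        return out
    s = list(out)
    dels = np.nonzero(rng.random(len(s)) < spec.error_del)[0]
    for p in dels[::-1]:
        del s[p]
    ins = np.nonzero(rng.random(len(s) + 1) < spec.error_ins)[0]
    for p in ins[::-1]:
        s[p:p] = _random_seq(rng, 1)
    return "".join(s)


def simulate_reads(
    family: GeneFamily,
    truth: pd.DataFrame,
    spec: ReadSimSpec,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate per-sample reads and the realized editing truth summary.

    Samples are named rep1..repN plus ``mock``.  Each sample holds
    ``n_reads`` reads per amplicon: the reference, optionally edited at each
    truth site it hosts (independent Bernoulli at that site's rate; always 0
    in the mock), then passed through the error channel and flipped to the
    reverse strand with probability 1/2.  The summary records the exact
    number of edited reads per (sample, site).
    """
    samples = [f"rep{i + 1}" for i in range(spec.n_replicates)]
    if spec.include_mock:
        samples.append("mock")
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(len(samples))

    sites_by_amp: dict[str, list[tuple[str, int, float]]] = {}
    for _, row in truth.iterrows():
        rate = float(spec.edit_rates.get(row.site_id, 0.0))
        sites_by_amp.setdefault(row.host_amplicon, []).append(
            (row.site_id, int(row.cut_position), rate))

    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    summary_rows: list[dict] = []
    for sample, child in zip(samples, child_seeds):
        rng = np.random.default_rng(child)
        is_mock = sample == "mock"
        reads: list[tuple[str, str]] = []
        for amp, _guide in family.members:
            sites = sites_by_amp.get(amp.name, [])
            edited_counts = {sid: 0 for sid, _, _ in sites}
            for i in range(spec.n_reads):
                seq = amp.sequence
                # apply rightmost site first so earlier cut coordinates survive
                for sid, cut, rate in sorted(sites, key=lambda t: -t[1]):
                    if not is_mock and rate > 0 and rng.random() < rate:
                        seq = _apply_cut_indel(rng, seq, cut, spec)
                        edited_counts[sid] += 1
                seq = _apply_errors(rng, seq, spec)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                reads.append((f"{sample}_{amp.name}_r{i}", seq))
            for sid, _, rate in sites:
                summary_rows.append({
                    "sample": sample, "site_id": sid, "n_reads": spec.n_reads,
                    "n_edited_true": edited_counts[sid],
                    "true_rate": 0.0 if is_mock else rate,
                })
        reads_by_sample[sample] = reads
    summary = pd.DataFrame(summary_rows,
                           columns=["sample", "site_id", "n_reads", "n_edited_true", "true_rate"])
    return reads_by_sample, summary


def write_reads_fastq(reads_by_sample: dict[str, list[tuple[str, str]]], outdir: str | Path,
                      gzip_out: bool = False) -> dict[str, Path]:
    """Write one FASTQ per sample; returns sample -> path."""
    import gzip as _gzip

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, reads in reads_by_sample.items():
        path = outdir / (f"{sample}.fastq.gz" if gzip_out else f"{sample}.fastq")
        opener = _gzip.open if gzip_out else open
        with opener(path, "wt") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths


def write_simulation(
    family: GeneFamily,
    truth: pd.DataFrame,
    reads_by_sample: dict[str, list[tuple[str, str]]],
    summary: pd.DataFrame,
    outdir: str | Path,
    gzip_out: bool = False,
) -> dict[str, Path]:
    """Materialize a full simulated dataset (FASTA, guides, FASTQs, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "amplicons.fasta"
    guides = outdir / "guides.csv"
    write_family(family, fasta, guides)
    truth.to_csv(outdir / "truth_sites.csv", index=False)
    summary.to_csv(outdir / "truth_reads.csv", index=False)
    fastqs = write_reads_fastq(reads_by_sample, outdir, gzip_out)
    samples_csv = outdir / "samples.csv"
    with open(samples_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "fastq_path", "is_mock"])
        for sample, path in fastqs.items():
            w.writerow([sample, path.name, sample == "mock"])
    return {"fasta": fasta, "guides": guides, "samples": samples_csv, **fastqs}
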