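import numpy as np
import pytest

from crossfam._util import revcomp
from crossfam.activity import (QuantError, SiteLocus, assign_reads, call_edit,
                               corrected_estimate, estimate_activity, locate_site,
                               quantify)
from crossfam.config import ConfigRow, ConfigTable
from crossfam.simulate import ReadSimSpec, simulate_reads

from conftest import random_seq
from oracles import ora_fisher_greater, ora_wilson


@pytest.fixture(scope="module")
def locus_setup():
    rng = np.random.default_rng(31)
    guide = random_seq(rng, 20)
    ref = random_seq(rng, 300) + guide + "TGG" + random_seq(rng, 300)
    cut = 300 + 17
    return ref, guide, cut


class TestLocateSite:
    def test_forward_cut_17nt_into_protospacer(self, locus_setup):
        ref, guide, cut = locus_setup
        pos, strand, cut_found = locate_site(guide, ref)
        assert (pos, strand, cut_found) == (300, "+", cut)

    def test_reverse_cut_mirrors_geometry(self, locus_setup):
        ref, guide, cut = locus_setup
        pos, strand, cut_rc = locate_site(guide, revcomp(ref))
        assert strand == "-"
        # blunt cut junction mirrors exactly under reverse complement
        assert cut_rc == len(ref) - cut

    def test_missing_sequence_fatal(self, locus_setup):
        ref, _, _ = locus_setup
        with pytest.raises(QuantError):
            locate_site("A" * 20, ref[:100])


class TestAssignReads:
    def test_exact_copies_assign_perfectly(self, sim_family):
        family, _ = sim_family
        reads = [(f"{a.name}_r", a.sequence) for a, _ in family.members]
        reads += [(f"{a.name}_rc", revcomp(a.sequence)) for a, _ in family.members]
        assigned, unassigned = assign_reads(reads, family)
        assert not unassigned
        for name, pairs in assigned.items():
            assert all(rid.startswith(name) for rid, _ in pairs)
            # reads come back in reference orientation
            assert all(seq == family.amplicons[name].sequence for _, seq in pairs)

    def test_random_reads_are_unassigned(self, sim_family, rng):
        family, _ = sim_family
        reads = [(f"r{i}", random_seq(rng, 1000)) for i in range(10)]
        _, unassigned = assign_reads(reads, family, max_assign_distance_frac=0.3)
        assert len(unassigned) == 10

    def test_fragments_are_filtered(self, sim_family):
        family, _ = sim_family
        short = family.members[0][0].sequence[:300]
        _, unassigned = assign_reads([("frag", short)], family)
        assert unassigned == ["frag"]

    def test_noisy_pool_assignment_accuracy(self, sim_family):
        """CCS-like reads from a ~5%-divergent 2-member pool assign back to
        their amplicon of origin >= 99% of the time."""
        family, truth = sim_family
        reads_by_sample, _ = simulate_reads(
            family, truth, ReadSimSpec(n_reads=150, n_replicates=1, include_mock=False,
                                       seed=7))
        assigned, unassigned = assign_reads(reads_by_sample["rep1"], family)
        total = sum(len(v) for v in assigned.values()) + len(unassigned)
        correct = sum(rid.split("_")[1] == name
                      for name, pairs in assigned.items() for rid, _ in pairs)
        assert correct / total >= 0.99


class TestCallEdit:
    @pytest.mark.parametrize("method", ["unit", "affine"])
    def test_identity_read_unedited(self, locus_setup, method):
        ref, _, cut = locus_setup
        locus = SiteLocus("A", cut, 10)
        assert call_edit(ref, ref, locus, method) == "unedited"

    @pytest.mark.parametrize("method", ["unit", "affine"])
    def test_deletion_straddling_cut_is_edited(self, locus_setup, method):
        ref, _, cut = locus_setup
        read = ref[: cut - 1] + ref[cut + 2:]  # 3 bp deletion over the junction
        assert call_edit(read, ref, SiteLocus("A", cut, 10), method) == "edited"

    @pytest.mark.parametrize("method", ["unit", "affine"])
    def test_insertion_at_cut_is_edited(self, locus_setup, method):
        ref, _, cut = locus_setup
        read = ref[:cut] + "ACGTA" + ref[cut:]
        assert call_edit(read, ref, SiteLocus("A", cut, 10), method) == "edited"

    def test_distal_insertion_is_unedited(self, locus_setup):
        ref, _, cut = locus_setup
        read = ref[: cut + 50] + "T" + ref[cut + 50:]
        assert call_edit(read, ref, SiteLocus("A", cut, 10)) == "unedited"

    def test_substitutions_never_count(self, locus_setup):
        ref, _, cut = locus_setup
        read = list(ref)
        for off in (-3, 0, 3):
            read[cut + off] = "ACGT"["ACGT".index(read[cut + off]) - 1]
        assert call_edit("".join(read), ref, SiteLocus("A", cut, 10)) == "unedited"

    def test_read_not_spanning_window_is_discarded(self, locus_setup):
        ref, _, cut = locus_setup
        read = ref[cut + 5:]  # starts inside the window
        assert call_edit(read, ref, SiteLocus("A", cut, 10)) == "discarded"

    def test_window_monotonicity(self, locus_setup, rng):
        """Widening the window never turns an edited read unedited."""
        ref, _, cut = locus_setup
        reads = []
        for _ in range(30):
            p = int(rng.integers(0, len(ref) - 4))
            reads.append(ref[:p] + ref[p + int(rng.integers(1, 4)):])
        for hw in (0, 5, 10, 25):
            wide = SiteLocus("A", cut, hw + 5)
            narrow = SiteLocus("A", cut, hw)
            for read in reads:
                if call_edit(read, ref, narrow) == "edited":
                    assert call_edit(read, ref, wide) == "edited"


class TestEstimate:
    def test_zero_count_boundary(self):
        est = estimate_activity(0, 1000)
        assert est.rate == 0.0
        assert est.ci_low == 0.0
        assert est.flags == {"lt_1pct", "lt_0.3pct", "lt_0.1pct", "lt_0.01pct"}
        assert not est.significant_vs_mock

    def test_wilson_matches_closed_form(self):
        for count, nobs in [(500, 1000), (5, 1000), (1, 2000), (999, 1000)]:
            est = estimate_activity(count, nobs)
            lo, hi = ora_wilson(count, nobs)
            assert est.ci_low == pytest.approx(lo, abs=1e-9)
            assert est.ci_high == pytest.approx(hi, abs=1e-9)
            assert est.ci_low <= est.rate <= est.ci_high

    def test_fisher_matches_hypergeometric_enumeration(self):
        est = estimate_activity(5, 1000, mock_edited=0, mock_reads=1000)
        assert est.rate == pytest.approx(0.005)
        assert "lt_1pct" in est.flags
        assert "lt_0.1pct" not in est.flags
        expected_p = ora_fisher_greater(5, 995, 0, 1000)
        assert est.p_value == pytest.approx(expected_p, rel=1e-9)
        assert est.significant_vs_mock

    def test_zero_reads_fatal(self):
        with pytest.raises(QuantError):
            estimate_activity(0, 0)

    def test_corrected_estimate_removes_background(self):
        # 15% background in both arms, true signal 10% of the remainder
        rate, lo, hi = corrected_estimate(235, 1000, 150, 1000)
        assert rate == pytest.approx(0.1, abs=0.001)
        assert lo < 0.1 < hi


def _one_site_config(name, ref, guide, amp_name="A"):
    return ConfigTable(target="g1", rows=[
        ConfigRow(site_name=name, amplicon_name=amp_name, amplicon_sequence=ref,
                  grna=guide, role="on_target", source_guide="g1")])


@pytest.fixture(scope="module")
def clean_setup():
    rng = np.random.default_rng(41)
    guide = random_seq(rng, 20)
    ref = random_seq(rng, 200) + guide + "TGG" + random_seq(rng, 200)
    cut = 200 + 17
    edited = ref[: cut - 2] + ref[cut + 2:]
    return ref, guide, cut, edited


class TestQuantify:
    def test_counts_partition_assigned_reads(self, clean_setup):
        ref, guide, cut, edited = clean_setup
        reads = {"t": [("r1", ref), ("r2", edited), ("r3", ref[cut + 5:]),
                       ("r4", revcomp(edited))]}
        # truncated read r3 spans neither the window nor half the reference -> fragment
        est = quantify(_one_site_config("A_on", ref, guide), reads)[0]
        assert est.n_edited == 2
        assert est.n_reads + est.n_discarded == 3

    def test_planted_rate_recovered_without_errors(self, clean_setup):
        ref, guide, cut, edited = clean_setup
        reads = {"t": [(f"r{i}", edited if i < 30 else ref) for i in range(100)]}
        est = quantify(_one_site_config("A_on", ref, guide), reads)[0]
        assert est.n_reads == 100
        assert est.rate == pytest.approx(0.30)

    def test_mock_self_comparison_not_significant(self, clean_setup):
        ref, guide, _, _ = clean_setup
        reads = {"t": [(f"r{i}", ref) for i in range(50)],
                 "mock": [(f"m{i}", ref) for i in range(50)]}
        ests = quantify(_one_site_config("A_on", ref, guide), reads,
                        mock_sample="mock")
        assert all(not e.significant_vs_mock for e in ests)

    def test_missing_mock_downgrades_with_warning(self, clean_setup):
        ref, guide, _, _ = clean_setup
        reads = {"t": [(f"r{i}", ref) for i in range(10)]}
        with pytest.warns(UserWarning, match="mock"):
            ests = quantify(_one_site_config("A_on", ref, guide), reads,
                            mock_sample="nope")
        assert len(ests) == 1

    def test_edits_at_one_site_leave_others_at_zero(self, sim_family):
        """With no sequencing error and edits planted only at S1's on-target,
        every other configured site reports rate 0."""
        from crossfam.config import build_config
        from crossfam.enumeration import enumerate_offtargets, select_reported_sites

        family, truth = sim_family
        reads, _ = simulate_reads(
            family, truth,
            ReadSimSpec(n_reads=60, n_replicates=1, include_mock=False,
                        error_sub=0, error_ins=0, error_del=0,
                        edit_rates={"S1_on": 0.5}, seed=13))
        sites = select_reported_sites(
            enumerate_offtargets(family, min_alignment_score=0), 2)
        refs = {a.name: a.sequence for a, _ in family.members}
        edited_cut = int(truth.set_index("site_id").loc["S1_on", "cut_position"])
        for target in ("S1", "S2"):
            table = build_config(family, sites, target)
            loci = {r.site_name: locate_site(r.grna, r.amplicon_sequence)
                    for r in table.rows}
            for est in quantify(table, reads, window_halfwidth=10, references=refs):
                amp = next(r.amplicon_name for r in table.rows
                           if r.site_name == est.site_name)
                cut = loci[est.site_name][2]
                if est.site_name == "S1_on":
                    assert 0.3 < est.rate < 0.7
                elif amp == "S1" and abs(cut - edited_cut) < 40:
                    continue  # window overlaps the edited locus; edits leak in
                else:
                    assert est.rate == 0.0

    def test_unit_and_affine_calls_agree_on_simulated_reads(self, sim_family):
        family, truth = sim_family
        reads, _ = simulate_reads(
            family, truth,
            ReadSimSpec(n_reads=25, n_replicates=1, include_mock=False,
                        error_sub=0, error_ins=0, error_del=0,
                        edit_rates={"S1_on": 0.4}, seed=17))
        refs = {a.name: a.sequence for a, _ in family.members}
        amp = family.amplicons["S1"]
        guide = family.guides["S1"]
        table = _one_site_config("S1_on", amp.sequence, guide.sequence, amp_name="S1")
        est_unit = quantify(table, reads, method="unit", references=refs)[0]
        est_affine = quantify(table, reads, method="affine", references=refs)[0]
        assert est_unit.n_reads == est_affine.n_reads == 25
        assert est_unit.n_edited == est_affine.n_edited > 0
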