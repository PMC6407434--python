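import numpy as np
import pytest

import smmipseq as s
from smmipseq.quantify import UniqueReadGroup
from smmipseq.variants import (
    VariantError,
    build_pileup,
    call_variants,
    classify_somatic,
    left_align_indel,
    write_vcf,
)

from conftest import sequences


@pytest.fixture(scope="module")
def probe_ctx(small_panel):
    probe = small_panel.probes[0]
    window = small_panel.target_window(probe)
    return small_panel, probe, window


def groups_with_alt(probe, window, n_ref, n_alt, alt_offset=10, alt_base=None):
    ref_base = window[alt_offset]
    alt_base = alt_base or ("G" if ref_base != "G" else "T")
    alt_fill = window[:alt_offset] + alt_base + window[alt_offset + 1 :]
    groups = [
        UniqueReadGroup(probe.probe_id, f"REF{i:05d}"[:8], window, 1)
        for i in range(n_ref)
    ]
    groups += [
        UniqueReadGroup(probe.probe_id, f"ALT{i:05d}"[:8], alt_fill, 1)
        for i in range(n_alt)
    ]
    return groups, ref_base, alt_base


class TestPileup:
    def test_all_reference_single_allele(self, probe_ctx):
        panel, probe, window = probe_ctx
        groups, _, _ = groups_with_alt(probe, window, n_ref=10, n_alt=0)
        pileup = build_pileup(groups, panel)
        for k, pos in enumerate(range(probe.target_start, probe.target_end)):
            key = (probe.transcript_id, pos)
            assert pileup.coverage[key] == 10
            assert pileup.alleles[key] == {window[k]: 10}

    def test_alt_allele_counted(self, probe_ctx):
        panel, probe, window = probe_ctx
        groups, ref_base, alt_base = groups_with_alt(probe, window, 7, 3)
        pileup = build_pileup(groups, panel)
        key = (probe.transcript_id, probe.target_start + 10)
        assert pileup.alleles[key] == {ref_base: 7, alt_base: 3}
        assert pileup.coverage[key] == 10

    def test_n_bases_cover_but_carry_no_allele(self, probe_ctx):
        panel, probe, window = probe_ctx
        n_fill = "N" + window[1:]
        groups = [
            UniqueReadGroup(probe.probe_id, "AAAAAAAA", window, 1),
            UniqueReadGroup(probe.probe_id, "CCCCCCCC", n_fill, 1),
        ]
        pileup = build_pileup(groups, panel)
        key = (probe.transcript_id, probe.target_start)
        assert pileup.coverage[key] == 2
        assert pileup.alleles[key] == {window[0]: 1}

    def test_deletion_located_and_left_aligned(self, probe_ctx):
        panel, probe, window = probe_ctx
        # delete one base in the middle of the window
        off = 20
        del_fill = window[:off] + window[off + 1 :]
        groups = [
            UniqueReadGroup(probe.probe_id, f"R{i:07d}", window, 1) for i in range(8)
        ] + [
            UniqueReadGroup(probe.probe_id, f"D{i:07d}", del_fill, 1) for i in range(4)
        ]
        pileup = build_pileup(groups, panel)
        calls = call_variants(pileup, panel, "s", min_vaf=0.1, min_coverage=5)
        indels = [c for c in calls if len(c.ref) != len(c.alt)]
        assert len(indels) == 1
        call = indels[0]
        assert len(call.ref) == 2 and len(call.alt) == 1
        assert call.variant_unique_reads == 4
        ref_seq = panel.transcripts[probe.transcript_id]
        # left-aligned: the base before the reported anchor must differ
        # from the deleted base (no further left shift possible)
        lpos, lref, lalt = left_align_indel(ref_seq, call.position, call.ref, call.alt)
        assert (lpos, lref, lalt) == (call.position, call.ref, call.alt)

    def test_overlong_fill_skipped(self, probe_ctx):
        panel, probe, window = probe_ctx
        junk = window + "ACGT" * 10
        pileup = build_pileup(
            [UniqueReadGroup(probe.probe_id, "AAAAAAAA", junk, 1)], panel
        )
        assert pileup.skipped_groups == 1
        assert not pileup.coverage


class TestCalling:
    def test_three_of_ten_called(self, probe_ctx):
        panel, probe, window = probe_ctx
        groups, ref_base, alt_base = groups_with_alt(probe, window, 7, 3)
        calls = call_variants(build_pileup(groups, panel), panel, "s")
        assert len(calls) == 1
        call = calls[0]
        assert (call.ref, call.alt) == (ref_base, alt_base)
        assert call.vaf == pytest.approx(0.30)
        assert call.variant_unique_reads / call.total_unique_reads == call.vaf

    def test_one_of_twenty_not_called(self, probe_ctx):
        panel, probe, window = probe_ctx
        groups, _, _ = groups_with_alt(probe, window, 19, 1)
        assert call_variants(build_pileup(groups, panel), panel, "s") == []

    def test_vaf_29_percent_passes_default_threshold(self, probe_ctx):
        # 29% of unique reads clears the 10% reporting floor
        panel, probe, window = probe_ctx
        groups, _, _ = groups_with_alt(probe, window, 71, 29)
        calls = call_variants(build_pileup(groups, panel), panel, "s")
        assert len(calls) == 1
        assert calls[0].vaf == pytest.approx(0.29)

    def test_coverage_floor(self, probe_ctx):
        panel, probe, window = probe_ctx
        groups, _, _ = groups_with_alt(probe, window, 4, 3)  # coverage 7 < 10
        assert call_variants(build_pileup(groups, panel), panel, "s") == []

    def test_threshold_monotone_nesting(self, probe_ctx):
        panel, probe, window = probe_ctx
        groups = []
        for off, (n_ref, n_alt) in zip((5, 15, 25, 35), [(8, 4), (15, 3), (10, 5), (18, 2)]):
            g, _, _ = groups_with_alt(probe, window, n_ref, n_alt, alt_offset=off)
            # unique UMIs across constructed groups
            groups += [
                UniqueReadGroup(x.probe_id, f"{off:02d}{x.umi[:6]}", x.consensus_fill, 1)
                for x in g
            ]
        pileup = build_pileup(groups, panel)
        previous = None
        for thr in (0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5):
            keys = {c.key for c in call_variants(pileup, panel, "s", min_vaf=thr, min_coverage=1)}
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_invalid_threshold(self, probe_ctx):
        panel, probe, window = probe_ctx
        with pytest.raises(VariantError):
            call_variants(build_pileup([], panel), panel, "s", min_vaf=0.0)


class TestSomatic:
    def make_pileups(self, probe_ctx, healthy_alt, healthy_n):
        panel, probe, window = probe_ctx
        tumor_groups, ref_base, alt_base = groups_with_alt(probe, window, 21, 29)
        healthy_groups, _, _ = groups_with_alt(
            probe, window, healthy_n - healthy_alt, healthy_alt
        )
        tumor = build_pileup(tumor_groups, panel)
        healthy = build_pileup(healthy_groups, panel)
        calls = call_variants(tumor, panel, "t")
        return calls, healthy

    def test_absent_in_healthy_is_somatic(self, probe_ctx):
        calls, healthy = self.make_pileups(probe_ctx, healthy_alt=0, healthy_n=50)
        [call] = classify_somatic(calls, healthy)
        assert call.somatic is True
        assert call.vaf == pytest.approx(0.58)

    def test_present_in_healthy_is_not_somatic(self, probe_ctx):
        calls, healthy = self.make_pileups(probe_ctx, healthy_alt=20, healthy_n=50)
        [call] = classify_somatic(calls, healthy)
        assert call.somatic is False

    def test_low_healthy_coverage_not_evaluable(self, probe_ctx):
        calls, healthy = self.make_pileups(probe_ctx, healthy_alt=0, healthy_n=3)
        [call] = classify_somatic(calls, healthy)
        assert call.somatic is None


class TestSimulatedVariants:
    def test_sensitivity_and_healthy_specificity(self, small_panel):
        """Tumor-only variants at VAF 0.5, deep coverage, no error:
        every tumor biopsy yields the somatic call, healthy yields none."""
        probe = small_panel.probes[2]
        ref = small_panel.transcripts[probe.transcript_id]
        pos = probe.target_start + 30
        alt = "T" if ref[pos] != "T" else "A"
        var = s.SpikedVariant(probe.transcript_id, pos, ref[pos], alt, vaf=0.5)
        sim = s.simulate_cohort(
            s.SimulationConfig(
                panel=small_panel,
                seed=23,
                n_patients=1,
                baseline_molecules_per_probe=100,
                duplication_mean=2.0,
                error_rate=0.0,
                spiked_variants=[var],
            )
        )
        groups, _, _ = s.quantify_cohort(sequences(sim), small_panel)
        healthy_pileup = build_pileup(groups["A_H"], small_panel)
        assert call_variants(healthy_pileup, small_panel, "A_H") == []
        for t in ("A_T1", "A_T2", "A_T3"):
            calls = call_variants(build_pileup(groups[t], small_panel), small_panel, t)
            match = [c for c in calls if c.key == (probe.transcript_id, pos, ref[pos], alt)]
            assert len(match) == 1
            [som] = classify_somatic(match, healthy_pileup)
            assert som.somatic is True
            truth = sim.truth.variant_fractions
            expected = truth.loc[truth.sample_id == t, "fraction"].iloc[0]
            assert som.vaf == pytest.approx(expected, abs=0.02)


def test_vcf_positions_are_one_based(probe_ctx, tmp_path):
    panel, probe, window = probe_ctx
    groups, ref_base, alt_base = groups_with_alt(probe, window, 7, 3)
    calls = call_variants(build_pileup(groups, panel), panel, "s")
    path = tmp_path / "calls.vcf"
    write_vcf(calls, path, panel)
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(body) == 1
    fields = body[0].split("\t")
    assert int(fields[1]) == calls[0].position + 1
    assert fields[3] == ref_base and fields[4] == alt_base
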