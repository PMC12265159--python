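"""Bisulfite-space matching, CpG calling and per-sample deconvolution."""

import numpy as np
import pytest

from fecalsig.markers import Marker, MarkerPanel
from fecalsig.methylprofile import (
    CpGState,
    aggregate_sample,
    call_cpgs,
    marker_fraction,
    match_read,
    read_fastq,
)
from fecalsig.synthio import (
    MixtureSpec,
    generate_marker_panel,
    simulate_bisulfite_reads,
    write_fastq,
)


def bisulfite_convert(marker: Marker, methylated: bool) -> str:
    """Fully converted read: non-CpG C -> T; CpG C -> C (meth) or T (unmeth)."""
    seq = list(marker.sequence)
    for i, b in enumerate(seq):
        if b == "C":
            if i in marker.cpg_offsets:
                seq[i] = "C" if methylated else "T"
            else:
                seq[i] = "T"
    return "".join(seq)


class TestMatchRead:
    def test_converted_reference_matches_at_100(self, small_panel):
        m = small_panel.markers[0]
        read = bisulfite_convert(m, methylated=True)
        mid, sim = match_read(read, small_panel)
        assert mid == m.marker_id
        assert sim == 100.0

    def test_unmethylated_read_also_100(self, small_panel):
        m = small_panel.markers[1]
        read = bisulfite_convert(m, methylated=False)
        mid, sim = match_read(read, small_panel)
        assert mid == m.marker_id and sim == 100.0

    def test_random_read_is_no_match(self, small_panel):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=150))
        assert match_read(read, small_panel) is None

    def test_argmax_prefers_closer_marker(self):
        base = generate_marker_panel(1, 1, 150, 5, seed=5).markers[0]
        # marker B: same as A but 25 positions mutated (non-CpG)
        seq_b = list(base.sequence)
        protected = set()
        for o in base.cpg_offsets:
            protected.update((o, o + 1))
        mutated = 0
        for i in range(len(seq_b)):
            if i in protected or mutated >= 25:
                continue
            seq_b[i] = {"A": "T", "T": "A", "C": "A", "G": "T"}[seq_b[i]]
            if seq_b[i] == "C":  # keep bisulfite space unambiguous
                seq_b[i] = "A"
            mutated += 1
        b = Marker("B", "colon", "".join(seq_b), base.cpg_offsets)
        panel = MarkerPanel([base, b])
        read = bisulfite_convert(base, methylated=True)
        mid, sim = match_read(read, panel, min_similarity=0)
        assert mid == base.marker_id
        assert sim == 100.0

    def test_raising_threshold_is_monotone_filter(self, small_panel):
        rng = np.random.default_rng(1)
        reads = []
        for m in small_panel:
            for _ in range(30):
                seq = list(bisulfite_convert(m, methylated=True))
                n_err = rng.integers(0, 60)
                for pos in rng.choice(len(seq), size=n_err, replace=False):
                    seq[pos] = rng.choice(list("ACGT"))
                reads.append("".join(seq))
        counts = []
        for thr in (0.0, 50.0, 80.0, 95.0):
            counts.append(
                sum(match_read(r, small_panel, min_similarity=thr) is not None for r in reads)
            )
        assert counts[0] == len(reads)  # zero threshold assigns everything
        assert counts == sorted(counts, reverse=True)

    def test_short_read_unassignable(self, small_panel):
        m = small_panel.markers[0]
        assert match_read(m.sequence[:60], small_panel) is None


class TestCallCpgs:
    def test_all_tg_is_unmethylated(self, tiny_marker):
        read = bisulfite_convert(tiny_marker, methylated=False)
        call = call_cpgs(read, tiny_marker)
        assert call.cpg_states == (CpGState.UNMETH,) * 4
        assert call.fully_unmethylated and call.conversion_ok

    def test_non_cg_tg_site_is_ambiguous(self, tiny_marker):
        read = list(bisulfite_convert(tiny_marker, methylated=True))
        o = tiny_marker.cpg_offsets[-1]
        read[o], read[o + 1] = "T", "A"
        call = call_cpgs("".join(read), tiny_marker)
        assert call.cpg_states[:3] == (CpGState.METH,) * 3
        assert call.cpg_states[3] == CpGState.AMBIG

    def test_unconverted_read_fails_conversion_qc(self, tiny_marker):
        # raw reference: every non-CpG C still C
        call = call_cpgs(tiny_marker.sequence, tiny_marker)
        assert not call.conversion_ok

    def test_offset_beyond_read_is_ambiguous(self, tiny_marker):
        read = bisulfite_convert(tiny_marker, methylated=False)[:10]
        call = call_cpgs(read, tiny_marker)
        assert call.cpg_states[-1] == CpGState.AMBIG


class TestMarkerFraction:
    def _call(self, marker, states, ok=True):
        from fecalsig.methylprofile import MoleculeCall

        return MoleculeCall(marker, 100.0, tuple(states), ok)

    def test_direct_count(self):
        calls = [self._call("m", [CpGState.UNMETH] * 3)] * 3 + [
            self._call("m", [CpGState.METH] * 3)
        ] * 7
        mf = marker_fraction(calls)
        assert (mf.n, mf.n_all_unmeth, mf.fraction) == (10, 3, 0.3)

    def test_all_unmethylated(self):
        calls = [self._call("m", [CpGState.UNMETH] * 5)] * 4
        assert marker_fraction(calls).fraction == 1.0

    def test_ambiguous_molecules_excluded(self):
        calls = [
            self._call("m", [CpGState.UNMETH, CpGState.AMBIG]) for _ in range(5)
        ]
        mf = marker_fraction(calls)
        assert mf.n == 0 and mf.fraction == 0.0 and mf.warning

    def test_order_and_duplication_invariance(self):
        a = [self._call("m", [CpGState.UNMETH] * 2)] * 2
        b = [self._call("m", [CpGState.METH] * 2)] * 3
        f1 = marker_fraction(a + b).fraction
        f2 = marker_fraction(b + a).fraction
        f3 = marker_fraction((a + b) * 4).fraction
        assert f1 == f2 == f3


class TestAggregateSample:
    def test_low_read_qc(self, small_panel):
        m = small_panel.markers[0]
        reads = [bisulfite_convert(m, True)] * 999
        prof = aggregate_sample(reads, small_panel)
        assert not prof.qc_pass and prof.qc_reason == "low_reads"
        prof2 = aggregate_sample(reads + [bisulfite_convert(m, True)], small_panel)
        assert prof2.qc_reason != "low_reads"

    def test_fraction_sum_qc(self, small_panel):
        # every marker fully unmethylated -> each cell type at 100%, sum 300%
        reads = []
        for m in small_panel:
            reads.extend([bisulfite_convert(m, False)] * 400)
        prof = aggregate_sample(reads, small_panel)
        assert not prof.qc_pass and prof.qc_reason == "fraction_sum"
        assert sum(prof.per_cell_type_fraction.values()) == pytest.approx(300.0)

    def test_ddpcr_normalization_product(self, small_panel):
        m = small_panel.markers[0]
        reads = [bisulfite_convert(m, False)] * 400 + [
            bisulfite_convert(m, True)
        ] * 600
        prof = aggregate_sample(reads, small_panel, ddpcr_human_pct=10.0)
        assert prof.per_cell_type_fraction[m.cell_type] == pytest.approx(40.0)
        assert prof.normalized_fraction[m.cell_type] == pytest.approx(4.0)

    def test_recovers_planted_mixture(self, small_panel):
        truth = {"neutrophil": 0.5, "colon": 0.3, "T_cell": 0.2}
        mix = MixtureSpec(truth, 5.0)
        reads = simulate_bisulfite_reads(small_panel, mix, 10_000, 1.0, 0.0, seed=8)
        prof = aggregate_sample(reads, small_panel)
        for ct, f in truth.items():
            se = np.sqrt(f * (1 - f) / 10_000)
            assert abs(prof.per_cell_type_fraction[ct] / 100 - f) < 3 * se

    def test_fastq_round_trip(self, small_panel, tmp_path):
        mix = MixtureSpec({"neutrophil": 1.0}, 5.0)
        reads = simulate_bisulfite_reads(small_panel, mix, 30, 1.0, 0.0, seed=4)
        write_fastq(reads, tmp_path / "s.fastq")
        back = read_fastq(tmp_path / "s.fastq")
        assert [seq for _, seq in back] == [seq for _, seq in reads]

    def test_brute_force_oracle(self):
        """Exhaustive independent re-implementation on <=20 reads, 2 markers."""
        panel = generate_marker_panel(
            2, 1, 60, 5, seed=17, cell_type_names=["neutrophil", "colon"]
        )
        mix = MixtureSpec({"neutrophil": 0.4, "colon": 0.6}, 5.0)
        reads = simulate_bisulfite_reads(panel, mix, 10, 0.95, 0.01, seed=19)
        seqs = [s for _, s in reads]

        # -- oracle: plain string loops, no numpy ------------------------
        def oracle_sim(read, ref):
            ov = min(len(read), len(ref))
            hits = 0
            for i in range(ov):
                if read[i] == ref[i] or (ref[i] == "C" and read[i] == "T"):
                    hits += 1
            return hits / ov * 100

        per_marker = {m.marker_id: [] for m in panel}
        retained = 0
        for read in seqs:
            best, best_sim = None, -1.0
            for m in panel:
                if len(read) < 0.5 * len(m.sequence):
                    continue
                s = oracle_sim(read, m.sequence)
                if s > best_sim:
                    best, best_sim = m, s
            if best is None or best_sim < 80:
                continue
            noncpg = [
                i
                for i, b in enumerate(best.sequence)
                if b == "C" and i not in best.cpg_offsets and i < len(read)
            ]
            unconv = sum(1 for i in noncpg if read[i] == "C") / max(len(noncpg), 1)
            if unconv > 0.10:
                continue
            retained += 1
            states = []
            for o in best.cpg_offsets:
                pair = read[o : o + 2]
                states.append(
                    "M" if pair == "CG" else ("U" if pair == "TG" else "A")
                )
            per_marker[best.marker_id].append(states)

        oracle_frac = {}
        for mid, mols in per_marker.items():
            usable = [s for s in mols if "A" not in s]
            oracle_frac[mid] = (
                sum(1 for s in usable if set(s) == {"U"}) / len(usable)
                if usable
                else 0.0
            )

        prof = aggregate_sample(seqs, panel, min_reads=1)
        assert prof.total_reads == retained
        for m in panel:
            assert prof.per_marker[m.marker_id].fraction == pytest.approx(
                oracle_frac[m.marker_id]
            )
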