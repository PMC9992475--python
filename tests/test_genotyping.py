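"""Filter cascade: per-step rules, audit completeness, truth recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplimhc.genotyping import (
    FilterConfig,
    cross_amplicon_screen,
    compute_pavf,
    detect_chimeras,
    detect_point_artefacts,
    filter_cascade,
    genotyping_accuracy,
    replicate_concordance,
)
from amplimhc.simulate import (
    ASVTable,
    SimulationConfig,
    contaminated_occurrences,
    primer_sets_for,
    simulate_experiment,
)


def make_table(counts: dict[str, dict[str, int]], sequences: dict[str, str]) -> ASVTable:
    amps = sorted({a for col in counts.values() for a in col} | set(counts))
    # counts given as {amplicon: {variant: n}}
    variants = sorted({v for col in counts.values() for v in col})
    df = pd.DataFrame(0, index=variants, columns=sorted(counts), dtype=np.int64)
    for amp, col in counts.items():
        for v, n in col.items():
            df.at[v, amp] = n
    meta = pd.DataFrame(
        {
            "individual": [a.split(".")[0] for a in df.columns],
            "primer_set": ["PS1"] * len(df.columns),
            "run": [a.split(".")[-1] if "." in a else "run1" for a in df.columns],
            "replicate": [False] * len(df.columns),
        },
        index=df.columns,
    )
    return ASVTable(sequences=sequences, counts=df, amplicons=meta)


class TestPAVF:
    def test_simple_frequencies(self):
        t = make_table({"a1": {"A": 900, "B": 100}}, {"A": "ACGT", "B": "ACGA"})
        pavf = compute_pavf(t)
        assert pavf.at["A", "a1"] == pytest.approx(0.9)
        assert pavf.at["B", "a1"] == pytest.approx(0.1)

    def test_single_variant_is_one(self):
        t = make_table({"a1": {"A": 55}}, {"A": "ACGT"})
        assert compute_pavf(t).at["A", "a1"] == 1.0

    def test_zero_total_amplicon_excluded(self):
        t = make_table({"a1": {"A": 10}, "a2": {"A": 0}}, {"A": "ACGT"})
        pavf = compute_pavf(t)
        assert "a2" not in pavf.columns

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(5, 4))
        counts[0] += 1  # keep totals positive
        t = make_table(
            {
                f"a{j}": {f"v{i}": int(counts[i, j]) for i in range(5)}
                for j in range(4)
            },
            {f"v{i}": "ACGT" for i in range(5)},
        )
        pavf = compute_pavf(t)
        assert np.allclose(pavf.sum(axis=0), 1.0)


class TestChimeraDetection:
    def test_constructed_chimera_flagged(self):
        p1, p2 = "AAAAAAAA", "CCCCCCCC"
        v = "AAAACCCC"
        flags = detect_chimeras(
            {"p1": p1, "p2": p2, "v": v}, {"p1": 0.45, "p2": 0.45, "v": 0.10}
        )
        assert flags == {"v"}

    def test_identity_breakpoint_not_flagged(self):
        # v identical to a parent must never count as a chimera
        p1, p2 = "AAAAAAAA", "CCCCCCCC"
        flags = detect_chimeras(
            {"p1": p1, "p2": p2, "v": p1}, {"p1": 0.5, "p2": 0.4, "v": 0.1}
        )
        assert flags == set()

    def test_parents_must_have_higher_frequency(self):
        p1, p2 = "AAAAAAAA", "CCCCCCCC"
        v = "AAAACCCC"
        flags = detect_chimeras(
            {"p1": p1, "p2": p2, "v": v}, {"p1": 0.3, "p2": 0.3, "v": 0.4}
        )
        assert flags == set()

    def test_simulated_chimeras_recovered(self):
        cfg = SimulationConfig(seed=21, chimera_rate=0.05, error_rate=0.0,
                               contamination_rate=0.0)
        reg, truth, table = simulate_experiment(cfg)
        psets = primer_sets_for(cfg.n_loci)
        calls = filter_cascade(
            table,
            reg.founders,
            FilterConfig(max_expected_alleles={p: 2 * len(l) for p, l in psets.items()}),
        )
        chim_ids = {v for v, c in truth.artefact_class.items() if c == "chimera"}
        flagged = total = 0
        for c in calls:
            for v in chim_ids & (set(c.rejected) | set(c.called)):
                total += 1
                if c.rejected.get(v) in ("chimera", "low_pavf", "low_count"):
                    flagged += 1
        assert total > 0
        assert flagged / total >= 0.95


class TestPointArtefacts:
    def test_low_frequency_child_flagged(self):
        seqs = {"p": "ACGTACGT", "v": "ACGTACGA"}
        flags = detect_point_artefacts(seqs, {"p": 0.45, "v": 0.05}, FilterConfig())
        assert flags == {"v"}

    def test_codominant_pair_not_flagged(self):
        seqs = {"p": "ACGTACGT", "v": "ACGTACGA"}
        flags = detect_point_artefacts(seqs, {"p": 0.48, "v": 0.46}, FilterConfig())
        assert flags == set()

    def test_indel_child_flagged(self):
        seqs = {"p": "ACGTACGT", "v": "ACGACGT"}  # 1-nt deletion
        flags = detect_point_artefacts(seqs, {"p": 0.6, "v": 0.1}, FilterConfig())
        assert flags == {"v"}

    def test_simulated_point_errors_recovered_and_no_true_losses(self):
        cfg = SimulationConfig(seed=22, chimera_rate=0.0, error_rate=0.02,
                               contamination_rate=0.0)
        reg, truth, table = simulate_experiment(cfg)
        psets = primer_sets_for(cfg.n_loci)
        calls = filter_cascade(
            table,
            reg.founders,
            FilterConfig(max_expected_alleles={p: 2 * len(l) for p, l in psets.items()}),
        )
        err_ids = {v for v, c in truth.artefact_class.items() if c == "point_error"}
        flagged = total = 0
        for c in calls:
            for v in err_ids & (set(c.rejected) | set(c.called)):
                total += 1
                if v in c.rejected:
                    flagged += 1
        assert total > 0
        assert flagged / total >= 0.95
        acc = genotyping_accuracy(calls, truth, psets)
        assert acc["precision"] == 1.0  # no true allele mistaken for an artefact


class TestCrossAmpliconScreen:
    def _pavf(self):
        return pd.DataFrame(
            {"a": {"v": 0.02, "w": 0.98}, "b": {"v": 0.5, "w": 0.5}}
        )

    def test_low_frequency_elsewhere_called_variant_flagged(self):
        pavf = self._pavf()
        flags = cross_amplicon_screen(
            {"a": {"v", "w"}, "b": {"v", "w"}}, pavf, FilterConfig()
        )
        assert flags["a"] == {"v"}
        assert flags["b"] == set()

    def test_moderate_frequency_not_flagged(self):
        pavf = pd.DataFrame({"a": {"v": 0.30}, "b": {"v": 0.5}})
        flags = cross_amplicon_screen({"a": {"v"}, "b": {"v"}}, pavf, FilterConfig())
        assert flags["a"] == set()

    def test_simulated_contaminants_flagged(self):
        cfg = SimulationConfig(seed=23, contamination_rate=0.02)
        reg, truth, table = simulate_experiment(cfg)
        psets = primer_sets_for(cfg.n_loci)
        calls = filter_cascade(
            table,
            reg.founders,
            FilterConfig(max_expected_alleles={p: 2 * len(l) for p, l in psets.items()}),
        )
        by_amp = {c.amplicon: c for c in calls}
        occ = contaminated_occurrences(truth)
        assert occ
        flagged = sum(1 for v, amp in occ if v in by_amp[amp].rejected)
        assert flagged / len(occ) >= 0.90


class TestFilterCascade:
    def test_low_coverage_amplicon_discarded(self):
        t = make_table(
            {"a1": {"A": 99}, "a2": {"A": 500}}, {"A": "ACGTACGTACGT"}
        )
        calls = {c.amplicon: c for c in filter_cascade(t, ["ACGTACGTACGT"])}
        assert calls["a1"].status == "discarded_low_coverage"
        assert calls["a1"].called == []
        assert calls["a2"].called == ["A"]

    def test_low_max_count_variant_rejected(self):
        t = make_table(
            {"a1": {"A": 500, "B": 9}, "a2": {"A": 400, "B": 8}},
            {"A": "ACGTACGTACGT", "B": "ACGAACGTACGT"},
        )
        calls = {c.amplicon: c for c in filter_cascade(t, ["ACGTACGTACGT"])}
        assert calls["a1"].rejected["B"] == "low_count"
        assert calls["a2"].rejected["B"] == "low_count"

    def test_off_target_variant_rejected(self):
        t = make_table(
            {"a1": {"A": 500, "X": 400}},
            {"A": "ACGTACGTACGT", "X": "TTTTTTTTTTTT"},
        )
        calls = {c.amplicon: c for c in filter_cascade(t, ["ACGTACGTACGT"])}
        assert calls["a1"].rejected["X"] == "off_target"
        assert calls["a1"].called == ["A"]

    def test_every_occurrence_called_or_rejected(self, default_experiment, default_calls):
        _, _, _, table = default_experiment
        calls, _, _ = default_calls
        by_amp = {c.amplicon: c for c in calls}
        for amp in table.counts.columns:
            call = by_amp[amp]
            if call.status == "discarded_low_coverage":
                continue
            present = set(table.counts.index[table.counts[amp] > 0])
            assert present == set(call.called) | set(call.rejected)

    def test_raising_min_pavf_never_adds_calls(self, default_experiment):
        _, registry, _, table = default_experiment
        lo = filter_cascade(table, registry.founders, FilterConfig(min_pavf=0.01))
        hi = filter_cascade(table, registry.founders, FilterConfig(min_pavf=0.05))
        lo_by = {c.amplicon: set(c.called) for c in lo}
        for c in hi:
            assert set(c.called) <= lo_by[c.amplicon]

    def test_empty_table_rejected(self):
        t = make_table({"a1": {"A": 5}}, {"A": "ACGT"})
        t.counts = t.counts.iloc[0:0]
        with pytest.raises(ValueError):
            filter_cascade(t, ["ACGT"])

    def test_over_cap_marks_unclear(self):
        seqs = {f"v{i}": f"ACGTACGTACG{b}" for i, b in enumerate("ATCG")}
        t = make_table({"a1": {v: 300 for v in seqs}}, seqs)
        calls = filter_cascade(t, ["ACGTACGTACGA"], FilterConfig(max_expected_alleles=2))
        assert calls[0].status == "unclear"


class TestReplicates:
    def test_identical_sets_concordant(self, default_calls):
        calls, _, _ = default_calls
        # noise-free comparison on the called data itself: duplicated calls
        # are trivially concordant
        report = replicate_concordance(calls + calls)
        assert report.concordance == 1.0 or report.pairs_compared > 0

    def test_nine_outputs_give_36_comparisons(self):
        from amplimhc.genotyping import GenotypeCall

        calls = [
            GenotypeCall(amplicon=f"x{i}", individual="ind1", primer_set="PS1",
                         called=["A"])
            for i in range(9)
        ]
        report = replicate_concordance(calls)
        assert report.pairs_compared == 36
        assert report.concordance == 1.0

    def test_noise_free_simulation_fully_concordant(self):
        cfg = SimulationConfig(
            seed=24, chimera_rate=0, error_rate=0, contamination_rate=0,
            replicate_fraction=0.5,
        )
        reg, truth, table = simulate_experiment(cfg)
        psets = primer_sets_for(cfg.n_loci)
        calls = filter_cascade(
            table,
            reg.founders,
            FilterConfig(max_expected_alleles={p: 2 * len(l) for p, l in psets.items()}),
        )
        report = replicate_concordance(calls)
        assert report.pairs_compared > 0
        assert report.concordance == 1.0

    def test_differing_sets_listed(self):
        from amplimhc.genotyping import GenotypeCall

        a = GenotypeCall(amplicon="x1", individual="i", primer_set="PS1", called=["A"])
        b = GenotypeCall(amplicon="x2", individual="i", primer_set="PS1", called=["B"])
        report = replicate_concordance([a, b])
        assert report.concordance == 0.0
        assert report.diffs[0]["only_a"] == ["A"]
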