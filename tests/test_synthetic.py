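import numpy as np
import pandas as pd
import pytest
from scipy import stats

from denovotx import dating, orf_screen
from denovotx.phylo import branch_id
from denovotx.synthetic import (
    simulate_expression,
    simulate_junction_reads,
    simulate_orf_history,
)
from denovotx.splicing import JunctionRecord


class TestOrfHistory:
    def test_injected_shared_stop(self, tree3):
        history = simulate_orf_history(
            tree3, "human", 30,
            shared_disablers=[(("chimp", "rhesus"), 5, "premature_stop")],
            seed=0,
        )
        for species in ("chimp", "rhesus"):
            disablers = orf_screen.detect_disablers(history.alignments[species])
            assert any(
                d.focal_codon == 5 and d.kind == "premature_stop"
                for d in disablers
            )

    def test_root_birth_no_disablers(self, tree3):
        root = branch_id(tree3.leaves)
        history = simulate_orf_history(
            tree3, root, 30, shared_disablers=[], seed=0
        )
        # no out-groups exist: every species carries the intact ORF
        assert len(set(history.sequences.values())) == 1
        assert history.alignments  # in-group pairs only
        for aln in history.alignments.values():
            assert orf_screen.detect_disablers(aln) == []

    def test_ingroup_orf_intact(self, tree5):
        history = simulate_orf_history(
            tree5, branch_id({"human", "chimp"}), 40, seed=1
        )
        orf = history.sequences["human"]
        assert orf == history.sequences["chimp"]
        assert orf.startswith("ATG") and orf.endswith("TAA")
        internal = [orf[i:i + 3] for i in range(3, len(orf) - 3, 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in internal)

    def test_position_out_of_range_rejected(self, tree3):
        with pytest.raises(ValueError, match="out of range"):
            simulate_orf_history(
                tree3, "human", 20,
                shared_disablers=[(("rhesus",), 20, "premature_stop")],
                seed=0,
            )

    def test_bad_branch_rejected(self, tree3):
        with pytest.raises(ValueError, match="not a branch"):
            simulate_orf_history(tree3, "human,rhesus", 20, seed=0)

    def test_disabler_inside_birth_clade_rejected(self, tree5):
        with pytest.raises(ValueError, match="inside the birth clade"):
            simulate_orf_history(
                tree5, branch_id({"human", "chimp"}), 20,
                shared_disablers=[(("chimp",), 5, "premature_stop")],
                seed=0,
            )

    def test_seed_reproducible(self, tree5):
        a = simulate_orf_history(tree5, "human", 50, seed=9)
        b = simulate_orf_history(tree5, "human", 50, seed=9)
        assert a.sequences == b.sequences
        assert {k: (v.focal_seq, v.outgroup_seq)
                for k, v in a.alignments.items()} == {
            k: (v.focal_seq, v.outgroup_seq) for k, v in b.alignments.items()
        }

    def test_truth_recovery_pipeline(self, tree5):
        """dating + orf_screen recover the birth branch on noise-free
        replicates (spec demands >= 95%; exact recovery expected)."""
        rng = np.random.default_rng(123)
        candidate_branches = ["human", branch_id({"human", "chimp"})]
        recovered = 0
        n = 100
        for i in range(n):
            birth = candidate_branches[int(rng.integers(0, 2))]
            history = simulate_orf_history(
                tree5, birth, 60, seed=int(rng.integers(0, 2**31)),
                focal_species="human",
            )
            states = {"human": "present"}
            for species, aln in history.alignments.items():
                disablers = orf_screen.detect_disablers(aln)
                call = orf_screen.call_orf_status(aln, disablers)
                states[species] = call.status
            age = dating.assign_age(
                tree5, dating.PresenceProfile(entity="orf", states=states)
            )
            if age.status == "dated" and age.branch == birth:
                recovered += 1
        assert recovered / n >= 0.95

    def test_shared_disabler_sets_recovered(self, tree5):
        """Injected species-sets are recovered exactly, noise-free."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            codon = int(rng.integers(2, 25))
            injected = frozenset({"rhesus", "mouse", "dog"})
            history = simulate_orf_history(
                tree5, "human", 50,
                shared_disablers=[(tuple(injected), codon, "premature_stop")],
                seed=int(rng.integers(0, 2**31)),
            )
            calls = []
            for species, aln in history.alignments.items():
                disablers = orf_screen.detect_disablers(aln)
                calls.append(orf_screen.call_orf_status(aln, disablers))
            shared = orf_screen.shared_ancestral_disablers(calls)
            at_site = [s for s in shared if s.focal_codon == codon
                       and s.kind == "premature_stop"]
            assert len(at_site) == 1
            assert at_site[0].species >= injected


LIBS = {t: 20_000_000 for t in ("a", "b", "c", "d", "e", "f", "g")}


class TestExpression:
    def test_degenerate_rho_one_identical_proportions(self):
        focal, outgroup, truth = simulate_expression(
            20, list(LIBS), rho=1.0, lam=1.0, dispersion=0.0,
            library_sizes=LIBS, seed=0, mean_total_rpkm=200.0,
        )
        latent_f, latent_o = truth.latent_profiles
        assert np.allclose(latent_f, latent_o, atol=1e-6)
        # observed RPKM agrees up to Poisson noise
        rs = [
            stats.spearmanr(focal.rpkm.loc[g], outgroup.rpkm.loc[g]).statistic
            for g in focal.genes
        ]
        assert np.mean(rs) > 0.9

    def test_rho_zero_mean_correlation_near_zero(self):
        focal, outgroup, _ = simulate_expression(
            500, list(LIBS), rho=0.0, lam=1.0, dispersion=0.01,
            library_sizes=LIBS, seed=1, mean_total_rpkm=100.0,
        )
        rs = [
            stats.spearmanr(focal.rpkm.loc[g], outgroup.rpkm.loc[g]).statistic
            for g in focal.genes
        ]
        assert abs(np.nanmean(rs)) < 0.1

    def test_amplification_factor(self):
        focal, outgroup, _ = simulate_expression(
            500, list(LIBS), rho=0.5, lam=2.0, dispersion=0.1,
            library_sizes=LIBS, seed=2,
        )
        totals_f = focal.rpkm.sum(axis=1)
        totals_o = outgroup.rpkm.sum(axis=1)
        ratio = (totals_f / totals_o).replace([np.inf], np.nan).dropna()
        assert 1.7 <= ratio.mean() <= 2.3

    def test_rpkm_recomputable_from_counts(self):
        focal, _, _ = simulate_expression(
            10, ["a", "b", "c"], rho=0.5, lam=1.0, dispersion=0.1,
            library_sizes={"a": 10**7, "b": 2 * 10**7, "c": 10**7},
            seed=3, region_length=500,
        )
        recomputed = (
            focal.counts / (500 / 1000)
        ).div(focal.library_sizes / 1e6, axis=1)
        assert np.allclose(recomputed.values, focal.rpkm.values)

    def test_reproducible(self):
        a = simulate_expression(5, ["a", "b", "c"], 0.5, 1.5, 0.1,
                                {"a": 10**7, "b": 10**7, "c": 10**7}, seed=4)
        b = simulate_expression(5, ["a", "b", "c"], 0.5, 1.5, 0.1,
                                {"a": 10**7, "b": 10**7, "c": 10**7}, seed=4)
        assert a[0].rpkm.equals(b[0].rpkm)
        assert a[1].rpkm.equals(b[1].rpkm)

    def test_bad_library_size_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(5, ["a", "b"], 0.5, 1.0, 0.1,
                                {"a": 0, "b": 10**7}, seed=0)

    def test_bad_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(5, ["a", "b"], 1.5, 1.0, 0.1,
                                {"a": 10**7, "b": 10**7}, seed=0)


def _templates(n):
    return [
        JunctionRecord("chr1", 1000 * (i + 1), 1000 * (i + 1) + 300, "+")
        for i in range(n)
    ]


class TestJunctionReads:
    def test_no_strand_error_all_correct(self):
        table, _ = simulate_junction_reads(_templates(20), depth=10,
                                           strand_error=0.0, seed=0)
        assert (table["mislabeled_reads"] == 0).all()
        assert (table["correct_strand_reads"] == table["spanning_reads"]).all()

    def test_tiny_depth_zero_read_junctions(self):
        table, _ = simulate_junction_reads(_templates(5), depth=1e-4, seed=0)
        assert (table["spanning_reads"] == 0).any()

    def test_strand_error_ratio_exceeds_qc_bar(self):
        table, _ = simulate_junction_reads(
            _templates(200), depth=1000, strand_error=0.005, seed=1
        )
        correct = table["correct_strand_reads"].sum()
        mislabeled = table["mislabeled_reads"].sum()
        ratio = correct / mislabeled
        assert 150 < ratio < 260  # ~199:1 expected
        assert ratio > 100  # the QC acceptance bar

    def test_poisson_mean(self):
        table, _ = simulate_junction_reads(_templates(500), depth=10, seed=2)
        assert table["spanning_reads"].mean() == pytest.approx(10, rel=0.1)

    def test_coverage_tracks_emitted(self):
        table, tracks = simulate_junction_reads(_templates(3), depth=5, seed=3)
        assert len(tracks) == 3
        for name in table["junction"]:
            assert tracks[name].shape == (40,)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            simulate_junction_reads(_templates(1), depth=0, seed=0)
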