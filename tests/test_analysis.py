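"""Mixture-of-PWMs clustering, QC, library comparison, promiscuity and the
8-mer specificity pipeline, checked against brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from zfhelix.analysis import (
    ClusterModel,
    EightMerTable,
    PwmCluster,
    filter_8mer_reads,
    fit_pwm_mixture,
    library_distance,
    plasmid_entropy,
    promiscuity_entropy,
    selection_qc,
    write_meme,
)
from zfhelix.types import AMINO_ACIDS, BASES, InputError


def draw_from_pwm(pwm, n, rng, alphabet=AMINO_ACIDS):
    out = []
    for _ in range(n):
        out.append(
            "".join(
                alphabet[rng.choice(len(alphabet), p=row)] for row in pwm
            )
        )
    return out


def planted_pwms(rng, L=6, A=20, peak=0.95):
    """Two well-separated peaky PWMs."""
    pwms = []
    for comp in range(2):
        pwm = np.full((L, A), (1 - peak) / (A - 1))
        for pos in range(L):
            pwm[pos, (comp * 7 + pos * 3) % A] = peak
        pwms.append(pwm)
    return pwms


class TestMixture:
    def test_k1_equals_weighted_frequency_matrix(self):
        """A single-component fit is the weighted PFM with pseudocounts."""
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(30)]
        w = rng.integers(1, 20, 30).astype(float)
        model = fit_pwm_mixture(seqs, w, k=1, n_restarts=1)
        counts = np.full((6, 20), 0.5)
        for s, wi in zip(seqs, w):
            for pos, aa in enumerate(s):
                counts[pos, AMINO_ACIDS.index(aa)] += wi
        expected = counts / counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(model.clusters[0].pwm, expected, atol=1e-9)

    def test_recovers_planted_components(self):
        rng = np.random.default_rng(1)
        pwms = planted_pwms(rng)
        seqs = draw_from_pwm(pwms[0], 500, rng) + draw_from_pwm(pwms[1], 500, rng)
        labels = np.array([0] * 500 + [1] * 500)
        model = fit_pwm_mixture(seqs, k=2, n_restarts=5, seed=3)
        # match components to planted PWMs by best TV
        perm = (
            (0, 1)
            if np.abs(model.clusters[0].pwm - pwms[0]).sum()
            < np.abs(model.clusters[1].pwm - pwms[0]).sum()
            else (1, 0)
        )
        for planted, fitted in zip(pwms, perm):
            tv = 0.5 * np.abs(model.clusters[fitted].pwm - planted).sum(axis=1)
            assert tv.max() < 0.05
        hard = model.assignments
        mapped = np.array([perm.index(h) if h in perm else h for h in hard])
        assert (mapped == labels).mean() >= 0.95

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(40)]
        a = fit_pwm_mixture(seqs, k=2, n_restarts=3, seed=9)
        b = fit_pwm_mixture(seqs, k=2, n_restarts=3, seed=9)
        for ca, cb in zip(a.clusters, b.clusters):
            np.testing.assert_array_equal(ca.pwm, cb.pwm)

    def test_objective_monotone(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            seqs = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(40)]
            model = fit_pwm_mixture(seqs, k=2, n_restarts=1, seed=trial)
            diffs = np.diff(model.log_likelihood_trace)
            assert (diffs >= -1e-7).all()

    def test_errors(self):
        with pytest.raises(InputError):
            fit_pwm_mixture([], k=1)
        with pytest.raises(InputError):
            fit_pwm_mixture(["AAAAAA"], k=2)

    def test_auto_k_prefers_two_for_separated_data(self):
        rng = np.random.default_rng(4)
        pwms = planted_pwms(rng, peak=0.95)
        seqs = draw_from_pwm(pwms[0], 100, rng) + draw_from_pwm(pwms[1], 100, rng)
        model = fit_pwm_mixture(seqs, k="auto", n_restarts=3, seed=0, max_k=3)
        assert model.k >= 2


def make_cluster(pwm):
    pwm = np.asarray(pwm, dtype=float)
    return ClusterModel(
        clusters=[PwmCluster(pwm=pwm, weight=1.0, alphabet=AMINO_ACIDS)],
        responsibilities=np.ones((1, 1)),
        log_likelihood_trace=[0.0],
        sequences=["AAAAAA"],
        weights=np.ones(1),
    )


class TestSelectionQc:
    def test_deterministic_column_passes_with_max_ic(self):
        pwm = np.full((6, 20), 1 / 20)
        pwm[2] = 0.0
        pwm[2, 0] = 1.0
        result = selection_qc(make_cluster(pwm))
        assert result.passed
        assert result.max_information_content == pytest.approx(math.log2(20))

    def test_uniform_pwm_fails(self):
        result = selection_qc(make_cluster(np.full((6, 20), 1 / 20)))
        assert not result.passed
        assert result.max_information_content == pytest.approx(0.0, abs=1e-9)

    def test_two_equiprobable_residues_pass(self):
        pwm = np.full((6, 20), 1 / 20)
        pwm[0] = 0.0
        pwm[0, :2] = 0.5  # entropy 1 bit <= 2
        assert selection_qc(make_cluster(pwm)).passed

    def test_threshold_equivalence(self):
        """entropy <= 2 bits at a position iff information content >=
        log2(20) - 2 bits there."""
        pwm = np.full((6, 20), 1 / 20)
        pwm[3] = 0.0
        pwm[3, :4] = 0.25  # exactly 2 bits
        cluster = make_cluster(pwm).clusters[0]
        assert selection_qc(make_cluster(pwm)).passed
        assert cluster.max_information_content == pytest.approx(math.log2(20) - 2)


class TestLibraryDistance:
    def test_identical_sets_zero(self):
        assert library_distance(["AAAAAA", "CCCCCC"], ["AAAAAA", "CCCCCC"]).distance == 0.0

    def test_single_substitution(self):
        cmp = library_distance(["AAAAAA"], ["AAAAAC"])
        assert cmp.distance == pytest.approx(1 / 6)

    def test_pooled_mean_of_minima(self):
        cmp = library_distance(["AAAAAA", "CCCCCC"], ["AAAAAA"])
        assert cmp.distance == pytest.approx(1 / 3)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        a = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(30)]
        b = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(25)]
        a, b = sorted(set(a)), sorted(set(b))
        mins = []
        for x, other in ((a, b), (b, a)):
            for s in x:
                mins.append(
                    min(
                        sum(c1 != c2 for c1, c2 in zip(s, t)) / 6 for t in other
                    )
                )
        assert library_distance(a, b).distance == pytest.approx(
            float(np.mean(mins)), abs=1e-12
        )

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(6)
        a = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(10)]
        b = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(12)]
        d_ab = library_distance(a, b).distance
        d_ba = library_distance(b, a).distance
        assert 0.0 <= d_ab <= 1.0
        assert d_ab == pytest.approx(d_ba)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            library_distance([], ["AAAAAA"])


class TestPromiscuity:
    def test_specific_core_is_zero_bits(self):
        scores = promiscuity_entropy({"RDHT": ["GCA", "GCA", "GCA"]})
        assert scores["GCA"].entropy_bits == pytest.approx(0.0)

    def test_uniform_recovery_is_six_bits(self):
        from itertools import product

        all_3mers = ["".join(p) for p in product(BASES, repeat=3)]
        scores = promiscuity_entropy({"RDHT": all_3mers})
        for s in scores.values():
            assert s.entropy_bits == pytest.approx(6.0)

    def test_two_targets_one_bit(self):
        scores = promiscuity_entropy({"RDHT": ["ACG", "ACT"]})
        assert scores["ACG"].entropy_bits == pytest.approx(1.0)
        assert scores["ACT"].entropy_bits == pytest.approx(1.0)


class TestEightMer:
    def background(self, kmers):
        return {k: 100 for k in kmers}

    def test_low_read_8mer_removed(self):
        table = EightMerTable(
            counts={"AAAAAAAA": {"p1": 5, "p2": 4}, "CCCCCCCC": {"p1": 6, "p2": 6}},
            background=self.background(["AAAAAAAA", "CCCCCCCC"]),
        )
        result = filter_8mer_reads(table, n_restarts=2, k=1)
        assert result.dropped["AAAAAAAA"] == "reads"
        assert "CCCCCCCC" in result.weights

    def test_single_plasmid_removed(self):
        table = EightMerTable(
            counts={"AAAAAAAA": {"p1": 60}, "CCCCCCCC": {"p1": 6, "p2": 6}},
            background=self.background(["AAAAAAAA", "CCCCCCCC"]),
        )
        result = filter_8mer_reads(table, n_restarts=2, k=1)
        assert result.dropped["AAAAAAAA"] == "single-plasmid"

    def test_escapee_plasmid_dropped_then_reads_reapplied(self):
        """A heavily skewed plasmid distribution (normalized entropy below
        0.1) loses its dominant plasmid; if the remainder falls below ten
        reads the 8-mer is dropped."""
        skewed = {"p1": 990, "p2": 1, "p3": 1}
        assert plasmid_entropy(skewed) < 0.1
        table = EightMerTable(
            counts={"AAAAAAAA": skewed, "CCCCCCCC": {"p1": 6, "p2": 6}},
            background=self.background(["AAAAAAAA", "CCCCCCCC"]),
        )
        result = filter_8mer_reads(table, n_restarts=2, k=1)
        assert result.dropped["AAAAAAAA"] == "reads-after-escapee-drop"
        # without re-application the 8-mer survives with the residual reads
        relaxed = filter_8mer_reads(
            table, reapply_reads_filter=False, n_restarts=2, k=1
        )
        assert "AAAAAAAA" in relaxed.weights
        assert relaxed.weights["AAAAAAAA"] == pytest.approx(2 / (100 / 200))

    def test_moderately_skewed_plasmids_kept(self):
        """98/2 across two plasmids has normalized entropy above 0.1 under
        the bits-per-log2(n-plasmids) convention and keeps all reads."""
        counts = {"p1": 98, "p2": 2}
        assert plasmid_entropy(counts) > 0.1
        table = EightMerTable(
            counts={"AAAAAAAA": counts, "CCCCCCCC": {"p1": 6, "p2": 6}},
            background=self.background(["AAAAAAAA", "CCCCCCCC"]),
        )
        result = filter_8mer_reads(table, n_restarts=2, k=1)
        assert result.weights["AAAAAAAA"] == pytest.approx(100 / (100 / 200))

    def test_missing_background_is_error(self):
        table = EightMerTable(
            counts={"AAAAAAAA": {"p1": 6, "p2": 6}}, background={"CCCCCCCC": 10}
        )
        with pytest.raises(InputError, match="AAAAAAAA"):
            filter_8mer_reads(table, n_restarts=2, k=1)

    def test_two_motif_clustering_and_meme_export(self, tmp_path):
        rng = np.random.default_rng(7)
        kmers = {}
        for base in "AC":
            for _ in range(12):
                k = "".join(
                    rng.choice(list(BASES), 8, p=[0.7 if b == base else 0.1 for b in BASES])
                )
                kmers[k] = {"p1": 30, "p2": 30}
        table = EightMerTable(counts=kmers, background=self.background(kmers))
        result = filter_8mer_reads(table, k=2, n_restarts=3, seed=0)
        assert result.model.k == 2
        out = tmp_path / "motifs.meme"
        write_meme(result.model, out, name_prefix="motif")
        text = out.read_text()
        assert "MEME version 4" in text
        assert text.count("MOTIF") == 2
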